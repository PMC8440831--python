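"""Monte-Carlo propagation of operator variability into joint kinematics.

Pipeline: deviations of each operator's model from the per-subject baseline
(the average model) are pooled over vertebral levels and subjects into 15
component/parameter/direction groups; a Gaussian kernel density estimate is
fitted per group; each Monte-Carlo iteration draws one value per parameter
from its group's sampler, perturbs the baseline model, re-runs inverse
kinematics of the same trial, and records the time-normalized joint-angle
curves relative to the baseline solution. The simulation stops when the
running mean and SD of every output variable (each of the 51 joint angles
averaged over the motion) are stable over the last 10% of iterations, and
is summarized as pointwise 5-95% confidence bands, box statistics at the
time of maximal variance, and a 294 x 51 grid of Pearson sensitivity
factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import (
    N_JOINTS,
    N_PARAMETERS,
    ParameterVector,
    SpineModel,
    apply_perturbation,
    average_models,
    joint_angle_labels,
    model_to_vector,
)
from .pipeline import (
    IKConvergenceError,
    MotionTrial,
    normalize_series,
    smooth_series,
    solve_ik,
)

#: pooled groups: markers have positions only
GROUP_KEYS = [("marker", "position", d) for d in "xyz"] + \
    [(c, p, d) for c in ("body", "joint")
     for p in ("position", "orientation") for d in "xyz"]


# ---------------------------------------------------------------------------
# deviation pooling and summary
# ---------------------------------------------------------------------------

@dataclass
class DeviationPool:
    """Signed operator-minus-baseline deviations per pooled group.

    ``groups`` maps (component, parameter, direction) to a 1-D array pooled
    over vertebral levels, operators and subjects. ``marker_vectors`` keeps
    the per-marker 3-D deviation vectors for Euclidean-distance summaries.
    """

    groups: dict
    marker_vectors: np.ndarray
    n_subjects: int
    n_operators: int

    def group(self, component, parameter, direction) -> np.ndarray:
        return self.groups[(component, parameter, direction)]


def pool_deviations(operator_models, baselines=None) -> DeviationPool:
    """Pool signed deviations of operator models from per-subject baselines.

    ``operator_models``: list over subjects of lists of operator variants.
    ``baselines``: matching list of baseline models; computed with
    :func:`average_models` when omitted.
    """
    if baselines is None:
        baselines = [average_models(ops) for ops in operator_models]
    if len(baselines) != len(operator_models):
        raise ValueError("need one baseline per subject")
    groups = {key: [] for key in GROUP_KEYS}
    marker_vecs = []
    n_ops = None
    for ops, base in zip(operator_models, baselines):
        if len(ops) < 2:
            raise ValueError("each subject needs >= 2 operator models")
        n_ops = len(ops) if n_ops is None else n_ops
        layout = ParameterVector.layout(base.marker_names)
        for op in ops:
            vec = model_to_vector(op, base)
            df = layout.assign(value=vec.values)
            for key in GROUP_KEYS:
                c, p, d = key
                sel = (df["component"] == c) & (df["parameter"] == p) & \
                    (df["direction"] == d)
                groups[key].append(df.loc[sel, "value"].to_numpy())
            marker_vecs.append(vec.marker_deltas)
    return DeviationPool(
        groups={k: np.concatenate(v) for k, v in groups.items()},
        marker_vectors=np.concatenate(marker_vecs, axis=0),
        n_subjects=len(operator_models), n_operators=n_ops)


@dataclass
class DeviationSummary:
    """Median and maximum absolute deviation per group (Table-3 shape)."""

    table: pd.DataFrame
    marker_distance_median: float
    marker_distance_max: float


def summarize_deviations(pool: DeviationPool) -> DeviationSummary:
    """Median (max) absolute deviations per group + marker 3-D distance."""
    rows = []
    for (c, p, d), vals in pool.groups.items():
        if vals.size == 0:
            raise ValueError(f"empty deviation group {(c, p, d)}")
        a = np.abs(vals)
        rows.append({"component": c, "parameter": p, "direction": d,
                     "median": float(np.median(a)), "max": float(a.max()),
                     "n": int(a.size),
                     "units": "mm" if p == "position" else "deg"})
    dist = np.linalg.norm(pool.marker_vectors, axis=1)
    return DeviationSummary(pd.DataFrame(rows),
                            float(np.median(dist)), float(dist.max()))


# ---------------------------------------------------------------------------
# kernel density perturbation sampling
# ---------------------------------------------------------------------------

class KDESampler:
    """Gaussian-kernel density sampler over one pooled deviation group.

    Sampling picks a source sample uniformly and adds kernel noise of the
    Silverman bandwidth; with identical samples and the default zero
    bandwidth floor the sampler is exactly degenerate at that value.
    """

    def __init__(self, samples, bandwidth_floor: float = 0.0):
        self.samples = np.asarray(samples, dtype=float).reshape(-1)
        if self.samples.size < 5:
            raise ValueError(
                "need >= 5 samples per group to fit a KDE; supply spreads "
                "directly via OperatorVariabilitySpec instead")
        sd = float(np.std(self.samples, ddof=1))
        iqr = float(np.subtract(*np.percentile(self.samples, [75, 25])))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        self.bandwidth = max(0.9 * spread * self.samples.size ** (-0.2),
                             bandwidth_floor)

    def sample(self, rng, size: int) -> np.ndarray:
        idx = rng.integers(0, self.samples.size, size=size)
        out = self.samples[idx]
        if self.bandwidth > 0:
            out = out + self.bandwidth * rng.standard_normal(size)
        return out

    def pdf(self, x) -> np.ndarray:
        """Evaluate the KDE density (integrates to 1)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        h = self.bandwidth if self.bandwidth > 0 else 1e-12
        z = (x[:, None] - self.samples[None, :]) / h
        return np.exp(-0.5 * z * z).sum(axis=1) / (
            self.samples.size * h * math.sqrt(2.0 * math.pi))


@dataclass
class PerturbationDistributions:
    """One KDE sampler per pooled deviation group."""

    samplers: dict

    def sampler(self, component, parameter, direction) -> KDESampler:
        return self.samplers[(component, parameter, direction)]

    def bandwidths(self) -> dict:
        return {k: s.bandwidth for k, s in self.samplers.items()}

    def sample_counts(self) -> dict:
        return {k: s.samples.size for k, s in self.samplers.items()}


def fit_kde(pool: DeviationPool,
            bandwidth_floor: float = 0.0) -> PerturbationDistributions:
    """Fit a Gaussian KDE (Silverman bandwidth) to every pooled group.

    KDEs are fitted on the *signed* deviations so sampled perturbations go
    in both directions; absolute values are used only for the Table-3-style
    summary.
    """
    return PerturbationDistributions(
        {k: KDESampler(v, bandwidth_floor) for k, v in pool.groups.items()})


def sample_parameter_vector(dists: PerturbationDistributions,
                            marker_names, rng) -> ParameterVector:
    """Draw one 294-entry perturbation, one value per scalar parameter.

    Draws are independent across parameters; each entry comes from its
    component/parameter/direction group's sampler.
    """
    layout = ParameterVector.layout(marker_names)
    values = np.empty(N_PARAMETERS)
    for key in GROUP_KEYS:
        c, p, d = key
        sel = ((layout["component"] == c) & (layout["parameter"] == p) &
               (layout["direction"] == d)).to_numpy()
        values[sel] = dists.samplers[key].sample(rng, int(sel.sum()))
    return ParameterVector(values, list(marker_names))


# ---------------------------------------------------------------------------
# convergence criterion
# ---------------------------------------------------------------------------

def _stable_at(history, n, window_frac, tol, abs_floor, floor_below):
    """Are all running means/SDs over the last window within tolerance of
    their values at iteration n?"""
    w = max(2, math.ceil(window_frac * n))
    if n - w + 1 < 2:
        return False
    counts = np.arange(1, n + 1, dtype=float)[:, None]
    h = history[:n]
    csum = np.cumsum(h, axis=0)
    csum2 = np.cumsum(h * h, axis=0)
    means = csum / counts
    var = np.maximum(csum2 - counts * means ** 2, 0.0)
    var[1:] /= (counts[1:] - 1.0)
    var[0] = np.nan
    sds = np.sqrt(var)
    lo = n - w
    for ref, run in ((means[n - 1], means[lo:n]),
                     (sds[n - 1], sds[lo:n])):
        tol_abs = np.where(np.abs(ref) < floor_below, abs_floor,
                           tol * np.abs(ref))
        if np.any(np.abs(run - ref) > tol_abs):
            return False
    return True


def check_convergence(history, window_frac: float = 0.1, tol: float = 0.02,
                      min_iter: int = 100, abs_floor: float = 0.01,
                      floor_below: float = 0.5):
    """First iteration count n at which the simulation has converged.

    At candidate n, the running mean and SD of every output variable over
    the last ``window_frac`` of iterations must be within ``tol`` (relative)
    of their values at n; an absolute tolerance ``abs_floor`` replaces the
    relative test when the reference magnitude is below ``floor_below``
    (the relative criterion is ill-posed near zero). Returns None when no
    n in [min_iter, len(history)] converges.
    """
    h = np.asarray(history, dtype=float)
    if h.ndim == 1:
        h = h[:, None]
    for n in range(max(min_iter, 2), h.shape[0] + 1):
        if _stable_at(h, n, window_frac, tol, abs_floor, floor_below):
            return n
    return None


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass
class MonteCarloSettings:
    max_iter: int = 1000
    min_iter: int = 100
    window_frac: float = 0.1
    tol: float = 0.02
    seed: int = 0
    smooth_width: int = 3
    max_failed_frac: float = 0.05


@dataclass
class MonteCarloResult:
    """Everything one Monte-Carlo run produced.

    ``relative_curves``: (n, 51, 100) joint angles minus the baseline
    solution, on the normalized time axis, degrees. ``draws``: (n, 294)
    sampled perturbations. ``output_history``: (n, 51) motion-averaged
    joint angles used by the convergence criterion.
    """

    n_iterations: int
    converged_n: object
    draws: np.ndarray
    relative_curves: np.ndarray
    output_history: np.ndarray
    baseline_curves: np.ndarray
    t_percent: np.ndarray
    channel_names: list = field(default_factory=joint_angle_labels)
    settings: MonteCarloSettings = None

    def bands(self) -> np.ndarray:
        return confidence_bands(self.relative_curves)

    def box_stats(self) -> pd.DataFrame:
        return t_sigma_max_stats(self.relative_curves,
                                 channel_names=self.channel_names)

    def sensitivity(self, marker_names):
        return sensitivity_factors(self.draws, self.relative_curves,
                                   marker_names=marker_names)


def _normalized_angles(spine_model, trial, weights, smooth_width):
    series = solve_ik(spine_model, trial, weights=weights)
    series = normalize_series(series, 100)
    if smooth_width and smooth_width > 1:
        series = smooth_series(series, smooth_width)
    return series.angles


def run_monte_carlo(baseline: SpineModel, dists: PerturbationDistributions,
                    trial: MotionTrial,
                    settings: MonteCarloSettings = None,
                    weights=None) -> MonteCarloResult:
    """Sample perturbed models and propagate them through inverse kinematics.

    Per iteration: draw a 294-entry perturbation, apply it to the baseline
    model, solve IK on the (same) trial, time-normalize to 100 frames,
    smooth, and store the joint-angle curves relative to the baseline
    solution. Stops at the first n passing the convergence criterion (or at
    ``max_iter``). Fully reproducible given ``settings.seed``.
    """
    settings = settings or MonteCarloSettings()
    rng = np.random.default_rng(settings.seed)
    base_curves = _normalized_angles(baseline, trial, weights,
                                     settings.smooth_width)
    n_max = settings.max_iter
    draws = np.empty((n_max, N_PARAMETERS))
    rel = np.empty((n_max, 3 * N_JOINTS, 100))
    outputs = np.empty((n_max, 3 * N_JOINTS))
    failed = 0
    n_done = 0
    converged_n = None
    for i in range(n_max):
        vec = sample_parameter_vector(dists, baseline.marker_names, rng)
        try:
            curves = _normalized_angles(apply_perturbation(baseline, vec),
                                        trial, weights, settings.smooth_width)
        except IKConvergenceError:
            failed += 1
            if failed > settings.max_failed_frac * max(i + 1, 1):
                raise IKConvergenceError(
                    f"{failed} of {i + 1} Monte-Carlo iterations failed "
                    "inverse kinematics")
            continue
        draws[n_done] = vec.values
        rel[n_done] = (curves - base_curves).T
        outputs[n_done] = curves.mean(axis=0)
        n_done += 1
        if n_done >= settings.min_iter and _stable_at(
                outputs, n_done, settings.window_frac, settings.tol,
                abs_floor=0.01, floor_below=0.5):
            converged_n = n_done
            break
    return MonteCarloResult(
        n_iterations=n_done, converged_n=converged_n,
        draws=draws[:n_done].copy(), relative_curves=rel[:n_done].copy(),
        output_history=outputs[:n_done].copy(),
        baseline_curves=base_curves.T.copy(),
        t_percent=np.linspace(0.0, 100.0, 100), settings=settings)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def confidence_bands(relative_curves, low: float = 5.0,
                     high: float = 95.0) -> np.ndarray:
    """Pointwise percentile bands across iterations, (51, 100, 2).

    Percentiles use linear interpolation between order statistics.
    """
    rc = np.asarray(relative_curves, dtype=float)
    bands = np.percentile(rc, [low, high], axis=0)
    return np.moveaxis(bands, 0, -1)


def t_sigma_max_stats(relative_curves, channel_names=None) -> pd.DataFrame:
    """Box statistics at each DOF's time of maximal across-iteration
    variance (ties broken to the earliest frame)."""
    rc = np.asarray(relative_curves, dtype=float)
    if rc.shape[0] < 5:
        raise ValueError("need >= 5 iterations")
    var = rc.var(axis=0)                       # (51, 100)
    t_idx = var.argmax(axis=1)                 # earliest max per DOF
    names = channel_names or joint_angle_labels()
    rows = []
    for d, ti in enumerate(t_idx):
        vals = rc[:, d, ti]
        q25, q50, q75 = np.percentile(vals, [25, 50, 75])
        rows.append({"channel": names[d], "t_sigma_max": int(ti),
                     "min": float(vals.min()), "q25": float(q25),
                     "median": float(q50), "q75": float(q75),
                     "max": float(vals.max())})
    return pd.DataFrame(rows)


def sensitivity_factors(draws, relative_curves, marker_names=None,
                        magnitude: bool = True):
    """Pearson correlations between perturbation draws and output deviations.

    The output per DOF is the maximum over normalized time of the absolute
    relative joint-angle curve. By default the *magnitude* of each draw is
    correlated with that output: for zero-mean symmetric perturbations the
    response magnitude is even in the draw, so the signed correlation is
    identically zero by symmetry and carries no sensitivity information;
    the magnitude-to-magnitude association is the quantity the factor is
    meant to capture (``magnitude=False`` gives the signed variant).
    Returns (r, defined) where r is (294, 51) and ``defined`` flags cells
    whose correlation exists (zero-variance inputs or outputs are reported
    as r = 0, flagged False).
    """
    x = np.asarray(draws, dtype=float)
    if magnitude:
        x = np.abs(x)
    rc = np.asarray(relative_curves, dtype=float)
    if x.shape[0] != rc.shape[0]:
        raise ValueError("draws and curves must align on iterations")
    y = np.abs(rc).max(axis=2)                 # (n, 51)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc * xc).sum(axis=0))
    sy = np.sqrt((yc * yc).sum(axis=0))
    defined = (sx[:, None] > 0) & (sy[None, :] > 0)
    denom = np.where(defined, sx[:, None] * sy[None, :], 1.0)
    r = (xc.T @ yc) / denom
    r = np.where(defined, r, 0.0)
    return r, defined


def sensitivity_frame(r, defined, marker_names) -> pd.DataFrame:
    """Label the 294 x 51 sensitivity grid with parameter and channel tags."""
    layout = ParameterVector.layout(marker_names)
    df = pd.DataFrame(r, columns=joint_angle_labels())
    return pd.concat([layout, df], axis=1)
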