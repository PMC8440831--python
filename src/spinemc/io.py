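"""File formats: TRC marker trajectories, MOT/STO joint kinematics, JSON
model serialization, YAML settings and the run manifest."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import (
    BodySegment,
    ModelStructureError,
    SphericalJoint,
    SpineModel,
    VirtualMarker,
)
from .pipeline import BASE_LABELS, JointKinematicsSeries, MotionTrial

MODEL_SCHEMA_VERSION = "1.0"


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# TRC
# ---------------------------------------------------------------------------

_TRC_UNIT_SCALE = {"mm": 1.0, "m": 1000.0, "cm": 10.0}


def read_trc(path) -> MotionTrial:
    """Read a tab-delimited TRC marker trajectory file.

    Positions are normalized to mm; blank cells become masked samples.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path}: truncated TRC header")
    keys = lines[1].split("\t")
    vals = lines[2].split("\t")
    header = dict(zip(keys, vals))
    try:
        rate = float(header["DataRate"])
        n_frames = int(header["NumFrames"])
        n_markers = int(header["NumMarkers"])
        units = header.get("Units", "mm")
    except (KeyError, ValueError) as e:
        raise ParseError(f"{path}: malformed TRC header line 3: {e}") from None
    if units not in _TRC_UNIT_SCALE:
        raise ParseError(f"{path}: unknown units {units!r}")
    scale = _TRC_UNIT_SCALE[units]

    label_cells = lines[3].rstrip("\n").split("\t")
    names = [c for c in label_cells[2:] if c.strip()]
    if len(names) != n_markers:
        raise ParseError(
            f"{path}: line 4 declares {len(names)} marker names but header "
            f"says NumMarkers={n_markers}")

    positions = np.full((n_frames, n_markers, 3), np.nan)
    data_lines = [ln for ln in lines[5:] if ln.strip()]
    if len(data_lines) != n_frames:
        raise ParseError(
            f"{path}: expected {n_frames} data rows, found {len(data_lines)}")
    for r, ln in enumerate(data_lines):
        cells = ln.split("\t")
        expected = 2 + 3 * n_markers
        if len(cells) < expected:
            cells = cells + [""] * (expected - len(cells))
        for m in range(n_markers):
            triple = cells[2 + 3 * m:5 + 3 * m]
            if any(c.strip() == "" for c in triple):
                continue
            try:
                positions[r, m] = [float(c) for c in triple]
            except ValueError:
                raise ParseError(
                    f"{path}: bad value in frame {r + 1}, marker "
                    f"{names[m]}") from None
    if not np.isfinite(positions[-1]).any():
        raise ParseError(f"{path}: truncated final row (frame {n_frames})")
    return MotionTrial(names, positions * scale, rate)


def write_trc(path, trial: MotionTrial):
    path = Path(path)
    n, m = trial.n_frames, len(trial.marker_names)
    rows = []
    rows.append(f"PathFileType\t4\t(X/Y/Z)\t{path.name}")
    rows.append("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames")
    rows.append(f"{trial.rate:g}\t{trial.rate:g}\t{n}\t{m}\tmm\t"
                f"{trial.rate:g}\t1\t{n}")
    labels = "Frame#\tTime"
    for name in trial.marker_names:
        labels += f"\t{name}\t\t"
    rows.append(labels)
    axes = "\t"
    for i in range(1, m + 1):
        axes += f"\tX{i}\tY{i}\tZ{i}"
    rows.append(axes)
    times = trial.times
    for f in range(n):
        cells = [str(f + 1), f"{times[f]:.5f}"]
        for k in range(m):
            if trial.mask[f, k]:
                cells.extend(f"{v:.6f}" for v in trial.positions[f, k])
            else:
                cells.extend(["", "", ""])
        rows.append("\t".join(cells))
    path.write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# MOT/STO joint kinematics
# ---------------------------------------------------------------------------

def write_mot(path, series: JointKinematicsSeries, name: str = "kinematics"):
    """Tab-delimited MOT/STO-style time series, angles in degrees."""
    path = Path(path)
    df = series.to_frame()
    header = [name, "version=1", f"nRows={len(df)}",
              f"nColumns={df.shape[1]}", "inDegrees=yes", "endheader"]
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.8f")


def read_mot(path) -> JointKinematicsSeries:
    path = Path(path)
    with path.open() as fh:
        for line in fh:
            if line.strip() == "endheader":
                break
        else:
            raise ParseError(f"{path}: no endheader line")
        df = pd.read_csv(fh, sep="\t")
    from .model import joint_angle_labels
    angle_cols = joint_angle_labels()
    missing = [c for c in ["time"] + BASE_LABELS + angle_cols
               if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing[:5]}")
    time = df["time"].to_numpy()
    normalized = bool(len(df) == 100 and time[-1] == 100.0)
    return JointKinematicsSeries(
        df[angle_cols].to_numpy(), df[BASE_LABELS].to_numpy(), time,
        normalized=normalized)


# ---------------------------------------------------------------------------
# model JSON
# ---------------------------------------------------------------------------

def _listify(a):
    return np.asarray(a, dtype=float).tolist()


def model_to_dict(spine_model: SpineModel) -> dict:
    return {
        "schema_version": MODEL_SCHEMA_VERSION,
        "units": {"position": "mm", "orientation": "deg",
                  "euler_sequence": "body-fixed xyz"},
        "static_base_pose": _listify(spine_model.static_base_pose),
        "segments": [
            {"name": s.name, "position": _listify(s.position),
             "euler_xyz": _listify(s.euler_xyz),
             "landmarks": {k: _listify(v) for k, v in s.landmarks.items()}}
            for s in spine_model.segments],
        "joints": [
            {"name": j.name, "parent": j.parent, "child": j.child,
             "position": _listify(j.position),
             "euler_xyz": _listify(j.euler_xyz),
             "child_offset_position": _listify(j.child_offset_position),
             "child_offset_euler": _listify(j.child_offset_euler)}
            for j in spine_model.joints],
        "markers": [
            {"name": m.name, "body": m.body, "position": _listify(m.position)}
            for m in spine_model.markers],
    }


def model_from_dict(d: dict) -> SpineModel:
    problems = []
    if d.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ParseError(
            f"unsupported schema_version {d.get('schema_version')!r}; "
            f"expected {MODEL_SCHEMA_VERSION!r}")
    for key in ("static_base_pose", "segments", "joints", "markers"):
        if key not in d:
            problems.append(f"$.{key}: missing")
    if problems:
        raise ParseError("model JSON schema violations: " + "; ".join(problems))
    try:
        segments = [BodySegment(s["name"], s["position"], s["euler_xyz"],
                                {k: v for k, v in s["landmarks"].items()})
                    for s in d["segments"]]
        joints = [SphericalJoint(j["name"], j["parent"], j["child"],
                                 j["position"], j["euler_xyz"],
                                 j["child_offset_position"],
                                 j["child_offset_euler"])
                  for j in d["joints"]]
        markers = [VirtualMarker(m["name"], m["body"], m["position"])
                   for m in d["markers"]]
        return SpineModel(segments, joints, markers, d["static_base_pose"])
    except KeyError as e:
        raise ParseError(f"model JSON missing field {e}") from None
    except ModelStructureError as e:
        raise ParseError(f"model JSON invalid: {e}") from None


def write_model(path, spine_model: SpineModel):
    Path(path).write_text(
        json.dumps(model_to_dict(spine_model), indent=1) + "\n")


def read_model(path) -> SpineModel:
    return model_from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# YAML settings and run manifest
# ---------------------------------------------------------------------------

def read_settings(path) -> dict:
    with open(path) as fh:
        out = yaml.safe_load(fh) or {}
    if not isinstance(out, dict):
        raise ParseError(f"{path}: settings file must be a mapping")
    return out


def file_digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, command: str, seed, inputs: dict, settings: dict,
                   extra: dict = None):
    """Record everything needed to reproduce a run.

    Contains the tool version, command, seed, input digests and settings;
    deliberately no wall-clock timestamp, so reruns with identical inputs
    produce bit-identical manifests.
    """
    manifest = {
        "tool": "spinemc",
        "version": __version__,
        "command": command,
        "seed": seed,
        "inputs": {k: file_digest(v) for k, v in inputs.items()},
        "settings": settings,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
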