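"""File formats: landmark CSV / .fcsv, transform JSON, study configs.

All coordinates are millimetres.  Landmark files come in two dialects:

* plain CSV with header ``label,x,y,z`` — written with ``repr`` floats so a
  write/read cycle is lossless;
* a 3D Slicer-style ``.fcsv`` markups dialect: ``#`` comment header lines,
  then CSV rows whose columns include ``id,x,y,z,label`` (the full
  14-column Slicer layout is written).  Coordinates are taken as-is; no
  RAS/LPS conversion is attempted.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, InvalidInputError
from .fiducials import FiducialSet
from .simulation import (
    HEAD_LANDMARKS,
    PhantomSpec,
    SimulationReport,
    run_fre_study,
    run_tracking_study,
)
from .transforms import RigidTransform

__all__ = [
    "read_landmarks",
    "write_landmarks",
    "read_transform",
    "write_transform",
    "load_study_config",
    "run_study",
]

_FCSV_COLUMNS = [
    "id", "x", "y", "z", "ow", "ox", "oy", "oz",
    "vis", "sel", "lock", "label", "desc", "associatedNodeID",
]


def _read_csv_landmarks(path: Path, frame: str) -> FiducialSet:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{path}: not a readable CSV ({exc})") from exc
    missing = {"label", "x", "y", "z"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return FiducialSet(df["label"].astype(str), df[["x", "y", "z"]].to_numpy(float), frame)


def _read_fcsv_landmarks(path: Path, frame: str) -> FiducialSet:
    text = Path(path).read_text()
    columns = _FCSV_COLUMNS
    data_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            # honour an explicit "# columns = ..." declaration
            stripped = line.lstrip("#").strip()
            if stripped.lower().startswith("columns"):
                _, _, spec = stripped.partition("=")
                columns = [c.strip() for c in spec.split(",")]
            continue
        if line.strip():
            data_lines.append(line)
    if not data_lines:
        raise FormatError(f"{path}: no data rows")
    try:
        df = pd.read_csv(
            _io.StringIO("\n".join(data_lines)), header=None,
            float_precision="round_trip",
        )
    except Exception as exc:
        raise FormatError(f"{path}: unparsable fcsv rows ({exc})") from exc
    if df.shape[1] == 5 and len(columns) != 5:
        columns = ["id", "x", "y", "z", "label"]
    if df.shape[1] != len(columns):
        raise FormatError(
            f"{path}: {df.shape[1]} columns, expected {len(columns)} ({columns})"
        )
    df.columns = columns
    for needed in ("x", "y", "z", "label"):
        if needed not in df.columns:
            raise FormatError(f"{path}: fcsv columns lack {needed!r}")
    return FiducialSet(df["label"].astype(str), df[["x", "y", "z"]].to_numpy(float), frame)


def read_landmarks(path, frame: str = "image") -> FiducialSet:
    """Read a landmark file (.csv or .fcsv) into a FiducialSet."""
    p = Path(path)
    if not p.exists():
        raise FormatError(f"{p}: no such file")
    if p.suffix.lower() == ".fcsv":
        return _read_fcsv_landmarks(p, frame)
    return _read_csv_landmarks(p, frame)


def write_landmarks(path, fids: FiducialSet) -> None:
    """Write a FiducialSet; dialect chosen by suffix (.fcsv vs CSV).

    The CSV dialect uses ``repr`` floats and round-trips losslessly.
    """
    p = Path(path)
    if p.suffix.lower() == ".fcsv":
        lines = [
            "# Markups fiducial file version = 4.11",
            "# CoordinateSystem = 0",
            "# columns = " + ",".join(_FCSV_COLUMNS),
        ]
        for i, (lab, pt) in enumerate(zip(fids.labels, fids.points)):
            x, y, z = (repr(float(c)) for c in pt)
            lines.append(
                f"vtkMRMLMarkupsFiducialNode_{i},{x},{y},{z},0,0,0,1,1,1,0,{lab},,"
            )
        p.write_text("\n".join(lines) + "\n")
    else:
        lines = ["label,x,y,z"]
        for lab, pt in zip(fids.labels, fids.points):
            x, y, z = (repr(float(c)) for c in pt)
            lines.append(f"{lab},{x},{y},{z}")
        p.write_text("\n".join(lines) + "\n")


def read_transform(path) -> RigidTransform:
    """Read a rigid transform from its 4×4 homogeneous-matrix JSON file."""
    p = Path(path)
    if not p.exists():
        raise FormatError(f"{p}: no such file")
    try:
        return RigidTransform.from_json(p.read_text())
    except (json.JSONDecodeError, KeyError) as exc:
        raise FormatError(f"{p}: not a transform JSON ({exc})") from exc


def write_transform(path, t: RigidTransform) -> None:
    Path(path).write_text(t.to_json() + "\n")


def _motion_from_config(node) -> RigidTransform:
    if node is None:
        return RigidTransform.identity()
    if isinstance(node, dict):
        if "matrix" in node:
            return RigidTransform.from_matrix(node["matrix"])
        t = node.get("translation", (0.0, 0.0, 0.0))
        if "axis" in node or "angle_deg" in node:
            axis = node.get("axis", (0.0, 0.0, 1.0))
            angle = np.deg2rad(float(node.get("angle_deg", 0.0)))
            return RigidTransform.from_axis_angle(axis, angle, t)
        return RigidTransform.from_translation(t)
    return RigidTransform.from_matrix(node)


def load_study_config(path) -> dict:
    """Parse a YAML study config into a PhantomSpec plus study parameters.

    Layout::

        phantom:
          subset: [nasal_bridge, ...]   # optional, default all 9 sites
          fle_sigma: 2.0                # mm
          seed: 7
          true_motion: {translation: [10, 0, 0]}   # or {matrix: ...}
        study:
          kind: fre | tracking
          n_trials: 1000
          bed_motion: {translation: [0, 0, 50]}    # tracking only
          marker_noise_sigma: 0.5                  # mm, tracking only
    """
    p = Path(path)
    if not p.exists():
        raise FormatError(f"{p}: no such file")
    try:
        cfg = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{p}: invalid YAML ({exc})") from exc
    if not isinstance(cfg, dict) or "study" not in cfg:
        raise FormatError(f"{p}: config needs a 'study' section")
    ph = cfg.get("phantom") or {}
    spec = PhantomSpec(
        subset=tuple(ph.get("subset", tuple(HEAD_LANDMARKS))),
        true_motion=_motion_from_config(ph.get("true_motion")),
        fle_sigma=float(ph.get("fle_sigma", 2.0)),
        seed=int(ph.get("seed", 0)),
    )
    study = dict(cfg["study"])
    kind = study.get("kind", "fre")
    if kind not in ("fre", "tracking"):
        raise FormatError(f"{p}: unknown study kind {kind!r}")
    return {
        "spec": spec,
        "kind": kind,
        "n_trials": int(study.get("n_trials", 1000)),
        # default bed movement: +50 mm upwards
        "bed_motion": _motion_from_config(
            study.get("bed_motion", {"translation": [0.0, 0.0, 50.0]})
        ),
        "marker_noise_sigma": float(study.get("marker_noise_sigma", 0.0)),
    }


def run_study(config: dict) -> SimulationReport:
    """Execute a parsed study config (see :func:`load_study_config`)."""
    if config["kind"] == "fre":
        return run_fre_study(config["spec"], config["n_trials"])
    return run_tracking_study(
        config["spec"],
        config["bed_motion"],
        config["marker_noise_sigma"],
        config["n_trials"],
    )
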