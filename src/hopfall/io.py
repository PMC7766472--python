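"""File formats: IMU CSV traces and JSON matrices/templates/weights.

All formats are plain text.  A recording is a CSV with header
``t,Gx,Gy,Gz,Ax,Ay,Az,Mx,My,Mz`` plus a sidecar ``<name>.meta.json``
carrying label and seed; templates and weights are small JSON documents.
Readers validate strictly (header, bipolar entries, weight symmetry) and
name the offending column or row in errors.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import BinaryFeatureMatrix, PatternTemplate
from .hopfield import WeightMatrix
from .imu_synth import CHANNELS, ImuRecording

__all__ = [
    "write_imu_csv",
    "read_imu_csv",
    "write_template_json",
    "read_template_json",
    "write_weights_json",
    "read_weights_json",
    "write_binary_matrix_json",
    "read_binary_matrix_json",
    "write_vector_json",
    "read_vector_json",
]

IMU_HEADER = ("t",) + CHANNELS


def _sidecar(path: Path) -> Path:
    return path.with_name(path.stem + ".meta.json")


def write_imu_csv(rec: ImuRecording, path: str | Path) -> Path:
    """Write a recording as CSV plus a ``<name>.meta.json`` sidecar."""
    path = Path(path)
    rec.to_frame().to_csv(path, index=False, float_format="%.10g")
    meta = {"label": rec.label, "seed": rec.seed, "sample_rate": rec.sample_rate}
    _sidecar(path).write_text(json.dumps(meta, indent=2) + "\n")
    return path


def read_imu_csv(path: str | Path) -> ImuRecording:
    """Read a recording CSV (and its sidecar, if present) back into memory."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in IMU_HEADER if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {', '.join(missing)}")
    for col in IMU_HEADER:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any() or frame[col].isna().any():
            row = int((coerced.isna()).idxmax())
            raise ValueError(
                f"{path}: malformed value in column {col!r} at line {row + 2}"
            )
        frame[col] = coerced
    label, seed, rate = "Fall", 0, None
    sidecar = _sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        label = meta.get("label", label)
        seed = int(meta.get("seed", seed))
        rate = meta.get("sample_rate")
    if rate is None:
        t = frame["t"].to_numpy()
        rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 50.0
    return ImuRecording(
        data=frame[list(CHANNELS)].to_numpy(dtype=float),
        sample_rate=float(rate),
        label=label,
        seed=seed,
    )


def write_template_json(template: PatternTemplate, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "grid": template.grid.astype(int).tolist(),
        "class": template.class_label,
        "window_start": template.window_start,
    }
    path.write_text(json.dumps(doc, indent=2) + "\n")
    return path


def read_template_json(path: str | Path) -> PatternTemplate:
    path = Path(path)
    doc = json.loads(path.read_text())
    grid = np.asarray(doc["grid"], dtype=np.int8)
    return PatternTemplate(
        grid=grid,
        class_label=doc.get("class"),
        window_start=doc.get("window_start"),
    )


def write_weights_json(W: WeightMatrix, path: str | Path) -> Path:
    path = Path(path)
    doc = {"n": W.n, "eta": W.eta, "w": W.w.tolist()}
    path.write_text(json.dumps(doc) + "\n")
    return path


def read_weights_json(path: str | Path) -> WeightMatrix:
    path = Path(path)
    doc = json.loads(path.read_text())
    w = np.asarray(doc["w"], dtype=float)
    if w.shape != (doc["n"], doc["n"]):
        raise ValueError(f"{path}: weight matrix shape {w.shape} != n={doc['n']}")
    # WeightMatrix validation rejects asymmetric / self-feedback matrices.
    return WeightMatrix(w=w, eta=float(doc.get("eta", 1.0)))


def write_binary_matrix_json(matrix: BinaryFeatureMatrix, path: str | Path) -> Path:
    path = Path(path)
    doc = {
        "entries": matrix.entries.astype(int).tolist(),
        "thresholds": list(matrix.thresholds),
        "mode": matrix.mode,
    }
    path.write_text(json.dumps(doc) + "\n")
    return path


def read_binary_matrix_json(path: str | Path) -> BinaryFeatureMatrix:
    doc = json.loads(Path(path).read_text())
    return BinaryFeatureMatrix(
        entries=np.asarray(doc["entries"], dtype=np.int8),
        thresholds=tuple(doc["thresholds"]),
        mode=doc.get("mode", "per-feature"),
    )


def write_vector_json(v: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps({"v": np.asarray(v).astype(int).tolist()}) + "\n")
    return path


def read_vector_json(path: str | Path) -> np.ndarray:
    """Read a bipolar state vector: either ``{"v": [...]}`` or a template."""
    doc = json.loads(Path(path).read_text())
    if "v" in doc:
        return np.asarray(doc["v"], dtype=float)
    if "grid" in doc:
        return np.asarray(doc["grid"], dtype=float).reshape(-1)
    raise ValueError(f"{path}: expected a 'v' or 'grid' field")
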