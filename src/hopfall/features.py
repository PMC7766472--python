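"""Sensor fusion, threshold binarization and 5x5 template extraction.

The nine IMU axes are fused per timestep into five features:

    M1 = (|Gx|+1)(|Gy|+1)(|Gz|+1)          gyroscope magnitude product
    M2 = (|Ax|+1)(|Ay|+1)(|Az|+1)          accelerometer magnitude product
    M3 = (|Mx|+1)(|My|+1)(|Mz|+1)          magnetometer magnitude product
    M4 = (Ax*My*Gz - Gx*My*Az) / 2         signed cross-sensor product
    M5 = (Gx*Ay + Ax*My + Mx*Gy
          - Gx*My - Ax*Gy - Mx*Ay) / 2     signed cross-sensor product

M1..M3 are >= 1 everywhere (products of terms >= 1); M4 and M5 are signed.
Each feature row is then compared against a fixed threshold vector
t = [16, 24, 32, 40, 48] (strict ">"), producing a 5xN bipolar matrix, and
a sliding 5x5 window with the greatest count of +1 entries is extracted as
the activity's pattern template (one entry per neuron of the 25-neuron
associative memory, flattened row-major).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imu_synth import ImuRecording

__all__ = [
    "DEFAULT_THRESHOLDS",
    "FusedFeatureSeries",
    "BinaryFeatureMatrix",
    "PatternTemplate",
    "fuse_axes",
    "binarize",
    "extract_template",
]

#: Fixed binarization thresholds, one per feature row.
DEFAULT_THRESHOLDS = (16.0, 24.0, 32.0, 40.0, 48.0)


@dataclass(frozen=True)
class FusedFeatureSeries:
    """Five fused feature series M1..M5, shape (5, N)."""

    m: np.ndarray

    def __post_init__(self) -> None:
        if self.m.ndim != 2 or self.m.shape[0] != 5:
            raise ValueError(f"expected shape (5, N), got {self.m.shape}")

    @property
    def n_steps(self) -> int:
        return self.m.shape[1]


@dataclass(frozen=True)
class BinaryFeatureMatrix:
    """5xN bipolar matrix: entries[i, n] = +1 iff feature > thresholds[i]."""

    entries: np.ndarray
    thresholds: tuple[float, ...]
    mode: str = "per-feature"

    def __post_init__(self) -> None:
        if self.entries.ndim != 2 or self.entries.shape[0] != 5:
            raise ValueError(f"expected shape (5, N), got {self.entries.shape}")
        if not np.isin(self.entries, (-1, 1)).all():
            raise ValueError("entries must be bipolar (+1/-1)")


@dataclass(frozen=True)
class PatternTemplate:
    """A 5x5 bipolar template; ``vector`` is its row-major 25-flattening."""

    grid: np.ndarray
    class_label: str | None = None
    window_start: int | None = None

    def __post_init__(self) -> None:
        if self.grid.shape != (5, 5):
            raise ValueError(f"grid must be 5x5, got {self.grid.shape}")
        if not np.isin(self.grid, (-1, 1)).all():
            raise ValueError("grid must be bipolar (+1/-1)")

    @property
    def vector(self) -> np.ndarray:
        """Row-major flattening, one entry per neuron."""
        return self.grid.reshape(-1)

    @classmethod
    def from_vector(cls, vector: np.ndarray, **kwargs) -> "PatternTemplate":
        vector = np.asarray(vector)
        if vector.shape != (25,):
            raise ValueError(f"vector must have length 25, got {vector.shape}")
        return cls(grid=vector.reshape(5, 5), **kwargs)


def fuse_axes(rec: ImuRecording) -> FusedFeatureSeries:
    """Fuse the nine channels into M1..M5, pointwise per timestep."""
    gx, gy, gz = (rec.channel(c) for c in ("Gx", "Gy", "Gz"))
    ax, ay, az = (rec.channel(c) for c in ("Ax", "Ay", "Az"))
    mx, my, mz = (rec.channel(c) for c in ("Mx", "My", "Mz"))
    m1 = (np.abs(gx) + 1) * (np.abs(gy) + 1) * (np.abs(gz) + 1)
    m2 = (np.abs(ax) + 1) * (np.abs(ay) + 1) * (np.abs(az) + 1)
    m3 = (np.abs(mx) + 1) * (np.abs(my) + 1) * (np.abs(mz) + 1)
    m4 = 0.5 * (ax * my * gz - gx * my * az)
    m5 = 0.5 * (gx * ay + ax * my + mx * gy - gx * my - ax * gy - mx * ay)
    return FusedFeatureSeries(m=np.stack([m1, m2, m3, m4, m5]))


def binarize(
    feat: FusedFeatureSeries,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    mode: str = "per-feature",
    thermometer_feature: int = 0,
) -> BinaryFeatureMatrix:
    """Threshold the fused features into a 5xN bipolar matrix.

    ``mode="per-feature"`` (default): row i is the indicator
    M(i+1) > thresholds[i].  ``mode="thermometer"``: all five rows
    threshold the single feature ``thermometer_feature`` at the five
    levels (a thermometer code).  Comparison is strict; a value exactly
    equal to its threshold maps to -1.
    """
    thresholds = tuple(float(t) for t in thresholds)
    if len(thresholds) != 5:
        raise ValueError(f"exactly 5 thresholds required, got {len(thresholds)}")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")
    t = np.asarray(thresholds)[:, None]
    if mode == "per-feature":
        values = feat.m
    elif mode == "thermometer":
        values = np.repeat(feat.m[thermometer_feature][None, :], 5, axis=0)
    else:
        raise ValueError(f"unknown binarization mode {mode!r}")
    entries = np.where(values > t, 1, -1).astype(np.int8)
    return BinaryFeatureMatrix(entries=entries, thresholds=thresholds, mode=mode)


def extract_template(
    bin_matrix: BinaryFeatureMatrix,
    class_label: str | None = None,
    flip: bool = False,
) -> PatternTemplate:
    """Slide a 5x5 window over the bipolar matrix and keep the best one.

    The window (contiguous columns, stride 1) maximizing the count of +1
    entries is selected; ties break to the earliest start index.  With
    ``flip=True`` the chosen window is mirrored left-right before storage
    (both a pattern and its mirror are equally valid Hebbian templates).
    """
    entries = bin_matrix.entries
    n = entries.shape[1]
    if n < 5:
        raise ValueError(f"need at least 5 columns, got {n}")
    col_counts = (entries == 1).sum(axis=0)
    window_counts = np.convolve(col_counts, np.ones(5, dtype=int), mode="valid")
    start = int(np.argmax(window_counts))  # argmax takes the earliest tie
    grid = entries[:, start : start + 5].copy()
    if flip:
        grid = grid[:, ::-1].copy()
    return PatternTemplate(grid=grid, class_label=class_label, window_start=start)
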