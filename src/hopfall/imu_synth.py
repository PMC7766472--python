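"""Seeded synthetic 9-axis IMU recordings for five activity classes.

The generator stands in for wrist-worn IMU captures (gyroscope,
accelerometer, magnetometer; 50 Hz; 5-10 s per recording) of the five
activities Fall, SitDown, StandUp, Under and Walk.  The signal model is
deliberately simple: per-channel Gaussian baseline noise plus a
class-specific deterministic envelope -- a half-sine transient for the
transition activities (Fall, SitDown, StandUp), a sinusoid for Walk, and a
flat baseline for Under (treated as a low-motion class).

Envelope amplitudes are calibrated so that the downstream fused features
M1..M5 (see :mod:`hopfall.features`) separate Fall from every other class:
during the Fall transient all five features exceed their per-row thresholds
t = [16, 24, 32, 40, 48], while the other classes cross at most the lowest
thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ACTIVITY_CLASSES",
    "CHANNELS",
    "ClassEnvelope",
    "SynthConfig",
    "ImuRecording",
    "generate_activity",
    "generate_dataset",
]

#: Canonical activity labels; "Fall" is the positive class downstream.
ACTIVITY_CLASSES = ("Fall", "SitDown", "StandUp", "Under", "Walk")

#: Channel order used everywhere (CSV columns, envelope dicts).
CHANNELS = ("Gx", "Gy", "Gz", "Ax", "Ay", "Az", "Mx", "My", "Mz")


@dataclass(frozen=True)
class ClassEnvelope:
    """Deterministic signal envelope for one activity class.

    Parameters
    ----------
    noise_sd:
        Standard deviation of the per-channel Gaussian baseline noise
        (arbitrary sensor units).
    peaks:
        Per-channel peak magnitude of the deterministic envelope.
    transient_duration:
        Width in seconds of the half-sine transient (ignored for periodic
        and flat classes).
    periodicity_hz:
        If set, the envelope is a sinusoid at this frequency (Walk);
        otherwise a single half-sine transient (or flat if all peaks are 0).
    """

    noise_sd: float = 0.05
    peaks: dict[str, float] = field(default_factory=dict)
    transient_duration: float = 1.0
    periodicity_hz: float | None = None


def _default_envelopes() -> dict[str, ClassEnvelope]:
    # Fall peaks are chosen so that at the transient maximum:
    #   M1 = (3+1)(0.3+1)(3+1)      = 20.8 > 16
    #   M2 = (12+1)(10+1)(0.5+1)    = 214.5 > 24
    #   M3 = (0.3+1)(10+1)(3+1)     = 57.2 > 32
    #   M4 = (12*10*3 - 3*10*0.5)/2 = 172.5 > 40
    #   M5 = (0 + 12*9.7 - 0.3*9.7)/2 = 56.7 > 48
    # so all five binarized rows go high for a contiguous run of samples.
    return {
        "Fall": ClassEnvelope(
            peaks={
                "Gx": 3.0, "Gy": 0.3, "Gz": 3.0,
                "Ax": 12.0, "Ay": 10.0, "Az": 0.5,
                "Mx": 0.3, "My": 10.0, "Mz": 3.0,
            },
            transient_duration=0.8,
        ),
        # Moderate transients: cross only the lowest thresholds (M1, M2).
        "SitDown": ClassEnvelope(
            peaks={c: 2.0 for c in CHANNELS[:6]} | {c: 0.8 for c in CHANNELS[6:]},
            transient_duration=1.2,
        ),
        "StandUp": ClassEnvelope(
            peaks={c: 1.8 for c in CHANNELS[:6]} | {c: 0.7 for c in CHANNELS[6:]},
            transient_duration=1.0,
        ),
        # Low-motion class: baseline noise only.
        "Under": ClassEnvelope(peaks={}),
        # Periodic gait, sub-threshold throughout.
        "Walk": ClassEnvelope(
            peaks={c: 1.0 for c in CHANNELS[:3]}
            | {c: 1.2 for c in CHANNELS[3:6]}
            | {c: 0.3 for c in CHANNELS[6:]},
            periodicity_hz=2.0,
        ),
    }


@dataclass(frozen=True)
class SynthConfig:
    """Generator configuration: sampling, per-class envelopes, dataset size."""

    sample_rate: float = 50.0
    duration: float = 6.0
    n_per_class: int = 10
    seed: int = 0
    envelopes: dict[str, ClassEnvelope] = field(default_factory=_default_envelopes)

    def __post_init__(self) -> None:
        if self.sample_rate <= 0 or self.duration <= 0:
            raise ValueError("sample_rate and duration must be positive")


@dataclass(frozen=True)
class ImuRecording:
    """A labelled 9-channel IMU trace sampled at a fixed rate.

    ``data`` has shape (n_samples, 9) with columns in :data:`CHANNELS`
    order; ``label`` is one of :data:`ACTIVITY_CLASSES`.
    """

    data: np.ndarray
    sample_rate: float
    label: str
    seed: int

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] != len(CHANNELS):
            raise ValueError(
                f"data must have shape (n, {len(CHANNELS)}), got {self.data.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, CHANNELS.index(name)]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.data, columns=list(CHANNELS))
        frame.insert(0, "t", self.t)
        return frame


def _envelope_series(env: ClassEnvelope, t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude envelope evaluated at times ``t`` (shape (n, 9))."""
    n = t.size
    if env.periodicity_hz is not None:
        # Per-channel phase offsets so gait axes are not perfectly in phase.
        phases = rng.uniform(0.0, 2 * np.pi, size=len(CHANNELS))
        return np.sin(2 * np.pi * env.periodicity_hz * t[:, None] + phases[None, :])
    if not env.peaks:
        return np.zeros((n, len(CHANNELS)))
    # Half-sine transient with a mildly jittered onset, same for all channels.
    span = t[-1] if n > 1 else 0.0
    latest = max(span - env.transient_duration, 0.0)
    onset = rng.uniform(0.3, 0.7) * latest
    phase = (t - onset) / env.transient_duration
    burst = np.where((phase >= 0) & (phase <= 1), np.sin(np.pi * np.clip(phase, 0, 1)), 0.0)
    return np.repeat(burst[:, None], len(CHANNELS), axis=1)


def generate_activity(label: str, config: SynthConfig | None = None, seed: int = 0) -> ImuRecording:
    """Generate one seeded recording of the given activity class.

    Identical ``(label, config, seed)`` always yields bit-identical data.
    """
    config = config or SynthConfig()
    if label not in ACTIVITY_CLASSES:
        raise ValueError(
            f"unknown activity label {label!r}; expected one of {ACTIVITY_CLASSES}"
        )
    env = config.envelopes[label]
    n = round(config.sample_rate * config.duration)
    rng = np.random.default_rng(seed)
    t = np.arange(n) / config.sample_rate
    shape = _envelope_series(env, t, rng)
    peaks = np.array([env.peaks.get(c, 0.0) for c in CHANNELS])
    noise = rng.normal(0.0, env.noise_sd, size=(n, len(CHANNELS)))
    return ImuRecording(
        data=shape * peaks[None, :] + noise,
        sample_rate=config.sample_rate,
        label=label,
        seed=seed,
    )


def generate_dataset(config: SynthConfig | None = None) -> list[ImuRecording]:
    """Generate ``n_per_class`` recordings per class (exactly balanced).

    Per-recording seeds are derived from the master seed by a deterministic
    counter offset, so the whole dataset is reproducible and seeds never
    collide within a run.
    """
    config = config or SynthConfig()
    if config.n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    recordings = []
    counter = 0
    for label in ACTIVITY_CLASSES:
        for _ in range(config.n_per_class):
            recordings.append(generate_activity(label, config, seed=config.seed + counter))
            counter += 1
    return recordings


def with_n_per_class(config: SynthConfig, n: int) -> SynthConfig:
    """Convenience copy-with: same generator, different dataset size."""
    return replace(config, n_per_class=n)
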