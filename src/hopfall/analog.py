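"""Behavioral simulation of the op-amp Hopfield neuron circuit.

Each neuron is a summing amplifier: resistors on the inverting /
non-inverting inputs realize the signed synaptic weights (weight
magnitude as conductance, weight sign as the input the connection is
routed through), a constant bias source injects the external input, and
the KCL current balance at the summing node plus the node capacitance
give the classical RC relaxation

    tau * du_i/dt = -u_i + sum_j G_ij v_j + bias_i + noise(t)
    v_i = rails * tanh(gain * u_i)

integrated by fixed-step explicit Euler.  At high amplifier gain the
thresholded steady states coincide with the fixed points of the ideal
digital network, which is what makes the circuit usable as an associative
memory despite analog noise.

Conductances are normalized so max |G_ij| = 1 (no absolute resistor values
are modelled); zero weights are open circuits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hopfield import WeightMatrix

__all__ = [
    "CircuitConfig",
    "CircuitParams",
    "AnalogResult",
    "AnalogDivergenceError",
    "map_weights_to_circuit",
    "simulate_circuit",
    "threshold_readout",
    "continuous_energy",
]


class AnalogDivergenceError(RuntimeError):
    """Raised when the Euler integration blows up (|u| > 1e6 x rails)."""


@dataclass(frozen=True)
class CircuitConfig:
    """Behavioral circuit parameters.

    gain:      amplifier transfer slope (dimensionless); >= 10 puts the
               circuit in the near-digital regime.
    tau:       relaxation time constant in seconds (membrane resistance
               times the implicit node capacitance).
    dt:        Euler step in seconds; defaults to tau / 100.
    duration:  integration time in seconds; defaults to 40 * tau.
    noise_sd:  standard deviation of white Gaussian noise injected at the
               summing node, in volts.
    rails:     output saturation level (supply rails), volts.
    bias:      per-neuron constant bias voltages (defaults to zero).
    """

    gain: float = 10.0
    tau: float = 1.0
    dt: float | None = None
    duration: float | None = None
    noise_sd: float = 0.0
    rails: float = 1.0
    bias: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        dt = self.step
        if dt <= 0 or self.span < dt:
            raise ValueError("need dt > 0 and duration >= dt")

    @property
    def step(self) -> float:
        return self.dt if self.dt is not None else self.tau / 100.0

    @property
    def span(self) -> float:
        return self.duration if self.duration is not None else 40.0 * self.tau


@dataclass(frozen=True)
class CircuitParams:
    """Signed normalized conductances; sign = inverting vs non-inverting path."""

    g: np.ndarray

    def __post_init__(self) -> None:
        g = self.g
        if g.ndim != 2 or g.shape[0] != g.shape[1]:
            raise ValueError(f"conductance matrix must be square, got {g.shape}")
        if not np.allclose(g, g.T):
            raise ValueError("conductance matrix must be symmetric")
        if np.any(np.diag(g) != 0):
            raise ValueError("conductance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return self.g.shape[0]


@dataclass(frozen=True)
class AnalogResult:
    """Final amplifier outputs plus the bipolar readout and diagnostics."""

    v: np.ndarray          # final continuous outputs, volts
    readout: np.ndarray    # thresholded bipolar states
    settled: bool          # True if |du| fell below the settle tolerance
    steps: int
    trace: np.ndarray | None = None  # optional (steps+1, N) output trajectory


def map_weights_to_circuit(W: WeightMatrix, config: CircuitConfig | None = None) -> CircuitParams:
    """Map trained weights onto signed conductances with max |G| = 1.

    Negative weights route through the inverting input (negative sign);
    zero weights are open circuits.  An all-zero weight matrix maps to all
    open circuits.
    """
    w = W.w
    peak = np.max(np.abs(w))
    g = w / peak if peak > 0 else np.zeros_like(w)
    return CircuitParams(g=g)


def threshold_readout(v_final: np.ndarray, init: np.ndarray) -> np.ndarray:
    """High voltage -> +1, low -> -1; exact zero keeps the initial state."""
    v_final = np.asarray(v_final, dtype=float)
    init = np.asarray(init, dtype=float)
    return np.where(v_final > 0, 1.0, np.where(v_final < 0, -1.0, init))


def simulate_circuit(
    params: CircuitParams,
    config: CircuitConfig | None = None,
    init: np.ndarray | None = None,
    seed: int = 0,
    record_trace: bool = False,
) -> AnalogResult:
    """Integrate the circuit from a bipolar initial state scaled to the rails.

    ``init`` is a bipolar vector; the amplifiers start at ``init * rails``
    (equivalently u0 = atanh(0.999 * init) / gain, just inside saturation).
    Returns the final outputs and their bipolar readout.  Raises
    :class:`AnalogDivergenceError` if any |u| exceeds 1e6 x rails.
    """
    config = config or CircuitConfig()
    init = np.asarray(init, dtype=float)
    if init.shape != (params.n,):
        raise ValueError(f"init has shape {init.shape}, expected ({params.n},)")
    if not np.isin(init, (-1.0, 1.0)).all():
        raise ValueError("init must be bipolar (+1/-1)")
    dt, tau, lam, rails = config.step, config.tau, config.gain, config.rails
    bias = np.zeros(params.n) if config.bias is None else np.asarray(config.bias, dtype=float)
    n_steps = int(round(config.span / dt))
    rng = np.random.default_rng(seed)
    # Start just inside the rails so u0 = f^-1(v0) is finite.
    u = np.arctanh(0.999 * init) / lam
    v = rails * np.tanh(lam * u)
    trace = [v.copy()] if record_trace else None
    settled = False
    settle_tol = 1e-12 * max(rails, 1.0)
    steps_done = 0
    for step in range(n_steps):
        drive = params.g @ v + bias
        if config.noise_sd > 0:
            drive = drive + rng.normal(0.0, config.noise_sd, size=params.n)
        du = (dt / tau) * (-u + drive)
        u = u + du
        if np.max(np.abs(u)) > 1e6 * rails:
            raise AnalogDivergenceError(
                f"integration diverged at step {step}: max |u| exceeds 1e6 x rails"
            )
        v = rails * np.tanh(lam * u)
        steps_done = step + 1
        if trace is not None:
            trace.append(v.copy())
        if config.noise_sd == 0 and np.max(np.abs(du)) < settle_tol:
            settled = True
            break
    else:
        # Deterministic runs that used the whole span are considered settled
        # if the last step barely moved; noisy runs never formally settle.
        settled = config.noise_sd == 0 and np.max(np.abs(du)) < 1e-6 * max(rails, 1.0)
    return AnalogResult(
        v=v,
        readout=threshold_readout(v, init),
        settled=settled,
        steps=steps_done,
        trace=None if trace is None else np.asarray(trace),
    )


def continuous_energy(params: CircuitParams, config: CircuitConfig, v: np.ndarray) -> float:
    """Lyapunov function of the noiseless relaxation.

    E(v) = -1/2 v'Gv - bias'v + (1/gain) sum_i int_0^{v_i} atanh(s/rails) ds,
    which is non-increasing along noise-free trajectories for symmetric G.
    """
    v = np.asarray(v, dtype=float)
    rails, lam = config.rails, config.gain
    bias = np.zeros(params.n) if config.bias is None else np.asarray(config.bias, dtype=float)
    x = np.clip(v / rails, -1 + 1e-15, 1 - 1e-15)
    # int_0^v atanh(s/rails) ds = rails * (x atanh x + 0.5 log(1 - x^2))
    leak = rails * (x * np.arctanh(x) + 0.5 * np.log1p(-(x**2)))
    return float(-0.5 * v @ params.g @ v - bias @ v + np.sum(leak) / lam)
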