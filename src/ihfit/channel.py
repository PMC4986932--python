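"""Two-state Hodgkin–Huxley description of one Ih component.

A hyperpolarization-activated cation (Ih) component is fully described by
its maximal conductance ``G`` together with two voltage-dependent
characteristic curves:

* the steady-state activation ``r_inf(V)``, a Boltzmann sigmoid with
  half-activation voltage ``Vh`` and slope factor ``k`` (negative for a
  current that opens on hyperpolarization), and
* the activation time constant ``tau_r(V)``, a Gaussian bump of amplitude
  ``A`` and width ``S`` centred on voltage ``M``, riding on a base time
  constant ``B``.

Under a voltage-clamp step the activation gate relaxes exponentially, so the
current has a closed form (`step_current`).  Units are mV, ms, nS and pA
throughout (1 nS x 1 mV = 1 pA).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np

__all__ = [
    "ComponentParams",
    "StepSpec",
    "ChannelConstants",
    "activation",
    "time_constant",
    "step_current",
    "deactivation_current",
    "total_current",
]

#: Order in which a component's parameters are laid out in flat vectors.
PARAM_NAMES = ("Vh", "k", "M", "S", "A", "B", "G")


@dataclass(frozen=True)
class ComponentParams:
    """Parameters of one Ih component.

    Attributes
    ----------
    Vh : float
        Half-activation voltage (mV).
    k : float
        Boltzmann slope factor (mV); negative for hyperpolarization-activated
        channels.
    M : float
        Voltage of maximal time constant (mV).
    S : float
        Width of the Gaussian kinetic curve (mV).
    A : float
        Amplitude of the Gaussian kinetic curve (ms).
    B : float
        Base (offset) time constant (ms).
    G : float
        Maximal conductance (nS).
    """

    Vh: float
    k: float
    M: float
    S: float
    A: float
    B: float
    G: float

    def __post_init__(self) -> None:
        if self.k == 0:
            raise ValueError("slope factor k must be non-zero")
        if self.S <= 0:
            raise ValueError("kinetic width S must be positive")
        if self.A <= 0 or self.B <= 0:
            raise ValueError("kinetic amplitudes A and B must be positive")
        if self.G < 0:
            raise ValueError("maximal conductance G must be non-negative")

    @property
    def tau_peak(self) -> float:
        """Peak time constant A + B (ms), attained at V = M."""
        return self.A + self.B

    def to_vector(self) -> np.ndarray:
        """Flatten to (Vh, k, M, S, A, B, G)."""
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_vector(cls, vec) -> "ComponentParams":
        vec = np.asarray(vec, dtype=float)
        if vec.shape != (7,):
            raise ValueError("parameter vector must have length 7")
        return cls(**dict(zip(PARAM_NAMES, vec)))

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kw) -> "ComponentParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class StepSpec:
    """One voltage-clamp step: hold at ``Vps``, step to ``Vs``, return.

    ``t_step`` and ``t_post`` are the durations (ms) of the step and of the
    post-step (deactivation) segment back at ``Vps``.
    """

    Vps: float
    Vs: float
    t_step: float
    t_post: float = 0.0

    def __post_init__(self) -> None:
        if self.t_step <= 0:
            raise ValueError("step duration must be positive")
        if self.t_post < 0:
            raise ValueError("post-step duration must be non-negative")


@dataclass(frozen=True)
class ChannelConstants:
    """Fixed constants of the Ih model: the reversal potential Eh (mV)."""

    Eh: float = -36.0


def activation(V, p: ComponentParams):
    """Steady-state activation r_inf(V) = 1 / (1 + exp(-(V - Vh)/k)).

    Strictly monotone in V (decreasing when k < 0) and bounded in (0, 1).
    """
    V = np.asarray(V, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(V - p.Vh) / p.k))
    return out if out.ndim else float(out)


def time_constant(V, p: ComponentParams):
    """Activation time constant tau_r(V) = B + A * exp(-(M - V)^2 / S^2).

    Maximum A + B exactly at V = M; tends to the base value B far from M.
    """
    V = np.asarray(V, dtype=float)
    out = p.B + p.A * np.exp(-((p.M - V) ** 2) / p.S**2)
    return out if out.ndim else float(out)


def step_current(t, step: StepSpec, p: ComponentParams, c: ChannelConstants = ChannelConstants()):
    """Closed-form Ih during a voltage step, measured from step onset.

    The gate starts at the pre-step steady state r_inf(Vps) and relaxes
    first-order toward r_inf(Vs) with time constant tau_r(Vs) (voltage held
    piecewise constant)::

        Ih(t) = G * [r_inf(Vs) + (r_inf(Vps) - r_inf(Vs)) * exp(-t/tau_r(Vs))] * (Vs - Eh)
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative (measured from step onset)")
    r_s = activation(step.Vs, p)
    r_ps = activation(step.Vps, p)
    tau = time_constant(step.Vs, p)
    r = r_s + (r_ps - r_s) * np.exp(-t / tau)
    out = p.G * r * (step.Vs - c.Eh)
    return out if out.ndim else float(out)


def deactivation_current(t, step: StepSpec, p: ComponentParams, c: ChannelConstants = ChannelConstants()):
    """Closed-form Ih after return to the pre-step potential (tail current).

    Time is measured from step offset.  Kinetics are symmetric: the same
    tau_r curve is used, evaluated at the post-step voltage Vps.  The gate
    starts from the activation actually reached at the end of the step and
    relaxes back toward r_inf(Vps).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative (measured from step offset)")
    r_s = activation(step.Vs, p)
    r_ps = activation(step.Vps, p)
    tau_step = time_constant(step.Vs, p)
    # activation reached at step offset
    r0 = r_s + (r_ps - r_s) * np.exp(-step.t_step / tau_step)
    tau_post = time_constant(step.Vps, p)
    r = r_ps + (r0 - r_ps) * np.exp(-t / tau_post)
    out = p.G * r * (step.Vps - c.Eh)
    return out if out.ndim else float(out)


def total_current(t, step: StepSpec, slow: ComponentParams, fast: ComponentParams,
                  c: ChannelConstants = ChannelConstants()):
    """Sum of the slow and fast component step currents (additive model)."""
    return step_current(t, step, slow, c) + step_current(t, step, fast, c)
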