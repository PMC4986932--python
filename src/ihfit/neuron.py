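"""Single-compartment vestibular ganglion neuron model with two Ih components.

The membrane carries a fast sodium current, high- and low-threshold
potassium currents (cochlear-nucleus kinetics, see `_rm03`), a leak, and the
slow and fast Ih components identified by the voltage-clamp methods::

    C dV/dt = -[ G_Na m^3 h (V-E_Na) + G_KH (0.85 n^2 + 0.15 p)(V-E_K)
                 + G_KL w^4 z (V-E_K) + G_l (V-E_l) + I_hs + I_hf ] + I_t

Two firing phenotypes are distinguished by the low-threshold potassium
conductance: sustained (tonic) neurons have G_KL = 0 nS, transient
(single-onset-spike) neurons G_KL = 50 nS.  All gating time constants are
accelerated from the 22 degrees C tables to physiological temperature with
a Q10 of 3.  Each Ih component is a first-order gate dr/dt = (r_inf - r)/tau_r
using the component's Boltzmann/Gaussian characteristic curves.

cAMP modulation of the Ih components (`apply_camp`) multiplies the maximal
conductances by 1.91, shifts the half-activations by +12 mV (toward
depolarisation, slope unchanged) and accelerates the kinetics by dividing
the fast component's time constants by 2.87 and the slow component's
by 5.31.

Integration is fixed-step exponential Euler for the gates with an
exponential update of the membrane equation (unconditionally stable),
dt = 0.01 ms by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from ._rm03 import GATE_NAMES, _inf_tau
from .channel import ComponentParams
from .clamp import recorded_cell_fixture

__all__ = ["NeuronConfig", "StimulusSpec", "SimResult", "ModulationSpec",
           "apply_camp", "simulate", "find_rest", "find_threshold_epsc",
           "conditioning_protocol", "rebound_map", "metrics"]

#: Ih maximal conductances used for the neuron simulations.  The recorded
#: cells' G_hs/G_hf were never published; these values are this package's
#: calibration (see docs/methods.md): with G_hs = 1.3 nS the slow-only
#: sustained model fires duration-graded rebound bursts in control and
#: duration-independent bursts of 2 (-250 pA) / 3 (-300 pA) spikes under
#: cAMP; with G_hf = 4 nS the fast-only model fires exactly one rebound
#: spike at the published test amplitudes.  G_HS_CONTROL_TRIPLE = 0.9 nS is
#: the alternative calibration at which the control -250 pA burst grades
#: exactly through 1/2/3 spikes with duration.
G_HS_DEFAULT = 1.3
G_HF_DEFAULT = 4.0
G_HS_CONTROL_TRIPLE = 0.9


def _default_slow() -> ComponentParams:
    # "figure" width assignment: the slow kinetic curve is the wide one,
    # keeping the slow component slow over the rebound-relevant voltages
    slow, _ = recorded_cell_fixture(widths="figure")
    return slow.replace(G=G_HS_DEFAULT)


def _default_fast() -> ComponentParams:
    _, fast = recorded_cell_fixture(widths="figure")
    return fast.replace(G=G_HF_DEFAULT)


@dataclass(frozen=True)
class NeuronConfig:
    """Conductances (nS), reversal potentials (mV) and Ih components.

    ``slow``/``fast`` may be None to remove a component.  ``temperature``
    and ``ref_temperature`` (degrees C) set the Q10 scaling: gating time
    constants accelerate by q10 ** (dT/10), and the transcribed Na/K
    conductances (whose table values are 22-degree magnitudes) grow by
    cond_q10 ** (dT/10), following the source model family.  The Ih
    conductances are taken as given (they are calibrated, not measured).
    """

    C: float = 12.0                 # pF
    G_Na: float = 1000.0
    G_KH: float = 140.0
    G_KL: float = 0.0
    G_l: float = 2.0
    E_Na: float = 50.0
    E_K: float = -77.0
    E_h: float = -36.0
    E_l: float = -67.0
    slow: ComponentParams | None = None
    fast: ComponentParams | None = None
    q10: float = 3.0
    cond_q10: float = 2.0
    temperature: float = 37.0
    ref_temperature: float = 22.0

    @property
    def phi(self) -> float:
        """Temperature acceleration factor applied to every gating tau."""
        return self.q10 ** ((self.temperature - self.ref_temperature) / 10.0)

    @property
    def phi_g(self) -> float:
        """Temperature scale factor applied to the Na/K conductances."""
        return self.cond_q10 ** ((self.temperature - self.ref_temperature) / 10.0)

    @property
    def phenotype(self) -> str:
        return "sustained" if self.G_KL == 0 else "transient"

    @classmethod
    def sustained(cls, ih: str = "both", camp: bool = False, **kw) -> "NeuronConfig":
        """Sustained (tonic-firing) phenotype: G_KL = 0 nS."""
        return cls._build(G_KL=0.0, ih=ih, camp=camp, **kw)

    @classmethod
    def transient(cls, ih: str = "both", camp: bool = False, **kw) -> "NeuronConfig":
        """Transient (single-onset-spike) phenotype: G_KL = 50 nS."""
        return cls._build(G_KL=50.0, ih=ih, camp=camp, **kw)

    @classmethod
    def _build(cls, G_KL: float, ih: str, camp: bool, **kw) -> "NeuronConfig":
        slow = kw.pop("slow", _default_slow())
        fast = kw.pop("fast", _default_fast())
        if camp:
            slow, fast = apply_camp(slow, fast)
        if ih == "slow":
            fast = None
        elif ih == "fast":
            slow = None
        elif ih == "none":
            slow = fast = None
        elif ih != "both":
            raise ValueError("ih must be 'both', 'slow', 'fast' or 'none'")
        return cls(G_KL=G_KL, slow=slow, fast=fast, **kw)

    def replace(self, **kw) -> "NeuronConfig":
        return replace(self, **kw)


@dataclass(frozen=True)
class ModulationSpec:
    """The cAMP transform of an Ih component's parameters."""

    conductance_factor: float = 1.91
    activation_shift_mV: float = 12.0
    fast_kinetic_divisor: float = 2.87
    slow_kinetic_divisor: float = 5.31
    divide_base: bool = True    # divide B as well as A (uniform speed-up)

    def __post_init__(self) -> None:
        if min(self.conductance_factor, self.fast_kinetic_divisor,
               self.slow_kinetic_divisor) <= 0:
            raise ValueError("modulation factors must be positive")


def apply_camp(slow: ComponentParams | None, fast: ComponentParams | None,
               mod: ModulationSpec = ModulationSpec()):
    """Apply cAMP modulation to the (slow, fast) Ih component pair.

    Conductances scale by the amplitude factor, half-activations shift
    toward depolarisation, and each component's kinetics accelerate by its
    own divisor; the slope k, kinetic-peak voltage M and width S are
    untouched.
    """
    def one(p: ComponentParams | None, divisor: float):
        if p is None:
            return None
        kw = dict(G=p.G * mod.conductance_factor,
                  Vh=p.Vh + mod.activation_shift_mV,
                  A=p.A / divisor)
        if mod.divide_base:
            kw["B"] = p.B / divisor
        return p.replace(**kw)

    return one(slow, mod.slow_kinetic_divisor), one(fast, mod.fast_kinetic_divisor)


@dataclass(frozen=True)
class StimulusSpec:
    """Injected-current stimulus: a rectangular step or a double-exponential
    EPSC-shaped transient (rise 0.05 ms, decay 5 ms by default)."""

    kind: str                    # "step" | "epsc"
    amplitude: float             # pA (positive = depolarizing)
    onset: float                 # ms
    duration: float = 0.0        # ms, step only
    tau_rise: float = 0.05       # ms, epsc only
    tau_decay: float = 5.0       # ms, epsc only

    def __post_init__(self) -> None:
        if self.kind not in ("step", "epsc"):
            raise ValueError("kind must be 'step' or 'epsc'")
        if self.kind == "epsc" and not self.tau_rise < self.tau_decay:
            raise ValueError("epsc needs tau_rise < tau_decay")

    def waveform(self, t: np.ndarray) -> np.ndarray:
        """Injected current (pA) on the time grid ``t`` (ms)."""
        out = np.zeros_like(t)
        if self.kind == "step":
            mask = (t >= self.onset) & (t < self.onset + self.duration)
            out[mask] = self.amplitude
        else:
            s = t - self.onset
            mask = s >= 0
            tpk = (self.tau_rise * self.tau_decay / (self.tau_decay - self.tau_rise)
                   * np.log(self.tau_decay / self.tau_rise))
            norm = np.exp(-tpk / self.tau_decay) - np.exp(-tpk / self.tau_rise)
            out[mask] = self.amplitude / norm * (
                np.exp(-s[mask] / self.tau_decay) - np.exp(-s[mask] / self.tau_rise))
        return out


# ---------------------------------------------------------------------------
# integration kernel


@njit(cache=True)
def _ih_inf_tau(v, Vh, k, M, S, A, B):
    r_inf = 1.0 / (1.0 + np.exp(-(v - Vh) / k))
    tau = B + A * np.exp(-((M - v) ** 2) / (S * S))
    return r_inf, tau


@njit(cache=True)
def _run(V0, g0, dt, n, stim, clampV, clamped, phi,
         C, GNa, GKH, GKL, Gl, ENa, EK, El, Eh,
         Ghs, ps, Ghf, pf):
    V = np.empty(n + 1)
    gates = np.empty((n + 1, 8))
    V[0] = V0
    gates[0] = g0
    for i in range(n):
        v = V[i]
        (m_inf, tau_m, h_inf, tau_h, n_inf, tau_n,
         p_inf, tau_p, w_inf, tau_w, z_inf, tau_z) = _inf_tau(v)
        m = m_inf + (gates[i, 0] - m_inf) * np.exp(-dt * phi / tau_m)
        h = h_inf + (gates[i, 1] - h_inf) * np.exp(-dt * phi / tau_h)
        nn = n_inf + (gates[i, 2] - n_inf) * np.exp(-dt * phi / tau_n)
        p = p_inf + (gates[i, 3] - p_inf) * np.exp(-dt * phi / tau_p)
        w = w_inf + (gates[i, 4] - w_inf) * np.exp(-dt * phi / tau_w)
        z = z_inf + (gates[i, 5] - z_inf) * np.exp(-dt * phi / tau_z)
        if Ghs > 0.0:
            rs_inf, tau_s = _ih_inf_tau(v, ps[0], ps[1], ps[2], ps[3], ps[4], ps[5])
            rs = rs_inf + (gates[i, 6] - rs_inf) * np.exp(-dt * phi / tau_s)
        else:
            rs = 0.0
        if Ghf > 0.0:
            rf_inf, tau_f = _ih_inf_tau(v, pf[0], pf[1], pf[2], pf[3], pf[4], pf[5])
            rf = rf_inf + (gates[i, 7] - rf_inf) * np.exp(-dt * phi / tau_f)
        else:
            rf = 0.0
        gates[i + 1, 0] = m
        gates[i + 1, 1] = h
        gates[i + 1, 2] = nn
        gates[i + 1, 3] = p
        gates[i + 1, 4] = w
        gates[i + 1, 5] = z
        gates[i + 1, 6] = rs
        gates[i + 1, 7] = rf
        if clamped[i]:
            V[i + 1] = clampV[i]
        else:
            gNa = GNa * m * m * m * h
            gKH = GKH * (0.85 * nn * nn + 0.15 * p)
            gKL = GKL * w * w * w * w * z
            gh = Ghs * rs + Ghf * rf
            g_tot = gNa + gKH + gKL + Gl + gh
            drive = (gNa * ENa + (gKH + gKL) * EK + Gl * El + gh * Eh + stim[i])
            v_inf = drive / g_tot
            V[i + 1] = v_inf + (v - v_inf) * np.exp(-dt * g_tot / C)
    return V, gates


def _params6(p: ComponentParams | None) -> np.ndarray:
    if p is None:
        return np.zeros(6)
    return np.array([p.Vh, p.k, p.M, p.S, p.A, p.B], dtype=float)


def _gate_steady(config: NeuronConfig, v: float) -> np.ndarray:
    vals = _inf_tau(float(v))
    g = np.empty(8)
    g[:6] = vals[0::2]
    for j, p in enumerate((config.slow, config.fast)):
        if p is None:
            g[6 + j] = 0.0
        else:
            g[6 + j] = 1.0 / (1.0 + np.exp(-(v - p.Vh) / p.k))
    return g


@dataclass
class SimResult:
    """Simulated voltage trajectory with spike times and gate histories."""

    t: np.ndarray
    V: np.ndarray
    gates: np.ndarray
    dt: float
    config: NeuronConfig
    stim: np.ndarray | None = None
    spike_threshold: float = -10.0
    spikes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.spikes = detect_spikes(self.t, self.V, self.spike_threshold)

    @property
    def spike_count(self) -> int:
        return len(self.spikes)

    def spikes_after(self, t0: float) -> np.ndarray:
        return self.spikes[self.spikes >= t0]

    def gate(self, name: str) -> np.ndarray:
        return self.gates[:, GATE_NAMES.index(name)]

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t, self.V, lw=0.8)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("V (mV)")
        return ax


def detect_spikes(t: np.ndarray, V: np.ndarray, threshold: float = -10.0,
                  refractory: float = 1.0) -> np.ndarray:
    """Spike peak times: upward threshold crossings grouped by a refractory
    window, each reported at the local voltage maximum that follows."""
    above = V >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    peaks = []
    last = -np.inf
    for idx in crossings:
        if t[idx] - last < refractory:
            continue
        end = idx
        while end + 1 < len(V) and above[end + 1]:
            end += 1
        peak_idx = idx + int(np.argmax(V[idx:end + 1]))
        peaks.append(t[peak_idx])
        last = t[idx]
    return np.asarray(peaks)


def simulate(config: NeuronConfig, stim: StimulusSpec | np.ndarray | None,
             t_end: float, dt: float = 0.01, V0: float | None = None,
             gates0: np.ndarray | None = None,
             clamp: np.ndarray | None = None) -> SimResult:
    """Integrate the membrane equation for ``t_end`` ms.

    ``stim`` is a `StimulusSpec`, a pre-sampled current array (pA) on the
    step grid, or None.  ``clamp`` may give a commanded voltage per step
    (NaN = free) to emulate voltage-clamp segments.  When ``V0`` is omitted
    the resting state is found first by relaxation.
    """
    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    if V0 is None:
        V0, gates0 = find_rest(config, dt=dt)
    if gates0 is None:
        gates0 = _gate_steady(config, V0)
    if isinstance(stim, StimulusSpec):
        stim_arr = stim.waveform(t[:-1])
    elif stim is None:
        stim_arr = np.zeros(n)
    else:
        stim_arr = np.asarray(stim, dtype=float)
        if stim_arr.size != n:
            raise ValueError("stimulus array must have one value per step")
    if clamp is None:
        clampV = np.zeros(n)
        clamped = np.zeros(n, dtype=np.bool_)
    else:
        clamp = np.asarray(clamp, dtype=float)
        clamped = ~np.isnan(clamp)
        clampV = np.where(clamped, clamp, 0.0)
    Ghs = config.slow.G if config.slow is not None else 0.0
    Ghf = config.fast.G if config.fast is not None else 0.0
    fg = config.phi_g
    V, gates = _run(float(V0), gates0.astype(float), dt, n, stim_arr, clampV,
                    clamped, config.phi, config.C, fg * config.G_Na,
                    fg * config.G_KH, fg * config.G_KL, config.G_l,
                    config.E_Na, config.E_K, config.E_l, config.E_h,
                    Ghs, _params6(config.slow), Ghf, _params6(config.fast))
    return SimResult(t=t, V=V, gates=gates, dt=dt, config=config, stim=stim_arr)


def find_rest(config: NeuronConfig, t_settle: float = 3000.0, dt: float = 0.02,
              V_start: float = -64.0) -> tuple[float, np.ndarray]:
    """Resting potential and steady gate values, found by relaxation."""
    n = int(round(t_settle / dt))
    g0 = _gate_steady(config, V_start)
    Ghs = config.slow.G if config.slow is not None else 0.0
    Ghf = config.fast.G if config.fast is not None else 0.0
    fg = config.phi_g
    V, gates = _run(V_start, g0, dt, n, np.zeros(n), np.zeros(n),
                    np.zeros(n, dtype=np.bool_), config.phi, config.C,
                    fg * config.G_Na, fg * config.G_KH, fg * config.G_KL,
                    config.G_l, config.E_Na, config.E_K, config.E_l,
                    config.E_h,
                    Ghs, _params6(config.slow), Ghf, _params6(config.fast))
    return float(V[-1]), gates[-1]


def find_threshold_epsc(config: NeuronConfig, tau_rise: float = 0.05,
                        tau_decay: float = 5.0, t_window: float = 30.0,
                        dt: float = 0.01, rel_tol: float = 1e-3,
                        A_max: float = 50000.0) -> float:
    """Minimal EPSC peak amplitude (pA) that elicits an action potential.

    Bisection on the peak amplitude of the double-exponential stimulus
    delivered at rest; raises if no action potential exists (no sodium
    conductance) or if even ``A_max`` fails to fire.
    """
    if config.G_Na == 0:
        raise RuntimeError("no spike threshold exists without a sodium "
                           "conductance (G_Na = 0)")
    V0, g0 = find_rest(config, dt=dt)

    def fires(amp: float) -> bool:
        stim = StimulusSpec("epsc", amp, onset=1.0, tau_rise=tau_rise,
                            tau_decay=tau_decay)
        sim = simulate(config, stim, t_end=t_window, dt=dt, V0=V0, gates0=g0)
        return sim.spike_count > 0

    hi = 200.0
    while not fires(hi):
        hi *= 2.0
        if hi > A_max:
            raise RuntimeError("no spike even at the maximal test amplitude; "
                               "is the sodium conductance present?")
    lo = 0.0
    while (hi - lo) > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if fires(mid):
            hi = mid
        else:
            lo = mid
    return hi


def conditioning_protocol(config: NeuronConfig, V_cond: float,
                          epsc_amplitude: float | None = None,
                          t_cond: float = 500.0, t_gap: float = 5.0,
                          t_after: float = 100.0, dt: float = 0.01,
                          tau_rise: float = 0.05, tau_decay: float = 5.0) -> SimResult:
    """Hyperpolarizing conditioning followed by an EPSC.

    The membrane is held (voltage-clamp-like) at ``V_cond`` for ``t_cond``
    ms — long enough for the Ih gates to approach steady state — then
    released current-free for ``t_gap`` ms before the EPSC is delivered.
    When ``epsc_amplitude`` is None it defaults to 10% above the unconditioned
    threshold.  A warning-worthy short conditioning (< 3 slow time constants)
    is allowed but will not reach Ih steady state.
    """
    if epsc_amplitude is None:
        epsc_amplitude = 1.10 * find_threshold_epsc(config, tau_rise, tau_decay, dt=dt)
    V0, g0 = find_rest(config, dt=dt)
    t_end = t_cond + t_gap + t_after
    n = int(round(t_end / dt))
    t = np.arange(n) * dt
    clamp = np.full(n, np.nan)
    clamp[t < t_cond] = V_cond
    stim = StimulusSpec("epsc", epsc_amplitude, onset=t_cond + t_gap,
                        tau_rise=tau_rise, tau_decay=tau_decay)
    sim = simulate(config, stim.waveform(t), t_end, dt=dt, V0=V0, gates0=g0,
                   clamp=clamp)
    sim.meta = {"stim_onset": t_cond + t_gap, "V_cond": V_cond,
                "epsc_amplitude": epsc_amplitude, "t_cond": t_cond,
                "t_gap": t_gap}
    return sim


def rebound_map(config: NeuronConfig, amplitudes=(-250.0, -300.0),
                durations=(100.0, 300.0, 500.0, 1000.0), t_after: float = 1000.0,
                dt: float = 0.02) -> np.ndarray:
    """Rebound action-potential counts after hyperpolarizing current steps.

    Returns an (n_amplitudes, n_durations) integer matrix of the number of
    spikes fired after stimulus offset.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if np.any(amplitudes >= 0):
        raise ValueError("rebound stimuli must be hyperpolarizing (negative)")
    V0, g0 = find_rest(config, dt=dt)
    out = np.zeros((len(amplitudes), len(durations)), dtype=int)
    for i, amp in enumerate(amplitudes):
        for j, dur in enumerate(durations):
            stim = StimulusSpec("step", amp, onset=10.0, duration=dur)
            sim = simulate(config, stim, t_end=10.0 + dur + t_after, dt=dt,
                           V0=V0, gates0=g0)
            out[i, j] = len(sim.spikes_after(10.0 + dur))
    return out


def _exp1(t, a, tau, c):
    return a * np.exp(-t / tau) + c


def _exp2(t, a1, tau1, a2, tau2, c):
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2) + c


def metrics(sim: SimResult, stim_onset: float | None = None,
            double_exp_tol: float = 0.02) -> dict:
    """Spike/EPSP metrics of a simulated response.

    AP latency is measured from the stimulus onset to the first spike peak
    (None when no spike fired).  The EPSP amplitude is the peak depolarization
    over the pre-stimulus baseline, and the decay time constant comes from a
    single-exponential fit to the falling phase; when the single-exponential
    residual exceeds ``double_exp_tol`` of the amplitude a double-exponential
    fit is reported as well (``decay_tau`` then holds the slower constant).
    """
    from scipy.optimize import curve_fit

    if stim_onset is None:
        stim_onset = getattr(sim, "meta", {}).get("stim_onset", 0.0)
    i_on = int(round(stim_onset / sim.dt))
    baseline = float(sim.V[max(0, i_on - 1)])
    post = sim.V[i_on:]
    t_post = sim.t[i_on:] - stim_onset
    spikes = sim.spikes_after(stim_onset)
    out: dict = {
        "resting_potential": baseline,
        "ap_count": int(len(spikes)),
        "ap_latency": float(spikes[0] - stim_onset) if len(spikes) else None,
    }
    i_peak = int(np.argmax(post))
    amp = float(post[i_peak] - baseline)
    out["epsp_amplitude"] = amp
    out["epsp_decay_tau"] = None
    out["epsp_decay_double"] = None
    if amp <= 0 or len(spikes):
        return out
    # falling phase: from the peak until the depolarization has mostly decayed
    decayed = np.flatnonzero(post[i_peak:] - baseline < 0.02 * amp)
    i_end = i_peak + (int(decayed[0]) if len(decayed) else len(post) - 1 - i_peak)
    seg_t = t_post[i_peak:i_end + 1] - t_post[i_peak]
    seg_v = post[i_peak:i_end + 1] - baseline
    if len(seg_t) < 5:
        return out
    try:
        p1, _ = curve_fit(_exp1, seg_t, seg_v, p0=(amp, 5.0, 0.0), maxfev=5000)
        resid1 = float(np.sqrt(np.mean((_exp1(seg_t, *p1) - seg_v) ** 2)))
        out["epsp_decay_tau"] = float(abs(p1[1]))
        if resid1 > double_exp_tol * amp:
            p2, _ = curve_fit(_exp2, seg_t, seg_v,
                              p0=(0.7 * amp, 2.0, 0.3 * amp, 15.0, 0.0),
                              maxfev=10000)
            taus = sorted((abs(p2[1]), abs(p2[3])))
            out["epsp_decay_double"] = {"tau_fast": taus[0], "tau_slow": taus[1]}
            out["epsp_decay_tau"] = taus[1]
    except RuntimeError:
        pass
    return out
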