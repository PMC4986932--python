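"""Voltage-clamp protocols, synthetic trace sets and parameter fixtures.

No public recordings exist for the two-component vestibular Ih currents this
package targets, so benchmarks are produced synthetically: the closed-form
two-component current is evaluated under the standard hyperpolarizing step
protocol (hold -60 mV, steps -60 ... -150/-160 mV in -10 mV decrements) and
corrupted with additive Gaussian white noise (SD 10 pA by default).

Trace sets round-trip through a CSV matrix (time column + one column per
step, header = step voltage) with a JSON sidecar holding the protocol
metadata, units and the noise seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .channel import ChannelConstants, ComponentParams, StepSpec, total_current

__all__ = [
    "ClampProtocol",
    "TraceSet",
    "standard_protocol",
    "synthesize",
    "benchmark_fixture",
    "recorded_cell_fixture",
    "import_traces",
    "export_traces",
]


@dataclass(frozen=True)
class ClampProtocol:
    """A family of voltage steps from a common holding potential.

    Attributes
    ----------
    V_hold : float
        Holding (pre-step and post-step) voltage, mV.
    step_voltages : tuple of float
        Ordered step voltages, mV.
    t_step : float
        Step duration, ms.
    t_post : float
        Post-step (deactivation) duration at ``V_hold``, ms.
    sample_interval : float
        Sampling interval, ms.
    """

    V_hold: float
    step_voltages: tuple
    t_step: float
    t_post: float
    sample_interval: float

    def __post_init__(self) -> None:
        if len(self.step_voltages) == 0:
            raise ValueError("protocol needs at least one step voltage")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.t_step <= 0 or self.t_post < 0:
            raise ValueError("invalid step timing")
        object.__setattr__(self, "step_voltages", tuple(float(v) for v in self.step_voltages))

    @property
    def n_steps(self) -> int:
        return len(self.step_voltages)

    @property
    def n_samples_step(self) -> int:
        return int(round(self.t_step / self.sample_interval))

    @property
    def n_samples_post(self) -> int:
        return int(round(self.t_post / self.sample_interval))

    @property
    def n_samples(self) -> int:
        return self.n_samples_step + self.n_samples_post

    @property
    def times(self) -> np.ndarray:
        """Sample times (ms) from step onset, spanning step + post segments."""
        return np.arange(self.n_samples) * self.sample_interval

    def step_spec(self, Vs: float) -> StepSpec:
        return StepSpec(Vps=self.V_hold, Vs=Vs, t_step=self.t_step, t_post=self.t_post)

    def to_dict(self) -> dict:
        return {
            "V_hold": self.V_hold,
            "step_voltages": list(self.step_voltages),
            "t_step": self.t_step,
            "t_post": self.t_post,
            "sample_interval": self.sample_interval,
        }


@dataclass
class TraceSet:
    """Current traces recorded or synthesized under a `ClampProtocol`.

    ``traces`` has shape (n_steps, n_samples): one row per step voltage,
    sampled at the protocol's interval from step onset through the post-step
    segment.  Units: pA.
    """

    protocol: ClampProtocol
    traces: np.ndarray
    noise_sd: float = 0.0
    seed: int | None = None
    provenance: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValueError("traces must be a 2-D array (n_steps, n_samples)")
        if self.traces.shape[0] != self.protocol.n_steps:
            raise ValueError(
                f"trace count {self.traces.shape[0]} != protocol step count {self.protocol.n_steps}"
            )
        if self.traces.shape[1] != self.protocol.n_samples:
            raise ValueError("trace length does not match protocol timing")

    @property
    def times(self) -> np.ndarray:
        return self.protocol.times

    @property
    def activation(self) -> np.ndarray:
        """The activation segment of every trace (samples during the step)."""
        return self.traces[:, : self.protocol.n_samples_step]

    @property
    def deactivation(self) -> np.ndarray:
        """The post-step (tail) segment of every trace."""
        return self.traces[:, self.protocol.n_samples_step:]


def standard_protocol(V_min: float = -150.0, t_step: float = 4000.0, t_post: float = 1000.0,
                      sample_interval: float = 1.0) -> ClampProtocol:
    """The hyperpolarizing step family used throughout: hold -60 mV, steps
    -60, -70, ... down to ``V_min`` in -10 mV decrements, then back to -60 mV.

    ``V_min=-150`` gives the 10-step benchmark protocol; ``V_min=-160`` the
    11-step variant used on recorded cells.
    """
    steps = np.arange(-60.0, V_min - 5.0, -10.0)
    return ClampProtocol(V_hold=-60.0, step_voltages=tuple(steps), t_step=t_step,
                         t_post=t_post, sample_interval=sample_interval)


def noiseless_traces(slow: ComponentParams, fast: ComponentParams | None,
                     protocol: ClampProtocol,
                     constants: ChannelConstants = ChannelConstants()) -> np.ndarray:
    """Closed-form total current matrix (n_steps, n_samples), no noise.

    ``fast`` may be None for a one-component current.  The post-step segment
    uses the symmetric deactivation closed form.
    """
    from .channel import deactivation_current, step_current

    n_act = protocol.n_samples_step
    t_act = np.arange(n_act) * protocol.sample_interval
    t_post = np.arange(protocol.n_samples_post) * protocol.sample_interval
    comps = [slow] if fast is None else [slow, fast]
    out = np.zeros((protocol.n_steps, protocol.n_samples))
    for i, Vs in enumerate(protocol.step_voltages):
        spec = protocol.step_spec(Vs)
        for p in comps:
            out[i, :n_act] += step_current(t_act, spec, p, constants)
            if protocol.n_samples_post:
                out[i, n_act:] += deactivation_current(t_post, spec, p, constants)
    return out


def synthesize(slow: ComponentParams, fast: ComponentParams | None = None,
               protocol: ClampProtocol | None = None, noise_sd: float = 10.0,
               seed: int | None = None,
               constants: ChannelConstants = ChannelConstants()) -> TraceSet:
    """Synthesize a noisy two-component (or one-component) trace set.

    White noise is i.i.d. zero-mean Gaussian with standard deviation
    ``noise_sd`` pA, added to every sample.  Deterministic under a fixed
    ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if protocol is None:
        protocol = standard_protocol()
    clean = noiseless_traces(slow, fast, protocol, constants)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        traces = clean + rng.normal(0.0, noise_sd, size=clean.shape)
    else:
        traces = clean
    return TraceSet(protocol=protocol, traces=traces, noise_sd=noise_sd, seed=seed,
                    provenance="synthetic")


def benchmark_fixture() -> tuple[ComponentParams, ComponentParams]:
    """The benchmark (slow, fast) parameter pair used for method evaluation.

    Chosen to match known inner-ear Ih physiology: a slow high-voltage-
    activated component and a fast low-voltage-activated one.
    """
    slow = ComponentParams(Vh=-100.0, k=-6.0, M=-80.0, S=80.0, A=1000.0, B=60.0, G=3.0)
    fast = ComponentParams(Vh=-130.0, k=-9.0, M=-80.0, S=40.0, A=250.0, B=40.0, G=4.0)
    return slow, fast


def recorded_cell_fixture(widths: str = "text", G_slow: float = 3.0, G_fast: float = 4.0,
                 M: float = -80.0) -> tuple[ComponentParams, ComponentParams]:
    """Parameters identified from recorded mouse vestibular ganglion cells.

    The published account assigns the Gaussian widths inconsistently between
    the running text (Sf = 59.8, Ss = 31.2) and the kinetic-curve figure
    legend (slow 59.8, fast 31.2); pass ``widths="text"`` or
    ``widths="figure"`` to select either reading.

    The maximal conductances and the kinetic-peak voltage M were never
    printed for the recorded cells; the defaults here (G 3 / 4 nS, M -80 mV,
    as in the synthetic benchmark) are this package's stand-ins, not
    published values.
    """
    if widths == "text":
        S_fast, S_slow = 59.8, 31.2
    elif widths == "figure":
        S_slow, S_fast = 59.8, 31.2
    else:
        raise ValueError("widths must be 'text' or 'figure'")
    # peak time constants 0.995 s (slow) and 0.244 s (fast); kinetic
    # amplitudes 0.99 and 0.24 s, so the bases are the small remainders
    slow = ComponentParams(Vh=-108.6, k=-9.6, M=M, S=S_slow, A=990.0, B=5.0, G=G_slow)
    fast = ComponentParams(Vh=-130.6, k=-5.1, M=M, S=S_fast, A=240.0, B=4.0, G=G_fast)
    return slow, fast


# ---------------------------------------------------------------------------
# CSV + JSON sidecar round-trip

def export_traces(ts: TraceSet, path: str | Path) -> None:
    """Write a trace set to ``path`` (CSV) plus ``path.json`` (sidecar)."""
    path = Path(path)
    cols = {"time_ms": ts.times}
    for Vs, row in zip(ts.protocol.step_voltages, ts.traces):
        cols[f"{Vs:g}"] = row
    pd.DataFrame(cols).to_csv(path, index=False)
    sidecar = {
        "schema": "ihfit-traceset-1",
        "units": {"time": "ms", "voltage": "mV", "current": "pA"},
        "protocol": ts.protocol.to_dict(),
        "noise_sd": ts.noise_sd,
        "seed": ts.seed,
        "provenance": ts.provenance,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def import_traces(path: str | Path) -> TraceSet:
    """Read a trace set written by `export_traces`.

    Raises if the sidecar is missing, units are not ms/mV/pA, or the trace
    columns do not match the protocol's step voltages.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing protocol sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    units = sidecar.get("units", {})
    if units != {"time": "ms", "voltage": "mV", "current": "pA"}:
        raise ValueError(f"unsupported units: {units}")
    protocol = ClampProtocol(**sidecar["protocol"])
    df = pd.read_csv(path)
    volt_cols = [c for c in df.columns if c != "time_ms"]
    got = [float(c) for c in volt_cols]
    if got != list(protocol.step_voltages):
        raise ValueError(
            f"trace columns {got} do not match protocol step voltages "
            f"{list(protocol.step_voltages)}"
        )
    traces = df[volt_cols].to_numpy().T
    return TraceSet(protocol=protocol, traces=traces, noise_sd=sidecar.get("noise_sd", 0.0),
                    seed=sidecar.get("seed"), provenance=sidecar.get("provenance", "imported"))
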