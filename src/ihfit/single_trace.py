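"""Classical per-trace (single-trace) identification of Ih components.

The single-trace method is the textbook Hodgkin–Huxley procedure: each
voltage-clamp trace is fitted independently with the closed-form step
response, yielding per-step estimates of the steady-state activation
r_inf(Vs), the time constant tau_r(Vs) and the maximal conductance G(Vs)
for every component.  The characteristic curves are then obtained in a
second stage: the conductances are averaged across steps, the r_inf(Vs)
points are fitted with a Boltzmann sigmoid (Vh, k) and the tau_r(Vs) points
with a Gaussian (M, S, A, B).

Because a single trace only constrains the product G * r_inf(Vs), the
(G, r) split is intrinsically degenerate at the per-trace stage; that
degeneracy is part of the baseline and is deliberately left in place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .channel import ChannelConstants, StepSpec
from .clamp import TraceSet
from .fitting import (IdentificationResults, SearchRegion, TrialRecord,
                      canonical_order, spawn_seeds)
from .full_trace import FullTraceModel

__all__ = ["PerStepEstimate", "SingleTraceModel"]


@dataclass
class PerStepEstimate:
    """Per-component amplitude/activation/kinetics estimate for one step.

    Arrays are ordered slow-first (larger tau).  ``flagged`` marks steps
    whose trace carries no signal (Vs equal to the pre-step voltage), where
    the time constant is unidentifiable.
    """

    Vs: float
    G: np.ndarray
    r: np.ndarray
    tau: np.ndarray
    rss: float
    flagged: bool = False


def _boltzmann(V, Vh, k):
    return 1.0 / (1.0 + np.exp(-(V - Vh) / k))


def _gaussian_tau(V, M, S, A, B):
    return B + A * np.exp(-((M - V) ** 2) / S**2)


def _multistart_curve_fit(fun, x, y, lower, upper, rng, n_restarts: int = 5):
    """Bounded least-squares curve fit with uniform random restarts."""
    best = None
    for _ in range(n_restarts):
        x0 = rng.uniform(lower, upper)
        try:
            res = optimize.least_squares(
                lambda p: fun(x, *p) - y, x0, bounds=(lower, upper), method="trf")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("curve fit failed from every restart")
    return best.x


class SingleTraceModel:
    """Per-trace identification baseline for a voltage-clamp trace set.

    Interface mirrors `FullTraceModel`: construct with a `TraceSet` and a
    `SearchRegion`, call :meth:`fit` for the multi-start pipeline.  Each
    trial fits every trace independently (random uniform initialization of
    the per-trace variables inside their bounds) and then assembles the
    characteristic curves; trials are ranked by the residual of the
    assembled reconstruction against the data.
    """

    def __init__(self, traceset: TraceSet, region: SearchRegion, n_components: int = 2,
                 constants: ChannelConstants = ChannelConstants(),
                 n_restarts: int = 5, maxfev: int = 100):
        if n_components not in (1, 2):
            raise ValueError("n_components must be 1 or 2")
        if region.n_components != n_components:
            region = region.for_order(n_components)
        self.traceset = traceset
        self.region = region
        self.n_components = n_components
        self.constants = constants
        self.n_restarts = n_restarts
        self.maxfev = maxfev
        # vectorized reconstruction/residual helper (shares the forward model)
        self._predictor = FullTraceModel(traceset, region, n_components,
                                         constants=constants)
        proto = traceset.protocol
        self._t_act = proto.times[:proto.n_samples_step]
        # per-trace bounds: G from the region, r in [0,1], tau from the
        # region's A+B band (the search range "A+B +/- tol")
        gl, gu = region.lower[:, 6], region.upper[:, 6]
        tl = region.lower[:, 4] + region.lower[:, 5]
        tu = region.upper[:, 4] + region.upper[:, 5]
        n = n_components
        self._lo = np.concatenate([np.maximum(gl, 0.0), np.zeros(n), np.maximum(tl, 1e-3)])
        self._up = np.concatenate([gu, np.ones(n), tu])

    # -- stage 1: independent fit of one trace -------------------------------
    def _trace_model(self, p: np.ndarray, drive: float) -> np.ndarray:
        """Σ_i G_i r_i (1 - exp(-t/tau_i)) * (Vs - Eh); gate starts at the
        pre-step steady state, which is 0 for Ih at the holding potential."""
        n = self.n_components
        G, r, tau = p[:n], p[n:2 * n], p[2 * n:]
        amp = (G * r)[:, None]
        return (amp * (1.0 - np.exp(-self._t_act[None, :] / tau[:, None]))).sum(axis=0) * drive

    def fit_trace(self, trace: np.ndarray, step: StepSpec,
                  rng: np.random.Generator | None = None) -> PerStepEstimate:
        """Least-squares mono-/bi-exponential fit of one activation segment.

        Returns per-component (G, r, tau) ordered slow-first by tau; ties
        broken by amplitude.  A step at the pre-step potential is flagged
        (amplitude ~ 0, tau unidentifiable).
        """
        trace = np.asarray(trace, dtype=float)[: self._t_act.size]
        if trace.size < 3 * self.n_components:
            raise ValueError("fewer samples than parameters")
        if rng is None:
            rng = np.random.default_rng()
        drive = step.Vs - self.constants.Eh
        x0 = rng.uniform(self._lo, self._up)
        n = self.n_components
        t = self._t_act

        def jac(p):
            G, r, tau = p[:n], p[n:2 * n], p[2 * n:]
            E = np.exp(-t[None, :] / tau[:, None])           # (comps, t)
            out = np.empty((t.size, 3 * n))
            out[:, :n] = (r[:, None] * (1 - E) * drive).T
            out[:, n:2 * n] = (G[:, None] * (1 - E) * drive).T
            out[:, 2 * n:] = (-(G * r)[:, None] * E
                              * (t[None, :] / tau[:, None] ** 2) * drive).T
            return out

        res = optimize.least_squares(
            lambda p: self._trace_model(p, drive) - trace, x0, jac=jac,
            bounds=(self._lo, self._up), method="trf", x_scale=self._up - self._lo,
            max_nfev=self.maxfev)
        p = np.clip(res.x, self._lo, self._up)
        rss = float(np.sum((self._trace_model(p, drive) - trace) ** 2))
        n = self.n_components
        G, r, tau = p[:n], p[n:2 * n], p[2 * n:]
        order = np.lexsort((-G * r, -tau))          # slow (largest tau) first
        flagged = abs(step.Vs - step.Vps) < 1e-9
        return PerStepEstimate(Vs=step.Vs, G=G[order], r=r[order], tau=tau[order],
                               rss=rss, flagged=flagged)

    # -- stage 2: characteristic-curve assembly ------------------------------
    def assemble(self, estimates: list[PerStepEstimate],
                 rng: np.random.Generator | None = None) -> np.ndarray:
        """Fit the characteristic curves to the per-step estimates.

        Per component: G is the across-step mean of the per-step maximal
        conductances, (Vh, k) come from a Boltzmann fit to the r_inf(Vs)
        points and (M, S, A, B) from a Gaussian fit to the tau_r(Vs) points.
        Both curve fits are bounded multi-start least squares.  Flagged
        steps (no signal: Vs at the pre-step potential, where the time
        constant is unidentifiable) are excluded.
        """
        estimates = [e for e in estimates if not e.flagged]
        if len(estimates) < 4:
            raise ValueError("need at least 4 usable steps to fit the curves")
        if rng is None:
            rng = np.random.default_rng()
        Vs = np.array([e.Vs for e in estimates])
        out = np.empty((self.n_components, 7))
        for ci in range(self.n_components):
            r_pts = np.array([e.r[ci] for e in estimates])
            tau_pts = np.array([e.tau[ci] for e in estimates])
            G = float(np.mean([e.G[ci] for e in estimates]))
            lo, up = self.region.lower[ci], self.region.upper[ci]
            Vh, k = _multistart_curve_fit(_boltzmann, Vs, r_pts,
                                          lo[:2], up[:2], rng, self.n_restarts)
            M, S, A, B = _multistart_curve_fit(_gaussian_tau, Vs, tau_pts,
                                               lo[2:6], up[2:6], rng, self.n_restarts)
            out[ci] = (Vh, k, M, S, A, B, G)
        return canonical_order(out)

    # -- multi-start pipeline -------------------------------------------------
    def fit_one(self, seed: int | None = None) -> TrialRecord:
        """One complete single-trace trial over all traces."""
        rng = np.random.default_rng(seed)
        proto = self.traceset.protocol
        estimates = [
            self.fit_trace(self.traceset.traces[i], proto.step_spec(Vs), rng)
            for i, Vs in enumerate(proto.step_voltages)
        ]
        x = self.assemble(estimates, rng)
        rss = self._predictor.rss(x)
        return TrialRecord(x0=np.full_like(x, np.nan), x=x, rss=rss,
                           converged=True, seed=seed)

    def fit(self, n_trials: int = 50, keep_fraction: float = 0.28,
            seed: int | None = None) -> IdentificationResults:
        """Multi-start single-trace identification (same retention scheme as
        the full-trace method: keep the lowest-residual fraction, average)."""
        if n_trials < 1:
            raise ValueError("n_trials must be at least 1")
        seeds = spawn_seeds(seed, n_trials)
        trials = [self.fit_one(seed=s) for s in seeds]
        return IdentificationResults(self, trials, keep_fraction, "single-trace", seed)

    # reconstruction helpers reuse the shared forward model
    def predict(self, mat: np.ndarray, segment: str = "activation") -> np.ndarray:
        return self._predictor.predict(mat, segment)

    def rss(self, mat: np.ndarray) -> float:
        return self._predictor.rss(mat)
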