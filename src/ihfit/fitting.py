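"""Shared infrastructure for the two identification methods.

Both methods search a bounded region around a centre parameter vector
(`SearchRegion`), run many independent randomly-initialized trials, retain
the best fraction (the first mode of the residual distribution), and average
the retained parameter vectors.  `IdentificationResults` is the common
results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .channel import ChannelConstants, ComponentParams, PARAM_NAMES
from .clamp import TraceSet, noiseless_traces

__all__ = ["SearchRegion", "TrialRecord", "IdentificationResults", "spawn_seeds"]


def spawn_seeds(seed: int | None, n: int) -> list[int]:
    """Deterministically derive ``n`` independent sub-seeds from a master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


@dataclass(frozen=True)
class SearchRegion:
    """Box constraints per component parameter.

    ``lower`` and ``upper`` have shape (n_components, 7) in the canonical
    parameter order (Vh, k, M, S, A, B, G).  Regions are usually built as a
    fractional tolerance band around a centre vector: each bound is
    centre ± |centre| * tol, so a tol of 0.8 spans 80% either side.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.atleast_2d(np.asarray(self.lower, dtype=float))
        up = np.atleast_2d(np.asarray(self.upper, dtype=float))
        if lo.shape != up.shape or lo.shape[1] != 7:
            raise ValueError("bounds must have shape (n_components, 7)")
        if not np.all(lo < up):
            raise ValueError("every lower bound must be strictly below its upper bound")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)

    @classmethod
    def around(cls, components, tol: float = 0.8) -> "SearchRegion":
        """Tolerance band of fractional size ``tol`` around centre components."""
        if tol <= 0 or tol >= 1:
            raise ValueError("tol must lie in (0, 1) so bounds keep their sign")
        centres = np.array([c.to_vector() for c in components])
        half = np.abs(centres) * tol
        return cls(centres - half, centres + half)

    @property
    def n_components(self) -> int:
        return self.lower.shape[0]

    @property
    def centre(self) -> np.ndarray:
        return 0.5 * (self.lower + self.upper)

    def for_order(self, n: int) -> "SearchRegion":
        """Adapt the region to a model of ``n`` components.

        Components are assumed ordered slow-first.  Shrinking to one
        component pools the maximal conductance bounds (the single component
        has to carry the whole current); growing repeats the last component.
        """
        if n == self.n_components:
            return self
        lo, up = self.lower.copy(), self.upper.copy()
        if n < self.n_components:
            lo, up = lo[:n].copy(), up[:n].copy()
            if n == 1:
                lo[0, 6] = self.lower[:, 6].sum()
                up[0, 6] = self.upper[:, 6].sum()
        else:
            extra = n - self.n_components
            lo = np.vstack([lo] + [lo[-1:]] * extra)
            up = np.vstack([up] + [up[-1:]] * extra)
        return SearchRegion(lo, up)

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        """Uniform random parameter matrix (n_components, 7) inside the region."""
        return rng.uniform(self.lower, self.upper)

    def clip(self, mat: np.ndarray) -> np.ndarray:
        return np.clip(mat, self.lower, self.upper)

    def flat_bounds(self) -> list[tuple[float, float]]:
        return list(zip(self.lower.ravel(), self.upper.ravel()))


@dataclass
class TrialRecord:
    """One randomly initialized identification trial."""

    x0: np.ndarray          # initial parameter matrix (n_components, 7)
    x: np.ndarray           # final parameter matrix, canonically ordered
    rss: float              # residual sum of squares against the data
    converged: bool
    seed: int | None = None

    def components(self) -> list[ComponentParams]:
        return [ComponentParams.from_vector(row) for row in self.x]


def canonical_order(mat: np.ndarray) -> np.ndarray:
    """Order component rows slow-first by peak time constant A + B.

    Ties (identical kinetics) are broken by amplitude G, larger first, so
    label permutations of identical trials average identically.
    """
    mat = np.atleast_2d(mat)
    tau_peak = mat[:, 4] + mat[:, 5]
    order = np.lexsort((-mat[:, 6], -tau_peak))
    return mat[order]


class IdentificationResults:
    """Identified component parameters plus per-trial provenance.

    Produced by ``SingleTraceModel.fit`` and ``FullTraceModel.fit``.  The
    final estimate is the arithmetic mean of the retained (lowest-residual)
    trials' parameter vectors after canonical slow-first relabelling.
    """

    def __init__(self, model, trials: list[TrialRecord], keep_fraction: float,
                 method: str, seed: int | None):
        if not trials:
            raise ValueError("no trials to summarize")
        self.model = model
        self.trials = trials
        self.keep_fraction = keep_fraction
        self.method = method
        self.seed = seed
        order = np.argsort([t.rss for t in trials], kind="stable")
        n_keep = max(1, int(round(keep_fraction * len(trials))))
        self.kept_indices = order[:n_keep]
        stack = np.array([trials[i].x for i in self.kept_indices])
        self._kept_stack = stack
        self.params = stack.mean(axis=0)

    # -- parameter access ---------------------------------------------------
    @property
    def n_components(self) -> int:
        return self.params.shape[0]

    @property
    def components(self) -> list[ComponentParams]:
        return [ComponentParams.from_vector(row) for row in self.params]

    @property
    def slow(self) -> ComponentParams:
        return self.components[0]

    @property
    def fast(self) -> ComponentParams:
        if self.n_components < 2:
            raise ValueError("fit has a single component")
        return self.components[-1]

    @property
    def kept_trials(self) -> list[TrialRecord]:
        return [self.trials[i] for i in self.kept_indices]

    @property
    def best_rss(self) -> float:
        return float(self.trials[self.kept_indices[0]].rss)

    # -- reconstruction and goodness of fit ---------------------------------
    def _component_split(self) -> tuple[ComponentParams, ComponentParams | None]:
        comps = self.components
        if len(comps) == 1:
            return comps[0], None
        if len(comps) == 2:
            return comps[0], comps[1]
        raise ValueError("reconstruction helpers support 1 or 2 components")

    def reconstruct(self, which: str = "total") -> np.ndarray:
        """Noise-free reconstruction of the traces from the final estimate.

        ``which`` is "total", "slow" or "fast"; shape matches the data.
        """
        ts: TraceSet = self.model.traceset
        c: ChannelConstants = self.model.constants
        slow, fast = self._component_split()
        if which == "total":
            return noiseless_traces(slow, fast, ts.protocol, c)
        if which == "slow":
            return noiseless_traces(slow, None, ts.protocol, c)
        if which == "fast":
            if fast is None:
                raise ValueError("fit has no fast component")
            return noiseless_traces(fast, None, ts.protocol, c)
        raise ValueError(f"unknown reconstruction target {which!r}")

    def gof(self, which: str = "total", reference: np.ndarray | None = None,
            segment: str = "activation") -> float:
        """Coefficient-of-determination goodness of fit of the reconstruction.

        Compared against ``reference`` traces when given (e.g. the noiseless
        truth of one component), else against the fitted data themselves.
        """
        from .evaluation import goodness_of_fit

        recon = self.reconstruct(which)
        ref = self.model.traceset.traces if reference is None else np.asarray(reference)
        n_act = self.model.traceset.protocol.n_samples_step
        if segment == "activation":
            recon, ref = recon[:, :n_act], ref[:, :n_act]
        return goodness_of_fit(ref.ravel(), recon.ravel())

    # -- error reporting ----------------------------------------------------
    def percent_errors(self, truth) -> pd.DataFrame:
        """Per-parameter percent identification error per retained trial.

        ``truth`` is the list of true ComponentParams (slow first).  Errors
        use epsilon = |p - p_i| / |p| * 100.  Returns a tidy DataFrame with
        one row per (trial, component, parameter).
        """
        truth_mat = canonical_order(np.array([c.to_vector() for c in truth]))
        if truth_mat.shape[0] != self.n_components:
            raise ValueError("truth component count does not match the fit")
        labels = self._component_labels()
        rows = []
        for rank, idx in enumerate(self.kept_indices):
            est = self.trials[idx].x
            eps = 100.0 * np.abs(truth_mat - est) / np.abs(truth_mat)
            for ci in range(self.n_components):
                for pi, pname in enumerate(PARAM_NAMES):
                    rows.append({"trial": int(idx), "rank": rank,
                                 "component": labels[ci], "parameter": pname,
                                 "error_pct": eps[ci, pi]})
        return pd.DataFrame(rows)

    def grand_mean_error(self, truth) -> float:
        """Mean percent error over all parameters and retained trials."""
        df = self.percent_errors(truth)
        return float(df.groupby(["component", "parameter"])["error_pct"].mean().mean())

    def _component_labels(self) -> list[str]:
        if self.n_components == 1:
            return ["only"]
        if self.n_components == 2:
            return ["slow", "fast"]
        return [f"c{i}" for i in range(self.n_components)]

    # -- presentation --------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"{self.method} identification ({self.n_components} component"
            f"{'s' if self.n_components > 1 else ''})",
            f"trials: {len(self.trials)}, retained: {len(self.kept_indices)} "
            f"(keep_fraction={self.keep_fraction}), seed={self.seed}",
            f"best residual sum of squares: {self.best_rss:.6g} pA^2",
            "",
            "         " + "".join(f"{n:>10}" for n in PARAM_NAMES),
        ]
        sem = self._kept_stack.std(axis=0, ddof=1) / np.sqrt(len(self.kept_indices)) \
            if len(self.kept_indices) > 1 else np.zeros_like(self.params)
        for label, row, se in zip(self._component_labels(), self.params, sem):
            lines.append(f"{label:>8} " + "".join(f"{v:>10.3f}" for v in row))
            lines.append(f"{'SEM':>8} " + "".join(f"{v:>10.3f}" for v in se))
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Overlay the data traces and the reconstruction (activation segment)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ts = self.model.traceset
        n_act = ts.protocol.n_samples_step
        t = ts.times[:n_act]
        recon = self.reconstruct("total")[:, :n_act]
        for i in range(ts.protocol.n_steps):
            ax.plot(t, ts.traces[i, :n_act], color="0.7", lw=0.6)
            ax.plot(t, recon[i], color="k", lw=1.0)
        ax.set_xlabel("time (ms)")
        ax.set_ylabel("current (pA)")
        ax.set_title(f"{self.method} reconstruction")
        return ax

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "seed": self.seed,
            "keep_fraction": self.keep_fraction,
            "n_trials": len(self.trials),
            "kept_indices": [int(i) for i in self.kept_indices],
            "components": [c.to_dict() for c in self.components],
            "trials": [
                {"x0": t.x0.tolist(), "x": t.x.tolist(), "rss": float(t.rss),
                 "converged": bool(t.converged), "seed": t.seed}
                for t in self.trials
            ],
        }
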