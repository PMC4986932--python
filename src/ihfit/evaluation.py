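"""Method evaluation: error metrics, goodness of fit, comparisons, sweeps.

The two identification methods are benchmarked on synthetic two-component
trace sets whose generating parameters are known, so every identified
parameter carries a relative error epsilon = |p - p_i| / |p| * 100.  The
comparison report mirrors the standard layout: per-parameter mean +/- SEM
percent error over the retained trials for each method, slow-vs-fast
Student t-tests per parameter, and the grand mean over all parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .channel import ChannelConstants, ComponentParams, PARAM_NAMES
from .clamp import ClampProtocol, noiseless_traces, standard_protocol, synthesize
from .fitting import SearchRegion
from .full_trace import FullTraceModel
from .single_trace import SingleTraceModel

__all__ = ["percent_error", "goodness_of_fit", "compare_methods",
           "sensitivity_sweep", "MethodComparison", "SweepResult"]


def percent_error(p_true: float, p_est: float) -> float:
    """Relative identification error epsilon = |p - p_i| / |p| * 100 (%).

    Falls back to the absolute difference when the true value is exactly
    zero (the relative form is undefined there); callers can detect the
    fallback by checking ``p_true == 0``.
    """
    if p_true == 0:
        return abs(p_est)
    return 100.0 * abs(p_true - p_est) / abs(p_true)


def goodness_of_fit(y_data, y_model) -> float:
    """Coefficient-of-determination goodness of fit, GoF <= 1.

    GoF = 1 - sum((y - y_hat)^2) / sum((y - mean(y))^2); 1 for a perfect
    fit, 0 for a fit no better than the data mean.  Raises on a constant
    reference series (denominator undefined).
    """
    y = np.asarray(y_data, dtype=float).ravel()
    yhat = np.asarray(y_model, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("series must have equal length")
    denom = float(np.sum((y - y.mean()) ** 2))
    if denom == 0.0:
        raise ValueError("goodness of fit undefined for a constant reference")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / denom


# ---------------------------------------------------------------------------


@dataclass
class MethodComparison:
    """Side-by-side error report for the single- and full-trace methods."""

    table: pd.DataFrame          # per (method, component, parameter): mean, sem
    pvalues: pd.DataFrame        # per (method, parameter): slow-vs-fast P
    grand_mean: dict             # method -> grand mean % error
    gof: dict                    # method -> {"combined", "slow", "fast"}
    results: dict = field(default_factory=dict, repr=False)

    def summary(self) -> str:
        lines = ["Method comparison (percent identification error, mean +/- SEM)"]
        for method in self.table.index.get_level_values(0).unique():
            lines.append(f"\n{method} (grand mean {self.grand_mean[method]:.2f}%)")
            sub = self.table.loc[method]
            header = "          " + "".join(f"{p:>12}" for p in PARAM_NAMES)
            lines.append(header)
            for comp in ("slow", "fast"):
                row = sub.loc[comp]
                cells = "".join(
                    f"{row.loc[p, 'mean']:>6.1f}±{row.loc[p, 'sem']:<5.1f}"
                    for p in PARAM_NAMES)
                lines.append(f"{comp:>8}  {cells}")
            pv = self.pvalues.loc[method]
            lines.append("       P  " + "".join(f"{pv[p]:>12.3f}" for p in PARAM_NAMES))
            g = self.gof[method]
            lines.append(f"   GoF combined {g['combined']:.3f}, slow {g['slow']:.3f}, "
                         f"fast {g['fast']:.3f}")
        return "\n".join(lines)


def _error_table(results, truth, method: str, equal_var: bool) -> tuple:
    df = results.percent_errors(truth)
    stats_df = (df.groupby(["component", "parameter"])["error_pct"]
                  .agg(["mean", "sem"]))
    pvals = {}
    for p in PARAM_NAMES:
        a = df[(df.component == "slow") & (df.parameter == p)]["error_pct"]
        b = df[(df.component == "fast") & (df.parameter == p)]["error_pct"]
        pvals[p] = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
    grand = float(stats_df["mean"].mean())
    return stats_df, pd.Series(pvals), grand


def compare_methods(slow: ComponentParams, fast: ComponentParams,
                    protocol: ClampProtocol | None = None, noise_sd: float = 10.0,
                    tol: float = 0.8, n_trials: int = 50, keep_fraction: float = 0.28,
                    seed: int | None = None, equal_var: bool = True,
                    constants: ChannelConstants = ChannelConstants(),
                    optimizer: str = "least_squares") -> MethodComparison:
    """Run both identification methods on one synthetic benchmark.

    Synthesizes a noisy two-component trace set from the true parameters,
    feeds the same trace set to both methods (multi-start with the given
    trial count and retention fraction, search region of fractional size
    ``tol`` around the truth) and reports per-parameter percent errors,
    slow-vs-fast t-tests, grand means, and reconstruction GoF values for the
    combined current and each isolated component.
    """
    if protocol is None:
        protocol = standard_protocol()
    ts = synthesize(slow, fast, protocol, noise_sd=noise_sd, seed=seed,
                    constants=constants)
    region = SearchRegion.around((slow, fast), tol=tol)
    truth = [slow, fast]
    clean = {
        "combined": noiseless_traces(slow, fast, protocol, constants),
        "slow": noiseless_traces(slow, None, protocol, constants),
        "fast": noiseless_traces(fast, None, protocol, constants),
    }

    table_parts, pv_parts, grand, gof, results = [], [], {}, {}, {}
    runs = {
        "single-trace": SingleTraceModel(ts, region, constants=constants),
        "full-trace": FullTraceModel(ts, region, constants=constants,
                                     optimizer=optimizer),
    }
    for name, model in runs.items():
        res = model.fit(n_trials=n_trials, keep_fraction=keep_fraction, seed=seed)
        results[name] = res
        tdf, pv, g = _error_table(res, truth, name, equal_var)
        tdf = pd.concat({name: tdf}, names=["method"])
        table_parts.append(tdf)
        pv_parts.append(pd.concat({name: pv}, names=["method"]))
        grand[name] = g
        gof[name] = {
            "combined": res.gof("total", clean["combined"]),
            "slow": res.gof("slow", clean["slow"]),
            "fast": res.gof("fast", clean["fast"]),
        }
    return MethodComparison(table=pd.concat(table_parts),
                            pvalues=pd.concat(pv_parts).unstack(level=-1),
                            grand_mean=grand, gof=gof, results=results)


# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """Per-grid-point identification errors for one swept variable."""

    variable: str
    grid: np.ndarray
    table: pd.DataFrame   # rows: grid points; columns: (method, error name)

    def averaged_error(self, method: str) -> np.ndarray:
        """The per-point averaged error m of one method (mean over the
        Vhs, Vhf, As, Af errors)."""
        cols = [(method, k) for k in ("Vhs", "Vhf", "As", "Af")]
        return self.table[cols].mean(axis=1).to_numpy()


_SWEEP_DEFAULTS = {
    # tol must stay below 1 so the bounds keep each parameter's sign
    "tol": np.linspace(0.2, 0.9, 5),
    "delta_act": np.linspace(-130.0, -90.0, 5),   # swept Vhs
    "delta_kin": np.linspace(250.0, 1250.0, 5),   # swept As
}


def sensitivity_sweep(variable: str, grid=None,
                      base: tuple[ComponentParams, ComponentParams] | None = None,
                      protocol: ClampProtocol | None = None, noise_sd: float = 10.0,
                      tol: float = 0.8, n_trials: int = 20, keep_fraction: float = 0.3,
                      seed: int | None = None, optimizer: str = "least_squares") -> SweepResult:
    """Sensitivity of both methods to the search-zone size or the component
    separation.

    ``variable`` is one of:

    * ``"tol"`` — the fractional size of the search region;
    * ``"delta_act"`` — the slow half-activation Vhs (changing the
      activation separation |Vhs - Vhf| at fixed Vhf);
    * ``"delta_kin"`` — the slow kinetic amplitude As (changing the kinetic
      separation |As - Af| at fixed Af).

    At every grid point the benchmark is regenerated from the modified
    truth, both methods are run, and the mean percent errors of Vhs, Vhf,
    As and Af over the retained trials are recorded.
    """
    if variable not in _SWEEP_DEFAULTS:
        raise ValueError(f"unknown sweep variable {variable!r}")
    if grid is None:
        grid = _SWEEP_DEFAULTS[variable]
    grid = np.asarray(grid, dtype=float)
    if base is None:
        from .clamp import benchmark_fixture
        base = benchmark_fixture()
    slow0, fast0 = base
    if protocol is None:
        protocol = standard_protocol()

    from .fitting import spawn_seeds
    seeds = spawn_seeds(seed, len(grid))
    rows = []
    for point, s in zip(grid, seeds):
        slow, fast, tol_i = slow0, fast0, tol
        if variable == "tol":
            tol_i = float(point)
        elif variable == "delta_act":
            slow = slow0.replace(Vh=float(point))
        else:
            slow = slow0.replace(A=float(point))
        # Vhs == Vhf (or As == Af) leaves the two components formally
        # unidentifiable; the errors are still recorded, just expect them
        # to be large there.
        cmp_res = compare_methods(slow, fast, protocol, noise_sd=noise_sd,
                                  tol=tol_i, n_trials=n_trials,
                                  keep_fraction=keep_fraction, seed=s,
                                  optimizer=optimizer)
        row = {}
        for method in ("single-trace", "full-trace"):
            sub = cmp_res.table.loc[method]
            row[(method, "Vhs")] = sub.loc[("slow", "Vh"), "mean"]
            row[(method, "Vhf")] = sub.loc[("fast", "Vh"), "mean"]
            row[(method, "As")] = sub.loc[("slow", "A"), "mean"]
            row[(method, "Af")] = sub.loc[("fast", "A"), "mean"]
        rows.append(row)
    table = pd.DataFrame(rows, index=pd.Index(grid, name=variable))
    table.columns = pd.MultiIndex.from_tuples(table.columns,
                                              names=["method", "error"])
    return SweepResult(variable=variable, grid=grid, table=table)
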