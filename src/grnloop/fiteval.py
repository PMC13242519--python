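"""Weighted least-squares fitting, L1 reduction and goodness-of-fit.

The objective is the chi-square misfit: each residual is
(simulated - measured) / SE_eff for one (gene, time point) record, and
chi2 is the sum of squared residuals.  Fitting is multi-start bounded
least squares: initial parameter vectors are sampled reproducibly from a
seed (log-uniform for strengths a_* and decays delta_*, uniform for Hill
exponents h_* and productions b_*), each start is refined by a bounded
trust-region optimizer, and the lowest-chi2 solution wins.

Model reduction is a three-stage protocol: (1) fit with an additive L1
penalty lambda * sum |theta| on the interaction parameters (prefixes a_,
b_, h_, delta_; the absolute value is smoothed as sqrt(theta^2 + eps^2)
so the bounded optimizer sees a differentiable objective), (2) fix every
penalized parameter whose L1 estimate is below the threshold (default
|p| < 10) at that estimate, (3) refit the surviving free parameters
without penalty from the L1 solution.  An essentially unchanged chi2
after reduction indicates the fixed parameters were redundant.

Goodness of fit: dof = n - k; the p-value is the upper tail of the
chi-square distribution at the observed chi2 (the probability of the
observed misfit under pure white noise); AIC = chi2 + 2k,
AICc = AIC + 2k(k+1)/(n-k-1), BIC = chi2 + k ln n.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2 as chi2_dist

from ._fastode import FastIntegrator
from .odemodel import GRNModel, SimulationError, simulate
from .preprocess import TimeSeriesDataset

L1_PREFIXES = ("a_", "b_", "h_", "delta_")
_SMOOTH_EPS = 1e-8
_FAIL_RESIDUAL = 1e6


@dataclass
class L1Config:
    """L1-reduction settings: penalty weight, penalized classes, threshold."""

    penalty: float = 50.0
    prefixes: tuple = L1_PREFIXES
    fix_threshold: float = 10.0

    def __post_init__(self):
        if self.penalty < 0 or self.fix_threshold < 0:
            raise ValueError("penalty and threshold must be >= 0")


@dataclass
class FitResult:
    """Best multi-start estimate with the per-point chi-square table."""

    params: dict                    # all parameters, fixed ones included
    chi2: float
    per_point: pd.DataFrame         # gene, time_days, exp_mean, se, simulated, chi2
    n: int                          # number of non-missing residuals
    k: int                          # free parameters
    fixed: dict = field(default_factory=dict)
    n_starts: int = 1
    best_start: int = 0
    seed: int = 0
    start_chi2: tuple = ()

    def per_point_csv(self, path) -> None:
        df = self.per_point.copy()
        df.columns = ["Variable", "Time", "ExpData", "Std", "SimulatedData",
                      "Chi2"]
        df["DataIndex"] = np.arange(len(df))
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class GoFStats:
    """Model-selection statistics derived from (chi2, n, k)."""

    chi2: float
    n: int
    k: int
    dof: int
    p_value: float
    aic: float
    aicc: float
    bic: float
    chi2_per_dof: float

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "n": self.n, "k": self.k, "dof": self.dof,
                "p_value": self.p_value, "aic": self.aic, "aicc": self.aicc,
                "bic": self.bic, "chi2_per_dof": self.chi2_per_dof}


def gof_stats(chi2: float, n: int, k: int) -> GoFStats:
    """All goodness-of-fit statistics from a (chi2, n, k) triple."""
    if chi2 < 0 or n < 0 or k < 0:
        raise ValueError("chi2, n and k must be non-negative")
    dof = n - k
    if dof > 0:
        p = float(chi2_dist.sf(chi2, dof))
        per_dof = chi2 / dof
    else:
        warnings.warn("n <= k: p-value and chi2/dof undefined")
        p = math.nan
        per_dof = math.nan
    aic = chi2 + 2 * k
    bic = chi2 + k * math.log(n) if n > 0 else math.nan
    if n - k - 1 > 0:
        aicc = aic + 2 * k * (k + 1) / (n - k - 1)
    else:
        warnings.warn("n - k - 1 <= 0: AICc undefined")
        aicc = math.nan
    return GoFStats(chi2=chi2, n=n, k=k, dof=dof, p_value=p, aic=aic,
                    aicc=aicc, bic=bic, chi2_per_dof=per_dof)


class _Objective:
    """Residual evaluator binding model, dataset and fixed parameters."""

    def __init__(self, model: GRNModel, dataset: TimeSeriesDataset,
                 x0=None, u: float = 1.0, rtol: float = 1e-6,
                 atol: float = 1e-8, fixed: dict = None, fast: bool = True):
        extra = set(dataset.genes) - set(model.genes)
        if extra:
            raise ValueError(f"dataset genes not in model: {sorted(extra)}")
        self.model = model
        self.dataset = dataset
        self.u = u
        self.rtol = rtol
        self.atol = atol
        self.fixed = dict(fixed or {})
        self._fast = FastIntegrator(model) if fast else None
        table = dataset.table.sort_values(["gene", "time_days"]).reset_index(drop=True)
        if np.any(table["se_eff"] <= 0):
            raise ValueError("all SE_eff values must be > 0 (floor them upstream)")
        self.table = table
        self.times = np.sort(table["time_days"].unique())
        tidx = {t: i for i, t in enumerate(self.times)}
        gidx = {g: i for i, g in enumerate(model.genes)}
        self.rec_t = table["time_days"].map(tidx).to_numpy()
        self.rec_g = table["gene"].map(gidx).to_numpy()
        self.means = table["mean"].to_numpy(dtype=float)
        self.ses = table["se_eff"].to_numpy(dtype=float)
        self.x0 = (np.asarray(x0, dtype=float) if x0 is not None
                   else dataset.initial_state(model.genes))
        free = [n for n in model.param_names if n not in self.fixed]
        self.free_names = tuple(free)
        self.fixed_vec = np.array(
            [self.fixed.get(n, 0.0) for n in model.param_names])
        self.free_pos = np.array(
            [i for i, n in enumerate(model.param_names) if n not in self.fixed],
            dtype=int)

    @property
    def n_records(self) -> int:
        return len(self.table)

    def full_vector(self, free_vec: np.ndarray) -> np.ndarray:
        theta = self.fixed_vec.copy()
        theta[self.free_pos] = free_vec
        return theta

    def simulated(self, theta: np.ndarray) -> np.ndarray:
        if self._fast is not None:
            values, ok = self._fast(theta, self.times, self.x0, u=self.u,
                                    rtol=self.rtol, atol=self.atol)
            if not ok:
                raise SimulationError("fast integrator failed to converge")
            return values[self.rec_t, self.rec_g]
        traj = simulate(self.model, theta, self.times, self.x0, u=self.u,
                        rtol=self.rtol, atol=self.atol)
        return traj.values[self.rec_t, self.rec_g]

    def residuals(self, free_vec: np.ndarray) -> np.ndarray:
        try:
            sim = self.simulated(self.full_vector(free_vec))
        except SimulationError:
            return np.full(self.n_records, _FAIL_RESIDUAL)
        return (sim - self.means) / self.ses

    def per_point_table(self, theta: np.ndarray) -> pd.DataFrame:
        sim = self.simulated(theta)
        r2 = ((sim - self.means) / self.ses) ** 2
        return pd.DataFrame({
            "gene": self.table["gene"],
            "time_days": self.table["time_days"],
            "exp_mean": self.means,
            "se": self.ses,
            "simulated": sim,
            "chi2": r2,
        })


def chi2_objective(model: GRNModel, params, dataset: TimeSeriesDataset,
                   x0=None, u: float = 1.0, rtol: float = 1e-8,
                   atol: float = 1e-10):
    """Residual vector and total chi2 for one parameter set.

    Residual r = (simulated - mean) / SE per non-missing record; records
    listed in ``dataset.missing`` never appear in the table, so they are
    skipped by construction.
    """
    obj = _Objective(model, dataset, x0=x0, u=u, rtol=rtol, atol=atol)
    theta = (model.params_to_vector(params) if isinstance(params, dict)
             else np.asarray(params, dtype=float))
    sim = obj.simulated(theta)
    r = (sim - obj.means) / obj.ses
    return r, float(np.sum(r ** 2))


def informed_start(model: GRNModel, dataset: TimeSeriesDataset,
                   fixed: dict = None) -> np.ndarray:
    """Data-informed start vector over the free parameters.

    Each gene's uncoupled kinetics are matched to its data: basal
    production set to the gene's mean expression (with unit decay, the
    uncoupled steady state equals the mean), decay 1/day, all edge
    strengths weak (0.05) and Hill exponents at mid-range.  The
    construction uses only the dataset, never the topology being fitted,
    so it treats competing network structures identically; the optimizer
    then grows the couplings that the data supports.
    """
    fixed = fixed or {}
    means = dataset.table.groupby("gene")["mean"].mean()
    values = []
    for name in model.param_names:
        if name in fixed:
            continue
        parts = name.split("_")
        if parts[0] == "b" and len(parts) == 2:
            gene = model.genes[int(parts[1]) - 1]
            values.append(max(0.01, float(means.get(gene, 0.2))))
        elif parts[0] == "delta":
            values.append(1.0)
        elif parts[0] == "a":
            values.append(0.05)
        elif parts[0] == "h":
            values.append(3.0)
        else:  # stimulus production b_i_e
            values.append(0.1)
    free = [n for n in model.param_names if n not in fixed]
    lo, hi = model.bounds_arrays(free)
    return np.clip(np.array(values), lo, hi)


def sample_starts(model: GRNModel, free_names, n_starts: int,
                  seed: int) -> np.ndarray:
    """Reproducible start vectors: log-uniform a_/delta_, uniform h_/b_."""
    rng = np.random.default_rng(seed)
    lo, hi = model.bounds_arrays(free_names)
    classes = np.array([n.split("_")[0] for n in free_names])
    loguni = np.isin(classes, ("a", "delta"))
    starts = np.empty((n_starts, len(free_names)))
    lo_log = np.log(np.maximum(lo, 1e-3))
    hi_log = np.log(np.maximum(hi, 2e-3))
    for s in range(n_starts):
        uni = rng.uniform(lo, hi)
        logs = np.exp(rng.uniform(lo_log, hi_log))
        starts[s] = np.where(loguni, np.clip(logs, lo, hi), uni)
    return starts


def fit(model: GRNModel, dataset: TimeSeriesDataset, n_starts: int = 64,
        seed: int = 0, fixed: dict = None, x0=None, u: float = 1.0,
        starts: np.ndarray = None, l1_penalty: float = 0.0,
        l1_prefixes: tuple = L1_PREFIXES, max_nfev: int = None,
        rtol: float = 1e-6, atol: float = 1e-8,
        refine_top: int = None, ftol: float = 1e-8,
        use_informed_start: bool = False) -> FitResult:
    """Multi-start bounded weighted least squares.

    ``fixed`` maps parameter names to frozen values excluded from the
    optimization.  ``starts`` overrides the sampled start matrix (e.g. to
    start at a previous solution).  With ``l1_penalty`` > 0 the objective
    gains lambda * sum sqrt(theta^2 + eps^2) over free parameters whose
    name starts with one of ``l1_prefixes``.  By default every start is
    refined; with ``refine_top`` = m the starts are first screened by
    their initial objective value and only the m most promising are
    refined (the screening reading of multi-start).  Identical (seed,
    inputs) give identical results.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    obj = _Objective(model, dataset, x0=x0, u=u, rtol=rtol, atol=atol,
                     fixed=fixed)
    free_names = obj.free_names
    if not free_names:
        theta = obj.fixed_vec
        table = obj.per_point_table(theta)
        return FitResult(params=model.vector_to_params(theta),
                         chi2=float(table["chi2"].sum()), per_point=table,
                         n=obj.n_records, k=0, fixed=dict(obj.fixed),
                         n_starts=0, seed=seed)
    lo, hi = model.bounds_arrays(free_names)
    if starts is None:
        if use_informed_start:
            sampled = sample_starts(model, free_names,
                                    max(n_starts - 1, 1), seed)
            starts = np.vstack([informed_start(model, dataset, obj.fixed)
                                [None, :], sampled])[:n_starts]
        else:
            starts = sample_starts(model, free_names, n_starts, seed)
    else:
        starts = np.atleast_2d(np.asarray(starts, dtype=float))
    starts = np.clip(starts, lo, hi)

    penal_mask = np.array(
        [n.startswith(tuple(l1_prefixes)) for n in free_names]) \
        if l1_penalty > 0 else None

    def residual_fn(v):
        r = obj.residuals(v)
        if l1_penalty > 0:
            pen = np.sqrt(l1_penalty
                          * np.sqrt(v[penal_mask] ** 2 + _SMOOTH_EPS ** 2))
            r = np.concatenate([r, pen])
        return r

    n_sampled = len(starts)
    start_ids = list(range(len(starts)))
    if refine_top is not None and refine_top < len(starts):
        initial = np.array([float(np.sum(residual_fn(s) ** 2)) for s in starts])
        keep = np.argsort(initial, kind="stable")[:refine_top]
        start_ids = [int(i) for i in keep]
        starts = starts[keep]

    results = []
    for s, start in zip(start_ids, starts):
        try:
            sol = least_squares(residual_fn, start, bounds=(lo, hi),
                                method="trf", max_nfev=max_nfev, ftol=ftol)
            data_res = obj.residuals(sol.x)
            chi2_val = float(np.sum(data_res ** 2))
            penalized = float(np.sum(sol.fun ** 2))
            results.append((chi2_val, penalized, s, sol.x))
        except Exception as exc:  # noqa: BLE001 - per-start failure recorded
            results.append((math.inf, math.inf, s, None))
            warnings.warn(f"start {s} failed: {exc}")
    ok = [r for r in results if r[3] is not None and np.isfinite(r[1])]
    if not ok:
        raise RuntimeError(
            "all starts failed: "
            + "; ".join(f"start {s}: inf" for _, _, s, _ in results))
    # best by the optimized objective (penalized when L1 is active)
    best = min(ok, key=lambda r: r[1])
    theta = obj.full_vector(best[3])
    table = obj.per_point_table(theta)
    return FitResult(params=model.vector_to_params(theta),
                     chi2=float(table["chi2"].sum()), per_point=table,
                     n=obj.n_records, k=len(free_names),
                     fixed=dict(obj.fixed), n_starts=n_sampled,
                     best_start=int(best[2]), seed=seed,
                     start_chi2=tuple(r[0] for r in results))


def l1_reduce_refit(model: GRNModel, dataset: TimeSeriesDataset,
                    config: L1Config = None, seed: int = 0,
                    n_starts: int = 16, fixed: dict = None, x0=None,
                    u: float = 1.0, max_nfev: int = None,
                    rtol: float = 1e-6, atol: float = 1e-8):
    """L1 fit -> fix small parameters -> unpenalized refit.

    Returns ``(l1_fit, fixed_set, reduced_fit, kept_edges)`` where
    ``fixed_set`` maps each newly fixed parameter to its L1 estimate and
    ``kept_edges`` lists the edges whose strength parameter stayed free.
    """
    config = config or L1Config()
    l1_fit = fit(model, dataset, n_starts=n_starts, seed=seed, fixed=fixed,
                 x0=x0, u=u, l1_penalty=config.penalty,
                 l1_prefixes=config.prefixes, max_nfev=max_nfev,
                 rtol=rtol, atol=atol)
    base_fixed = dict(fixed or {})
    newly_fixed = {}
    for name, value in l1_fit.params.items():
        if name in base_fixed:
            continue
        if name.startswith(tuple(config.prefixes)) and abs(value) < config.fix_threshold:
            newly_fixed[name] = float(value)
    all_fixed = {**base_fixed, **newly_fixed}
    free_names = [n for n in model.param_names if n not in all_fixed]
    if free_names:
        l1_start = np.array([l1_fit.params[n] for n in free_names])
        reduced_fit = fit(model, dataset, n_starts=1, seed=seed,
                          fixed=all_fixed, x0=x0, u=u,
                          starts=l1_start[None, :], max_nfev=max_nfev,
                          rtol=rtol, atol=atol)
    else:
        reduced_fit = fit(model, dataset, n_starts=1, seed=seed,
                          fixed=all_fixed, x0=x0, u=u, max_nfev=max_nfev,
                          rtol=rtol, atol=atol)
    gi = {g: i for i, g in enumerate(model.genes)}
    kept_edges = [
        (s, t, w) for s, t, w in model.edges
        if f"a_{gi[t] + 1}_{gi[s] + 1}" not in all_fixed
    ]
    return l1_fit, newly_fixed, reduced_fit, kept_edges


def per_gene_chi2(fit_result: FitResult):
    """Per-gene chi-square totals and the worst-fitting gene.

    Trailing '_obs' suffixes are stripped from variable names; ties for
    the maximum are broken alphabetically (and logged).  The totals sum
    to the fit's total chi2.
    """
    df = fit_result.per_point.copy()
    df["gene"] = df["gene"].str.replace(r"_obs$", "", regex=True)
    totals = df.groupby("gene")["chi2"].sum().sort_values(ascending=False)
    top = totals[totals == totals.iloc[0]]
    if len(top) > 1:
        argmax = sorted(top.index)[0]
        warnings.warn(f"chi2 tie between {sorted(top.index)}; "
                      f"picking {argmax} alphabetically")
    else:
        argmax = totals.index[0]
    out = totals.reset_index()
    out.columns = ["gene", "chi2"]
    return out, str(argmax)


def plot_fits(fit_result: FitResult, dataset: TimeSeriesDataset,
              model: GRNModel = None, out_path=None, formats=("png",),
              n_cols: int = 3, u: float = 1.0):
    """Per-gene panels: data with +-1 SE_eff error bars and the model curve.

    Three-column grid, per-gene chi2 in each panel title, y-ticks 0 to 1
    in steps of 0.1.  When the model is supplied the simulated curve is
    drawn on a dense time grid; otherwise the simulated values at the
    data times are connected.  Returns the written file paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if dataset.n_records == 0:
        raise ValueError("empty dataset")
    totals, _ = per_gene_chi2(fit_result)
    totals = totals.set_index("gene")["chi2"]
    genes = sorted(fit_result.per_point["gene"].unique())
    n_rows = math.ceil(len(genes) / n_cols)
    fig, axes = plt.subplots(n_rows, n_cols,
                             figsize=(4 * n_cols, 3 * n_rows), squeeze=False)
    dense = None
    if model is not None:
        times = np.sort(fit_result.per_point["time_days"].unique())
        grid = np.linspace(times[0], times[-1], 101)
        traj = simulate(model, fit_result.params, grid,
                        dataset.initial_state(model.genes), u=u)
        dense = (grid, traj)
    for i, gene in enumerate(genes):
        ax = axes[i // n_cols][i % n_cols]
        sub = fit_result.per_point[fit_result.per_point["gene"] == gene]
        ax.errorbar(sub["time_days"], sub["exp_mean"], yerr=sub["se"],
                    fmt="o", ms=4, capsize=2, label="data")
        if dense is not None:
            ax.plot(dense[0], dense[1].gene_values(gene), "-", label="model")
        else:
            ax.plot(sub["time_days"], sub["simulated"], "-", label="model")
        ax.set_title(f"{gene}  chi2={totals[gene]:.2f}")
        ax.set_yticks(np.arange(0, 1.01, 0.1))
        ax.set_ylim(-0.05, 1.05)
        ax.grid(True, alpha=0.3)
    for j in range(len(genes), n_rows * n_cols):
        axes[j // n_cols][j % n_cols].axis("off")
    fig.tight_layout()
    paths = []
    if out_path is not None:
        base = str(out_path)
        for ext in formats:
            p = base if base.endswith(f".{ext}") else f"{base}.{ext}"
            fig.savefig(p, dpi=150)
            paths.append(p)
    plt.close(fig)
    return paths
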