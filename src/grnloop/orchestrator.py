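"""The iterative back-loop engine and intervention ("Lever") analysis.

One back-loop iteration:

1. pick the gene with the largest total chi-square contribution (the
   gene the current model explains worst);
2. decide the regulation the model is missing: if the simulated mean
   exceeds the experimental mean (ratio > 1) the gene is overestimated
   and needs inhibition, otherwise (ratio <= 1) activation;
3. ask the knowledge provider for one upstream regulator of that gene
   acting in that direction, excluding genes already in the network;
4. on a usable answer, enumerate the 2N+1 regulator/network pairs,
   collect verdicts (previously stored verdicts are immutable), extend
   and optionally prune the adjacency matrix;
5. rebuild the ODE model and refit.

The loop repeats until the fit is statistically unremarkable (p >=
alpha, default the 5% level), the provider answers EMPTY, the chi-square
stops improving, or an iteration cap is hit.  Only regulators present in
the measured dataset (after synonym mapping) are accepted.

Lever analysis perturbs, for a poorly fitted target gene, each candidate
parameter feeding that gene by multiplicative factors, re-simulates, and
ranks the candidates by how much they reduce the target's chi-square
contribution — a prioritized list of intervention points.
"""

from __future__ import annotations

import hashlib
import json
import os
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import knowledge as kn
from .fiteval import FitResult, GoFStats, fit, gof_stats, per_gene_chi2
from .network import (SignedAdjacency, build_adjacency,
                      enumerate_backloop_pairs, enumerate_pairs,
                      prune_redundant)
from .odemodel import GRNModel, build_model, simulate
from .preprocess import TimeSeriesDataset


@dataclass(frozen=True)
class RegulationCall:
    """Direction a misfit gene needs: inhibition iff sim/exp ratio > 1."""

    gene: str
    direction: str
    mean_simulated: float
    mean_experimental: float
    ratio: float


def assign_regulation(sim_values, exp_values, gene: str) -> RegulationCall:
    """Classify the model's bias on one gene as missing activation/inhibition.

    The ratio mean(simulated) / mean(experimental) is scale-equivariant;
    a zero experimental mean (ratio undefined) falls back to the sign of
    the simulated mean, with a warning.
    """
    sim = np.asarray(sim_values, dtype=float)
    exp = np.asarray(exp_values, dtype=float)
    if sim.size == 0 or sim.size != exp.size:
        raise ValueError("sim and exp values must be equal-length, non-empty")
    ms, me = float(np.mean(sim)), float(np.mean(exp))
    if me == 0.0:
        warnings.warn(f"experimental mean for {gene} is 0; "
                      "classifying by the simulated mean alone")
        ratio = np.inf if ms > 0 else 1.0
    else:
        ratio = ms / me
    direction = "inhibition" if ratio > 1 else "activation"
    return RegulationCall(gene=gene, direction=direction, mean_simulated=ms,
                          mean_experimental=me, ratio=ratio)


@dataclass
class LoopConfig:
    """Back-loop policy and fitting budget."""

    alpha: float = 0.05
    max_iter: int = 10
    patience: int = 2
    n_starts: int = 16
    seed: int = 0
    prune: bool = True
    relaxed_fallback: bool = False
    synonym_map: dict = field(default_factory=dict)
    stimuli: dict = field(default_factory=dict)   # gene -> sign, used if present
    context: str = ""
    max_nfev: int = None
    refine_top: int = None
    u: float = 1.0

    def fit_kwargs(self) -> dict:
        return {"n_starts": self.n_starts, "max_nfev": self.max_nfev,
                "refine_top": self.refine_top, "u": self.u}


@dataclass
class LoopState:
    """Where the iterative refinement currently stands."""

    iteration: int
    genes: tuple
    adjacency: SignedAdjacency
    model: GRNModel
    fit_result: FitResult
    gof: GoFStats
    history: list = field(default_factory=list)
    stop_reason: str = None
    verdict_store: kn.VerdictStore = field(default_factory=kn.VerdictStore)

    def summary(self) -> dict:
        return {
            "iteration": self.iteration,
            "genes": list(self.genes),
            "chi2": self.fit_result.chi2,
            "n": self.fit_result.n,
            "k": self.fit_result.k,
            "p_value": self.gof.p_value,
            "stop_reason": self.stop_reason,
            "history": self.history,
        }


def _fit_state(adjacency: SignedAdjacency, dataset: TimeSeriesDataset,
               config: LoopConfig, iteration: int,
               store: kn.VerdictStore, history: list) -> LoopState:
    stimuli = {g: s for g, s in config.stimuli.items() if g in adjacency.genes}
    model = build_model(adjacency, stimuli=stimuli)
    sub = dataset.table[dataset.table["gene"].isin(adjacency.genes)]
    subset = TimeSeriesDataset(table=sub.reset_index(drop=True),
                               n_eff=dataset.n_eff, missing=dataset.missing)
    fr = fit(model, subset, seed=config.seed + iteration,
             **config.fit_kwargs())
    gof = gof_stats(fr.chi2, fr.n, fr.k)
    return LoopState(iteration=iteration, genes=adjacency.genes,
                     adjacency=adjacency, model=model, fit_result=fr,
                     gof=gof, history=history, verdict_store=store)


def initial_state(initial_genes, provider, dataset: TimeSeriesDataset,
                  config: LoopConfig,
                  adjacency: SignedAdjacency = None) -> LoopState:
    """Build and fit the starting network.

    Without a supplied adjacency, all N^2 ordered pairs of the initial
    genes are classified by the provider and the verdicts assembled into
    a matrix (pruned when configured).
    """
    missing = set(initial_genes) - set(dataset.genes)
    if missing:
        raise ValueError(f"initial genes not in dataset: {sorted(missing)}")
    store = kn.VerdictStore()
    if adjacency is None:
        verdicts = [kn.classify_pair(provider, a, b, config.context, store)
                    for a, b in enumerate_pairs(initial_genes)]
        adjacency = build_adjacency(verdicts, genes=initial_genes)
        if config.prune:
            adjacency = prune_redundant(adjacency)
    return _fit_state(adjacency, dataset, config, 0, store, [])


def worst_gene_call(state: LoopState) -> RegulationCall:
    """Per-gene chi2 argmax plus the regulation direction it needs."""
    _, target = per_gene_chi2(state.fit_result)
    rows = state.fit_result.per_point
    sub = rows[rows["gene"].str.replace(r"_obs$", "", regex=True) == target]
    return assign_regulation(sub["simulated"], sub["exp_mean"], target)


def backloop_step(state: LoopState, provider, dataset: TimeSeriesDataset,
                  config: LoopConfig) -> LoopState:
    """One refinement iteration; returns the new state.

    If no usable regulator is obtained (EMPTY in strict — and relaxed,
    when enabled — mode, or a symbol absent from the dataset after
    synonym mapping) the state is returned unchanged except for a stop
    reason of ``"empty"``.
    """
    call = worst_gene_call(state)
    exclude = set(state.genes)
    query_exclude = exclude - {call.gene}
    symbol = kn.suggest_upstream_regulator(
        provider, call.gene, call.direction, query_exclude, strict=True,
        context=config.context)
    if symbol == kn.EMPTY and config.relaxed_fallback:
        symbol = kn.suggest_upstream_regulator(
            provider, call.gene, call.direction, query_exclude, strict=False,
            context=config.context)
    if symbol != kn.EMPTY:
        symbol, in_dataset = kn.standardize_symbol(
            symbol, config.synonym_map, known_genes=dataset.genes)
        if not in_dataset:
            warnings.warn(f"regulator {symbol!r} not in dataset; rejected")
            symbol = kn.EMPTY
        elif symbol in exclude:
            warnings.warn(f"regulator {symbol!r} already in network; rejected")
            symbol = kn.EMPTY
    if symbol == kn.EMPTY:
        state.stop_reason = "empty"
        return state

    pairs = enumerate_backloop_pairs(symbol, state.genes)
    verdicts = [kn.classify_pair(provider, a, b, config.context,
                                 state.verdict_store) for a, b in pairs]
    from .network import extend_adjacency

    adjacency = extend_adjacency(state.adjacency, verdicts)
    if config.prune:
        adjacency = prune_redundant(adjacency)
    chi2_before = state.fit_result.chi2
    new_state = _fit_state(adjacency, dataset, config, state.iteration + 1,
                           state.verdict_store, list(state.history))
    new_state.history.append({
        "added_gene": symbol,
        "target": call.gene,
        "direction": call.direction,
        "chi2_before": chi2_before,
        "chi2_after": new_state.fit_result.chi2,
        "p_after": new_state.gof.p_value,
    })
    return new_state


def run_loop(initial_genes, provider, dataset: TimeSeriesDataset,
             config: LoopConfig = None,
             adjacency: SignedAdjacency = None) -> LoopState:
    """Iterate back-loop steps until a stop condition fires.

    Stop reasons: ``converged`` (p >= alpha), ``empty`` (no usable
    regulator), ``max_iter``, ``no_improvement`` (chi2 not improved for
    ``patience`` consecutive iterations).
    """
    config = config or LoopConfig()
    state = initial_state(initial_genes, provider, dataset, config, adjacency)
    best_chi2 = state.fit_result.chi2
    stall = 0
    while True:
        if config.alpha >= 1.0 or (np.isfinite(state.gof.p_value)
                                   and state.gof.p_value >= config.alpha):
            state.stop_reason = "converged"
            return state
        if state.iteration >= config.max_iter:
            state.stop_reason = "max_iter"
            return state
        state = backloop_step(state, provider, dataset, config)
        if state.stop_reason == "empty":
            return state
        if state.fit_result.chi2 < best_chi2 - 1e-9:
            best_chi2 = state.fit_result.chi2
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                state.stop_reason = "no_improvement"
                return state


# ---------------------------------------------------------------------------
# Lever intervention analysis
# ---------------------------------------------------------------------------

DEFAULT_LEVER_FACTORS = (0.25, 0.5, 2.0, 4.0)


def lever_candidates(model: GRNModel, target: str) -> list:
    """Parameters that feed the target: incoming-edge a_/h_, own b_/delta_."""
    gi = {g: i for i, g in enumerate(model.genes)}
    t = gi[target] + 1
    names = [f"b_{t}", f"delta_{t}"]
    for s, tg, _ in model.edges:
        if tg == target:
            names.append(f"a_{t}_{gi[s] + 1}")
            names.append(f"h_{t}_{gi[s] + 1}")
    for g in model.stimuli:
        if g == target:
            names.append(f"b_{t}_1")
    return [n for n in names if n in model.param_names]


def lever_analysis(model: GRNModel, fit_result: FitResult, regulation_calls,
                   dataset: TimeSeriesDataset,
                   factors=DEFAULT_LEVER_FACTORS, u: float = 1.0) -> pd.DataFrame:
    """Scan multiplicative parameter perturbations for each target gene.

    For every (target, candidate parameter, factor): scale the fitted
    value by the factor (clipped into the parameter's bounds),
    re-simulate, and record the change in the target's peak value, its
    trapezoidal area under the curve, and its chi-square contribution.
    Rows are ranked by chi-square improvement (most negative delta_chi2
    first).  Factor 1 reproduces the fit exactly, so its deltas are zero.
    Simulation failures are logged per candidate and skipped.
    """
    if any(f <= 0 for f in factors):
        raise ValueError("factors must be positive")
    times = np.sort(fit_result.per_point["time_days"].unique())
    x0 = dataset.initial_state(model.genes)
    base = simulate(model, fit_result.params, times, x0, u=u)
    rows = []
    for call in regulation_calls:
        target = call.gene if hasattr(call, "gene") else str(call)
        direction = getattr(call, "direction", None)
        tj = model.genes.index(target)
        sub = fit_result.per_point[
            fit_result.per_point["gene"].str.replace(r"_obs$", "", regex=True)
            == target]
        exp_mean = sub["exp_mean"].to_numpy()
        ses = sub["se"].to_numpy()
        sub_times = sub["time_days"].to_numpy()
        t_pos = np.searchsorted(times, sub_times)
        base_target = base.values[:, tj]
        base_peak = float(base_target.max())
        base_auc = float(np.trapezoid(base_target, times))
        base_chi2 = float(np.sum(((base_target[t_pos] - exp_mean) / ses) ** 2))
        for name in lever_candidates(model, target):
            lo, hi = model.bounds[name]
            for f in factors:
                params = dict(fit_result.params)
                params[name] = float(np.clip(params[name] * f, lo, hi))
                try:
                    traj = simulate(model, params, times, x0, u=u)
                except Exception as exc:  # noqa: BLE001 - logged, scan continues
                    warnings.warn(f"lever simulation failed for {name} x{f}: "
                                  f"{exc}")
                    continue
                y = traj.values[:, tj]
                d_chi2 = float(np.sum(((y[t_pos] - exp_mean) / ses) ** 2)
                               - base_chi2)
                rows.append((target, direction, name, f,
                             float(y.max() - base_peak),
                             float(np.trapezoid(y, times) - base_auc),
                             d_chi2))
    report = pd.DataFrame(rows, columns=["target", "direction", "parameter",
                                         "factor", "delta_peak", "delta_auc",
                                         "delta_chi2"])
    return report.sort_values(["target", "delta_chi2"],
                              kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Config-driven pipeline
# ---------------------------------------------------------------------------

_CONFIG_KEYS = {"seed", "dataset", "provider", "initial_genes", "stimuli",
                "fit", "loop", "out_dir", "lever"}


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    unknown = set(config) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for required in ("dataset", "provider", "initial_genes"):
        if required not in config:
            raise ValueError(f"config missing required key {required!r}")
    return config


def _make_provider(cfg: dict):
    kind = cfg.get("kind", "mock")
    if kind == "mock":
        kb = kn.MockKnowledgeBase.from_json(cfg["knowledge_json"])
        return kn.MockProvider(kb)
    if kind == "fixture":
        return kn.FixtureProvider.from_jsonl(cfg["transcript"])
    if kind == "live":
        return kn.LiveProvider(kn.ProviderConfig(
            model=cfg.get("model", "sonar"),
            context=cfg.get("context", "")))
    raise ValueError(f"unknown provider kind {kind!r}")


def run_pipeline(config_path, out_dir=None) -> dict:
    """Execute the configured pipeline end to end into a run directory.

    Writes matrices, fit tables, the loop history and a manifest with
    input hashes and seeds; returns the report dictionary.
    """
    config = load_config(config_path)
    seed = int(config.get("seed", 0))
    out_dir = out_dir or config.get("out_dir", "grnloop_run")
    os.makedirs(out_dir, exist_ok=True)
    for sub in ("matrices", "fits"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)

    dataset = TimeSeriesDataset.from_csv(
        config["dataset"]["csv"], n_eff=config["dataset"].get("n_eff", 15))
    provider = _make_provider(config["provider"])
    fit_cfg = config.get("fit", {})
    loop_cfg = config.get("loop", {})
    lconf = LoopConfig(
        alpha=loop_cfg.get("alpha", 0.05),
        max_iter=loop_cfg.get("max_iter", 10),
        patience=loop_cfg.get("patience", 2),
        n_starts=fit_cfg.get("n_starts", 16),
        max_nfev=fit_cfg.get("max_nfev"),
        refine_top=fit_cfg.get("refine_top"),
        seed=seed,
        stimuli={k: int(v) for k, v in config.get("stimuli", {}).items()},
        synonym_map=loop_cfg.get("synonym_map", {}),
        relaxed_fallback=loop_cfg.get("relaxed_fallback", False),
        prune=loop_cfg.get("prune", True),
    )
    state = run_loop(config["initial_genes"], provider, dataset, lconf)

    state.adjacency.to_csv(os.path.join(out_dir, "matrices",
                                        "final_adjacency.csv"))
    state.fit_result.per_point_csv(os.path.join(out_dir, "fits",
                                                "chi2_full.csv"))
    totals, worst = per_gene_chi2(state.fit_result)
    totals.to_csv(os.path.join(out_dir, "fits",
                               "chi2_sums_per_variable.csv"), index=False)
    report = {
        "summary": state.summary(),
        "gof": state.gof.to_dict(),
        "worst_gene": worst,
    }
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1)
    with open(config["dataset"]["csv"], "rb") as fh:
        data_hash = hashlib.sha256(fh.read()).hexdigest()
    manifest = {
        "config": {k: v for k, v in config.items()},
        "seed": seed,
        "dataset_sha256": data_hash,
        "n_verdicts": len(state.verdict_store),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return report
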