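"""Planted ground truths, simulated noisy time courses, mock knowledge.

Everything the pipeline consumes can be generated here without any
download or network access: a random signed regulatory network with
known kinetic parameters, ODE-simulated expression time courses with the
error structure the preprocessing produces (per-gene, per-time-point
mean and SE_eff on the [0,1] scale; default grid 0, 0.5, 1, 2, 4, 7,
10 days with an effective sample size of 15), and a matched mock
knowledge base whose answers follow the planted graph.

Latent genes appear in the knowledge base but not in the observed gene
list; a two-hop sign-pure path through a latent gene induces an indirect
(+-2) verdict whose sign is the product of the path signs.  Note the
pruning rules later remove only *sign-pure* redundancies, so a -2 edge
induced by a (+,-) path is never pruned by a (+,-) direct path — the
generator is deliberately more general than the pruning logic.

Measurement noise is Gaussian on the normalized scale and applied to the
per-(gene, time) mean with standard deviation noise_sd / sqrt(n_eff):
``noise_sd`` plays the role of the per-cell spread, so the reported
SE_eff = noise_sd / sqrt(n_eff) is exactly the standard deviation of the
noise on the mean and fitted chi-square values are calibrated to their
degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .knowledge import MockKnowledgeBase
from .network import SignedAdjacency, build_adjacency
from .odemodel import GRNModel, simulate
from .preprocess import TimeSeriesDataset

DEFAULT_TIMES = (0.0, 0.5, 1.0, 2.0, 4.0, 7.0, 10.0)
NOISE_FREE_SE = 0.05  # reported SE_eff when the generator adds no noise


@dataclass
class GroundTruth:
    """A planted model with true parameters, plus the latent-gene layer."""

    model: GRNModel
    params: dict
    x0: np.ndarray
    latent_genes: tuple = ()
    latent_edges: dict = field(default_factory=dict)  # (a,b)->sign, via latents
    seed: int = 0

    @property
    def genes(self) -> tuple:
        return self.model.genes

    def all_edges(self) -> dict:
        """Direct signed edges over observed and latent genes."""
        edges = {(s, t): (1 if w > 0 else -1) for s, t, w in self.model.edges}
        edges.update(self.latent_edges)
        return edges

    def adjacency(self) -> SignedAdjacency:
        """Direct-edge skeleton restricted to the observed genes."""
        return build_adjacency(
            [(s, t, 1 if w > 0 else -1) for s, t, w in self.model.edges],
            genes=self.genes)


@dataclass
class SyntheticDataset:
    """Observed dataset plus the noise-free truth it was drawn from."""

    dataset: TimeSeriesDataset
    truth_values: np.ndarray     # (n_times, n_genes), noise-free
    times: np.ndarray
    noise_sd: float
    se_eff: float


def _draw_parameters(rng, genes, edges, stimuli):
    """True kinetics that keep trajectories inside the [0,1] data scale."""
    gi = {g: i for i, g in enumerate(genes)}
    params = {}
    indeg = {g: 0 for g in genes}
    for _, t, _ in edges:
        indeg[t] += 1
    delta = {}
    for g in genes:
        d = float(np.exp(rng.uniform(np.log(0.4), np.log(2.5))))
        delta[g] = d
        params[f"delta_{gi[g] + 1}"] = d
        # small basal production: regulation, not leak, shapes the dynamics
        params[f"b_{gi[g] + 1}"] = float(rng.uniform(0.01, 0.06))
    for s, t, _ in edges:
        share = delta[t] / max(indeg[t], 1)
        params[f"a_{gi[t] + 1}_{gi[s] + 1}"] = float(
            rng.uniform(0.70, 1.40) * share)
        params[f"h_{gi[t] + 1}_{gi[s] + 1}"] = float(rng.uniform(2.0, 6.0))
    for g in sorted(stimuli):
        params[f"b_{gi[g] + 1}_1"] = float(rng.uniform(0.1, 0.4) * delta[g])
    return params


def make_ground_truth(n_genes: int, edge_density: float = 0.2,
                      sign_fraction: float = 0.7, n_latent: int = 0,
                      seed: int = 0, stimulated=()) -> GroundTruth:
    """Random signed digraph with kinetics drawn inside the model bounds.

    Each ordered non-self pair among the observed genes carries an edge
    with probability ``edge_density``; ``sign_fraction`` of edges are
    activating.  Genes that happen to receive no incoming edge are roots
    driven only by their basal production.  Each latent gene is wired as
    a two-hop bridge observed -> latent -> observed, visible only to the
    knowledge base.  Reproducible under seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= edge_density <= 1:
        raise ValueError("edge_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = tuple(f"G{i + 1:02d}" for i in range(n_genes))
    edges = []
    for s in genes:
        for t in genes:
            if s != t and rng.random() < edge_density:
                sign = 1 if rng.random() < sign_fraction else -1
                edges.append((s, t, sign))
    stimuli = {g: 1 for g in stimulated}
    model = GRNModel(genes=genes, edges=tuple(edges), stimuli=stimuli)
    params = _draw_parameters(rng, genes, model.edges, stimuli)
    # spread initial states across the dynamic range so trajectories are
    # individually recognisable (some genes relax down, others switch up)
    x0 = rng.uniform(0.05, 0.90, size=n_genes)

    latent = tuple(f"L{i + 1:02d}" for i in range(n_latent))
    latent_edges = {}
    direct = {(s, t) for s, t, _ in edges}
    for lg in latent:
        a, b = rng.choice(n_genes, size=2, replace=False)
        ga, gb = genes[a], genes[b]
        if (ga, gb) in direct:  # keep the indirect pair distinct from direct
            b2 = (b + 1) % n_genes
            gb = genes[b2] if genes[b2] != ga else genes[(b2 + 1) % n_genes]
        s1 = 1 if rng.random() < sign_fraction else -1
        s2 = 1 if rng.random() < sign_fraction else -1
        latent_edges[(ga, lg)] = s1
        latent_edges[(lg, gb)] = s2
    return GroundTruth(model=model, params=params, x0=x0,
                       latent_genes=latent, latent_edges=latent_edges,
                       seed=seed)


def simulate_dataset(truth: GroundTruth, times=DEFAULT_TIMES,
                     noise_sd: float = 0.1, n_eff: float = 15.0,
                     seed: int = 0, se_eff: float = None,
                     u: float = 1.0) -> SyntheticDataset:
    """Noisy observations of the truth at the requested time grid.

    Observed means are the noise-free trajectories plus Gaussian noise of
    standard deviation noise_sd / sqrt(n_eff), clipped to [0,1]; the
    reported SE_eff equals that same value (override with ``se_eff``).
    With ``noise_sd`` = 0 the means equal the truth exactly and SE_eff
    falls back to a nominal measurement scale of 0.05 so chi-square
    weights stay defined.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    times = np.asarray(times, dtype=float)
    traj = simulate(truth.model, truth.params, times, truth.x0, u=u,
                    rtol=1e-10, atol=1e-12)
    rng = np.random.default_rng(seed)
    sd_mean = noise_sd / np.sqrt(n_eff)
    if se_eff is None:
        se = sd_mean if noise_sd > 0 else NOISE_FREE_SE
    else:
        se = float(se_eff)
    noisy = traj.values + rng.normal(0.0, sd_mean, size=traj.values.shape)
    noisy = np.clip(noisy, 0.0, 1.0)
    rows = []
    for j, g in enumerate(truth.genes):
        for i, t in enumerate(times):
            rows.append((g, float(t), float(noisy[i, j]), se, int(n_eff)))
    table = pd.DataFrame(rows, columns=["gene", "time_days", "mean",
                                        "se_eff", "n_cells"])
    return SyntheticDataset(
        dataset=TimeSeriesDataset(table=table, n_eff=n_eff),
        truth_values=traj.values, times=times, noise_sd=noise_sd,
        se_eff=se)


def make_mock_knowledge(truth: GroundTruth, error_rate: float = 0.0,
                        abstention_rate: float = 0.0,
                        seed: int = 0) -> MockKnowledgeBase:
    """Knowledge base answering from the planted graph (latents included)."""
    return MockKnowledgeBase(edges=truth.all_edges(), genes=truth.genes,
                             latent_genes=truth.latent_genes,
                             error_rate=error_rate,
                             abstention_rate=abstention_rate, seed=seed)


def make_planted_regulator_scenario(seed: int = 0, n_genes: int = 5,
                                    noise_sd: float = 0.08):
    """Harness for the back-loop: one true regulator withheld at start.

    Builds a truth in which a designated regulator strongly drives the
    alphabetically last gene, simulates a dataset from the full truth,
    and returns ``(truth, synthetic, kb, start_genes)`` where
    ``start_genes`` omits the regulator.  A model restricted to
    ``start_genes`` cannot reproduce the driven gene's dynamics, so the
    loop's worst-gene selection should recover the withheld regulator.
    """
    rng = np.random.default_rng(seed)
    genes = tuple(f"G{i + 1:02d}" for i in range(n_genes))
    regulator, driven = genes[0], genes[-1]
    # The withheld regulator is a slowly decaying repressor of the driven
    # gene: as it falls through the Hill threshold (K = 0.5) the driven
    # gene is released from repression and shows a delayed, switch-like
    # rise.  A model without the repressor overshoots the early low
    # phase of that trajectory (simulated mean > experimental mean), so
    # the misfit heuristic asks for an inhibitor — which is exactly the
    # planted regulation.
    edges = [(regulator, driven, -1)]
    # a sparse backbone among the start genes, not touching the driven gene
    for i in range(1, n_genes - 2):
        sign = 1 if rng.random() < 0.7 else -1
        edges.append((genes[i], genes[i + 1], sign))
    model = GRNModel(genes=genes, edges=tuple(edges))
    gi = {g: i for i, g in enumerate(genes)}
    params = _draw_parameters(rng, genes, model.edges, {})
    params[f"b_{gi[regulator] + 1}"] = 0.02
    params[f"delta_{gi[regulator] + 1}"] = 0.35
    params[f"b_{gi[driven] + 1}"] = 0.02
    params[f"delta_{gi[driven] + 1}"] = 0.8
    params[f"a_{gi[driven] + 1}_{gi[regulator] + 1}"] = 0.75
    params[f"h_{gi[driven] + 1}_{gi[regulator] + 1}"] = 6.0
    x0 = rng.uniform(0.05, 0.3, size=n_genes)
    x0[gi[regulator]] = 0.9
    x0[gi[driven]] = 0.05
    truth = GroundTruth(model=model, params=params, x0=x0, seed=seed)
    synthetic = simulate_dataset(truth, noise_sd=noise_sd, seed=seed + 1)
    kb = make_mock_knowledge(truth, seed=seed)
    start_genes = tuple(g for g in genes if g != regulator)
    return truth, synthetic, kb, start_genes


def make_benchmark_scenario(seed: int = 0, n_genes: int = 8,
                            edge_density: float = 0.16,
                            noise_sd: float = 0.06):
    """A reference truth suitable for the random-topology null benchmark.

    The reference must actually constrain the data for the comparison to
    be meaningful, so the planted network is required to be mostly
    regulated: between ``n_genes + 1`` and ``1.5 * n_genes`` edges
    (sparse, one-to-1.5 regulators per gene on average, the usual regime
    for curated GRNs) and at most one gene without an incoming edge.
    Candidate truths are drawn at deterministic seed offsets until one
    satisfies the requirement.  Returns ``(truth, synthetic_dataset)``.
    """
    for offset in range(50):
        truth = make_ground_truth(n_genes, edge_density=edge_density,
                                  seed=seed + 1000 * offset)
        m = truth.adjacency().matrix
        roots = int(np.sum(~np.any(m != 0, axis=0)))
        if (n_genes + 1 <= truth.model.n_edges <= (3 * n_genes) // 2
                and roots <= 1):
            break
    else:  # pragma: no cover - density makes this window very likely
        raise RuntimeError("no suitable reference topology found")
    synthetic = simulate_dataset(truth, noise_sd=noise_sd, seed=seed + 500)
    return truth, synthetic


def make_demo_bundle(out_dir, seed: int = 42) -> dict:
    """Write a complete offline demo: truth, dataset, knowledge base, config.

    Six observed genes plus two latent ones, the default 7-point grid, a
    faithful mock knowledge base and a ready-to-run pipeline config.
    Returns the written paths.
    """
    import os

    os.makedirs(out_dir, exist_ok=True)
    truth = make_ground_truth(n_genes=6, edge_density=0.25, n_latent=2,
                              seed=seed, stimulated=("G01",))
    synthetic = simulate_dataset(truth, noise_sd=0.1, seed=seed + 1)
    kb = make_mock_knowledge(truth, seed=seed)

    paths = {
        "dataset": os.path.join(out_dir, "timeseries.csv"),
        "knowledge": os.path.join(out_dir, "knowledge.json"),
        "adjacency": os.path.join(out_dir, "truth_adjacency.csv"),
        "model": os.path.join(out_dir, "truth_model.json"),
        "config": os.path.join(out_dir, "run.yaml"),
        "gene_list": os.path.join(out_dir, "gene_list.csv"),
    }
    synthetic.dataset.to_csv(paths["dataset"])
    kb.to_json(paths["knowledge"])
    truth.adjacency().to_csv(paths["adjacency"])
    truth.model.to_json(paths["model"], params=truth.params)
    pd.DataFrame({"gene": list(truth.genes)}).to_csv(paths["gene_list"],
                                                     index=False)
    config = {
        "seed": int(seed),
        "dataset": {"csv": paths["dataset"], "n_eff": 15},
        "provider": {"kind": "mock", "knowledge_json": paths["knowledge"]},
        "initial_genes": list(truth.genes)[:4],
        "stimuli": {"G01": 1},
        "fit": {"n_starts": 8, "max_nfev": 200},
        "loop": {"alpha": 0.05, "max_iter": 4, "patience": 2},
        "out_dir": os.path.join(out_dir, "run"),
    }
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config, fh)
    return paths
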