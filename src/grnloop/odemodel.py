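"""Signed adjacency -> parameterized ODE system -> simulated trajectories.

Each gene i follows additive Hill kinetics on the normalized [0,1] scale:

    dx_i/dt = b_i
              + sum_{j in Act(i)} a_i_j * H(x_j; h_i_j)
              + sum_{j in Inh(i)} a_i_j * (1 - H(x_j; h_i_j))
              + sum_{e in Stim(i)} s_e * b_i_e * u_e(t)
              - delta_i * x_i,

with the Hill function H(x; h) = x^h / (K^h + x^h), K fixed at 0.5 (the
mid-range of the normalized data), a first-order decay delta_i, a basal
production b_i, and a constant external input u_e(t) = 1 for treated
experiments.  Indirect edges (|weight| = 2) that survive pruning enter
the kinetics exactly like direct ones.

Parameter classes and default bounds: edge strengths a_* in [0, 50],
Hill exponents h_* in [1, 10], production terms b_* in [0, 5], decay
rates delta_* in (0, 50] (lower bound 1e-3 numerically).  Names encode
1-based gene indices in sorted order: a_i_j / h_i_j for the edge
gene_j -> gene_i (target first), b_i, b_i_e for a stimulus link, and
delta_i.

The additive Hill right-hand side is one concrete choice behind a narrow
interface (``rhs``); alternative kinetics (e.g. multiplicative gating)
can be substituted without touching the fitting layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .network import SignedAdjacency

HILL_K = 0.5

DEFAULT_BOUNDS = {
    "a": (0.0, 50.0),
    "h": (1.0, 10.0),
    "b": (0.0, 5.0),
    "delta": (1e-3, 50.0),
}


class SimulationError(RuntimeError):
    """Numerical integration failed; message carries solver diagnostics."""


def hill(x, h):
    """H(x; h) = x^h / (K^h + x^h) with K = 0.5, clamped to x >= 0."""
    x = np.maximum(x, 0.0)
    xh = x ** h
    return xh / (HILL_K ** h + xh)


@dataclass
class GRNModel:
    """Genes, signed edges, stimulus links and the named parameter table."""

    genes: tuple
    edges: tuple          # (source, target, weight) with weight in {-2,-1,1,2}
    stimuli: dict = field(default_factory=dict)   # gene -> +1 / -1
    bounds: dict = field(default_factory=dict)    # name -> (lo, hi)
    stimulus_name: str = "ETO"

    # derived
    param_names: tuple = field(init=False)
    _edge_src: np.ndarray = field(init=False, repr=False)
    _edge_tgt: np.ndarray = field(init=False, repr=False)
    _edge_act: np.ndarray = field(init=False, repr=False)
    _stim_tgt: np.ndarray = field(init=False, repr=False)
    _stim_sign: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self.genes = tuple(self.genes)
        gi = {g: i for i, g in enumerate(self.genes)}
        unknown = set(self.stimuli) - set(self.genes)
        if unknown:
            raise ValueError(f"stimulus on unknown genes: {sorted(unknown)}")
        edges = tuple((str(s), str(t), int(w)) for s, t, w in self.edges)
        self.edges = edges
        self._edge_src = np.array([gi[s] for s, _, _ in edges], dtype=int)
        self._edge_tgt = np.array([gi[t] for _, t, _ in edges], dtype=int)
        self._edge_act = np.array([w > 0 for _, _, w in edges], dtype=bool)
        stim = sorted(self.stimuli.items())
        self._stim_tgt = np.array([gi[g] for g, _ in stim], dtype=int)
        self._stim_sign = np.array([s for _, s in stim], dtype=float)

        names = []
        for i in range(len(self.genes)):
            names.append(f"b_{i + 1}")
            names.append(f"delta_{i + 1}")
        for s, t, _ in edges:
            names.append(f"a_{gi[t] + 1}_{gi[s] + 1}")
            names.append(f"h_{gi[t] + 1}_{gi[s] + 1}")
        for g, _ in stim:
            names.append(f"b_{gi[g] + 1}_1")  # one external input (index 1)
        self.param_names = tuple(names)

        sanitized = {}
        for name in names:
            cls = name.split("_")[0]
            lo, hi = DEFAULT_BOUNDS[cls]
            if name in self.bounds:
                ulo, uhi = self.bounds[name]
                clo, chi = max(ulo, lo), min(uhi, hi)
                if (clo, chi) != (ulo, uhi):
                    warnings.warn(
                        f"bounds for {name} clamped from [{ulo}, {uhi}] "
                        f"to [{clo}, {chi}]")
                if not clo < chi:
                    raise ValueError(f"empty bound interval for {name}")
                sanitized[name] = (clo, chi)
            else:
                sanitized[name] = (lo, hi)
        self.bounds = sanitized

    # ------------------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_parameters(self) -> int:
        return len(self.param_names)

    def params_to_vector(self, params: dict) -> np.ndarray:
        missing = set(self.param_names) - set(params)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        return np.array([float(params[n]) for n in self.param_names])

    def vector_to_params(self, vec) -> dict:
        return dict(zip(self.param_names, np.asarray(vec, dtype=float)))

    def bounds_arrays(self, names=None):
        names = names if names is not None else self.param_names
        lo = np.array([self.bounds[n][0] for n in names])
        hi = np.array([self.bounds[n][1] for n in names])
        return lo, hi

    # ------------------------------------------------------------------

    def _unpack(self, theta: np.ndarray):
        n, m = self.n_genes, self.n_edges
        b = theta[0:2 * n:2]
        delta = theta[1:2 * n:2]
        a = theta[2 * n:2 * n + 2 * m:2]
        h = theta[2 * n + 1:2 * n + 2 * m:2]
        b_stim = theta[2 * n + 2 * m:]
        return b, delta, a, h, b_stim

    def rhs(self, t: float, x: np.ndarray, theta: np.ndarray,
            u: float = 1.0) -> np.ndarray:
        """Right-hand side dx/dt at state x for the flat parameter vector."""
        b, delta, a, h, b_stim = self._unpack(theta)
        dx = b - delta * x
        if self.n_edges:
            hx = hill(x[self._edge_src], h)
            reg = a * np.where(self._edge_act, hx, 1.0 - hx)
            np.add.at(dx, self._edge_tgt, reg)
        if len(self._stim_tgt):
            np.add.at(dx, self._stim_tgt, self._stim_sign * b_stim * u)
        return dx

    # ------------------------------------------------------------------

    def to_json(self, path, params: dict = None, fixed: dict = None) -> None:
        doc = {
            "genes": list(self.genes),
            "edges": [list(e) for e in self.edges],
            "stimuli": dict(self.stimuli),
            "stimulus_name": self.stimulus_name,
            "bounds": {k: list(v) for k, v in self.bounds.items()},
            "params": params or {},
            "fixed": fixed or {},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GRNModel":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(genes=tuple(doc["genes"]),
                   edges=tuple(tuple(e) for e in doc["edges"]),
                   stimuli={k: int(v) for k, v in doc["stimuli"].items()},
                   bounds={k: tuple(v) for k, v in doc["bounds"].items()},
                   stimulus_name=doc.get("stimulus_name", "ETO"))


def build_model(adj: SignedAdjacency, stimuli: dict = None,
                bounds: dict = None) -> GRNModel:
    """Translate a signed adjacency matrix into a parameterized ODE model.

    Every nonzero entry becomes an edge with one strength (a) and one
    Hill-exponent (h) parameter; every gene gets a basal production (b)
    and a decay (delta); every stimulus link gets a production strength
    (b_i_e).  Free-parameter count is therefore
    ``2 * n_genes + 2 * n_edges + n_stimulus_links``.
    """
    edges = tuple(adj.edges())
    return GRNModel(genes=adj.genes, edges=edges, stimuli=dict(stimuli or {}),
                    bounds=dict(bounds or {}))


@dataclass(frozen=True)
class Trajectory:
    """Simulated state values per gene on a strictly increasing time grid."""

    times: np.ndarray
    values: np.ndarray          # shape (n_times, n_genes)
    genes: tuple
    diagnostics: dict = field(default_factory=dict)

    def gene_values(self, gene: str) -> np.ndarray:
        return self.values[:, self.genes.index(gene)]


def simulate(model: GRNModel, params, times, x0, u: float = 1.0,
             rtol: float = 1e-8, atol: float = 1e-10,
             method: str = "LSODA") -> Trajectory:
    """Integrate the model over ``times`` from state ``x0`` at times[0].

    Uses a stiff-capable solver (LSODA by default).  Integration failure
    raises :class:`SimulationError` with the solver message — never a
    silent NaN.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    theta = (model.params_to_vector(params) if isinstance(params, dict)
             else np.asarray(params, dtype=float))
    x0 = np.asarray(x0, dtype=float)
    if x0.shape != (model.n_genes,) or not np.all(np.isfinite(x0)):
        raise ValueError("x0 must be finite with one entry per gene")
    if len(times) == 1:
        return Trajectory(times, x0[None, :].copy(), model.genes,
                          {"nfev": 0, "success": True})
    sol = solve_ivp(model.rhs, (times[0], times[-1]), x0, t_eval=times,
                    args=(theta, u), method=method, rtol=rtol, atol=atol)
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise SimulationError(f"integration failed: {sol.message} "
                              f"(nfev={sol.nfev})")
    return Trajectory(times, sol.y.T.copy(), model.genes,
                      {"nfev": int(sol.nfev), "success": True,
                       "method": method})


def count_free_parameters(model: GRNModel, fixed_set=()) -> int:
    """k = total parameters minus the fixed ones."""
    fixed = set(fixed_set)
    unknown = fixed - set(model.param_names)
    if unknown:
        raise ValueError(f"fixed parameters not in model: {sorted(unknown)}")
    return model.n_parameters - len(fixed)
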