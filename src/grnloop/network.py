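"""Signed-adjacency graph layer.

A signed gene regulatory network is held as an N x N integer matrix over
the five-symbol alphabet {-2, -1, 0, 1, 2}: ``A[u, v]`` is the weight of
the edge gene_u -> gene_v, where +-1 encodes a direct activation or
inhibition and +-2 an indirect one (mediated by genes absent from the
model).  Genes are indexed in sorted (lexicographic) order.

Besides construction from verdict tables, the module provides pair
enumeration for knowledge-provider queries, redundancy pruning of
indirect edges, matrix extension for the iterative back-loop, and
edge-list / GraphML export.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

ALPHABET = frozenset({-2, -1, 0, 1, 2})


class VerdictConflictError(ValueError):
    """Raised when two verdicts disagree for the same ordered gene pair."""


@dataclass(frozen=True)
class SignedAdjacency:
    """Alphabetically indexed signed adjacency matrix.

    ``matrix[i, j]`` is the weight of the edge ``genes[i] -> genes[j]``.
    """

    genes: tuple
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self):
        genes = tuple(self.genes)
        if list(genes) != sorted(genes):
            raise ValueError("genes must be sorted lexicographically")
        if len(set(genes)) != len(genes):
            raise ValueError("gene identifiers must be unique")
        m = np.asarray(self.matrix, dtype=int)
        n = len(genes)
        if m.shape != (n, n):
            raise ValueError(f"matrix shape {m.shape} != ({n}, {n})")
        bad = set(np.unique(m)) - ALPHABET
        if bad:
            raise ValueError(f"weights outside {{-2,-1,0,1,2}}: {sorted(bad)}")
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.genes)

    def index(self, gene: str) -> int:
        return self.genes.index(gene)

    def weight(self, source: str, target: str) -> int:
        return int(self.matrix[self.index(source), self.index(target)])

    def edges(self):
        """Yield (source, target, weight) for every nonzero entry."""
        for i, j in zip(*np.nonzero(self.matrix)):
            yield self.genes[i], self.genes[j], int(self.matrix[i, j])

    def n_edges(self) -> int:
        return int(np.count_nonzero(self.matrix))

    def __eq__(self, other):
        return (
            isinstance(other, SignedAdjacency)
            and self.genes == other.genes
            and np.array_equal(self.matrix, other.matrix)
        )

    # -- CSV dialects -------------------------------------------------

    def to_csv(self, path) -> None:
        """Write with gene symbols as header row and index column."""
        pd.DataFrame(self.matrix, index=self.genes, columns=self.genes).to_csv(path)

    def to_csv_headerless(self, path) -> None:
        """Write the bare numeric matrix without any labels."""
        pd.DataFrame(self.matrix).to_csv(path, header=False, index=False)

    @classmethod
    def from_csv(cls, path) -> "SignedAdjacency":
        df = pd.read_csv(path, index_col=0)
        genes = [str(g) for g in df.index]
        if list(df.columns.astype(str)) != genes:
            raise ValueError("row and column gene labels differ")
        order = np.argsort(genes)
        m = df.to_numpy(dtype=int)[np.ix_(order, order)]
        return cls(tuple(sorted(genes)), m)

    @classmethod
    def zeros(cls, genes) -> "SignedAdjacency":
        genes = tuple(sorted(genes))
        return cls(genes, np.zeros((len(genes), len(genes)), dtype=int))


def enumerate_pairs(genes) -> list:
    """All N^2 ordered gene pairs, self-pairs included.

    Order is deterministic: sorted source, then sorted target.  These are
    the pairs submitted one at a time to the knowledge provider when a
    network is first assembled.
    """
    genes = sorted(set(genes))
    if len(genes) != len(set(genes)):
        raise ValueError("genes must be unique")
    return [(a, b) for a in genes for b in genes]


def enumerate_backloop_pairs(regulator: str, network_genes) -> list:
    """Pairs probing a newly proposed regulator against an existing network.

    Both orientations (regulator -> gene and gene -> regulator) for every
    network gene, plus the regulator's self-pair: exactly ``2 N + 1``
    pairs.  The regulator must not already be part of the network.
    """
    network_genes = sorted(set(network_genes))
    if regulator in network_genes:
        raise ValueError(f"regulator {regulator!r} already in the network")
    pairs = []
    for g in network_genes:
        pairs.append((regulator, g))
        pairs.append((g, regulator))
    pairs.append((regulator, regulator))
    return pairs


def build_adjacency(verdicts, genes=None) -> SignedAdjacency:
    """Assemble a signed adjacency matrix from interaction verdicts.

    ``verdicts`` is an iterable of (gene1, gene2, value) triples (or
    objects with those attributes); value is the signed interaction
    gene1 -> gene2.  The gene set is the sorted union of all names seen
    plus the optional ``genes`` argument.  Duplicate verdicts for one
    ordered pair must agree, otherwise :class:`VerdictConflictError`.
    """
    rows = []
    for v in verdicts:
        if hasattr(v, "source"):
            rows.append((v.source, v.target, int(v.value)))
        else:
            g1, g2, val = v
            rows.append((str(g1), str(g2), int(val)))
    names = set(genes or [])
    for g1, g2, _ in rows:
        names.add(g1)
        names.add(g2)
    adj = SignedAdjacency.zeros(names)
    m = adj.matrix.copy()
    seen = {}
    conflicts = []
    for g1, g2, val in rows:
        if val not in ALPHABET:
            raise ValueError(f"interaction value {val} for ({g1}, {g2}) "
                             "outside {-2,-1,0,1,2}")
        key = (g1, g2)
        if key in seen and seen[key] != val:
            conflicts.append((g1, g2, seen[key], val))
            continue
        seen[key] = val
        m[adj.index(g1), adj.index(g2)] = val
    if conflicts:
        raise VerdictConflictError(f"conflicting verdicts: {conflicts}")
    return SignedAdjacency(adj.genes, m)


def _reachable(mask: np.ndarray, start: int) -> np.ndarray:
    """Breadth-first reachability over the boolean edge mask ``mask``.

    Returns the set of nodes reachable from ``start`` along paths with at
    least one edge (so ``start`` itself is reachable only via a cycle).
    """
    n = mask.shape[0]
    visited = np.zeros(n, dtype=bool)
    frontier = list(np.nonzero(mask[start])[0])
    while frontier:
        nxt = []
        for v in frontier:
            if not visited[v]:
                visited[v] = True
                nxt.extend(np.nonzero(mask[v])[0])
        frontier = nxt
    return visited


def prune_redundant(adj: SignedAdjacency) -> SignedAdjacency:
    """Remove indirect edges already explained by sign-pure direct paths.

    An indirect activation (+2) i -> j is zeroed when j is reachable from
    i through edges of weight +1 only; an indirect inhibition (-2) is
    zeroed when j is reachable through weight -1 edges only.  Paths must
    contain at least one edge, so a +-2 self-loop is removed only when a
    same-sign direct cycle passes through the node.  Reachability is
    evaluated on the input matrix and all qualifying entries are zeroed
    simultaneously, so the result cannot depend on removal order.
    Direct (+-1) edges are never modified.
    """
    m = adj.matrix
    out = m.copy()
    for weight, direct in ((2, 1), (-2, -1)):
        sources = np.unique(np.nonzero(m == weight)[0])
        mask = m == direct
        for i in sources:
            reach = _reachable(mask, i)
            targets = np.nonzero(m[i] == weight)[0]
            out[i, targets[reach[targets]]] = 0
    return SignedAdjacency(adj.genes, out)


def extend_adjacency(base: SignedAdjacency, new_verdicts) -> SignedAdjacency:
    """Merge back-loop verdicts into an existing matrix.

    The gene set becomes the sorted union; baseline entries are copied
    unchanged.  A new verdict that contradicts an existing nonzero entry
    is an error listing the offending pairs: earlier verdicts are
    immutable by contract.
    """
    rows = []
    for v in new_verdicts:
        if hasattr(v, "source"):
            rows.append((v.source, v.target, int(v.value)))
        else:
            g1, g2, val = v
            rows.append((str(g1), str(g2), int(val)))
    names = set(base.genes)
    for g1, g2, _ in rows:
        names.update((g1, g2))
    merged = SignedAdjacency.zeros(names)
    m = merged.matrix.copy()
    for u, v, w in base.edges():
        m[merged.index(u), merged.index(v)] = w
    conflicts = []
    for g1, g2, val in rows:
        if val not in ALPHABET:
            raise ValueError(f"interaction value {val} outside alphabet")
        i, j = merged.index(g1), merged.index(g2)
        existing = base.weight(g1, g2) if (g1 in base.genes and g2 in base.genes) else 0
        if existing != 0 and val != existing:
            conflicts.append((g1, g2, existing, val))
            continue
        if existing == 0:
            m[i, j] = val
    if conflicts:
        raise VerdictConflictError(
            f"new verdicts contradict baseline entries: {conflicts}")
    return SignedAdjacency(merged.genes, m)


def to_edge_list(adj: SignedAdjacency) -> pd.DataFrame:
    """Edge list with sign notation: one row per nonzero entry.

    Columns: source, sign ('+' for weights 1/2, '-' for -1/-2), target,
    a blank spacer and the sorted unique gene list padded to length —
    the five-column topology layout consumed by graph editors.
    """
    triplets = [(u, "+" if w > 0 else "-", v) for u, v, w in adj.edges()]
    genes = list(adj.genes)
    n = max(len(triplets), len(genes))
    rows = []
    for i in range(n):
        s, sg, t = triplets[i] if i < len(triplets) else ("", "", "")
        g = genes[i] if i < len(genes) else ""
        rows.append((s, sg, t, "", g))
    return pd.DataFrame(rows, columns=["source", "sign", "target", "spacer", "gene"])


def to_graphml(adj: SignedAdjacency) -> str:
    """GraphML document with gene-symbol nodes and weight/sign edge attrs."""
    g = nx.DiGraph()
    g.add_nodes_from(adj.genes)
    for u, v, w in adj.edges():
        g.add_edge(u, v, weight=w, sign="+" if w > 0 else "-")
    buf = io.BytesIO()
    nx.write_graphml(g, buf)
    return buf.getvalue().decode()


def from_graphml(document: str) -> SignedAdjacency:
    """Inverse of :func:`to_graphml`; round-trips the adjacency exactly."""
    g = nx.read_graphml(io.BytesIO(document.encode()))
    adj = SignedAdjacency.zeros(g.nodes)
    m = adj.matrix.copy()
    for u, v, data in g.edges(data=True):
        m[adj.index(u), adj.index(v)] = int(data["weight"])
    return SignedAdjacency(adj.genes, m)


def export_topology(adj: SignedAdjacency, edge_csv=None, graphml_path=None):
    """Write the edge-list CSV and GraphML export; returns both objects."""
    edges = to_edge_list(adj)
    doc = to_graphml(adj)
    if edge_csv is not None:
        edges.to_csv(edge_csv, header=False, index=False)
    if graphml_path is not None:
        with open(graphml_path, "w") as fh:
            fh.write(doc)
    return edges, doc
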