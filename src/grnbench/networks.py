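"""Synthetic gene regulatory networks.

A gene regulatory network (GRN) is encoded as a signed, weighted adjacency
matrix ``A`` where ``A[i, j]`` is the strength of the regulation ``j -> i``:
**columns are regulators, rows are targets**.  This orientation makes the
steady-state model ``A @ Y + P = 0`` conformable with expression matrices of
shape (genes, experiments), and is used consistently everywhere in the
package (estimators, evaluation, serialization).

Diagonal entries are selfloops.  They model first-order degradation of each
transcript and are what makes the linear system stable; every generated
network carries a strictly negative diagonal.

The generator produces scale-free-like topologies by preferential attachment
(heavy-tailed degree distribution), assigns each off-diagonal edge a uniform
random direction, a Bernoulli(1/2) sign, and a magnitude bounded away from
zero, and then shifts the diagonal so that all eigenvalues have strictly
negative real part.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "Network",
    "generate_scale_free_network",
    "stabilize",
    "spectral_abscissa",
    "is_stable",
]


@dataclass
class Network:
    """Signed, weighted, directed GRN with selfloops.

    Parameters
    ----------
    weights : ndarray of shape (n_genes, n_genes)
        ``weights[i, j]`` is the signed strength of regulation ``j -> i``
        (column = regulator, row = target).
    gene_ids : list of str
        Ordered gene labels; defaults to ``G1..Gn``.
    """

    weights: np.ndarray
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("network weight matrix must be square")
        if self.weights.shape[0] < 1:
            raise ValueError("network needs at least one gene")
        if not self.gene_ids:
            self.gene_ids = [f"G{i + 1}" for i in range(self.n_genes)]
        if len(self.gene_ids) != self.n_genes:
            raise ValueError("gene_ids length does not match matrix size")

    @property
    def n_genes(self) -> int:
        return self.weights.shape[0]

    @property
    def has_selfloops(self) -> bool:
        return bool(np.any(np.diag(self.weights) != 0))

    def edges(self, include_diagonal: bool = True) -> frozenset[tuple[int, int]]:
        """Binary edge set as ``(target, regulator)`` index pairs."""
        mask = self.weights != 0
        if not include_diagonal:
            mask = mask & ~np.eye(self.n_genes, dtype=bool)
        rows, cols = np.nonzero(mask)
        return frozenset(zip(rows.tolist(), cols.tolist()))

    def n_links(self, include_diagonal: bool = True) -> int:
        return len(self.edges(include_diagonal=include_diagonal))

    def copy(self) -> "Network":
        return dataclasses.replace(self, weights=self.weights.copy(), gene_ids=list(self.gene_ids))


def spectral_abscissa(network: Network) -> float:
    """Largest real part of the eigenvalues of the weight matrix."""
    return float(np.max(np.linalg.eigvals(network.weights).real))


def is_stable(network: Network, margin: float = 0.0) -> bool:
    """True when all eigenvalues have real part below ``-margin``."""
    return spectral_abscissa(network) < -margin


def stabilize(network: Network, margin: float = 0.1) -> Network:
    """Shift the diagonal so the system is asymptotically stable.

    Subtracts ``max Re(eig) + margin`` from every diagonal entry whenever the
    spectral abscissa is above ``-margin``.  A uniform diagonal shift moves
    every eigenvalue by the same amount, so the returned network satisfies
    ``max Re(eig) <= -margin`` (hence is invertible) while the sparsity
    pattern and all off-diagonal signs are untouched.  Selfloops only get
    deeper (more negative), never created or destroyed in the off-diagonal
    pattern.
    """
    if margin <= 0:
        raise ValueError("stability margin must be positive")
    a = spectral_abscissa(network)
    if a < -margin:
        return network.copy()
    shifted = network.weights - (a + margin) * np.eye(network.n_genes)
    return Network(weights=shifted, gene_ids=list(network.gene_ids))


def _topology_edges(
    n_genes: int, n_edges: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Undirected preferential-attachment skeleton with exactly ``n_edges`` edges."""
    if n_edges <= 0:
        return []
    m = int(round(n_edges / max(n_genes - 1, 1)))
    m = min(max(m, 1), n_genes - 1)
    seed = int(rng.integers(0, 2**31 - 1))
    graph = nx.barabasi_albert_graph(n_genes, m, seed=seed)
    edges = {tuple(sorted(e)) for e in graph.edges()}
    # BA gives m*(n-m) edges; top up (preferentially) or thin (uniformly) to the budget.
    while len(edges) > n_edges:
        drop = list(edges)[int(rng.integers(len(edges)))]
        edges.discard(drop)
    if len(edges) < n_edges:
        degree = np.ones(n_genes)
        for u, v in edges:
            degree[u] += 1
            degree[v] += 1
        while len(edges) < n_edges:
            u = int(rng.choice(n_genes, p=degree / degree.sum()))
            v = int(rng.integers(n_genes))
            if u == v:
                continue
            e = (min(u, v), max(u, v))
            if e in edges:
                continue
            edges.add(e)
            degree[u] += 1
            degree[v] += 1
    return sorted(edges)


def generate_scale_free_network(
    n_genes: int,
    avg_links_per_node: float = 3.0,
    seed: int | None = None,
    weight_range: tuple[float, float] = (0.1, 1.0),
    stability_margin: float = 0.1,
) -> Network:
    """Generate a stable, signed, directed scale-free GRN with selfloops.

    ``avg_links_per_node`` is the total link budget per gene *including* the
    selfloop, so the off-diagonal edge count is about
    ``n_genes * (avg_links_per_node - 1)``; with the default of 3 links per
    node a 100-gene network carries ~200 directed off-diagonal links (~2 per
    gene), plus 100 selfloops.

    Off-diagonal edge magnitudes are drawn uniformly from ``weight_range``
    (bounded away from zero so every link is detectable in principle) with
    Bernoulli(1/2) signs.  Each selfloop is set to minus the sum of the
    absolute incoming weights of its gene plus a uniform draw from
    ``weight_range`` — degradation outweighs regulation, so the system is
    diagonally dominant and stable by the Gershgorin bound, with a
    well-conditioned steady state; :func:`stabilize` remains as a safety
    net for non-default weight choices.

    Same seed, same arguments -> bit-identical matrix.
    """
    if n_genes < 2:
        raise ValueError("n_genes must be at least 2")
    if avg_links_per_node < 1:
        raise ValueError("avg_links_per_node must be at least 1 (the selfloop)")
    if avg_links_per_node >= n_genes:
        raise ValueError("avg_links_per_node cannot reach full density")
    lo, hi = weight_range
    if not 0 < lo < hi:
        raise ValueError("weight_range must satisfy 0 < low < high")

    rng = np.random.default_rng(seed)
    n_offdiag = int(round(n_genes * (avg_links_per_node - 1.0)))
    skeleton = _topology_edges(n_genes, n_offdiag, rng)

    weights = np.zeros((n_genes, n_genes))
    for u, v in skeleton:
        # uniform random orientation of each undirected skeleton edge
        regulator, target = (u, v) if rng.random() < 0.5 else (v, u)
        magnitude = rng.uniform(lo, hi)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        weights[target, regulator] = sign * magnitude
    # degradation-dominant selfloops: Gershgorin row discs stay left of -lo
    incoming = np.abs(weights).sum(axis=1)
    weights[np.diag_indices(n_genes)] = -(incoming + rng.uniform(lo, hi, size=n_genes))

    return stabilize(Network(weights=weights), margin=stability_margin)
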