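"""Layer graphs, interlayer coupling, and node influence.

A layer is an undirected, static :class:`networkx.Graph` whose nodes are the
integers ``0 .. n-1``.  The influence of a carrier node factorises as

    influence(i) = DE(i) * EC(i) * Ar(i)

where ``DE`` is degree centrality, ``EC`` the dominant-eigenvector centrality
of the adjacency matrix (unit Euclidean norm), and ``Ar`` a role-dependent
attribute weight (spreader / variation / oyster).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .dynamics import NodeState
from .errors import ParameterError, StateError

CouplingMode = Literal["assortative", "disassortative", "random"]

__all__ = [
    "CouplingMode",
    "CoupledNetwork",
    "InfluenceBreakdown",
    "attribute_influence",
    "adjacency",
    "build_ba_network",
    "build_ws_network",
    "couple_layers",
    "degree_centrality",
    "eigen_centrality",
    "influence",
    "validate_layer",
]


@dataclass
class CoupledNetwork:
    """Two equal-sized layers joined by a one-to-one node mapping.

    ``mapping[i]`` is the offline-layer counterpart of online node ``i``;
    the inverse permutation is available as :attr:`inverse`.
    """

    online: nx.Graph
    offline: nx.Graph
    mapping: np.ndarray
    mode: str

    inverse: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.mapping = np.asarray(self.mapping, dtype=np.int64)
        n = self.online.number_of_nodes()
        if self.offline.number_of_nodes() != n:
            raise ParameterError(
                "coupled layers must have equal node counts, got "
                f"{n} online and {self.offline.number_of_nodes()} offline"
            )
        if sorted(self.mapping.tolist()) != list(range(n)):
            raise ParameterError("mapping must be a bijection onto 0..n-1")
        inv = np.empty(n, dtype=np.int64)
        inv[self.mapping] = np.arange(n)
        self.inverse = inv

    @property
    def n(self) -> int:
        return self.online.number_of_nodes()


@dataclass(frozen=True)
class InfluenceBreakdown:
    """The three multiplicative factors of a carrier's influence."""

    de: float
    ec: float
    ar: float

    @property
    def influence(self) -> float:
        return self.de * self.ec * self.ar


def validate_layer(g: nx.Graph) -> None:
    """Check the layer-graph contract: integer nodes 0..n-1, no self-loops."""
    n = g.number_of_nodes()
    if set(g.nodes) != set(range(n)):
        raise ParameterError("layer graph nodes must be the integers 0..n-1")
    if nx.number_of_selfloops(g):
        raise ParameterError("layer graph must not contain self-loops")


def adjacency(g: nx.Graph) -> sp.csr_array:
    """CSR adjacency with rows/columns in node-id order."""
    return sp.csr_array(
        nx.to_scipy_sparse_array(g, nodelist=range(g.number_of_nodes()), dtype=float)
    )


def build_ba_network(n: int, m: int, seed: int | None = None) -> nx.Graph:
    """Barabasi-Albert preferential-attachment graph on nodes 0..n-1.

    Each new node attaches ``m`` edges, giving |E| = m(n-m) and mean degree
    close to 2m for n >> m.

    Raises
    ------
    ParameterError
        If ``n <= m`` or ``m < 1``.
    """
    if m < 1:
        raise ParameterError(f"attachment parameter m must be >= 1, got {m}")
    if n <= m:
        raise ParameterError(f"node count n must exceed m, got n={n}, m={m}")
    return nx.barabasi_albert_graph(n, m, seed=seed)


def build_ws_network(n: int, k: int, p: float, seed: int | None = None) -> nx.Graph:
    """Watts-Strogatz small-world graph (optional offline-layer topology)."""
    if k >= n:
        raise ParameterError(f"ring degree k must be < n, got k={k}, n={n}")
    return nx.watts_strogatz_graph(n, k, p, seed=seed)


def _degree_order(g: nx.Graph, descending: bool) -> np.ndarray:
    """Node ids sorted by degree; ties broken by ascending node id."""
    n = g.number_of_nodes()
    deg = np.array([g.degree(i) for i in range(n)])
    key = -deg if descending else deg
    return np.lexsort((np.arange(n), key))


def couple_layers(
    online: nx.Graph,
    offline: nx.Graph,
    mode: CouplingMode = "random",
    seed: int | None = None,
) -> CoupledNetwork:
    """Join two layers node-for-node.

    assortative
        i-th highest-degree online node maps to the i-th highest-degree
        offline node (hubs pair with hubs).
    disassortative
        i-th highest maps to the i-th lowest.
    random
        Seeded uniform permutation.

    Equal-degree ties are broken by ascending node id so that a fixed seed
    (or no seed, for the deterministic modes) always yields the same mapping.
    """
    validate_layer(online)
    validate_layer(offline)
    n = online.number_of_nodes()
    if offline.number_of_nodes() != n:
        raise ParameterError(
            "layers must have equal node counts, got "
            f"{n} and {offline.number_of_nodes()}"
        )
    mapping = np.empty(n, dtype=np.int64)
    if mode == "assortative":
        mapping[_degree_order(online, True)] = _degree_order(offline, True)
    elif mode == "disassortative":
        mapping[_degree_order(online, True)] = _degree_order(offline, False)
    elif mode == "random":
        rng = np.random.default_rng(seed)
        mapping = rng.permutation(n)
    else:
        raise ParameterError(
            f"unknown coupling mode {mode!r}; "
            "expected assortative, disassortative or random"
        )
    return CoupledNetwork(online=online, offline=offline, mapping=mapping, mode=mode)


def degree_centrality(g: nx.Graph, i: int) -> float:
    """Degree of ``i`` over ``n - 1``, the fraction of possible neighbours."""
    n = g.number_of_nodes()
    if n < 2:
        raise ParameterError("degree centrality requires at least 2 nodes")
    return g.degree(i) / (n - 1)


def eigen_centrality(
    g: nx.Graph,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> np.ndarray:
    """Dominant-eigenvector centrality of the adjacency matrix.

    Computed by power iteration on ``A + I`` (the unit shift leaves the
    eigenvectors unchanged but makes the dominant eigenvalue strictly
    largest in modulus, so the iteration also converges on bipartite
    graphs).  The result is nonnegative and normalised to unit Euclidean
    norm; it satisfies ``A @ x = lambda_max * x`` to high accuracy.

    A graph with no edges has no meaningful centrality: an all-zero vector
    is returned with a warning.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ParameterError("eigen centrality is undefined on an empty graph")
    if g.number_of_edges() == 0:
        warnings.warn(
            "graph has no edges; eigen centrality reported as all zeros",
            stacklevel=2,
        )
        return np.zeros(n)
    a = adjacency(g)
    x = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        y = a @ x + x  # (A + I) x
        y /= np.linalg.norm(y)
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    return x


def attribute_influence(state: NodeState, config) -> float:
    """Role-dependent attribute weight: alpha1/alpha2/alpha3 for S/V/O."""
    if state == NodeState.SPREADER:
        return config.ar_s
    if state == NodeState.VARIATION:
        return config.ar_v
    if state == NodeState.OYSTER:
        return config.ar_o
    raise StateError(
        f"attribute influence is defined only for carrier states, got {state!r}"
    )


def influence(g: nx.Graph, i: int, state: NodeState, config) -> InfluenceBreakdown:
    """Full influence breakdown DE(i) * EC(i) * Ar(i) of carrier ``i``."""
    de = degree_centrality(g, i)
    ec = float(eigen_centrality(g)[i])
    ar = attribute_influence(state, config)
    return InfluenceBreakdown(de=de, ec=ec, ar=ar)
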