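"""Rich-club metrics on binary undirected graphs.

The rich-club coefficient at degree level k is the edge density of the
subgraph spanned by the nodes whose degree is *strictly greater* than k:

    phi(k) = 2 E_{>k} / (N_{>k} (N_{>k} - 1))

Because high-degree nodes are more likely to be interconnected by chance
alone, phi(k) is normalized by the mean phi(k) of an ensemble of
degree-preserving randomized graphs (double-edge-swap rewiring):

    phi_norm(k) = phi(k) / mean_null phi_random(k)

phi_norm(k) > 1 across a range of k indicates rich-club organization.
Edges are classified relative to a rich-node set: *rich* edges join two
rich nodes, *feeder* edges join a rich node to a peripheral node, and
*local* edges join two peripheral nodes.

Undefined values (fewer than two qualifying nodes, or a zero null mean)
are represented as NaN and are excluded from all downstream statistics —
they are never coerced to 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import shortest_path

log = logging.getLogger(__name__)

__all__ = [
    "BinaryGraph",
    "RichClubProfile",
    "EdgeClassMap",
    "NodalMetrics",
    "rich_club_coefficient",
    "rewire_preserving_degree",
    "normalized_rich_club",
    "select_rich_nodes",
    "classify_edges",
    "classify_pairs",
    "nodal_efficiency",
    "summarize_profiles",
    "has_rich_club_effect",
]

EDGE_CLASSES = ("rich", "feeder", "local")


@dataclass
class BinaryGraph:
    """Symmetric 0/1 adjacency matrix without self-loops."""

    adjacency: np.ndarray
    node_labels: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if np.any(np.diag(adj) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = adj.astype(np.int8)
        if self.node_labels is None:
            self.node_labels = [f"n{i}" for i in range(adj.shape[0])]
        elif len(self.node_labels) != adj.shape[0]:
            raise ValueError("node_labels length must equal node count")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_list(self) -> tuple[np.ndarray, np.ndarray]:
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        on = self.adjacency[iu, ju] == 1
        return iu[on], ju[on]


def _as_graph(g) -> BinaryGraph:
    return g if isinstance(g, BinaryGraph) else BinaryGraph(g)


@dataclass
class RichClubProfile:
    """Per-k rich-club curve, optionally with null-ensemble statistics.

    ``k_levels`` runs from 1 to the maximum degree.  ``phi`` is NaN where
    fewer than two nodes have degree > k; ``phi_norm`` is NaN wherever
    ``phi`` is undefined or the null mean is not positive.
    """

    k_levels: np.ndarray
    phi: np.ndarray
    n_gt_k: np.ndarray
    e_gt_k: np.ndarray
    phi_random_mean: np.ndarray
    phi_random_sd: np.ndarray
    phi_norm: np.ndarray
    n_null: int = 0
    seed: int | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "k": self.k_levels,
            "phi": self.phi,
            "n_gt_k": self.n_gt_k,
            "e_gt_k": self.e_gt_k,
            "phi_random_mean": self.phi_random_mean,
            "phi_random_sd": self.phi_random_sd,
            "phi_norm": self.phi_norm,
        })


def _phi_curve(adj: np.ndarray, degrees: np.ndarray) -> tuple[np.ndarray, ...]:
    """phi(k), N>k and E>k for k = 1 .. max degree."""
    kmax = int(degrees.max(initial=0))
    k_levels = np.arange(1, kmax + 1)
    phi = np.full(kmax, np.nan)
    n_gt = np.zeros(kmax, dtype=int)
    e_gt = np.zeros(kmax, dtype=int)
    for idx, k in enumerate(k_levels):
        mask = degrees > k
        n = int(mask.sum())
        n_gt[idx] = n
        if n == 0:
            continue
        e = int(adj[np.ix_(mask, mask)].sum()) // 2
        e_gt[idx] = e
        if n >= 2:
            phi[idx] = 2.0 * e / (n * (n - 1))
    return k_levels, phi, n_gt, e_gt


def rich_club_coefficient(g) -> RichClubProfile:
    """Rich-club curve phi(k) for k from 1 to the maximum degree.

    phi(k) is the density of the subgraph on nodes of degree strictly
    greater than k, NaN when fewer than two such nodes exist.
    """
    g = _as_graph(g)
    deg = g.degrees()
    k_levels, phi, n_gt, e_gt = _phi_curve(g.adjacency, deg)
    nan = np.full(len(k_levels), np.nan)
    return RichClubProfile(k_levels=k_levels, phi=phi, n_gt_k=n_gt,
                           e_gt_k=e_gt, phi_random_mean=nan.copy(),
                           phi_random_sd=nan.copy(), phi_norm=nan.copy())


def rewire_preserving_degree(
    g,
    n_swap_per_edge: int = 10,
    seed: int | np.random.Generator = 0,
    attempt_factor: int = 100,
) -> BinaryGraph:
    """Degree-preserving randomization by double edge swaps.

    Repeatedly picks two edges (a,b), (c,d) and replaces them with (a,d),
    (c,b) when the move creates no self-loop or duplicate edge.  Stops
    after ``n_swap_per_edge * E`` successful swaps or ``attempt_factor * E``
    attempts, whichever comes first (a warning is logged in the latter
    case).  The degree sequence is invariant under the swap move.
    """
    g = _as_graph(g)
    if g.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu, ju = g.edge_list()
    edges = list(zip(iu.tolist(), ju.tolist()))
    edge_set = set(edges)
    n_edges = len(edges)
    target = n_swap_per_edge * n_edges
    max_attempts = attempt_factor * n_edges
    swaps = attempts = 0
    chunk = max(256, 2 * target)  # draw randomness in blocks, not per attempt
    while swaps < target and attempts < max_attempts:
        n_draw = min(chunk, max_attempts - attempts)
        pick = rng.integers(0, n_edges, size=(n_draw, 2))
        orient = rng.integers(0, 2, size=n_draw)
        for (e1, e2), flip in zip(pick.tolist(), orient.tolist()):
            attempts += 1
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if flip:  # randomize which endpoints pair up
                c, d = d, c
            if a == d or c == b or a == c or b == d:
                continue
            new1 = (a, d) if a < d else (d, a)
            new2 = (c, b) if c < b else (b, c)
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard(edges[e1])
            edge_set.discard(edges[e2])
            edge_set.add(new1)
            edge_set.add(new2)
            edges[e1] = new1
            edges[e2] = new2
            swaps += 1
            if swaps == target:
                break
    if swaps < target:
        log.warning("rewiring hit the attempt cap: %d/%d swaps achieved",
                    swaps, target)
    adj = np.zeros_like(g.adjacency)
    if edges:
        ei = np.array([e[0] for e in edges])
        ej = np.array([e[1] for e in edges])
        adj[ei, ej] = 1
        adj[ej, ei] = 1
    return BinaryGraph(adj, list(g.node_labels))


def normalized_rich_club(
    g,
    n_null: int = 1000,
    n_swap_per_edge: int = 10,
    seed: int = 0,
) -> RichClubProfile:
    """phi(k) normalized by a degree-preserving null ensemble.

    ``phi_random_mean(k)`` is the mean phi(k) over ``n_null`` independently
    rewired copies of the graph; ``phi_norm(k) = phi(k)/phi_random_mean(k)``
    wherever both are defined.  Because rewiring preserves every degree,
    the set of defined k levels is identical across the ensemble.
    """
    g = _as_graph(g)
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    base = rich_club_coefficient(g)
    ss = np.random.SeedSequence(seed)
    null_phi = np.empty((n_null, len(base.k_levels)))
    for i, child in enumerate(ss.spawn(n_null)):
        null = rewire_preserving_degree(
            g, n_swap_per_edge=n_swap_per_edge,
            seed=np.random.default_rng(child))
        null_phi[i] = rich_club_coefficient(null).phi
    # degrees (hence the defined k levels) are identical across the
    # ensemble; suppress the all-NaN-slice warning for undefined k
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(null_phi, axis=0)
        sd = (np.nanstd(null_phi, axis=0, ddof=0) if n_null > 1
              else np.zeros_like(mean))
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = np.where(
            np.isfinite(base.phi) & np.isfinite(mean) & (mean > 0),
            base.phi / mean, np.nan)
    return RichClubProfile(
        k_levels=base.k_levels, phi=base.phi, n_gt_k=base.n_gt_k,
        e_gt_k=base.e_gt_k, phi_random_mean=mean, phi_random_sd=sd,
        phi_norm=norm, n_null=n_null, seed=seed)


def select_rich_nodes(mean_degree: np.ndarray, fraction: float = 0.15) -> np.ndarray:
    """Indices of the ``floor(fraction * N)`` highest-mean-degree nodes.

    Ties are broken deterministically: higher mean degree first, then the
    lower node index.  For a 116-node network at fraction 0.15 this yields
    the top 17 nodes.
    """
    mean_degree = np.asarray(mean_degree, dtype=float)
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n = len(mean_degree)
    m = int(np.floor(fraction * n))
    if m == 0:
        raise ValueError("fraction too small: selects zero nodes")
    order = np.lexsort((np.arange(n), -mean_degree))
    return np.sort(order[:m])


@dataclass
class EdgeClassMap:
    """Edges labeled rich / feeder / local relative to a rich-node set."""

    rich_nodes: np.ndarray
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_class: np.ndarray  # array of strings from EDGE_CLASSES

    @property
    def counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.edge_class == c)) for c in EDGE_CLASSES}

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"i": self.edge_i, "j": self.edge_j,
                             "edge_class": self.edge_class})


def _pair_class(i: np.ndarray, j: np.ndarray, rich: np.ndarray,
                n_nodes: int) -> np.ndarray:
    is_rich = np.zeros(n_nodes, dtype=bool)
    is_rich[rich] = True
    n_rich_ends = is_rich[i].astype(int) + is_rich[j].astype(int)
    classes = np.array(["local", "feeder", "rich"])
    return classes[n_rich_ends]


def classify_edges(g, rich_nodes) -> EdgeClassMap:
    """Label each edge rich / feeder / local by rich-node endpoint count."""
    g = _as_graph(g)
    rich = np.asarray(sorted(set(np.asarray(rich_nodes, dtype=int).tolist())),
                      dtype=int)
    if len(rich) and (rich.min() < 0 or rich.max() >= g.n_nodes):
        raise ValueError("rich_nodes out of range")
    iu, ju = g.edge_list()
    return EdgeClassMap(rich_nodes=rich, edge_i=iu, edge_j=ju,
                        edge_class=_pair_class(iu, ju, rich, g.n_nodes))


def classify_pairs(n_nodes: int, rich_nodes) -> np.ndarray:
    """Class of every node pair (upper-triangle order), edge or not."""
    rich = np.asarray(rich_nodes, dtype=int)
    iu, ju = np.triu_indices(n_nodes, k=1)
    return _pair_class(iu, ju, rich, n_nodes)


@dataclass
class NodalMetrics:
    """Per-node degree and efficiency for one binary graph."""

    degree: np.ndarray
    efficiency: np.ndarray


def nodal_efficiency(g) -> NodalMetrics:
    """Nodal efficiency: mean inverse shortest-path length to all others.

    ``eff(i) = (1/(N-1)) * sum_{j != i} 1/d(i,j)`` with unweighted
    shortest-path distance d; unreachable pairs contribute zero, so an
    isolated node has efficiency 0.
    """
    g = _as_graph(g)
    n = g.n_nodes
    dist = shortest_path(g.adjacency, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return NodalMetrics(degree=g.degrees(), efficiency=inv.sum(axis=1) / (n - 1))


def summarize_profiles(profiles: list[RichClubProfile]) -> pd.DataFrame:
    """Mean phi / phi_norm across profiles (e.g. a sparsity sweep), per k.

    Profiles may span different k ranges; each k is averaged over the
    profiles where it is defined, and NaN (undefined) entries are excluded
    rather than treated as zero.
    """
    if not profiles:
        raise ValueError("no profiles to summarize")
    kmax = max(int(p.k_levels.max(initial=0)) for p in profiles)
    phi = np.full((len(profiles), kmax), np.nan)
    norm = np.full((len(profiles), kmax), np.nan)
    for row, p in enumerate(profiles):
        kk = len(p.k_levels)
        phi[row, :kk] = p.phi
        norm[row, :kk] = p.phi_norm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = pd.DataFrame({
            "k": np.arange(1, kmax + 1),
            "phi": np.nanmean(phi, axis=0),
            "phi_norm": np.nanmean(norm, axis=0),
            "n_defined": np.sum(np.isfinite(norm), axis=0),
        })
    return out


def has_rich_club_effect(phi_norm: np.ndarray, k_levels: np.ndarray,
                         k_min: int = 2, k_max: int = 8) -> bool:
    """Whether phi_norm exceeds 1 at every defined k in [k_min, k_max].

    Returns False if no k in the window is defined.
    """
    phi_norm = np.asarray(phi_norm, dtype=float)
    k_levels = np.asarray(k_levels)
    window = (k_levels >= k_min) & (k_levels <= k_max)
    vals = phi_norm[window]
    vals = vals[np.isfinite(vals)]
    return bool(len(vals)) and bool(np.all(vals > 1.0))
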