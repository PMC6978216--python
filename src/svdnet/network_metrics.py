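"""Global graph measures and the rich-club connection-class decomposition.

Measures follow the weighted-connectome conventions of the Brain
Connectivity Toolbox: node degree counts present connections; density is
the realized fraction of possible undirected edges; total strength sums
edge weights; global efficiency averages inverse shortest-path lengths,
with per-edge travel length taken as the inverse of the connection
weight (stronger connections are "shorter").  Disconnected node pairs
contribute zero inverse distance.

Edges are classified against the a-priori rich-club node set: both
endpoints in the rich club -> rich-club connection; exactly one ->
feeder; neither -> peripheral.  Class strength is the mean weight over
the *present* edges of that class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .connectome import ConnectivityMatrix, Parcellation

__all__ = [
    "GlobalMetrics",
    "RichClubPartition",
    "node_degree",
    "network_density",
    "total_network_strength",
    "global_efficiency",
    "classify_edges",
    "class_mean_strength",
    "degree_rank_report",
    "compute_global_metrics",
]

EDGE_CLASSES = ("rich_club", "feeder", "peripheral")


@dataclass(frozen=True)
class GlobalMetrics:
    degree: np.ndarray
    density: float
    total_strength: float
    global_efficiency: float


@dataclass(frozen=True)
class RichClubPartition:
    """Per-edge class labels and class-level summaries.

    ``edge_class`` maps each present undirected edge (i, j), i < j, to one
    of ``rich_club``/``feeder``/``peripheral``.  ``class_strengths`` holds
    the mean weight per class (NaN when the class has no present edge).
    """

    edge_class: dict[tuple[int, int], str]
    class_strengths: dict[str, float]
    class_counts: dict[str, int]


def _check_n(matrix: ConnectivityMatrix) -> int:
    n = matrix.n_regions
    if n < 2:
        raise ValueError(f"need at least 2 regions, got {n}")
    return n


def node_degree(matrix: ConnectivityMatrix) -> np.ndarray:
    """Number of present connections of each node."""
    return (matrix.weights > 0).sum(axis=1).astype(int)


def network_density(matrix: ConnectivityMatrix) -> float:
    """Present undirected edges over n(n-1)/2 possible."""
    n = _check_n(matrix)
    return matrix.edge_count() / (n * (n - 1) / 2)


def total_network_strength(matrix: ConnectivityMatrix) -> float:
    """Sum of connection weights, each undirected edge counted once."""
    return float(np.triu(matrix.weights, k=1).sum())


def global_efficiency(matrix: ConnectivityMatrix, *, binary: bool = False) -> float:
    """Average inverse shortest-path length over ordered node pairs.

    Path length between adjacent nodes is 1/weight (or 1 if ``binary``);
    shortest paths minimise summed lengths.  Disconnected pairs count as
    zero inverse distance, so an edgeless network has efficiency 0.
    """
    n = _check_n(matrix)
    w = matrix.weights
    if not w.any():
        return 0.0
    lengths = np.zeros_like(w)
    nz = w > 0
    lengths[nz] = 1.0 if binary else 1.0 / w[nz]
    dist = dijkstra(csr_array(lengths), directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def classify_edges(
    matrix: ConnectivityMatrix, parcellation: Parcellation | None = None
) -> RichClubPartition:
    """Partition present edges into rich-club / feeder / peripheral.

    Class membership is decided by how many endpoints lie in the
    parcellation's rich-club set (2, 1 or 0).  Every present edge lands in
    exactly one class, so class counts sum to the edge count.
    """
    parc = parcellation if parcellation is not None else matrix.parcellation
    if parc.n_regions != matrix.n_regions:
        raise ValueError("parcellation size does not match matrix")
    rich = parc.rich_club_mask
    if not rich.any():
        warnings.warn(
            "rich-club set is empty: all edges classified as peripheral",
            stacklevel=2,
        )
    iu, ju = np.nonzero(np.triu(matrix.weights, k=1))
    n_rich_endpoints = rich[iu].astype(int) + rich[ju].astype(int)
    edge_class: dict[tuple[int, int], str] = {}
    sums = dict.fromkeys(EDGE_CLASSES, 0.0)
    counts = dict.fromkeys(EDGE_CLASSES, 0)
    for i, j, k in zip(iu.tolist(), ju.tolist(), n_rich_endpoints.tolist()):
        cls = EDGE_CLASSES[2 - k]
        edge_class[(i, j)] = cls
        sums[cls] += matrix.weights[i, j]
        counts[cls] += 1
    strengths = {
        cls: (sums[cls] / counts[cls] if counts[cls] else float("nan"))
        for cls in EDGE_CLASSES
    }
    return RichClubPartition(edge_class, strengths, counts)


def class_mean_strength(
    partition: RichClubPartition, matrix: ConnectivityMatrix
) -> tuple[float, float, float]:
    """Mean edge weight per class over present edges (NaN if class empty)."""
    sums = dict.fromkeys(EDGE_CLASSES, 0.0)
    counts = dict.fromkeys(EDGE_CLASSES, 0)
    for (i, j), cls in partition.edge_class.items():
        sums[cls] += matrix.weights[i, j]
        counts[cls] += 1
    return tuple(
        sums[c] / counts[c] if counts[c] else float("nan") for c in EDGE_CLASSES
    )


@dataclass(frozen=True)
class DegreeRankReport:
    labels: tuple[str, ...]
    degrees: np.ndarray
    ranks: np.ndarray
    within_top_k: np.ndarray
    k: int

    @property
    def all_within_top_k(self) -> bool:
        return bool(self.within_top_k.all())


def degree_rank_report(
    matrix: ConnectivityMatrix, parcellation: Parcellation | None = None, k: int = 12
) -> DegreeRankReport:
    """Degree and dense degree-rank of each rich-club node.

    Rank 1 is the highest degree; nodes with equal degree share a rank
    (dense ranking).  A rich node is flagged as within the top ``k`` when
    fewer than ``k`` nodes have a strictly higher degree.
    """
    parc = parcellation if parcellation is not None else matrix.parcellation
    if not 1 <= k <= parc.n_regions:
        raise ValueError(f"k must be in [1, {parc.n_regions}], got {k}")
    deg = node_degree(matrix)
    distinct = np.unique(deg)[::-1]  # descending
    rank_of = {d: r for r, d in enumerate(distinct, start=1)}
    idx = parc.rich_club_indices
    rich_deg = deg[idx]
    ranks = np.array([rank_of[d] for d in rich_deg], dtype=int)
    # "within top k degrees": among the k largest degree values counting
    # multiplicity — a node qualifies if fewer than k nodes have a
    # strictly higher degree.
    n_higher = np.array([(deg > d).sum() for d in rich_deg])
    within = n_higher < k
    return DegreeRankReport(tuple(parc.rich_club_labels), rich_deg, ranks, within, k)


def compute_global_metrics(matrix: ConnectivityMatrix, *, binary_efficiency: bool = False) -> GlobalMetrics:
    """Bundle degree, density, total strength and global efficiency."""
    return GlobalMetrics(
        degree=node_degree(matrix),
        density=network_density(matrix),
        total_strength=total_network_strength(matrix),
        global_efficiency=global_efficiency(matrix, binary=binary_efficiency),
    )
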