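"""Co-expression networks from Z-transformed time series.

Per-condition Pearson correlation matrices are binarized at a threshold
into boolean adjacency networks, and the elementwise intersection across
conditions gives the conserved co-expression structure. A threshold scan
reports how stable the detected community structure is across a grid of
correlation cut-offs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Network",
    "z_transform",
    "correlation_network",
    "intersect_networks",
    "threshold_scan",
    "ThresholdProfile",
]


@dataclass
class Network:
    """Thresholded co-expression network as a boolean adjacency matrix."""

    nodes: list[str]
    adjacency: np.ndarray  # symmetric bool, zero diagonal
    threshold: float
    label: str = ""

    def __post_init__(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("duplicate node ids")
        adj = np.asarray(self.adjacency, dtype=bool)
        if adj.shape != (len(self.nodes), len(self.nodes)):
            raise ValueError("adjacency shape does not match node list")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("self-edges are not allowed")
        self.adjacency = adj

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[str, str]]:
        iu, ju = np.triu_indices(len(self.nodes), k=1)
        mask = self.adjacency[iu, ju]
        return [(self.nodes[i], self.nodes[j]) for i, j in zip(iu[mask], ju[mask])]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g


def z_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene's profile to mean 0, SD 1 across timepoints.

    Constant rows cannot be standardized; they are returned as all-zero
    with a warning so downstream correlations treat them as uncorrelated.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 timepoints to Z-transform")
    vals = matrix.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values in expression matrix")
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene profile(s) set to zero",
            UserWarning,
            stacklevel=2,
        )
    sd[constant] = 1.0
    out = (vals - mean) / sd
    out[constant] = 0.0
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def correlation_network(
    matrix: pd.DataFrame,
    threshold: float = 0.6,
    mode: str = "signed",
    method: str = "pearson",
    label: str = "",
) -> Network:
    """Binary adjacency from pairwise gene-gene correlation.

    An edge joins genes i and j iff r(i, j) > ``threshold`` (strict).
    ``mode="signed"`` uses the signed correlation (positive co-expression,
    the regulon assumption); ``mode="abs"`` thresholds |r|. ``method``
    may be ``"pearson"`` or ``"spearman"``.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie strictly in (0, 1)")
    if mode not in ("signed", "abs"):
        raise ValueError("mode must be 'signed' or 'abs'")
    vals = matrix.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise ValueError("non-finite values in expression matrix")
    if method == "spearman":
        from scipy.stats import rankdata

        vals = rankdata(vals, axis=1)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.atleast_2d(np.corrcoef(vals))  # 0-d for a single gene
    r = np.nan_to_num(r, nan=0.0)  # constant rows correlate with nothing
    if mode == "abs":
        r = np.abs(r)
    adj = r > threshold
    np.fill_diagonal(adj, False)
    return Network(list(matrix.index), adj, threshold, label=label)


def intersect_networks(nets: Sequence[Network]) -> Network:
    """Edgewise AND of networks: the structure conserved in every input.

    Genes missing from any input are dropped (reported via the returned
    network's node list being the common subset, in first-input order).
    """
    if not nets:
        raise ValueError("cannot intersect an empty list of networks")
    common = set(nets[0].nodes)
    for net in nets[1:]:
        common &= set(net.nodes)
    nodes = [g for g in nets[0].nodes if g in common]
    if not nodes:
        raise ValueError("networks share no nodes")
    adj = np.ones((len(nodes), len(nodes)), dtype=bool)
    for net in nets:
        pos = {g: i for i, g in enumerate(net.nodes)}
        sel = [pos[g] for g in nodes]
        adj &= net.adjacency[np.ix_(sel, sel)]
    np.fill_diagonal(adj, False)
    return Network(nodes, adj, max(n.threshold for n in nets), label="intersection")


@dataclass
class ThresholdProfile:
    """Community stability across a grid of correlation thresholds."""

    thresholds: list[float]
    partitions: list[dict[str, int]]
    adjacent_ari: list[float] = field(repr=False)  # ARI between tau_k and tau_{k+1}
    stable_interval: tuple[float, float] | None = None


def threshold_scan(
    matrices: Sequence[pd.DataFrame],
    thresholds: Sequence[float],
    community_fn: Callable[[Network], dict[str, int]],
    mode: str = "signed",
    stability_ari: float = 0.9,
) -> ThresholdProfile:
    """Partition the intersection network at each threshold and compare.

    For every tau in the grid, the per-condition networks are rebuilt,
    intersected, and partitioned with ``community_fn``; the adjusted Rand
    index between partitions at adjacent thresholds measures robustness.
    The maximal contiguous tau interval with adjacent ARI >= the
    stability cut-off is reported.
    """
    from .communities import partition_similarity

    taus = sorted(float(t) for t in thresholds)
    if not taus:
        raise ValueError("empty threshold grid")
    partitions = []
    for tau in taus:
        nets = [correlation_network(m, tau, mode=mode) for m in matrices]
        partitions.append(community_fn(intersect_networks(nets)))
    aris = [
        partition_similarity(partitions[k], partitions[k + 1])
        for k in range(len(taus) - 1)
    ]
    best: tuple[float, float] | None = None
    start = 0
    for k in range(len(taus) - 1):
        if aris[k] >= stability_ari:
            if best is None or taus[k + 1] - taus[start] > best[1] - best[0]:
                best = (taus[start], taus[k + 1])
        else:
            start = k + 1
    return ThresholdProfile(taus, partitions, aris, best)
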