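"""Community detection by greedy modularity maximization.

Agglomerative best-merge search in the style of the fast-greedy
algorithm: start from singleton communities and repeatedly merge the
pair of connected communities with the largest modularity gain until no
merge increases Q. Merge gains are compared in exact integer arithmetic
(Delta-Q scaled by 2 m^2), so tie-breaking — lexicographically smallest
pair of community ids, where a community is identified by its smallest
member gene id — is deterministic and independent of node input order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .coexpression import Network

__all__ = [
    "Partition",
    "Community",
    "modularity",
    "greedy_modularity",
    "regulatory_modules",
    "partition_similarity",
]


@dataclass
class Partition:
    """Node -> community assignment with its modularity and merge history."""

    membership: dict[str, int]
    q: float
    merge_history: list[tuple[tuple[str, str], float]] = field(default_factory=list)

    def communities(self) -> dict[int, set[str]]:
        out: dict[int, set[str]] = {}
        for gene, cid in self.membership.items():
            out.setdefault(cid, set()).add(gene)
        return out


@dataclass(frozen=True)
class Community:
    id: int
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


def modularity(net: Network, partition: Mapping[str, object]) -> float:
    """Newman modularity Q = sum_c (e_c - a_c^2).

    ``e_c`` is the fraction of edges with both ends inside community c
    and ``a_c`` the fraction of edge ends attached to c.
    """
    missing = [g for g in net.nodes if g not in partition]
    if missing:
        raise ValueError(f"partition misses node(s) {missing[:3]!r}")
    m = net.n_edges
    if m == 0:
        raise ValueError("modularity undefined on an edgeless network")
    comm_of = [partition[g] for g in net.nodes]
    e_in: dict[object, int] = {}
    deg: dict[object, int] = {}
    adj = net.adjacency
    degrees = adj.sum(axis=1)
    for i, g in enumerate(net.nodes):
        deg[comm_of[i]] = deg.get(comm_of[i], 0) + int(degrees[i])
    iu, ju = np.triu_indices(len(net.nodes), k=1)
    mask = adj[iu, ju]
    for i, j in zip(iu[mask], ju[mask]):
        if comm_of[i] == comm_of[j]:
            e_in[comm_of[i]] = e_in.get(comm_of[i], 0) + 1
    q = 0.0
    for c in deg:
        q += e_in.get(c, 0) / m - (deg[c] / (2.0 * m)) ** 2
    return q


def greedy_modularity(net: Network) -> Partition:
    """Agglomerative modularity maximization with deterministic tie-breaks.

    Returns the partition at the point where no merge increases Q. On an
    edgeless network every node stays a singleton (with a warning).
    """
    nodes = list(net.nodes)
    m = net.n_edges
    if m == 0:
        warnings.warn("edgeless network: every node is a singleton community", UserWarning)
        return Partition({g: i for i, g in enumerate(sorted(nodes))}, 0.0, [])

    # community id = smallest member gene id; integer bookkeeping throughout
    idx = {g: i for i, g in enumerate(nodes)}
    comm: dict[str, set[str]] = {g: {g} for g in nodes}
    degrees = net.adjacency.sum(axis=1)
    deg = {g: int(degrees[idx[g]]) for g in nodes}
    between: dict[str, dict[str, int]] = {g: {} for g in nodes}
    e_in = {g: 0 for g in nodes}
    for a, b in net.edges():
        between[a][b] = between[a].get(b, 0) + 1
        between[b][a] = between[b].get(a, 0) + 1

    q = sum(-((d / (2.0 * m)) ** 2) for d in deg.values())
    history: list[tuple[tuple[str, str], float]] = []

    while True:
        # integer Delta-Q * 2 m^2; sorted iteration makes the first pair
        # attaining the maximum the lexicographically smallest one
        best_score = 0
        best_pair: tuple[str, str] | None = None
        for u in sorted(between):
            for v in sorted(between[u]):
                if v <= u:
                    continue
                score = 2 * m * between[u][v] - deg[u] * deg[v]
                if score > best_score:
                    best_score, best_pair = score, (u, v)
        if best_pair is None:
            break
        u, v = best_pair  # u < v; merged community keeps id u
        q += best_score / (2.0 * m * m)
        comm[u] |= comm.pop(v)
        e_in[u] += e_in.pop(v) + between[u][v]
        deg[u] += deg.pop(v)
        nbrs_v = between.pop(v)
        del between[u][v]
        for w, cnt in nbrs_v.items():
            if w == u:
                continue
            between[u][w] = between[u].get(w, 0) + cnt
            del between[w][v]
            between[w][u] = between[w].get(u, 0) + cnt
        history.append(((u, v), q))

    # relabel communities by descending size, smallest member id as tie-break
    order = sorted(comm.values(), key=lambda s: (-len(s), min(s)))
    membership = {g: cid for cid, members in enumerate(order) for g in members}
    return Partition(membership, q, history)


def regulatory_modules(
    partition: Partition | Mapping[str, int], min_size: int = 6
) -> list[Community]:
    """Communities with at least ``min_size`` members, largest first.

    The default of 6 encodes the convention of reporting modules with
    more than five genes each.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    mapping = partition.membership if isinstance(partition, Partition) else dict(partition)
    groups: dict[int, set[str]] = {}
    for gene, cid in mapping.items():
        groups.setdefault(cid, set()).add(gene)
    modules = [
        Community(cid, frozenset(members))
        for cid, members in groups.items()
        if len(members) >= min_size
    ]
    return sorted(modules, key=lambda c: (-c.size, min(c.members)))


def partition_similarity(
    p1: Partition | Mapping[str, int], p2: Partition | Mapping[str, int]
) -> float:
    """Adjusted Rand index between two partitions of the same node set."""
    m1 = p1.membership if isinstance(p1, Partition) else dict(p1)
    m2 = p2.membership if isinstance(p2, Partition) else dict(p2)
    if set(m1) != set(m2):
        raise ValueError("partitions cover different node sets")
    nodes = sorted(m1)
    return float(adjusted_rand_score([m1[g] for g in nodes], [m2[g] for g in nodes]))
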