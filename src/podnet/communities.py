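"""Community detection (WalkTrap) and partition overlap (variation of information).

WalkTrap finds communities by agglomerating vertices whose short random
walks look alike; dense regions "trap" the walker.  Here HWI edge weights
act as transition propensities, so communities are sets of individuals
with strong mutual association.  The merge dendrogram is cut at maximum
modularity; isolated vertices form singleton communities.

Overlap between the community structures of two networks is measured with
the variation of information,

    VI(P, Q) = H(P) + H(Q) - 2 I(P; Q),

a metric on partitions: 0 iff identical, bounded by log(n).  Smaller VI
means larger overlap.  Networks for different activities have different
vertex sets; either compare the shared vertices only (``intersection``) or
pad each partition with singletons for vertices missing from its network
(``union_singletons``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import igraph as ig
import numpy as np

from .association import ActivityNetwork

__all__ = [
    "Partition",
    "OverlapResult",
    "walktrap_partition",
    "community_stats",
    "variation_of_information",
    "write_partition",
    "read_partition",
]


@dataclass(frozen=True)
class Partition:
    """Disjoint non-empty blocks covering a network's vertex set."""

    blocks: tuple[frozenset[str], ...]
    network_activity: str = "all"
    walk_length: "int | None" = None
    modularity: "float | None" = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for block in self.blocks:
            if not block:
                raise ValueError("empty community block")
            if block & seen:
                raise ValueError("overlapping community blocks")
            seen |= block

    @property
    def n_communities(self) -> int:
        return len(self.blocks)

    @property
    def elements(self) -> frozenset[str]:
        out: set[str] = set()
        for block in self.blocks:
            out |= block
        return frozenset(out)

    @property
    def average_community_size(self) -> float:
        return len(self.elements) / self.n_communities

    def labels(self) -> dict[str, int]:
        """Element -> block index (blocks ordered by smallest member)."""
        ordered = sorted(self.blocks, key=min)
        return {el: k for k, block in enumerate(ordered) for el in block}


def walktrap_partition(net: ActivityNetwork, walk_length: int = 4) -> Partition:
    """WalkTrap communities of an HWI network, cut at maximum modularity.

    Deterministic for a fixed network and walk length.  Isolated vertices
    are detected separately and returned as singleton blocks; modularity is
    reported for the full graph with HWI weights.
    """
    if walk_length < 1:
        raise ValueError("walk_length must be >= 1")
    if net.n_vertices == 0:
        raise ValueError("network has no vertices")
    vertices = list(net.vertices)
    isolated = [v for v in vertices if net.graph.degree(v) == 0]
    connected = [v for v in vertices if net.graph.degree(v) > 0]

    blocks: list[frozenset[str]] = []
    if connected:
        index = {v: k for k, v in enumerate(connected)}
        edges = sorted(tuple(sorted(e)) for e in net.graph.edges)
        g = ig.Graph(
            n=len(connected),
            edges=[(index[a], index[b]) for a, b in edges],
        )
        weights = [net.weight(a, b) for a, b in edges]
        dendrogram = g.community_walktrap(weights=weights, steps=walk_length)
        clustering = dendrogram.as_clustering()  # max-modularity cut
        for community in clustering:
            blocks.append(frozenset(connected[i] for i in community))
    blocks.extend(frozenset([v]) for v in isolated)
    partition = Partition(
        blocks=tuple(blocks),
        network_activity=net.activity,
        walk_length=walk_length,
        modularity=_modularity(net, tuple(blocks)),
    )
    return partition


def _modularity(net: ActivityNetwork, blocks: Sequence[frozenset[str]]) -> float:
    """Weighted Newman modularity of a partition on the full network."""
    index = {v: k for k, v in enumerate(net.vertices)}
    membership = [0] * len(index)
    for k, block in enumerate(blocks):
        for v in block:
            membership[index[v]] = k
    edges = sorted(tuple(sorted(e)) for e in net.graph.edges)
    g = ig.Graph(n=len(index), edges=[(index[a], index[b]) for a, b in edges])
    weights = [net.weight(a, b) for a, b in edges]
    if not edges:
        return 0.0
    return g.modularity(membership, weights=weights)


def community_stats(partition: Partition) -> tuple[int, float]:
    """(number of communities, average community size)."""
    return partition.n_communities, partition.average_community_size


@dataclass(frozen=True)
class OverlapResult:
    activity_pair: tuple[str, str]
    vertex_handling: str
    log_base: str
    vi: float
    n_shared_vertices: int
    n_elements_compared: int

    def as_dict(self) -> dict:
        return {
            "activity_pair": list(self.activity_pair),
            "vertex_handling": self.vertex_handling,
            "log_base": self.log_base,
            "vi": self.vi,
            "n_shared_vertices": self.n_shared_vertices,
            "n_elements_compared": self.n_elements_compared,
        }


def variation_of_information(
    p1: Partition,
    p2: Partition,
    log_base: "str | int" = 2,
    vertex_handling: str = "union_singletons",
) -> OverlapResult:
    """VI distance between two community partitions.

    ``vertex_handling='intersection'`` restricts both partitions to the
    shared elements (dropping emptied blocks); ``'union_singletons'``
    extends each partition with singleton blocks for elements present only
    in the other, so that transient individuals count as maximally
    "their own community".  ``log_base`` is 2 (bits) or 'e' (nats).
    """
    e1, e2 = p1.elements, p2.elements
    shared = e1 & e2
    if vertex_handling == "intersection":
        if not shared:
            raise ValueError("partitions share no vertices")
        elements = sorted(shared)
        blocks1 = _restrict(p1.blocks, shared)
        blocks2 = _restrict(p2.blocks, shared)
    elif vertex_handling == "union_singletons":
        union = e1 | e2
        if not union:
            raise ValueError("both partitions are empty")
        elements = sorted(union)
        blocks1 = p1.blocks + tuple(frozenset([v]) for v in sorted(union - e1))
        blocks2 = p2.blocks + tuple(frozenset([v]) for v in sorted(union - e2))
    else:
        raise ValueError(f"unknown vertex_handling {vertex_handling!r}")

    vi = _vi_from_blocks(elements, blocks1, blocks2, log_base)
    return OverlapResult(
        activity_pair=(p1.network_activity, p2.network_activity),
        vertex_handling=vertex_handling,
        log_base="e" if log_base == "e" else "2",
        vi=vi,
        n_shared_vertices=len(shared),
        n_elements_compared=len(elements),
    )


def _restrict(
    blocks: Iterable[frozenset[str]], keep: frozenset[str]
) -> tuple[frozenset[str], ...]:
    out = tuple(b & keep for b in blocks)
    return tuple(b for b in out if b)


def _vi_from_blocks(
    elements: Sequence[str],
    blocks1: Sequence[frozenset[str]],
    blocks2: Sequence[frozenset[str]],
    log_base: "str | int",
) -> float:
    log = np.log if log_base == "e" else np.log2
    lab1 = {el: k for k, b in enumerate(blocks1) for el in b}
    lab2 = {el: k for k, b in enumerate(blocks2) for el in b}
    n = len(elements)
    cont = np.zeros((len(blocks1), len(blocks2)))
    for el in elements:
        cont[lab1[el], lab2[el]] += 1
    pij = cont / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    h1 = -float(np.sum(pi[pi > 0] * log(pi[pi > 0])))
    h2 = -float(np.sum(pj[pj > 0] * log(pj[pj > 0])))
    mask = pij > 0
    mi = float(np.sum(pij[mask] * log(pij[mask] / np.outer(pi, pj)[mask])))
    return max(h1 + h2 - 2.0 * mi, 0.0)


def write_partition(partition: Partition, path: "str | Path") -> None:
    """CSV ``individual_id,community_id`` with deterministic block numbering."""
    import csv

    labels = partition.labels()
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual_id", "community_id"])
        for ind in sorted(labels):
            writer.writerow([ind, labels[ind]])


def read_partition(path: "str | Path", network_activity: str = "all") -> Partition:
    import csv
    from collections import defaultdict

    groups: dict[str, set[str]] = defaultdict(set)
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            groups[row["community_id"]].add(row["individual_id"])
    blocks = tuple(frozenset(v) for _, v in sorted(groups.items()))
    return Partition(blocks=blocks, network_activity=network_activity)
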