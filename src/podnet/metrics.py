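"""Scalar network metrics and group-size statistics.

Conventions: clustering is computed on the unweighted topology (an edge
either exists or not), and vertices of degree < 2 contribute 0 to the
average rather than being excluded — this keeps the average well defined
on sparse networks such as a forage network.  Group sizes include
unidentified animals, and SDs are sample SDs.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, asdict

import networkx as nx

from .association import ActivityNetwork
from .sightings import Activity, ALL, SightingTable, select_records

__all__ = [
    "NetworkMetrics",
    "GroupSizeStats",
    "average_degree",
    "average_strength",
    "average_edge_weight",
    "connected_components",
    "average_clustering",
    "network_metrics",
    "group_size_stats",
]


@dataclass(frozen=True)
class NetworkMetrics:
    n_vertices: int
    n_edges: int
    average_degree: float
    average_strength: float
    average_edge_weight: float
    n_connected_components: int
    average_clustering: float

    def as_dict(self) -> dict:
        return asdict(self)


def average_degree(net: ActivityNetwork) -> float:
    """Mean number of edges incident on a vertex: 2E / V."""
    if net.n_vertices == 0:
        raise ValueError("network has no vertices")
    return 2.0 * net.n_edges / net.n_vertices


def average_strength(net: ActivityNetwork) -> float:
    """Mean over vertices of summed incident HWI weights: 2 sum(w) / V."""
    if net.n_vertices == 0:
        raise ValueError("network has no vertices")
    return 2.0 * sum(net.edge_weights()) / net.n_vertices


def average_edge_weight(net: ActivityNetwork) -> float:
    """Mean HWI over edges."""
    if net.n_edges == 0:
        raise ValueError("network has no edges")
    return sum(net.edge_weights()) / net.n_edges


def connected_components(net: ActivityNetwork) -> int:
    """Number of maximal connected vertex sets (isolated vertices count)."""
    if net.n_vertices == 0:
        raise ValueError("network has no vertices")
    return nx.number_connected_components(net.graph)


def average_clustering(net: ActivityNetwork) -> float:
    """Unweighted mean local clustering coefficient (degree < 2 counts as 0)."""
    if net.n_vertices == 0:
        raise ValueError("network has no vertices")
    return nx.average_clustering(net.graph, count_zeros=True)


def network_metrics(net: ActivityNetwork) -> NetworkMetrics:
    """All scalar metrics of a network in one record.

    ``average_strength == average_degree * average_edge_weight`` holds as
    an algebraic identity (both reduce to the same edge-weight sum).
    """
    return NetworkMetrics(
        n_vertices=net.n_vertices,
        n_edges=net.n_edges,
        average_degree=average_degree(net),
        average_strength=average_strength(net),
        average_edge_weight=(
            average_edge_weight(net) if net.n_edges > 0 else float("nan")
        ),
        n_connected_components=connected_components(net),
        average_clustering=average_clustering(net),
    )


@dataclass(frozen=True)
class GroupSizeStats:
    activity: str
    sizes: tuple[int, ...]
    mean: float
    sd: float


def group_size_stats(
    table: SightingTable, activity: "Activity | str | None" = ALL
) -> GroupSizeStats:
    """Per-sighting group sizes (identified + unidentified) for one activity."""
    records = select_records(table, activity)
    if not records:
        raise ValueError(f"no records with activity {activity!r}")
    sizes = tuple(r.group_size for r in records)
    act = activity if isinstance(activity, str) else activity.value
    return GroupSizeStats(
        activity=act or ALL,
        sizes=sizes,
        mean=statistics.fmean(sizes),
        sd=statistics.stdev(sizes) if len(sizes) > 1 else 0.0,
    )
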