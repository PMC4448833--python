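"""Dyadic association counts, the half-weight index, and network construction.

For an unordered pair (a, b), let X be the number of sightings containing
both, Ya the number containing a but not b, and Yb the converse.  The
half-weight index is

    HWI = X / (X + (Ya + Yb) / 2),

which equals 0 for pairs never seen together and 1 for pairs always seen
together; it corrects for the chance of observing only one member of an
associated pair.  Because only co-membership matters, HWI(a, b) is
unaffected by the sizes of groups that contain neither a nor b.

A per-activity network takes the sightings of one behavioural state (or
all of them), prunes individuals seen fewer than ``min_sightings`` times
*within that state*, and connects retained pairs with HWI > 0.  Pruning
does not edit sighting membership: counts for retained pairs still include
sightings in which pruned individuals appeared.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .sightings import Activity, ALL, SightingTable, select_records

logger = logging.getLogger(__name__)

__all__ = [
    "DyadCounts",
    "ActivityNetwork",
    "half_weight_index",
    "dyadic_counts",
    "build_activity_network",
    "threshold_scan",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
]


def half_weight_index(x: int, ya: int, yb: int) -> float:
    """HWI = X / (X + (Ya + Yb)/2).  Undefined (raises) when all counts are 0."""
    if min(x, ya, yb) < 0:
        raise ValueError("counts must be non-negative")
    denom = x + 0.5 * (ya + yb)
    if denom == 0:
        raise ValueError("HWI undefined: dyad with no sightings of either individual")
    return x / denom


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class DyadCounts:
    """Per-pair co-sighting tallies over one activity's records.

    ``together[(a, b)]`` is X for the sorted pair; ``n_sightings[i]`` is the
    number of selected records containing i, so Ya = n_a - X.
    """

    activity: str
    n_records: int
    n_sightings: Mapping[str, int]
    together: Mapping[tuple[str, str], int]

    @property
    def individuals(self) -> tuple[str, ...]:
        return tuple(sorted(self.n_sightings))

    def x(self, a: str, b: str) -> int:
        return self.together.get(_pair(a, b), 0)

    def ya(self, a: str, b: str) -> int:
        return self.n_sightings[a] - self.x(a, b)

    def yb(self, a: str, b: str) -> int:
        return self.n_sightings[b] - self.x(a, b)

    def hwi(self, a: str, b: str) -> float:
        return half_weight_index(self.x(a, b), self.ya(a, b), self.yb(a, b))


def dyadic_counts(
    table: SightingTable, activity: "Activity | str | None" = ALL
) -> DyadCounts:
    """Tally X and per-individual sighting counts over the selected records."""
    records = select_records(table, activity)
    if not records:
        raise ValueError(f"no records with activity {activity!r}")
    n: dict[str, int] = {}
    together: dict[tuple[str, str], int] = {}
    for rec in records:
        for ind in rec.members:
            n[ind] = n.get(ind, 0) + 1
        for a, b in combinations(sorted(rec.members), 2):
            together[(a, b)] = together.get((a, b), 0) + 1
    act = activity if isinstance(activity, str) else activity.value
    return DyadCounts(
        activity=act or ALL, n_records=len(records), n_sightings=n, together=together
    )


@dataclass(frozen=True)
class ActivityNetwork:
    """Simple undirected HWI-weighted network for one activity state.

    Vertices carry ``sightings_count`` (within-activity); edges carry
    ``weight`` = HWI in (0, 1].  Zero-HWI pairs carry no edge.
    """

    graph: nx.Graph
    activity: str
    min_sightings_threshold: int
    n_sightings_used: int

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def vertices(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    def weight(self, a: str, b: str) -> float:
        return self.graph.edges[a, b]["weight"]

    def edge_weights(self) -> list[float]:
        return [d["weight"] for _, _, d in self.graph.edges(data=True)]


def build_activity_network(
    table: SightingTable,
    activity: "Activity | str | None" = ALL,
    min_sightings: int = 3,
) -> ActivityNetwork:
    """Build the pruned HWI network for one activity.

    Individuals sighted fewer than ``min_sightings`` times within the
    selected records are removed; retained pairs with X > 0 get an edge
    weighted by their HWI.
    """
    if min_sightings < 1:
        raise ValueError("min_sightings must be >= 1")
    counts = dyadic_counts(table, activity)
    retained = {i for i, c in counts.n_sightings.items() if c >= min_sightings}
    if not retained:
        raise ValueError(
            f"no individuals with >= {min_sightings} sightings for activity "
            f"{counts.activity!r}"
        )
    g = nx.Graph(activity=counts.activity, min_sightings_threshold=min_sightings)
    for ind in sorted(retained):
        g.add_node(ind, sightings_count=counts.n_sightings[ind])
    for (a, b), x in counts.together.items():
        if x > 0 and a in retained and b in retained:
            g.add_edge(a, b, weight=counts.hwi(a, b))
    return ActivityNetwork(
        graph=g,
        activity=counts.activity,
        min_sightings_threshold=min_sightings,
        n_sightings_used=counts.n_records,
    )


def threshold_scan(
    table: SightingTable,
    activity: "Activity | str | None",
    thresholds: Iterable[int],
    n_permutations: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Vertex/edge counts and preferential-association p-value per threshold.

    Mirrors the threshold-selection procedure in which the working pruning
    threshold is the lowest that still shows significant non-random
    association (judged by the CV tail p-value of the data-stream
    permutation test); selection itself is left to the caller.
    """
    from .null_models import permute_group_memberships

    thresholds = list(thresholds)
    if not thresholds or sorted(thresholds) != thresholds:
        raise ValueError("thresholds must be non-empty and ascending")
    rows = []
    for k, thr in enumerate(thresholds):
        net = build_activity_network(table, activity, min_sightings=thr)
        res = permute_group_memberships(
            table,
            activity=activity,
            min_sightings=thr,
            n_permutations=n_permutations,
            seed=seed + k,
        )
        rows.append(
            {
                "threshold": thr,
                "n_vertices": net.n_vertices,
                "n_edges": net.n_edges,
                "cv_pvalue": res.p_cv_high,
            }
        )
    return pd.DataFrame(rows)


# --- serialization ---------------------------------------------------------

def write_edgelist(net: ActivityNetwork, path: "str | Path") -> None:
    """Weighted edge list CSV ``id_a,id_b,hwi`` (full float precision).

    Lossy for isolated vertices and attributes; use GraphML for exact
    round-trips.
    """
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id_a", "id_b", "hwi"])
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            writer.writerow([a, b, repr(net.weight(a, b))])


def read_edgelist(path: "str | Path") -> nx.Graph:
    g = nx.Graph()
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            g.add_edge(row["id_a"], row["id_b"], weight=float(row["hwi"]))
    return g


def write_graphml(net: ActivityNetwork, path: "str | Path") -> None:
    g = net.graph.copy()
    g.graph["activity"] = net.activity
    g.graph["min_sightings_threshold"] = net.min_sightings_threshold
    g.graph["n_sightings_used"] = net.n_sightings_used
    nx.write_graphml(g, path)


def read_graphml(path: "str | Path") -> ActivityNetwork:
    g = nx.read_graphml(path)
    return ActivityNetwork(
        graph=g,
        activity=g.graph["activity"],
        min_sightings_threshold=int(g.graph["min_sightings_threshold"]),
        n_sightings_used=int(g.graph["n_sightings_used"]),
    )
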