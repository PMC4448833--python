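"""Pairwise Mann-Whitney U comparisons of group sizes between activities.

Group size distributions differ between behavioural states (socializing in
large groups, foraging in small ones); the two-sided Mann-Whitney U test
compares each pair of activity classes, the "overall" class using every
sighting.  The exact null distribution is used for small samples without
ties; otherwise the normal approximation with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .metrics import group_size_stats
from .sightings import Activity, ALL, SightingTable

__all__ = ["PairwiseGroupSizeTest", "mann_whitney_group_sizes"]

_EXACT_MAX_N = 8


@dataclass(frozen=True)
class PairwiseGroupSizeTest:
    pair: tuple[str, str]
    u: float
    p_two_sided: float
    n1: int
    n2: int
    method: str

    def as_dict(self) -> dict:
        return {
            "pair": list(self.pair),
            "U": self.u,
            "p_two_sided": self.p_two_sided,
            "n1": self.n1,
            "n2": self.n2,
            "method": self.method,
        }


def mann_whitney_group_sizes(
    table: SightingTable,
    a: "Activity | str" = ALL,
    b: "Activity | str" = ALL,
) -> PairwiseGroupSizeTest:
    """Two-sided Mann-Whitney U test on per-sighting group sizes.

    The reported U is the statistic for the first sample, so
    U(a, b) + U(b, a) = n1 * n2.
    """
    sizes_a = group_size_stats(table, a).sizes
    sizes_b = group_size_stats(table, b).sizes
    has_ties = len(set(sizes_a) | set(sizes_b)) < len(sizes_a) + len(sizes_b)
    exact = min(len(sizes_a), len(sizes_b)) <= _EXACT_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(
        sizes_a, sizes_b, alternative="two-sided", method=method
    )
    name_a = a if isinstance(a, str) else a.value
    name_b = b if isinstance(b, str) else b.value
    return PairwiseGroupSizeTest(
        pair=(name_a, name_b),
        u=float(res.statistic),
        p_two_sided=float(res.pvalue),
        n1=len(sizes_a),
        n2=len(sizes_b),
        method=method,
    )
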