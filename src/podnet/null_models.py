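"""Resampling null models for association data and network metrics.

Two nulls are implemented:

1. **Data-stream permutation test** for preferential association
   (Bejder-style).  The sightings of one activity form a binary
   group-by-individual incidence matrix.  A Markov chain of matrices with
   identical margins (group sizes and individual sighting frequencies) is
   generated by checkerboard swaps: pick two occupied cells (g, i), (h, j)
   with A[g, j] = A[h, i] = 0 and flip the 2x2 submatrix.  Invalid
   proposals leave the chain in place (still counting as a step), which
   keeps the stationary distribution uniform over the margin-fixed
   ensemble.  After each recorded step the mean, SD and CV of the HWI
   values over all retained dyads (zeros included) are compared with the
   observed values; an elevated observed SD/CV signals preferred and
   avoided companionships.

   The chain layout is the serial scheme of Besag & Clifford: the observed
   matrix is embedded at a uniformly random position of a single chain
   path (run U <= n steps forward from the observed state, reset, run the
   remaining n - U), so that under the null the observed statistic and the
   n sampled ones are exchangeable and the rank p-value is exactly valid
   at any chain length — a plain burn-in chain is markedly anticonservative
   at short lengths because it underestimates the null spread.

2. **Edge-rearrangement randomization** for network metrics.  Random
   networks are generated from the observed one by degree-preserving
   double-edge swaps followed by random reassignment of the observed HWI
   weight multiset to the rewired edges.  Metrics this null conserves by
   construction (average degree; average edge weight; hence average
   strength) yield degenerate null distributions, which are flagged
   instead of being given meaningless p-values.

Statistics use denominators fixed by the margins: for a dyad (i, j),
HWI = X_ij / ((n_i + n_j)/2), so the chain only needs to track the
co-occurrence matrix X, which a swap changes in two rows/columns only —
each chain step is O(N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np

from .association import ActivityNetwork
from .sightings import Activity, ALL, SightingTable, select_records

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationTestResult",
    "RandomizationTestResult",
    "incidence_matrix",
    "permute_group_memberships",
    "edge_rearrangement_null",
    "NULL_METRICS",
]


def incidence_matrix(
    table: SightingTable, activity: "Activity | str | None" = ALL
) -> tuple[np.ndarray, list[str]]:
    """Binary group-by-individual matrix A (groups x individuals) and the
    sorted individual IDs labelling the columns."""
    records = select_records(table, activity)
    if not records:
        raise ValueError(f"no records with activity {activity!r}")
    ids = sorted(set().union(*(r.members for r in records)))
    index = {ind: j for j, ind in enumerate(ids)}
    a = np.zeros((len(records), len(ids)), dtype=np.int8)
    for g, rec in enumerate(records):
        for ind in rec.members:
            a[g, index[ind]] = 1
    return a, ids


@dataclass(frozen=True)
class PermutationTestResult:
    """Observed vs. permuted HWI summary statistics.

    Tail p-values are rank-based: (#{samples at or beyond the observed} + 1)
    / (n_permutations + 1), the observed statistic counting as a member of
    its own null set; ties count in both tails, so p_low + p_high >= 1.
    A small p_mean_low with an elevated observed SD/CV is the signature of
    preferential association.
    """

    activity: str
    n_permutations: int
    n_individuals_retained: int
    real_mean: float
    real_sd: float
    real_cv: float
    null_mean: float
    null_sd: float
    null_cv: float
    p_mean_low: float
    p_mean_high: float
    p_sd_high: float
    p_cv_high: float
    p_sd_low: float
    p_cv_low: float
    seed: int
    swaps_per_step: int
    burn_in: int
    scheme: str = "serial"
    samples: "np.ndarray | None" = field(default=None, repr=False, compare=False)

    def as_dict(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "activity", "n_permutations", "n_individuals_retained",
                "real_mean", "real_sd", "real_cv",
                "null_mean", "null_sd", "null_cv",
                "p_mean_low", "p_mean_high", "p_sd_high", "p_cv_high",
                "p_sd_low", "p_cv_low", "seed", "swaps_per_step", "burn_in",
                "scheme",
            )
        }
        return out


def permute_group_memberships(
    table: SightingTable,
    activity: "Activity | str | None" = ALL,
    min_sightings: int = 3,
    n_permutations: int = 200_000,
    swaps_per_step: int = 1,
    burn_in: int = 1000,
    seed: int = 0,
    scheme: str = "serial",
    keep_samples: bool = False,
    _check_every: int = 1000,
) -> PermutationTestResult:
    """Data-stream permutation test for preferential association.

    Statistics (mean, SD, CV of HWI) are computed over *all* dyads among
    individuals retained at ``min_sightings`` — zero-HWI dyads included.
    One sample is recorded per ``swaps_per_step`` attempted swaps.

    ``scheme='serial'`` (default) embeds the observed matrix at a uniform
    random position of the chain path (exactly valid rank p-values at any
    chain length; ``burn_in`` is ignored).  ``scheme='cumulative'`` is the
    classical layout: discard ``burn_in`` attempted swaps from the observed
    start, then record — approximate unless the chain is long enough to
    mix.  Margins are verified every ``_check_every`` recorded samples.
    Bit-reproducible for a fixed seed.
    """
    if scheme not in ("serial", "cumulative"):
        raise ValueError(f"unknown scheme {scheme!r}")
    a, ids = incidence_matrix(table, activity)
    n_groups, n_ind = a.shape
    if n_groups < 2 or n_ind < 3:
        raise ValueError(
            f"need >= 2 groups and >= 3 individuals, got {n_groups} x {n_ind}"
        )
    n = a.sum(axis=0).astype(np.int64)  # per-individual sighting counts (fixed)
    retained = np.flatnonzero(n >= min_sightings)
    if retained.size < 2:
        raise ValueError("fewer than 2 individuals retained at this threshold")

    x = (a.T.astype(np.int64) @ a.astype(np.int64))  # co-occurrence counts
    denom = 0.5 * (n[:, None] + n[None, :])  # fixed HWI denominators
    r_mask = np.zeros(n_ind, dtype=bool)
    r_mask[retained] = True
    iu = np.triu_indices(retained.size, k=1)
    m_dyads = iu[0].size

    def exact_sums() -> tuple[float, float]:
        h = x[np.ix_(retained, retained)][iu] / denom[np.ix_(retained, retained)][iu]
        return float(h.sum()), float((h * h).sum())

    def stats(s1: float, s2: float) -> tuple[float, float, float]:
        mean = s1 / m_dyads
        var = max((s2 - m_dyads * mean * mean) / (m_dyads - 1), 0.0) if m_dyads > 1 else 0.0
        sd = var ** 0.5
        cv = sd / mean if mean > 0 else float("nan")
        return mean, sd, cv

    s1, s2 = exact_sums()
    real_mean, real_sd, real_cv = stats(s1, s2)

    # chain state: coordinates of occupied cells
    rows, cols = np.nonzero(a)
    rows = rows.astype(np.int64)
    cols = cols.astype(np.int64)
    n_ones = rows.size
    # a checkerboard swap exists iff some pair of columns is incomparable
    # (each has a 1 in a row where the other has a 0)
    only = a.T.astype(np.int64) @ (1 - a.astype(np.int64))
    if not np.any(only * only.T):
        raise RuntimeError(
            f"no valid checkerboard swap exists for this {n_groups} x {n_ind} "
            "incidence matrix (all column supports are nested)"
        )
    row_sums0 = a.sum(axis=1).copy()

    rng = np.random.default_rng(seed)
    a = a.copy()
    state0 = (a.copy(), x.copy(), rows.copy(), cols.copy(), s1, s2)

    consecutive_failures = 0
    max_failures = max(100_000, 1000 * n_ones)

    def attempt_swap() -> None:
        nonlocal s1, s2, consecutive_failures
        k1, k2 = rng.integers(0, n_ones, size=2)
        g, i = rows[k1], cols[k1]
        h, j = rows[k2], cols[k2]
        if g == h or i == j or a[g, j] or a[h, i]:
            consecutive_failures += 1
            if consecutive_failures >= max_failures:
                raise RuntimeError(
                    f"no valid checkerboard swap found in {max_failures} proposals "
                    f"for incidence matrix of shape {n_groups} x {n_ind}"
                )
            return
        consecutive_failures = 0
        # column i leaves group g and joins h; column j does the converse
        d = a[h, :].astype(np.int64) - a[g, :].astype(np.int64)
        d[i] = 0
        d[j] = 0
        for col, sign in ((i, 1), (j, -1)):
            if r_mask[col]:
                ks = np.flatnonzero((d != 0) & r_mask)
                ks = ks[ks != col]
                if ks.size:
                    old = x[col, ks] / denom[col, ks]
                    new = (x[col, ks] + sign * d[ks]) / denom[col, ks]
                    s1 += float(new.sum() - old.sum())
                    s2 += float((new * new).sum() - (old * old).sum())
        x[i, :] += d
        x[:, i] += d
        x[j, :] -= d
        x[:, j] -= d
        a[g, i] = 0
        a[h, i] = 1
        a[h, j] = 0
        a[g, j] = 1
        rows[k1], cols[k1] = g, j
        rows[k2], cols[k2] = h, i

    def reset_to_observed() -> None:
        nonlocal s1, s2
        a[:], x[:] = state0[0], state0[1]
        rows[:], cols[:] = state0[2], state0[3]
        s1, s2 = state0[4], state0[5]

    samples = np.empty((n_permutations, 3))
    t = 0

    def record_steps(count: int) -> None:
        nonlocal t, s1, s2
        for _ in range(count):
            for _ in range(swaps_per_step):
                attempt_swap()
            samples[t] = stats(s1, s2)
            t += 1
            if t % _check_every == 0:
                if not (
                    np.array_equal(a.sum(axis=0), n)
                    and np.array_equal(a.sum(axis=1), row_sums0)
                ):
                    raise AssertionError("incidence-matrix margins were not conserved")
                s1, s2 = exact_sums()  # resync float accumulators

    if scheme == "serial":
        u = int(rng.integers(0, n_permutations + 1))
        record_steps(u)
        reset_to_observed()
        record_steps(n_permutations - u)
    else:
        for _ in range(burn_in):
            attempt_swap()
        record_steps(n_permutations)

    means, sds, cvs = samples[:, 0], samples[:, 1], samples[:, 2]

    def p_tail(values: np.ndarray, observed: float, high: bool) -> float:
        count = int(np.sum(values >= observed if high else values <= observed))
        return (count + 1) / (n_permutations + 1)
    return PermutationTestResult(
        activity=(activity if isinstance(activity, str) else activity.value) or ALL,
        n_permutations=n_permutations,
        n_individuals_retained=int(retained.size),
        real_mean=real_mean,
        real_sd=real_sd,
        real_cv=real_cv,
        null_mean=float(means.mean()),
        null_sd=float(sds.mean()),
        null_cv=float(cvs.mean()),
        p_mean_low=p_tail(means, real_mean, high=False),
        p_mean_high=p_tail(means, real_mean, high=True),
        p_sd_high=p_tail(sds, real_sd, high=True),
        p_sd_low=p_tail(sds, real_sd, high=False),
        p_cv_high=p_tail(cvs, real_cv, high=True),
        p_cv_low=p_tail(cvs, real_cv, high=False),
        seed=seed,
        swaps_per_step=swaps_per_step,
        burn_in=burn_in,
        scheme=scheme,
        samples=samples if keep_samples else None,
    )


# --- edge-rearrangement randomization --------------------------------------

def _metric_wrappers() -> Mapping[str, Callable[[ActivityNetwork], float]]:
    from . import communities as comm
    from . import metrics as met

    def n_communities(net: ActivityNetwork) -> float:
        return float(comm.walktrap_partition(net).n_communities)

    def average_community_size(net: ActivityNetwork) -> float:
        return comm.walktrap_partition(net).average_community_size

    return {
        "average_degree": met.average_degree,
        "average_strength": met.average_strength,
        "average_edge_weight": met.average_edge_weight,
        "n_connected_components": lambda net: float(met.connected_components(net)),
        "average_clustering": met.average_clustering,
        "n_communities": n_communities,
        "average_community_size": average_community_size,
    }


NULL_METRICS: tuple[str, ...] = tuple(_metric_wrappers().keys())


@dataclass(frozen=True)
class RandomizationTestResult:
    """Observed metric vs. its edge-rearrangement null ensemble.

    ``degenerate`` marks metrics the null conserves exactly (constant null
    distribution); no p-value is reported for those.  Otherwise
    p = 2 * min(#{null >= obs} + 1, #{null <= obs} + 1) / (n_random + 1),
    capped at 1 (the observed network counts as a member of its own null
    ensemble, so p >= 1/(n_random + 1)).
    """

    metric_name: str
    observed: float
    n_random: int
    null_mean: float
    null_sd: float
    null_quantiles: Mapping[str, float]
    p_two_tailed: "float | None"
    degenerate: bool
    significance_level: float
    seed: int

    def as_dict(self) -> dict:
        return {
            "metric_name": self.metric_name,
            "observed": self.observed,
            "n_random": self.n_random,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "null_quantiles": dict(self.null_quantiles),
            "p_two_tailed": self.p_two_tailed,
            "degenerate": self.degenerate,
            "significance_level": self.significance_level,
            "seed": self.seed,
        }


def rewire_preserving_degrees(
    net: ActivityNetwork, swaps_per_edge: int = 1, seed: "int | np.random.Generator" = 0
) -> ActivityNetwork:
    """One random network: double-edge-swap rewiring + weight reshuffle.

    Preserves every vertex's degree and the multiset of HWI edge weights.
    """
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    g.add_nodes_from(net.graph.nodes(data=True))
    g.add_edges_from(net.graph.edges)
    m = g.number_of_edges()
    if m >= 2 and g.number_of_nodes() >= 4:
        nx.double_edge_swap(
            g,
            nswap=swaps_per_edge * m,
            max_tries=100 * swaps_per_edge * m,
            seed=int(rng.integers(2**31)),
        )
    weights = np.array(net.edge_weights())
    rng.shuffle(weights)
    for w, (u, v) in zip(weights, sorted(tuple(sorted(e)) for e in g.edges)):
        g.edges[u, v]["weight"] = float(w)
    return ActivityNetwork(
        graph=g,
        activity=net.activity,
        min_sightings_threshold=net.min_sightings_threshold,
        n_sightings_used=net.n_sightings_used,
    )


def edge_rearrangement_null(
    net: ActivityNetwork,
    metrics: Sequence[str],
    n_random: int = 10_000,
    swaps_per_edge: int = 1,
    seed: int = 0,
    significance_level: float = 0.003,
) -> list[RandomizationTestResult]:
    """Randomization test of network metrics against rewired ensembles."""
    wrappers = _metric_wrappers()
    unknown = [m for m in metrics if m not in wrappers]
    if unknown:
        raise ValueError(
            f"unknown metric(s) {unknown}; valid names: {sorted(wrappers)}"
        )
    if net.n_edges < 2:
        raise ValueError("need at least 2 edges for edge rearrangement")
    rng = np.random.default_rng(seed)
    observed = {m: float(wrappers[m](net)) for m in metrics}
    null_values = {m: np.empty(n_random) for m in metrics}
    for r in range(n_random):
        random_net = rewire_preserving_degrees(
            net, swaps_per_edge=swaps_per_edge, seed=rng
        )
        for m in metrics:
            null_values[m][r] = wrappers[m](random_net)

    results = []
    for m in metrics:
        nulls = null_values[m]
        # conserved metrics vary only by float summation order
        spread = float(nulls.max() - nulls.min())
        scale = max(1.0, float(np.abs(nulls).max()), abs(observed[m]))
        degenerate = bool(
            spread <= 1e-9 * scale and abs(observed[m] - nulls[0]) <= 1e-9 * scale
        )
        if degenerate:
            p = None
            logger.info(
                "metric %r is conserved by the edge-rearrangement null; "
                "not testable under this null", m,
            )
        else:
            ge = int(np.sum(nulls >= observed[m])) + 1
            le = int(np.sum(nulls <= observed[m])) + 1
            p = min(2.0 * min(ge, le) / (n_random + 1), 1.0)
        q = np.quantile(nulls, [0.025, 0.5, 0.975])
        results.append(
            RandomizationTestResult(
                metric_name=m,
                observed=observed[m],
                n_random=n_random,
                null_mean=float(nulls.mean()),
                null_sd=float(nulls.std(ddof=1)) if n_random > 1 else 0.0,
                null_quantiles={"q025": float(q[0]), "q50": float(q[1]), "q975": float(q[2])},
                p_two_tailed=p,
                degenerate=degenerate,
                significance_level=significance_level,
                seed=seed,
            )
        )
    return results
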