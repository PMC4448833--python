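"""Permutation and edge-rearrangement null models."""

import itertools

import networkx as nx
import numpy as np
import pytest

from podnet import (
    SightingTable,
    SimulationConfig,
    build_activity_network,
    edge_rearrangement_null,
    filter_dependent_calves,
    filter_resights,
    incidence_matrix,
    permute_group_memberships,
    simulate_study,
)
from podnet.association import ActivityNetwork
from podnet.null_models import rewire_preserving_degrees

from conftest import rec


def hwi_stats_oracle(a, min_sightings=1):
    """Direct mean/SD/CV of HWI over all retained dyads of an incidence matrix."""
    n = a.sum(axis=0)
    keep = np.flatnonzero(n >= min_sightings)
    vals = []
    for i, j in itertools.combinations(keep, 2):
        x = int(np.sum(a[:, i] & a[:, j]))
        vals.append(x / (0.5 * (n[i] + n[j])))
    vals = np.array(vals)
    mean = vals.mean()
    sd = vals.std(ddof=1)
    return mean, sd, sd / mean


class TestPermutationChain:
    def test_chain_visits_exactly_the_margin_preserving_ensemble(self):
        """For a 3x3 incidence matrix, the sampled statistics cover exactly
        the statistic values of the brute-force set of all 0/1 matrices
        with the same margins, with roughly uniform frequencies."""
        table = SightingTable(
            (rec("s1", 1, "09:00", "AB"), rec("s2", 2, "09:00", "BC"),
             rec("s3", 3, "09:00", "AC"))
        )
        a, ids = incidence_matrix(table, "all")
        rows, cols = a.sum(axis=1), a.sum(axis=0)
        ensemble = []
        for bits in itertools.product([0, 1], repeat=9):
            m = np.array(bits, dtype=np.int8).reshape(3, 3)
            if np.array_equal(m.sum(axis=1), rows) and np.array_equal(m.sum(axis=0), cols):
                ensemble.append(m)
        expected_stats = {
            tuple(np.round(hwi_stats_oracle(m), 9)) for m in ensemble
        }
        assert len(ensemble) == 6  # complements of 3x3 permutation matrices

        res = permute_group_memberships(
            table, "all", min_sightings=1, n_permutations=6000, seed=3,
            keep_samples=True,
        )
        sampled = {tuple(np.round(s, 9)) for s in res.samples}
        assert sampled == expected_stats
        # frequencies near uniform over the (possibly tied) statistic values
        counts = {}
        for s in res.samples:
            counts[tuple(np.round(s, 9))] = counts.get(tuple(np.round(s, 9)), 0) + 1
        freqs = np.array(list(counts.values())) / res.n_permutations
        assert freqs.max() / freqs.min() < 3.0

    def test_real_statistics_match_direct_oracle(self):
        _, _, table = simulate_study(SimulationConfig(seed=2, n_days=30))
        a, _ = incidence_matrix(table, "all")
        mean, sd, cv = hwi_stats_oracle(a, min_sightings=2)
        res = permute_group_memberships(table, "all", 2, n_permutations=50, seed=0)
        assert res.real_mean == pytest.approx(mean)
        assert res.real_sd == pytest.approx(sd)
        assert res.real_cv == pytest.approx(cv)

    def test_margins_checked_every_step_without_error(self):
        _, _, table = simulate_study(SimulationConfig(seed=4, n_days=20))
        permute_group_memberships(
            table, "all", 1, n_permutations=300, seed=1, _check_every=1
        )

    def test_seeded_runs_bit_reproducible(self):
        _, _, table = simulate_study(SimulationConfig(seed=5, n_days=20))
        r1 = permute_group_memberships(table, "all", 2, n_permutations=400, seed=9)
        r2 = permute_group_memberships(table, "all", 2, n_permutations=400, seed=9)
        assert r1 == r2

    def test_different_seeds_agree_statistically(self):
        _, _, table = simulate_study(SimulationConfig(seed=6, n_days=40))
        runs = [
            permute_group_memberships(table, "all", 2, n_permutations=1000, seed=s,
                                      keep_samples=True)
            for s in (1, 2)
        ]
        m1, m2 = (r.samples[:, 0] for r in runs)
        pooled_se = np.hypot(m1.std(ddof=1), m2.std(ddof=1))
        assert abs(m1.mean() - m2.mean()) < 5 * pooled_se

    def test_tail_pairs_overlap(self):
        _, _, table = simulate_study(SimulationConfig(seed=7, n_days=20))
        r = permute_group_memberships(table, "all", 2, n_permutations=200, seed=2)
        assert r.p_mean_low + r.p_mean_high >= 1.0
        assert r.p_cv_low + r.p_cv_high >= 1.0
        assert r.real_cv == pytest.approx(r.real_sd / r.real_mean)

    def test_planted_companionship_detected(self):
        """Individuals forced into the same groups (two inseparable pairs
        joining alternate groups) inflate the observed CV far beyond the
        permuted null."""
        detections = 0
        pairs = [{"PA1", "PA2"}, {"PB1", "PB2"}]
        for trial in range(20):
            rng = np.random.default_rng(trial)
            records = []
            pool = [f"I{k}" for k in range(12)]
            for k in range(48):
                members = set(rng.choice(pool, size=3, replace=False))
                if k % 2 == 0:
                    members |= pairs[(k // 2) % 2]
                records.append(rec(f"s{k}", k % 28 + 1, "09:00", members))
            table = SightingTable(tuple(records))
            res = permute_group_memberships(
                table, "all", 1, n_permutations=500, seed=100 + trial
            )
            detections += res.p_cv_high < 0.05
        assert detections >= 18

    def test_degenerate_matrix_rejected(self):
        # every individual in every group: no checkerboard swap exists
        table = SightingTable(
            (rec("s1", 1, "09:00", "ABC"), rec("s2", 2, "09:00", "ABC"))
        )
        with pytest.raises(RuntimeError, match="no valid checkerboard swap"):
            permute_group_memberships(table, "all", 1, n_permutations=10, seed=0)

    def test_too_small_input_rejected(self):
        table = SightingTable((rec("s1", 1, "09:00", "AB"),))
        with pytest.raises(ValueError, match="groups"):
            permute_group_memberships(table, "all", 1, n_permutations=10, seed=0)


def planted_two_clique_network():
    g = nx.Graph()
    rng = np.random.default_rng(1)
    for base in (0, 6):
        for i, j in itertools.combinations(range(6), 2):
            g.add_edge(f"v{base + i}", f"v{base + j}", weight=float(rng.uniform(0.4, 0.9)))
    g.add_edge("v0", "v6", weight=0.2)
    return ActivityNetwork(g, "all", 1, 0)


class TestEdgeRearrangement:
    def test_rewiring_conserves_degrees_and_weight_multiset(self):
        net = planted_two_clique_network()
        deg0 = sorted(d for _, d in net.graph.degree)
        w0 = sorted(net.edge_weights())
        for s in range(50):
            rnd = rewire_preserving_degrees(net, seed=s)
            assert sorted(d for _, d in rnd.graph.degree) == deg0
            assert sorted(rnd.edge_weights()) == w0

    def test_conserved_metrics_flagged_degenerate(self):
        net = planted_two_clique_network()
        results = edge_rearrangement_null(
            net, ["average_degree", "average_strength", "average_edge_weight"],
            n_random=200, seed=2,
        )
        by_name = {r.metric_name: r for r in results}
        for name in by_name:
            assert by_name[name].degenerate, name
            assert by_name[name].p_two_tailed is None

    def test_planted_cliques_have_extreme_clustering(self):
        net = planted_two_clique_network()
        (res,) = edge_rearrangement_null(
            net, ["average_clustering"], n_random=1000, seed=3
        )
        assert not res.degenerate
        assert res.p_two_tailed <= 0.01

    def test_p_value_floor(self):
        net = planted_two_clique_network()
        (res,) = edge_rearrangement_null(net, ["average_clustering"], n_random=99, seed=4)
        assert res.p_two_tailed >= 1 / 100

    def test_unknown_metric_lists_valid_names(self):
        net = planted_two_clique_network()
        with pytest.raises(ValueError, match="average_clustering"):
            edge_rearrangement_null(net, ["betweenness"], n_random=5, seed=0)

    def test_community_metrics_evaluable_under_null(self):
        net = planted_two_clique_network()
        results = edge_rearrangement_null(
            net, ["n_communities", "average_community_size"], n_random=50, seed=5
        )
        assert {r.metric_name for r in results} == {"n_communities", "average_community_size"}
        for r in results:
            assert np.isfinite(r.null_mean)

    def test_seeded_reproducibility(self):
        net = planted_two_clique_network()
        r1 = edge_rearrangement_null(net, ["average_clustering"], n_random=50, seed=7)
        r2 = edge_rearrangement_null(net, ["average_clustering"], n_random=50, seed=7)
        assert r1 == r2
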