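"""Half-weight index, dyadic counts, and network construction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from podnet import (
    SightingTable,
    build_activity_network,
    dyadic_counts,
    half_weight_index,
    threshold_scan,
)
from podnet.association import read_graphml, write_graphml

from conftest import rec


def brute_force_hwi(records, a, b):
    """Independent all-pairs enumeration oracle: raw scan of record sets."""
    x = sum(1 for m in records if a in m and b in m)
    ya = sum(1 for m in records if a in m and b not in m)
    yb = sum(1 for m in records if b in m and a not in m)
    denom = x + 0.5 * (ya + yb)
    return x / denom if denom else None


class TestHalfWeightIndex:
    @pytest.mark.parametrize(
        "x,ya,yb,expected",
        [
            (4, 0, 0, 1.0),  # always together
            (0, 5, 3, 0.0),  # never together
            (2, 1, 1, 2 / 3),
            (1, 1, 1, 0.5),
        ],
    )
    def test_known_values(self, x, ya, yb, expected):
        assert half_weight_index(x, ya, yb) == pytest.approx(expected)

    def test_undefined_dyad_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            half_weight_index(0, 0, 0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            half_weight_index(-1, 0, 1)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_bounded_and_one_iff_always_together(self, x, ya, yb):
        if x + ya + yb == 0:
            return
        h = half_weight_index(x, ya, yb)
        assert 0.0 <= h <= 1.0
        assert (h == 1.0) == (x > 0 and ya == 0 and yb == 0)


class TestDyadicCounts:
    def test_three_record_enumeration(self, three_record_table):
        counts = dyadic_counts(three_record_table, "all")
        assert counts.x("A", "B") == 1
        assert counts.ya("A", "B") == 1
        assert counts.yb("A", "B") == 1
        assert counts.hwi("A", "B") == pytest.approx(0.5)

    def test_repeated_identical_groups(self):
        table = SightingTable(tuple(rec(f"s{k}", k + 1, "09:00", "AB") for k in range(4)))
        counts = dyadic_counts(table)
        assert counts.x("A", "B") == 4
        assert counts.ya("A", "B") == counts.yb("A", "B") == 0
        assert counts.hwi("A", "B") == 1.0

    def test_never_cosighted_pair(self, three_record_table):
        assert dyadic_counts(three_record_table).x("B", "C") == 0

    def test_counts_symmetric(self, three_record_table):
        c = dyadic_counts(three_record_table)
        assert c.x("A", "B") == c.x("B", "A")
        assert c.ya("A", "B") == c.yb("B", "A")

    def test_no_matching_activity_rejected(self, three_record_table):
        with pytest.raises(ValueError, match="forage"):
            dyadic_counts(three_record_table, "forage")


class TestBuildNetwork:
    def test_hand_computed_edge_weight(self):
        table = SightingTable(
            (rec("s1", 1, "09:00", "AB"), rec("s2", 2, "09:00", "AB"), rec("s3", 3, "09:00", "A"))
        )
        net = build_activity_network(table, "all", min_sightings=1)
        assert net.vertices == ("A", "B")
        assert net.weight("A", "B") == pytest.approx(2 / (2 + 0.5 * 1))  # 0.8

    def test_pruning_removes_undersighted(self):
        table = SightingTable(
            (rec("s1", 1, "09:00", "AB"), rec("s2", 2, "09:00", "AB"), rec("s3", 3, "09:00", "A"))
        )
        net = build_activity_network(table, "all", min_sightings=3)
        assert net.vertices == ("A",)
        assert net.n_edges == 0

    def test_disjoint_memberships_give_edgeless_network(self):
        table = SightingTable((rec("s1", 1, "09:00", "A"), rec("s2", 2, "09:00", "B")))
        net = build_activity_network(table, "all", min_sightings=1)
        assert net.n_vertices == 2 and net.n_edges == 0

    def test_empty_after_pruning_rejected(self):
        table = SightingTable((rec("s1", 1, "09:00", "AB"),))
        with pytest.raises(ValueError, match=">= 5"):
            build_activity_network(table, "all", min_sightings=5)

    def test_graphml_round_trip(self, tmp_path, three_record_table):
        net = build_activity_network(three_record_table, "all", 1)
        write_graphml(net, tmp_path / "n.graphml")
        back = read_graphml(tmp_path / "n.graphml")
        assert back.vertices == net.vertices
        assert back.min_sightings_threshold == net.min_sightings_threshold
        for a, b in net.graph.edges:
            assert back.weight(a, b) == pytest.approx(net.weight(a, b))


def random_tables(n_tables, max_records=6, max_inds=5, seed=0):
    rng = np.random.default_rng(seed)
    inds = "ABCDE"[:max_inds]
    for t in range(n_tables):
        n_rec = int(rng.integers(1, max_records + 1))
        records = []
        for k in range(n_rec):
            size = int(rng.integers(1, max_inds + 1))
            members = set(rng.choice(list(inds), size=size, replace=False))
            records.append(rec(f"s{k}", k % 28 + 1, "09:00", members))
        yield SightingTable(tuple(records))


class TestOracleAndInvariances:
    def test_edge_weights_match_brute_force_enumeration(self):
        """Every edge of every small random table equals the raw-scan oracle."""
        for table in random_tables(100, seed=7):
            net = build_activity_network(table, "all", min_sightings=1)
            member_sets = [r.members for r in table]
            for a, b in itertools.combinations(net.vertices, 2):
                expected = brute_force_hwi(member_sets, a, b) or 0.0
                got = net.weight(a, b) if net.graph.has_edge(a, b) else 0.0
                assert got == expected

    def test_duplicating_every_sighting_leaves_weights_unchanged(self):
        for table in random_tables(20, seed=11):
            net1 = build_activity_network(table, "all", 1)
            dup = SightingTable(
                tuple(
                    rec(f"{r.sighting_id}.{i}", r.date.day, f"{9 + i}:00", r.members,
                        r.activity.value, r.n_unidentified)
                    for r in table
                    for i in range(3)
                )
            )
            net3 = build_activity_network(dup, "all", 1)
            for a, b in net1.graph.edges:
                assert net3.weight(a, b) == pytest.approx(net1.weight(a, b))

    def test_weights_unaffected_by_group_size_of_other_sightings(self):
        """Adding individuals to sightings containing neither a nor b leaves
        HWI(a, b) unchanged — association is insensitive to average group size."""
        base = SightingTable(
            (rec("s1", 1, "09:00", "AB"), rec("s2", 2, "09:00", "A"), rec("s3", 3, "09:00", "CD"))
        )
        padded = SightingTable(
            (rec("s1", 1, "09:00", "AB"), rec("s2", 2, "09:00", "A"),
             rec("s3", 3, "09:00", "CDE"))
        )
        w1 = build_activity_network(base, "all", 1).weight("A", "B")
        w2 = build_activity_network(padded, "all", 1).weight("A", "B")
        assert w1 == w2


@pytest.fixture(scope="module")
def scan():
    from podnet import SimulationConfig, simulate_study

    _, _, table = simulate_study(SimulationConfig(seed=21, n_days=40))
    return table, threshold_scan(table, "all", [1, 2, 3], n_permutations=300, seed=4)


class TestThresholdScan:

    def test_vertex_counts_non_increasing(self, scan):
        _, df = scan
        assert list(df["threshold"]) == [1, 2, 3]
        assert df["n_vertices"].is_monotonic_decreasing

    def test_first_row_matches_unpruned_network(self, scan):
        table, df = scan
        net = build_activity_network(table, "all", 1)
        assert df.loc[0, "n_vertices"] == net.n_vertices
        assert df.loc[0, "n_edges"] == net.n_edges

    def test_planted_structure_detected_at_threshold(self, scan):
        _, df = scan
        assert df.loc[df["threshold"] == 3, "cv_pvalue"].iloc[0] < 0.05

    def test_unsorted_thresholds_rejected(self, three_record_table):
        with pytest.raises(ValueError, match="ascending"):
            threshold_scan(three_record_table, "all", [3, 1])
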