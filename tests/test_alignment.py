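"""Presence aggregation, orthogonality events and recursive deconvolution."""

import itertools

import numpy as np
import pytest

from batchfix.alignment import (
    AlignmentEvent,
    BatchAlignment,
    EventCluster,
    aggregate_presence,
    cluster_events,
    deconvolute,
    detect_events,
    find_candidates,
    merge_features,
    nearest_pairing,
)
from batchfix.peak_table import FeatureKey

from conftest import make_presence, make_table


def _ref_batch(batch, feature_vals, n_ref=5):
    """Single-batch table with n_ref Ref samples; feature_vals maps
    (id, mz, rt) -> list of per-Ref values (np.nan = missing)."""
    feats = [k for k in feature_vals]
    samples = [(f"{batch}_r{j}", j + 1, "Ref") for j in range(n_ref)]
    x = np.column_stack([np.asarray(feature_vals[k], dtype=float) for k in feats])
    return make_table(batch, feats, samples, x)


class TestPresence:
    def test_missingness_flags_batch_absence(self):
        # feature A missing in 4 of 5 Refs of batch 3 (0.8 not > 0.8 would be
        # present; here 4/5 = 0.8 exactly -> present; 5/5 -> absent)
        key = ("A", 100.0, 50.0)
        t1 = _ref_batch("B1", {key: [1, 1, 1, 1, 1]})
        t2 = _ref_batch("B2", {key: [1, 1, 1, np.nan, 1]})
        t3 = _ref_batch("B3", {key: [np.nan] * 5})
        p = aggregate_presence([t1, t2, t3], basis="Ref", threshold=0.8)
        assert p.row("A").tolist() == [True, True, False]
        np.testing.assert_allclose(p.proportion_na[0], [0.0, 0.2, 1.0])

    def test_boundary_proportion_exactly_at_threshold_is_present(self):
        key = ("A", 100.0, 50.0)
        t1 = _ref_batch("B1", {key: [np.nan, np.nan, np.nan, np.nan, 1.0]})  # 0.8
        t2 = _ref_batch("B2", {key: [1, 1, 1, 1, 1]})
        p = aggregate_presence([t1, t2], threshold=0.8)
        assert p.row("A").tolist() == [True, True]

    def test_feature_absent_from_batch_table_has_proportion_one(self):
        a, b = ("A", 100.0, 50.0), ("B", 200.0, 60.0)
        t1 = _ref_batch("B1", {a: [1, 1, 1], b: [1, 1, 1]}, n_ref=3)
        t2 = _ref_batch("B2", {a: [1, 1, 1]}, n_ref=3)
        p = aggregate_presence([t1, t2])
        assert p.proportion_na[p.index_of("B"), 1] == 1.0
        assert p.row("B").tolist() == [True, False]

    def test_full_presence_row_sum_equals_n_batches(self):
        key = ("A", 100.0, 50.0)
        tables = [_ref_batch(f"B{i}", {key: [1, 1, 1]}, n_ref=3) for i in range(1, 4)]
        p = aggregate_presence(tables)
        assert p.present.sum(axis=1)[0] == 3

    def test_raising_threshold_never_removes_presence(self, rng):
        key_specs = {(f"F{i}", 100.0 + i, 50.0): rng.choice(
            [1.0, np.nan], size=6, p=[0.5, 0.5]
        ).tolist() for i in range(20)}
        tables = [
            _ref_batch("B1", key_specs, n_ref=6),
            _ref_batch("B2", {k: [1.0] * 6 for k in key_specs}, n_ref=6),
        ]
        low = aggregate_presence(tables, threshold=0.5)
        high = aggregate_presence(tables, threshold=0.9)
        # presence is monotone in the threshold: present at low => present at high
        assert np.all(high.present[low.present])

    def test_no_basis_samples_rejected(self):
        t1 = make_table("B1", [("A", 100.0, 50.0)], [("s1", 1, "QC")], [[1.0]])
        t2 = make_table("B2", [("A", 100.0, 50.0)], [("s2", 1, "Ref")], [[1.0]])
        with pytest.raises(ValueError, match="no Ref samples"):
            aggregate_presence([t1, t2], basis="Ref")


class TestCandidatesAndEvents:
    def test_partial_presence_is_candidate(self):
        p = make_presence({"A": [1, 1, 0], "B": [1, 1, 1], "C": [0, 0, 0]})
        assert [f.id for f in find_candidates(p)] == ["A"]

    def test_event_within_box_and_orthogonal(self):
        p = make_presence(
            {"A": [1, 1, 0], "B": [0, 0, 1]},
            coords={"A": (300.0, 100.0), "B": (300.001, 105.0)},
        )
        events = detect_events(find_candidates(p), p, mz_tol=0.002, rt_tol=15.0)
        assert len(events) == 1
        e = events[0]
        assert e.pair == ("A", "B")
        assert e.d_mz == pytest.approx(0.001)
        assert e.d_rt == pytest.approx(5.0)
        assert e.distance == pytest.approx(np.hypot(0.5, 5 / 15))

    def test_co_presence_in_a_batch_excludes_event(self):
        p = make_presence(
            {"A": [1, 1, 0], "B": [0, 1, 1]},
            coords={"A": (300.0, 100.0), "B": (300.0005, 101.0)},
        )
        assert detect_events(find_candidates(p), p) == []

    def test_mz_outside_box_excludes_event(self):
        p = make_presence(
            {"A": [1, 0], "B": [0, 1]},
            coords={"A": (300.0, 100.0), "B": (300.003, 100.0)},
        )
        assert detect_events(find_candidates(p), p, mz_tol=0.002) == []

    def test_rt_outside_box_excludes_event(self):
        p = make_presence(
            {"A": [1, 0], "B": [0, 1]},
            coords={"A": (300.0, 100.0), "B": (300.0, 120.0)},
        )
        assert detect_events(find_candidates(p), p, rt_tol=15.0) == []


def _event(a, b, d):
    return AlignmentEvent(a=a, b=b, d_mz=0.0, d_rt=0.0, distance=d)


class TestClustering:
    def test_shared_candidate_joins_cluster(self):
        clusters = cluster_events([_event("A", "B", 1), _event("B", "C", 1)])
        assert len(clusters) == 1
        assert clusters[0].members == {"A", "B", "C"}

    def test_disjoint_events_separate_clusters(self):
        clusters = cluster_events([_event("A", "B", 1), _event("C", "D", 1)])
        assert [sorted(c.members) for c in clusters] == [["A", "B"], ["C", "D"]]

    def test_no_events_no_clusters(self):
        assert cluster_events([]) == []


def oracle_partition(members, events, presence):
    """Exhaustive search over orthogonal partitions: maximise merges, then
    minimise total within-group event distance.  Tractable for <= 6 members."""
    members = sorted(members)
    dist = {frozenset(e.pair): e.distance for e in events}

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for sub in partitions(rest):
            for i in range(len(sub)):
                yield sub[:i] + [[first] + sub[i]] + sub[i + 1 :]
            yield [[first]] + sub

    def group_ok(g):
        if len(g) == 1:
            return True
        for a, b in itertools.combinations(g, 2):
            if not presence.orthogonal(a, b):
                return False
        # connectivity through events
        import networkx as nx

        gr = nx.Graph()
        gr.add_nodes_from(g)
        for a, b in itertools.combinations(g, 2):
            if frozenset({a, b}) in dist:
                gr.add_edge(a, b)
        return nx.is_connected(gr)

    best = None
    for part in partitions(members):
        if not all(group_ok(g) for g in part):
            continue
        merges = sum(len(g) - 1 for g in part)
        cost = sum(
            dist[frozenset({a, b})]
            for g in part
            for a, b in itertools.combinations(g, 2)
            if frozenset({a, b}) in dist
        )
        key = (-merges, cost)
        if best is None or key < best[0]:
            best = (key, part)
    return {frozenset(g) for g in best[1] if len(g) > 1}


class TestDeconvolution:
    def test_two_orthogonal_candidates_merge(self):
        p = make_presence({"A": [1, 0, 0], "B": [0, 1, 1]})
        cluster = EventCluster(frozenset({"A", "B"}), (_event("A", "B", 0.5),))
        assert deconvolute(cluster, p) == [frozenset({"A", "B"})]

    def test_three_mutually_orthogonal_merge_as_one(self):
        # brute-force enumeration confirms a single maximal orthogonal group
        p = make_presence({"A": [1, 0, 0], "B": [0, 1, 0], "C": [0, 0, 1]})
        events = (_event("A", "B", 0.4), _event("B", "C", 0.6))
        cluster = EventCluster(frozenset({"A", "B", "C"}), events)
        result = deconvolute(cluster, p)
        assert result == [frozenset({"A", "B", "C"})]
        assert oracle_partition(cluster.members, events, p) == set(result)

    def test_largest_distance_removed_leaves_unique_correspondence(self):
        p = make_presence({"A": [1, 0, 0], "B": [0, 1, 1], "C": [1, 0, 0]})
        events = (_event("A", "B", 0.3), _event("B", "C", 0.9))
        cluster = EventCluster(frozenset({"A", "B", "C"}), events)
        result = deconvolute(cluster, p)
        assert result == [frozenset({"A", "B"})]  # C left unresolved
        assert oracle_partition(cluster.members, events, p) == set(result)

    def test_ambiguous_quadruple_matches_exhaustive_oracle(self):
        # two co-eluting compounds each split across the same batch boundary
        p = make_presence(
            {"X1": [1, 1, 0], "X2": [0, 0, 1], "Y1": [1, 1, 0], "Y2": [0, 0, 1]}
        )
        events = (
            _event("X1", "X2", 0.12),
            _event("Y1", "Y2", 0.12),
            _event("X1", "Y2", 0.92),
            _event("X2", "Y1", 0.68),
        )
        cluster = EventCluster(frozenset({"X1", "X2", "Y1", "Y2"}), events)
        result = set(deconvolute(cluster, p))
        assert result == {frozenset({"X1", "X2"}), frozenset({"Y1", "Y2"})}
        assert result == oracle_partition(cluster.members, events, p)

    def test_random_geometric_quadruples_match_oracle(self, rng):
        # co-eluting split pairs with intra-pair offsets well inside the
        # cross-pair offsets: deconvolution must find the oracle partition
        for _ in range(25):
            mz0 = float(rng.uniform(100, 900))
            rt0 = float(rng.uniform(50, 800))
            dmz_cross = float(rng.uniform(0.0008, 0.0016))
            drt_cross = float(rng.uniform(5.0, 11.0))
            coords = {
                "X1": (mz0, rt0),
                "X2": (mz0 + 0.0002, rt0 + rng.uniform(0.2, 1.5)),
                "Y1": (mz0 + dmz_cross, rt0 + drt_cross),
                "Y2": (mz0 + dmz_cross + 0.0002, rt0 + drt_cross + rng.uniform(0.2, 1.5)),
            }
            p = make_presence(
                {"X1": [1, 1, 0], "X2": [0, 0, 1], "Y1": [1, 1, 0], "Y2": [0, 0, 1]},
                coords=coords,
            )
            events = detect_events(find_candidates(p), p)
            clusters = cluster_events(events)
            assert len(clusters) == 1
            result = set(deconvolute(clusters[0], p))
            assert result == oracle_partition(
                clusters[0].members, clusters[0].events, p
            )
            assert result == {frozenset({"X1", "X2"}), frozenset({"Y1", "Y2"})}

    def test_naive_nearest_pairing_is_a_plain_greedy(self):
        # the greedy foil simply takes the shortest remaining event, even a
        # cross-pair one; kept only as a comparison baseline
        p = make_presence(
            {"X1": [1, 1, 0], "X2": [0, 0, 1], "Y1": [1, 1, 0], "Y2": [0, 0, 1]}
        )
        events = (
            _event("X1", "Y2", 0.10),
            _event("X1", "X2", 0.30),
            _event("Y1", "Y2", 0.35),
            _event("X2", "Y1", 0.95),
        )
        cluster = EventCluster(frozenset({"X1", "X2", "Y1", "Y2"}), events)
        naive = set(nearest_pairing(cluster, p))
        assert frozenset({"X1", "Y2"}) in naive

    def test_tied_largest_distances_removed_together(self):
        p = make_presence(
            {"X1": [1, 1, 0], "X2": [0, 0, 1], "Y1": [1, 1, 0], "Y2": [0, 0, 1]}
        )
        events = (
            _event("X1", "X2", 0.12),
            _event("Y1", "Y2", 0.12),
            _event("X1", "Y2", 0.80),
            _event("X2", "Y1", 0.80),  # tie with previous
        )
        cluster = EventCluster(frozenset({"X1", "X2", "Y1", "Y2"}), events)
        assert set(deconvolute(cluster, p)) == {
            frozenset({"X1", "X2"}),
            frozenset({"Y1", "Y2"}),
        }


class TestMergeAndModel:
    def _split_tables(self):
        a, b, other = ("A", 300.0, 100.0), ("B", 300.001, 104.0), ("Z", 500.0, 200.0)
        vals = [10.0, 11.0, 12.0]
        t1 = _ref_batch("B1", {a: vals, other: vals}, n_ref=3)
        t2 = _ref_batch("B2", {a: vals, other: vals}, n_ref=3)
        t3 = _ref_batch("B3", {b: [20.0, 21.0, 22.0], other: vals}, n_ref=3)
        return [t1, t2, t3]

    def test_merge_takes_values_from_present_member(self):
        tables = self._split_tables()
        res = BatchAlignment(tables).fit()
        assert res.map.groups == (frozenset({"A", "B"}),)
        merged = res.apply()
        assert all(t.n_features == 2 for t in merged)
        mid = "A+B"
        np.testing.assert_allclose(
            merged[0].intensities[:, merged[0].feature_index(mid)], [10, 11, 12]
        )
        np.testing.assert_allclose(
            merged[2].intensities[:, merged[2].feature_index(mid)], [20, 21, 22]
        )

    def test_merged_key_is_presence_weighted_mean(self):
        tables = self._split_tables()
        res = BatchAlignment(tables).fit()
        key = res.map.merged_keys[0]
        # A present in 2 batches, B in 1 -> weights 2:1
        assert key.mz == pytest.approx((2 * 300.0 + 1 * 300.001) / 3)
        assert key.rt == pytest.approx((2 * 100.0 + 1 * 104.0) / 3)

    def test_empty_map_is_identity(self):
        tables = self._split_tables()
        from batchfix.alignment import AlignmentMap

        out = merge_features(tables, AlignmentMap(groups=(), unresolved=(), log=()))
        for before, after in zip(tables, out):
            assert after.equals(before)

    def test_feature_count_decreases_by_group_sizes(self, small_sim):
        tables, truth = small_sim
        res = BatchAlignment(tables).fit()
        merged = res.apply()
        union_before = {f for t in tables for f in t.feature_ids}
        union_after = {f for t in merged for f in t.feature_ids}
        assert len(union_after) == len(union_before) - res.map.n_merges

    def test_recovers_planted_splits(self, small_sim):
        tables, truth = small_sim
        res = BatchAlignment(tables).fit()
        assert set(res.map.groups) == set(truth.alias_groups)

    def test_idempotent_on_merged_output(self, small_sim):
        tables, truth = small_sim
        res = BatchAlignment(tables).fit()
        merged = res.apply()
        second = BatchAlignment(merged).fit()
        assert second.map.groups == ()

    def test_groups_never_co_present(self, small_sim):
        tables, truth = small_sim
        res = BatchAlignment(tables).fit()
        for g in res.map.groups:
            rows = np.array([res.presence.row(m) for m in g], dtype=int)
            assert np.all(rows.sum(axis=0) <= 1)

    def test_summary_mentions_counts(self, small_sim):
        tables, _ = small_sim
        res = BatchAlignment(tables).fit()
        s = res.summary()
        assert "Merged groups" in s and "candidates" in s.lower()
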