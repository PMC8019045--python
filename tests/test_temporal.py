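import datetime as dt
import itertools

import numpy as np
import pytest

from multisoc.association import association_matrix
from multisoc.temporal import (
    NetworkSnapshot,
    bootstrap_ci,
    clustering_coefficient,
    cosine_similarity,
    edge_density,
    node_degree,
    node_strength,
    select_window_size,
    stability_series,
    window_networks,
)

from conftest import matrix_from_square, scan


def snapshot_from_square(units, square, window=(dt.date(2018, 1, 1), dt.date(2018, 2, 1))):
    return NetworkSnapshot(window, matrix_from_square(units, square))


def snapshot_from_edges(units, edges):
    sq = np.zeros((len(units), len(units)))
    idx = {u: k for k, u in enumerate(units)}
    for (a, b), w in edges.items():
        sq[idx[a], idx[b]] = sq[idx[b], idx[a]] = w
    return snapshot_from_square(units, sq)


class TestWindowing:
    def test_study_span_yields_twenty_windows(self):
        scans = [scan("2017-08-28", "A", {"B"}), scan("2019-05-13", "B", {"A"})]
        series = window_networks(scans, window_days=31, shift_days=31)
        assert len(series) == 20

    def test_exact_single_window(self):
        scans = [scan("2018-01-01", "A", {"B"}), scan("2018-01-31", "A", {"B"})]
        series = window_networks(scans, window_days=31, shift_days=31)
        assert len(series) == 1
        assert series[0].window == (dt.date(2018, 1, 1), dt.date(2018, 2, 1))

    def test_overlapping_windows_count(self):
        # span 62 days, window 31, shift 15: floor((62-31)/15) + 1 = 3
        scans = [scan("2018-01-01", "A", {"B"}), scan("2018-03-03", "A", {"B"})]
        series = window_networks(scans, window_days=31, shift_days=15)
        assert len(series) == 3

    def test_windows_partition_scans_when_shift_equals_window(self):
        rng = np.random.default_rng(0)
        scans = [
            scan(dt.date(2018, 1, 1) + dt.timedelta(days=int(rng.integers(0, 93))), "A", {"B"})
            for _ in range(60)
        ]
        series = window_networks(scans, window_days=31, shift_days=31)
        per_window = sum(len(s.scans) for s in series)
        assert per_window <= len(scans)
        seen = set()
        for s in series:
            ids = {id(x) for x in s.scans}
            assert not ids & seen
            seen |= ids

    def test_span_shorter_than_window_raises(self):
        scans = [scan("2018-01-01", "A", {"B"})]
        with pytest.raises(ValueError):
            window_networks(scans, window_days=31)


class TestNodeAndNetworkMetrics:
    def test_star_center_degree_and_strength(self):
        snap = snapshot_from_edges(
            ["hub", "a", "b", "c"], {("hub", "a"): 0.5, ("hub", "b"): 0.5, ("hub", "c"): 0.5}
        )
        assert node_degree(snap, "hub") == 3
        assert node_strength(snap, "hub") == pytest.approx(1.5)
        assert node_degree(snap, "a") == 1
        assert node_strength(snap, "a") == pytest.approx(0.5)

    def test_isolated_unit(self):
        snap = snapshot_from_edges(["a", "b", "c"], {("a", "b"): 0.4})
        assert node_degree(snap, "c") == 0
        assert node_strength(snap, "c") == 0.0

    def test_unknown_unit_raises(self):
        snap = snapshot_from_edges(["a", "b"], {("a", "b"): 0.4})
        with pytest.raises(KeyError):
            node_degree(snap, "zz")

    def test_density_anchors(self):
        n = 4
        full = snapshot_from_square(list("abcd"), np.full((n, n), 0.5))
        empty = snapshot_from_square(list("abcd"), np.zeros((n, n)))
        assert edge_density(full) == 1.0
        assert edge_density(empty) == 0.0

    def test_density_arithmetic(self):
        # 13 units, 39 positive edges -> 39/78 = 0.5
        units = [f"u{k:02d}" for k in range(13)]
        pairs = list(itertools.combinations(units, 2))[:39]
        snap = snapshot_from_edges(units, {p: 0.2 for p in pairs})
        assert edge_density(snap) == pytest.approx(0.5)

    def test_transitivity_anchors(self):
        tri = snapshot_from_edges(["a", "b", "c"], {("a", "b"): 1, ("b", "c"): 1, ("a", "c"): 1})
        star = snapshot_from_edges(["h", "a", "b", "c"], {("h", "a"): 1, ("h", "b"): 1, ("h", "c"): 1})
        assert clustering_coefficient(tri) == 1.0
        assert clustering_coefficient(star) == 0.0

    def test_no_connected_triples_flagged(self):
        snap = snapshot_from_edges(["a", "b", "c", "d"], {("a", "b"): 0.3})
        assert np.isnan(clustering_coefficient(snap))

    def test_density_and_transitivity_match_enumeration_all_graphs(self):
        """Exhaustive oracle over every 4-node graph (64 graphs):
        density and transitivity equal brute-force enumeration."""
        units = list("abcd")
        pairs = list(itertools.combinations(units, 2))
        for bits in range(2 ** len(pairs)):
            edges = {p: 1.0 for k, p in enumerate(pairs) if bits >> k & 1}
            snap = snapshot_from_edges(units, edges)
            # brute force
            dens = len(edges) / len(pairs)
            triangles = sum(
                all(
                    (tuple(sorted(e)) in {tuple(sorted(p)) for p in edges})
                    for e in itertools.combinations(tri, 2)
                )
                for tri in itertools.combinations(units, 3)
            )
            triples = 0
            for u in units:
                d = sum(1 for p in edges if u in p)
                triples += d * (d - 1) // 2
            assert edge_density(snap) == pytest.approx(dens)
            got = clustering_coefficient(snap)
            if triples == 0:
                assert np.isnan(got)
            else:
                assert got == pytest.approx(3 * triangles / triples)


class TestCosineSimilarity:
    def test_identical_networks_give_one(self):
        snap = snapshot_from_edges(["a", "b", "c", "d"], {("a", "b"): 0.5, ("b", "c"): 0.2, ("a", "d"): 0.7})
        assert cosine_similarity(snap, snap) == pytest.approx(1.0)

    def test_disjoint_edge_sets_give_zero(self):
        s1 = snapshot_from_edges(["a", "b", "c", "d"], {("a", "b"): 1.0})
        s2 = snapshot_from_edges(["a", "b", "c", "d"], {("c", "d"): 1.0})
        assert cosine_similarity(s1, s2) == 0.0

    def test_hand_dot_product(self):
        s1 = snapshot_from_edges(["a", "b", "c", "d"], {("a", "b"): 1.0})
        s2 = snapshot_from_edges(["a", "b", "c", "d"], {("a", "b"): 1.0, ("c", "d"): 1.0})
        assert cosine_similarity(s1, s2) == pytest.approx(1 / np.sqrt(2))

    def test_empty_network_gives_zero(self):
        s1 = snapshot_from_edges(["a", "b"], {})
        s2 = snapshot_from_edges(["a", "b"], {("a", "b"): 0.5})
        assert cosine_similarity(s1, s2) == 0.0

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(4)
        sq = np.zeros((5, 5))
        sq[np.triu_indices(5, 1)] = rng.random(10)
        sq += sq.T
        s1 = snapshot_from_square(list("abcde"), sq)
        s2 = snapshot_from_square(list("abcde"), sq * 0.35)
        assert cosine_similarity(s1, s2) == pytest.approx(cosine_similarity(s2, s1))
        # proportional weights with identical support -> similarity 1
        assert cosine_similarity(s1, s2) == pytest.approx(1.0)

    def test_union_roster_padding_invariance(self):
        s1 = snapshot_from_edges(["a", "b"], {("a", "b"): 0.6})
        s2 = snapshot_from_edges(["a", "b", "x", "y"], {("a", "b"): 0.3})
        assert cosine_similarity(s1, s2) == pytest.approx(1.0)


class TestStability:
    def _series(self, snaps):
        from multisoc.temporal import NetworkSeries

        return NetworkSeries(snaps, 31, 31)

    def test_identical_snapshots_give_all_ones(self):
        snap = snapshot_from_edges(["a", "b", "c"], {("a", "b"): 0.5, ("b", "c"): 0.1})
        series = self._series([snap, snap, snap])
        assert stability_series(series, "lag1")[1:] == pytest.approx([1.0, 1.0])
        assert stability_series(series, "to_first") == pytest.approx([1.0, 1.0, 1.0])

    def test_to_first_starts_at_one(self):
        s1 = snapshot_from_edges(["a", "b", "c", "d"], {("a", "b"): 1.0})
        s2 = snapshot_from_edges(["a", "b", "c", "d"], {("c", "d"): 1.0})
        vals = stability_series(self._series([s1, s2]), "to_first")
        assert vals[0] == 1.0
        assert vals[1] == 0.0

    def test_alternating_disjoint_networks_lag1_zero(self):
        s1 = snapshot_from_edges(["a", "b", "c", "d"], {("a", "b"): 1.0})
        s2 = snapshot_from_edges(["a", "b", "c", "d"], {("c", "d"): 1.0})
        vals = stability_series(self._series([s1, s2, s1, s2]), "lag1")
        assert vals[1:] == pytest.approx([0.0, 0.0, 0.0])

    def test_single_snapshot_raises(self):
        snap = snapshot_from_edges(["a", "b"], {("a", "b"): 1.0})
        with pytest.raises(ValueError):
            stability_series(self._series([snap]), "lag1")


class TestBootstrapCI:
    def test_constant_statistic_zero_width(self):
        scans = [scan("2018-01-01", "A", {"B", "C"}, time=dt.time(7 + 2 * k, 0)) for k in range(5)]
        lo, hi = bootstrap_ci(scans, edge_density, n_boot=50, seed=1)
        assert lo == hi == 1.0

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(6)
        scans = []
        for k in range(40):
            focal = "ABCD"[k % 4]
            assoc = {u for u in "ABCD" if u != focal and rng.random() < 0.4}
            scans.append(scan(dt.date(2018, 1, 1) + dt.timedelta(days=k % 10), focal, assoc))
        ci1 = bootstrap_ci(scans, edge_density, n_boot=80, seed=5)
        ci2 = bootstrap_ci(scans, edge_density, n_boot=80, seed=5)
        assert ci1 == ci2
        assert ci1[0] <= ci1[1]

    def test_interval_covers_point_estimate_on_simulated_windows(self):
        from multisoc.simulate import EcologyConfig, null_society, simulate_ecology, simulate_scans

        hits = 0
        for seed in range(10):
            soc = null_society(seed, study_days=31)
            fruit, _, _ = simulate_ecology(EcologyConfig(), soc.months, rng=seed)
            scans = simulate_scans(soc, fruit, rng=seed)
            m = association_matrix(scans)
            observed = edge_density(NetworkSnapshot((soc.study_start, soc.study_start), m))
            lo, hi = bootstrap_ci(scans, edge_density, n_boot=60, seed=seed)
            hits += lo - 1e-9 <= observed <= hi + 1e-9
        assert hits >= 9


class TestSelectWindowSize:
    def test_single_candidate_returned_unchanged(self):
        scans = [scan(dt.date(2018, 1, 1) + dt.timedelta(days=k), "A", {"B"}) for k in range(62)]
        chosen, table = select_window_size(scans, [31], n_boot=10, seed=0)
        assert chosen == 31
        assert list(table["window_days"]) == [31]

    def test_cycle_resolving_candidate_preferred(self):
        """With a strong 60-day density cycle, the chosen window resolves
        the cycle (<= 60 days)."""
        rng = np.random.default_rng(9)
        units = ["A", "B", "C", "D", "E"]
        scans = []
        for day in range(360):
            date = dt.date(2018, 1, 1) + dt.timedelta(days=day)
            dense = (day // 30) % 2 == 0  # 60-day on/off cycle
            focal = units[day % 5]
            p = 0.8 if dense else 0.05
            for k in range(3):
                assoc = {u for u in units if u != focal and rng.random() < p}
                scans.append(scan(date, focal, assoc, time=dt.time(7 + 2 * k, 0)))
        chosen, table = select_window_size(scans, [15, 30, 120], n_boot=10, seed=0)
        assert chosen <= 60
        assert set(table.columns) >= {"window_days", "signal", "noise", "signal_noise"}

    def test_candidate_longer_than_span_raises(self):
        scans = [scan("2018-01-01", "A", {"B"}), scan("2018-01-20", "A", {"B"})]
        with pytest.raises(ValueError):
            select_window_size(scans, [15, 90], n_boot=5, seed=0)
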