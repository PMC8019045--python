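import datetime as dt

import numpy as np
import pytest

from multisoc.association import association_matrix, unit_presence
from multisoc.clustering import ClanPartition
from multisoc.permutation import (
    _SwapEngine,
    cv_statistic,
    data_stream_permute,
    null_density_band,
    preferred_association_test,
    within_partition_statistic,
)
from multisoc.simulate import (
    EcologyConfig,
    null_society,
    simulate_ecology,
    simulate_scans,
    strong_clan,
)

from conftest import matrix_from_square, scan


def sighting_counts(scans):
    counts = {}
    for s in scans:
        for u in unit_presence(s):
            counts[u] = counts.get(u, 0) + 1
    return counts


class TestCVStatistic:
    def test_equal_dyads_give_zero_cv(self):
        m = matrix_from_square(["a", "b", "c"], np.full((3, 3), 0.2))
        assert cv_statistic(m) == pytest.approx(0.0, abs=1e-12)

    def test_population_sd_convention(self):
        # dyads {0.1, 0.2, 0.3}: mean 0.2, population SD sqrt(2/300)
        square = [[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]]
        m = matrix_from_square(["a", "b", "c"], square)
        assert cv_statistic(m) == pytest.approx(np.sqrt(1 / 150) / 0.2)
        assert cv_statistic(m, ddof=1) == pytest.approx(0.1 / 0.2)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.random(6) * 0.5
        sq = np.zeros((4, 4))
        sq[np.triu_indices(4, 1)] = vals
        sq += sq.T
        m1 = matrix_from_square(list("abcd"), sq)
        m2 = matrix_from_square(list("abcd"), sq * 0.5)
        assert cv_statistic(m1) == pytest.approx(cv_statistic(m2))

    def test_zero_mean_rejected(self):
        m = matrix_from_square(["a", "b", "c"], np.zeros((3, 3)))
        with pytest.raises(ValueError):
            cv_statistic(m)


def _random_scans(rng, n_scans=20, n_units=5):
    units = [f"U{k}" for k in range(n_units)]
    scans = []
    for k in range(n_scans):
        focal = units[k % n_units]
        assoc = {u for u in units if u != focal and rng.random() < 0.4}
        scans.append(
            scan(dt.date(2018, 1, 1) + dt.timedelta(days=k // 4), focal, assoc,
                 time=dt.time(7 + 2 * (k % 4), 0))
        )
    return scans


class TestSwapConservation:
    def test_forced_single_swap_bookkeeping(self):
        # presence sets {A,B} and {C,D}: the only legal swaps exchange the
        # two associates, preserving sizes and sighting counts
        scans = [scan("2018-01-01", "A", {"B"}, time=dt.time(9, 0)),
                 scan("2018-01-01", "C", {"D"}, time=dt.time(11, 0))]
        engine = _SwapEngine(scans, constraint="day")
        rng = np.random.default_rng(0)
        before = sighting_counts(scans)
        assert engine.run(rng, 1)
        permuted = engine.materialize()
        assert sighting_counts(permuted) == before
        assert [unit_presence(s) for s in permuted] == [{"A", "D"}, {"C", "B"}]

    def test_identical_presence_sets_cannot_mix(self):
        scans = [scan("2018-01-01", "A", {"B"}, time=dt.time(h, 0)) for h in (7, 9, 11)]
        engine = _SwapEngine(scans, constraint="day")
        rng = np.random.default_rng(0)
        assert not engine.run(rng, 1, max_attempts_per_swap=200)

    def test_thousand_swaps_conserve_counts_and_sizes(self):
        """Counting oracle: unit sighting counts and per-scan group sizes
        are identical after 1,000 accepted swaps."""
        rng_data = np.random.default_rng(42)
        scans = _random_scans(rng_data)
        sizes_before = sorted(len(unit_presence(s)) for s in scans)
        counts_before = sighting_counts(scans)
        engine = _SwapEngine(scans, constraint="day")
        assert engine.run(np.random.default_rng(1), 1000)
        permuted = engine.materialize()
        assert sorted(len(unit_presence(s)) for s in permuted) == sizes_before
        assert sighting_counts(permuted) == counts_before
        # the incrementally maintained counts must match a rebuild
        rebuilt = association_matrix(permuted, units=engine.units)
        for i, a in enumerate(engine.units):
            for j in range(i + 1, len(engine.units)):
                assert engine.joint[i][j] == rebuilt.counts(a, engine.units[j]).n_joint

    def test_day_constraint_swaps_within_days_only(self):
        rng_data = np.random.default_rng(3)
        scans = _random_scans(rng_data)
        by_day_before = {}
        for s in scans:
            for u in unit_presence(s):
                by_day_before[(s.date, u)] = by_day_before.get((s.date, u), 0) + 1
        engine = _SwapEngine(scans, constraint="day")
        engine.run(np.random.default_rng(2), 500)
        by_day_after = {}
        for s in engine.materialize():
            for u in unit_presence(s):
                by_day_after[(s.date, u)] = by_day_after.get((s.date, u), 0) + 1
        assert by_day_after == by_day_before


class TestDataStreamPermute:
    def test_yields_requested_number_and_is_seeded(self):
        scans = _random_scans(np.random.default_rng(0))
        sets1 = [s for s in data_stream_permute(scans, 5, seed=9)]
        sets2 = [s for s in data_stream_permute(scans, 5, seed=9)]
        assert len(sets1) == 5
        assert sets1 == sets2

    def test_no_legal_swap_warns_and_yields_nothing(self):
        scans = [scan("2018-01-01", "A", {"B"})]
        with pytest.warns(UserWarning):
            assert list(data_stream_permute(scans, 3, seed=0)) == []


class TestPreferredAssociationTest:
    def test_pvalue_is_add_one_and_reproducible(self):
        scans = _random_scans(np.random.default_rng(5), n_scans=40)
        r1 = preferred_association_test(scans, n_permutations=200, seed=3)
        r2 = preferred_association_test(scans, n_permutations=200, seed=3)
        assert r1 == r2
        assert 1 / 201 <= r1.p_value <= 1.0
        k = round(r1.p_value * 201 - 1)
        assert abs(k + 1 - r1.p_value * 201) < 1e-9

    def test_strong_clan_data_rejects(self):
        soc = strong_clan(0, study_days=120)
        fruit, _, _ = simulate_ecology(EcologyConfig(), soc.months, rng=0)
        scans = simulate_scans(soc, fruit, rng=0)
        r = preferred_association_test(scans, n_permutations=500, seed=0)
        assert r.cv_obs > r.cv_rand_mean
        assert r.p_value <= 0.05

    def test_node_label_cv_is_invariant_so_p_is_one(self):
        """The CV depends only on the multiset of dyad values, so label
        permutation cannot move it: the scheme must report p = 1."""
        rng = np.random.default_rng(2)
        sq = np.zeros((5, 5))
        sq[np.triu_indices(5, 1)] = rng.random(10)
        sq += sq.T
        m = matrix_from_square(list("abcde"), sq)
        r = preferred_association_test(m, scheme="node_label", n_permutations=200, seed=1)
        assert r.p_value == 1.0
        assert r.cv_rand_mean == pytest.approx(r.cv_obs)

    def test_node_label_with_partition_statistic_agrees_with_data_stream(self):
        """Both schemes reject on strongly clan-structured data when each
        uses a statistic its null can move."""
        soc = strong_clan(1, study_days=120)
        fruit, _, _ = simulate_ecology(EcologyConfig(), soc.months, rng=1)
        scans = simulate_scans(soc, fruit, rng=1)
        m = association_matrix(scans)
        truth = ClanPartition(
            {u: ("C1" if u.startswith("A") else "C2") for u in m.units}, 0.05
        )
        r_node = preferred_association_test(
            m, scheme="node_label", n_permutations=500, seed=1,
            statistic=within_partition_statistic(truth),
        )
        r_stream = preferred_association_test(scans, n_permutations=300, seed=1)
        assert r_node.p_value <= 0.05
        assert r_stream.p_value <= 0.05

    def test_few_permutations_warns(self):
        scans = _random_scans(np.random.default_rng(8))
        with pytest.warns(UserWarning):
            preferred_association_test(scans, n_permutations=50, seed=0)


class TestNullDensityBand:
    def test_permutation_invariant_input_collapses_band(self):
        # all units always together: no legal swap, band = observed density
        scans = [scan("2018-01-01", "A", {"B", "C"}, time=dt.time(h, 0)) for h in (7, 9, 11)]
        band = null_density_band(scans, [(dt.date(2018, 1, 1), dt.date(2018, 1, 2))],
                                 n_permutations=50, seed=0)
        assert band.lower[0] == band.upper[0] == 1.0

    def test_sparse_window_band_undefined(self):
        scans = [scan("2018-01-01", "A", {"B"})]
        band = null_density_band(scans, [(dt.date(2018, 1, 1), dt.date(2018, 1, 2))],
                                 n_permutations=20, seed=0)
        assert np.isnan(band.lower[0]) and np.isnan(band.upper[0])

    def test_null_data_band_covers_observed_density(self):
        soc = null_society(0, study_days=31)
        fruit, _, _ = simulate_ecology(EcologyConfig(), soc.months, rng=0)
        scans = simulate_scans(soc, fruit, rng=0)
        window = (soc.study_start, soc.study_start + dt.timedelta(days=31))
        band = null_density_band(scans, [window], n_permutations=200, seed=0)
        engine = _SwapEngine([s for s in scans], constraint="day")
        observed = engine.edge_density()
        assert band.lower[0] - 1e-9 <= observed <= band.upper[0] + 1e-9
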