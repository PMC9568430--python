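import numpy as np
import pytest

from polyhub import synthetic_data as syn
from polyhub.core import ContactMatrix, ConvergenceError, GenomicInterval, IntervalSet
from polyhub.hic_aggregates import (
    apa,
    ata,
    expected_by_distance,
    ice_balance,
    observed_over_expected,
    pescan,
    polycomb_pair_aggregate,
)


def _random_symmetric(rng, n, low=1.0, high=10.0):
    m = rng.uniform(low, high, size=(n, n))
    return np.triu(m) + np.triu(m, 1).T


def _iv(chrom, pos, name=None):
    return GenomicInterval(chrom, pos, pos + 1, name=name)


class TestIceBalance:
    def test_marginals_equal_within_tolerance(self, rng):
        cm = ContactMatrix("chr1", 10_000, _random_symmetric(rng, 500))
        bal = ice_balance(cm, tol=1e-5)
        s = bal.counts[~bal.mask].sum(axis=1)
        assert np.abs(s / s.mean() - 1).max() <= 1e-5

    def test_row_rescaled_matrix_balances_to_same_result(self, rng):
        m = _random_symmetric(rng, 100)
        d = np.ones(100)
        d[17] = 2.0  # scale one row/col by 2 symmetrically
        scaled = m * np.outer(d, d)
        bal_a = ice_balance(ContactMatrix("chr1", 10_000, m), tol=1e-10, max_iter=2000)
        bal_b = ice_balance(
            ContactMatrix("chr1", 10_000, scaled), tol=1e-10, max_iter=2000
        )
        np.testing.assert_allclose(bal_a.counts, bal_b.counts, rtol=1e-5)

    def test_constant_off_diagonal_matrix_unchanged_up_to_scale(self):
        m = np.ones((20, 20))
        bal = ice_balance(ContactMatrix("chr1", 10_000, m))
        np.testing.assert_allclose(bal.counts / bal.counts[0, 0], m, rtol=1e-6)

    def test_empty_row_masked_others_balanced(self, rng):
        m = _random_symmetric(rng, 50)
        m[7, :] = 0.0
        m[:, 7] = 0.0
        bal = ice_balance(ContactMatrix("chr1", 10_000, m))
        assert bal.mask[7]
        s = bal.counts[~bal.mask].sum(axis=1)
        assert np.abs(s / s.mean() - 1).max() <= 1e-5

    def test_non_convergence_raises_with_residual(self, rng):
        cm = ContactMatrix("chr1", 10_000, _random_symmetric(rng, 50))
        with pytest.raises(ConvergenceError) as err:
            ice_balance(cm, tol=1e-12, max_iter=1)
        assert err.value.residual > 0


class TestExpectedByDistance:
    def test_pure_distance_function_reproduced_exactly(self):
        n = 30
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        m = 1.0 / (1.0 + d)
        cm = ContactMatrix("chr1", 10_000, m)
        expected = expected_by_distance(cm)
        np.testing.assert_allclose(expected, 1.0 / (1.0 + np.arange(n)))

    def test_oe_of_distance_function_is_all_ones(self):
        n = 25
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        cm = ContactMatrix("chr1", 10_000, 2.0 / (1.0 + d))
        np.testing.assert_allclose(observed_over_expected(cm), np.ones((n, n)))

    def test_matches_diagonal_mean_oracle(self, rng):
        m = _random_symmetric(rng, 20)
        cm = ContactMatrix("chr1", 10_000, m)
        expected = expected_by_distance(cm)
        for d in range(20):
            oracle = np.mean([m[i, i + d] for i in range(20 - d)])
            assert expected[d] == pytest.approx(oracle)


class TestApa:
    def test_constant_oe_gives_unit_map_and_score(self):
        n = 60
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        cm = ContactMatrix("chr1", 10_000, 5.0 / (1.0 + d))
        pairs = [(_iv("chr1", 105_000), _iv("chr1", 405_000))]
        amap = apa(cm, pairs, half_window=5)
        np.testing.assert_allclose(amap.matrix, 1.0, rtol=1e-9)
        assert amap.center_score() == pytest.approx(1.0)

    def test_matches_brute_force_per_pair_extraction(self, rng):
        """Vectorized path equals an independent double-loop implementation."""
        n = 50
        m = _random_symmetric(rng, n)
        cm = ContactMatrix("chr1", 10_000, m)
        w = 3
        pairs = [
            (_iv("chr1", 85_000), _iv("chr1", 305_000)),
            (_iv("chr1", 125_000), _iv("chr1", 405_000)),
            (_iv("chr1", 55_000), _iv("chr1", 255_000)),
        ]
        amap = apa(cm, pairs, half_window=w)
        # brute force: per-pair python loops over O/E pixels
        expected = expected_by_distance(cm)
        acc = np.zeros((2 * w + 1, 2 * w + 1))
        for a, b in pairs:
            bi, bj = a.midpoint // 10_000, b.midpoint // 10_000
            for x in range(-w, w + 1):
                for y in range(-w, w + 1):
                    i, j = bi + x, bj + y
                    acc[x + w, y + w] += m[i, j] / expected[abs(i - j)]
        np.testing.assert_allclose(amap.matrix, acc / len(pairs), rtol=1e-12)
        assert amap.n_pairs == len(pairs)

    def test_pair_too_close_to_diagonal_excluded(self, rng):
        n = 60
        cm = ContactMatrix("chr1", 10_000, _random_symmetric(rng, n))
        pairs = [
            (_iv("chr1", 105_000), _iv("chr1", 405_000)),
            (_iv("chr1", 105_000), _iv("chr1", 155_000)),  # 5 bins apart < 2w
        ]
        amap = apa(cm, pairs, half_window=5)
        assert amap.n_pairs == 1

    def test_no_usable_pairs_is_an_error(self, rng):
        cm = ContactMatrix("chr1", 10_000, _random_symmetric(rng, 30))
        with pytest.raises(ValueError):
            apa(cm, [(_iv("chr1", 5_000), _iv("chr1", 25_000))], half_window=10)

    def test_implanted_loop_enrichment_recovered(self, genome_hic):
        """Loops implanted at 3x recover a center score near 3."""
        truth = syn.default_truth(
            genome_hic, n_domains=4, n_tads=0, n_loops=30, n_hub_pairs=0,
            loop_sep=(500_000, 4_000_000), seed=3,
        )
        scores = []
        for seed in range(5):
            raw = syn.simulate_contact_matrix(
                genome_hic, truth, "WT", depth=16_000_000, seed=500 + seed
            )
            bal = {c: ice_balance(m) for c, m in raw.items()}
            scores.append(apa(bal, truth.loops).center_value())
        se = np.std(scores, ddof=1) / np.sqrt(len(scores))
        assert abs(np.mean(scores) - 3.0) < 3 * max(se, 0.02)


class TestAta:
    def _tad_matrix(self, n=200, t0=60, t1=100, enrich=4.0):
        d = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        m = 10.0 / (1.0 + d)
        m[t0:t1, t0:t1] *= enrich
        return ContactMatrix("chr1", 10_000, m)

    def test_uniform_tad_enrichment_recovered_in_center_block(self):
        # sparse TAD (4% of bins) so the block barely inflates its own
        # distance expectation and the O/E center recovers the enrichment
        cm = self._tad_matrix(n=1000, t0=300, t1=340)
        tads = IntervalSet.from_intervals(
            [GenomicInterval("chr1", 3_000_000, 3_400_000)]
        )
        amap = ata(cm, tads, grid=100)
        center = amap.matrix[30:70, 30:70]
        corner = amap.matrix[0:20, 80:100]
        assert np.nanmean(center) == pytest.approx(4.0, rel=0.15)
        assert np.nanmean(corner) == pytest.approx(1.0, rel=0.15)

    def test_single_tad_map_equals_its_own_frame(self):
        cm = self._tad_matrix()
        one = IntervalSet.from_intervals([GenomicInterval("chr1", 600_000, 1_000_000)])
        amap1 = ata(cm, one, grid=50)
        amap2 = ata(cm, one, grid=50)
        np.testing.assert_array_equal(amap1.matrix, amap2.matrix)
        assert amap1.n_pairs == 1

    def test_short_tad_skipped(self):
        cm = self._tad_matrix()
        tads = IntervalSet.from_intervals(
            [
                GenomicInterval("chr1", 600_000, 1_000_000),
                GenomicInterval("chr1", 100_000, 130_000),  # 3 bins < 5
            ]
        )
        assert ata(cm, tads).n_pairs == 1

    def test_no_usable_tads_is_an_error(self):
        cm = self._tad_matrix()
        tads = IntervalSet.from_intervals([GenomicInterval("chr1", 0, 20_000)])
        with pytest.raises(ValueError):
            ata(cm, tads)


class TestPescan:
    def test_matches_brute_force_double_loop(self, rng):
        n = 30
        m = _random_symmetric(rng, n)
        cm = ContactMatrix("chr1", 10_000, m)
        anchors = IntervalSet.from_intervals(
            [_iv("chr1", 45_000), _iv("chr1", 145_000), _iv("chr1", 245_000)]
        )
        w = 2
        amap = pescan(
            cm, anchors, flank=20_000, bin_size=10_000,
            min_sep=50_000, max_sep=3_000_000, trim=0.0,
        )
        expected = expected_by_distance(cm)
        bins = [4, 14, 24]
        frames = []
        for i in range(3):
            for j in range(i + 1, 3):
                bi, bj = bins[i], bins[j]
                if bj - bi <= 2 * w or bj - bi < 5:
                    continue
                f = np.zeros((2 * w + 1, 2 * w + 1))
                for x in range(-w, w + 1):
                    for y in range(-w, w + 1):
                        f[x + w, y + w] = m[bi + x, bj + y] / expected[abs(bi + x - bj - y)]
                frames.append(f)
        np.testing.assert_allclose(amap.matrix, np.mean(frames, axis=0), rtol=1e-12)

    def test_zero_trim_is_plain_mean(self, rng):
        n = 40
        cm = ContactMatrix("chr1", 10_000, _random_symmetric(rng, n))
        anchors = IntervalSet.from_intervals(
            [_iv("chr1", 45_000), _iv("chr1", 205_000), _iv("chr1", 345_000)]
        )
        kw = dict(flank=20_000, bin_size=10_000, min_sep=60_000, max_sep=5_000_000)
        a = pescan(cm, anchors, trim=0.0, **kw)
        b = pescan(cm, anchors, trim=1e-9, **kw)
        np.testing.assert_allclose(a.matrix, b.matrix, rtol=1e-6)

    def test_winsorization_clamps_extremes(self, rng):
        n = 40
        m = _random_symmetric(rng, n)
        m[4, 24] = m[24, 4] = 1e4  # gross outlier at an anchor pixel
        cm = ContactMatrix("chr1", 10_000, m)
        anchors = IntervalSet.from_intervals(
            [_iv("chr1", 45_000), _iv("chr1", 205_000), _iv("chr1", 245_000)]
        )
        kw = dict(flank=20_000, bin_size=10_000, min_sep=60_000, max_sep=5_000_000)
        raw = pescan(cm, anchors, trim=0.0, **kw)
        trimmed = pescan(cm, anchors, trim=0.05, **kw)
        assert trimmed.matrix.max() < raw.matrix.max()

    def test_hub_enrichment_recovered_with_polycomb_preset(
        self, genome_hic, hub_truth
    ):
        centers = []
        for seed in range(5):
            raw = syn.simulate_contact_matrix(
                genome_hic, hub_truth, "WT", depth=16_000_000, seed=700 + seed
            )
            bal = {c: ice_balance(m) for c, m in raw.items()}
            amap = pescan(
                bal, hub_truth.domains, preset="polycomb",
                min_sep=1_000_000, max_sep=6_000_000,
            )
            centers.append(amap.center_value())
        se = np.std(centers, ddof=1) / np.sqrt(len(centers))
        assert abs(np.mean(centers) - 3.0) < 3 * max(se, 0.02)

    def test_no_qualifying_pairs_is_an_error(self, rng):
        cm = ContactMatrix("chr1", 10_000, _random_symmetric(rng, 30))
        anchors = IntervalSet.from_intervals([_iv("chr1", 45_000)])
        with pytest.raises(ValueError):
            pescan(cm, anchors, flank=20_000, bin_size=10_000)


class TestPairAggregate:
    def test_identical_conditions_give_zero_difference(self, rng):
        n = 80
        cm = ContactMatrix("chr1", 10_000, _random_symmetric(rng, n))
        pairs = [(_iv("chr1", 105_000), _iv("chr1", 605_000))]
        _, _, diff = polycomb_pair_aggregate(cm, cm, pairs, flank=50_000)
        np.testing.assert_allclose(diff.matrix, 0.0, atol=1e-12)

    def test_invariant_to_pair_order_and_anchor_swap(self, rng):
        n = 80
        cm = ContactMatrix("chr1", 10_000, _random_symmetric(rng, n))
        p1 = [
            (_iv("chr1", 105_000), _iv("chr1", 605_000)),
            (_iv("chr1", 205_000), _iv("chr1", 705_000)),
        ]
        p2 = [(b, a) for a, b in reversed(p1)]
        m1 = polycomb_pair_aggregate(cm, cm, p1, flank=50_000)[0]
        m2 = polycomb_pair_aggregate(cm, cm, p2, flank=50_000)[0]
        np.testing.assert_allclose(m1.matrix, m2.matrix)

    def test_resolution_mismatch_rejected(self, rng):
        a = ContactMatrix("chr1", 10_000, _random_symmetric(rng, 30))
        b = ContactMatrix("chr1", 20_000, _random_symmetric(rng, 30))
        with pytest.raises(ValueError):
            polycomb_pair_aggregate(a, b, [(_iv("chr1", 5_000), _iv("chr1", 250_000))])

    def test_hub_collapse_detected_in_difference_map(self, genome_hic, hub_truth):
        """WT 3x vs KO 1x hubs: difference-map center positive across seeds."""
        diffs = []
        for seed in range(5):
            raw_wt = syn.simulate_contact_matrix(
                genome_hic, hub_truth, "WT", depth=16_000_000, seed=800 + seed
            )
            raw_ko = syn.simulate_contact_matrix(
                genome_hic, hub_truth, "KO", depth=16_000_000, seed=850 + seed
            )
            bal_wt = {c: ice_balance(m) for c, m in raw_wt.items()}
            bal_ko = {c: ice_balance(m) for c, m in raw_ko.items()}
            _, _, diff = polycomb_pair_aggregate(
                bal_wt, bal_ko, hub_truth.hub_domain_pairs()
            )
            diffs.append(diff.center_value())
        assert all(d > 0 for d in diffs)
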