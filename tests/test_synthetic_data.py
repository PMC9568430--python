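import numpy as np
import pandas as pd
import pytest

from polyhub import synthetic_data as syn
from polyhub.core import GenomeModel, GenomicInterval, IntervalSet, PlacementError


class TestSimulateIntervals:
    def test_default_count_matches_domain_set_size(self):
        genome = syn.default_genome(3, 30_000_000, 10_000)
        ivs = syn.simulate_intervals(genome, seed=0)
        assert len(ivs) == 2097

    def test_intervals_sorted_non_overlapping_in_bounds(self):
        genome = syn.default_genome(2, 2_000_000, 10_000)
        ivs = syn.simulate_intervals(genome, n=100, length_range=(1_000, 5_000), seed=3)
        assert len(ivs) == 100
        df = ivs.df
        assert (df["start"] >= 0).all()
        for chrom, grp in df.groupby("chrom"):
            assert (grp["end"] <= genome.length(chrom)).all()
            assert (grp["start"].to_numpy()[1:] >= grp["end"].to_numpy()[:-1]).all()

    def test_single_interval_on_one_chromosome(self):
        genome = GenomeModel({"chrA": 100_000}, bin_size=1_000)
        ivs = syn.simulate_intervals(genome, n=1, length_range=(500, 600), seed=1)
        assert len(ivs) == 1
        assert 0 <= ivs[0].start < ivs[0].end <= 100_000

    def test_same_seed_identical_sets(self):
        genome = syn.default_genome(2, 2_000_000, 10_000)
        a = syn.simulate_intervals(genome, n=50, length_range=(1_000, 3_000), seed=9)
        b = syn.simulate_intervals(genome, n=50, length_range=(1_000, 3_000), seed=9)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_overfull_genome_raises_placement_error(self):
        genome = GenomeModel({"chr1": 50_000}, bin_size=1_000)
        with pytest.raises(PlacementError):
            syn.simulate_intervals(genome, n=100, length_range=(1_000, 2_000), seed=0)


class TestContactMatrix:
    def test_exactly_symmetric_and_nonnegative(self, genome_small, truth_basic):
        mats = syn.simulate_contact_matrix(
            genome_small, truth_basic, "WT", depth=1_000_000, seed=4
        )
        for cm in mats.values():
            np.testing.assert_array_equal(cm.counts, cm.counts.T)
            assert (cm.counts >= 0).all()

    def test_total_counts_near_requested_depth(self, genome_small, truth_basic):
        depth = 2_000_000
        mats = syn.simulate_contact_matrix(
            genome_small, truth_basic, "WT", depth=depth, seed=4
        )
        total = sum(m.counts.sum() for m in mats.values())
        # mirrored Poisson upper triangle: Var(total) <= 2 * depth
        assert abs(total - depth) < 3 * np.sqrt(2 * depth)

    def test_hub_pixels_enriched_by_condition_factor(self, genome_hic, hub_truth):
        """Sampled means at hub pixels match the analytic 3x / 1x expectation."""
        depth = 16_000_000
        expected = syn.contact_expectation(genome_hic, hub_truth, "KO")
        total = sum(m.sum() for m in expected.values())
        scale = depth / total
        for cond, factor in [("WT", 3.0), ("KO", 1.0)]:
            mats = syn.simulate_contact_matrix(
                genome_hic, hub_truth, cond, depth=depth, seed=11
            )
            obs, lam_bg = [], []
            for a, b in hub_truth.hub_domain_pairs():
                res = genome_hic.bin_size
                bi, bj = a.midpoint // res, b.midpoint // res
                d = abs(bj - bi)
                obs.append(mats[a.chrom].counts[bi, bj])
                lam_bg.append(scale * (1.0 + d) ** -1.0)
            obs, lam_bg = np.array(obs), np.array(lam_bg)
            expected_mean = factor * lam_bg.mean()
            se = np.sqrt((factor * lam_bg).sum()) / len(obs)
            assert abs(obs.mean() - expected_mean) < 3 * se

    def test_unknown_condition_and_zero_depth_rejected(self, genome_small, truth_basic):
        with pytest.raises(ValueError):
            syn.simulate_contact_matrix(genome_small, truth_basic, "nonesuch", seed=0)
        with pytest.raises(ValueError):
            syn.simulate_contact_matrix(
                genome_small, truth_basic, "WT", depth=0, seed=0
            )


class TestChipExperiment:
    def test_ip_efficiency_scales_both_compartments(self, genome_small, calibration_truth):
        exp = syn.simulate_chip_experiment(
            calibration_truth,
            genome_small,
            conditions=("A", "B"),
            replicates=1,
            ip_efficiency={"A": 1.0, "B": 2.0},
            depth=2_000_000,
            seed=5,
        )
        ips = {s.condition: s for s in exp.samples if s.role == "IP"}
        assert ips["B"].target_total / ips["A"].target_total == pytest.approx(2.0, rel=0.02)
        assert ips["B"].spike_total / ips["A"].spike_total == pytest.approx(2.0, rel=0.05)

    def test_halved_occupancy_halves_domain_enrichment(self, genome_small, occupancy_truth):
        """IP/input enrichment at domains drops 2x when occupancy halves."""
        exp = syn.simulate_chip_experiment(
            occupancy_truth,
            genome_small,
            conditions=("A", "B"),
            replicates=1,
            depth=4_000_000,
            seed=6,
        )
        by_id = {s.sample_id: s for s in exp.samples}
        dom = exp.domain_bins
        enrich = {}
        for cond in ("A", "B"):
            ip = by_id[f"{cond}_rep1_IP"]
            inp = by_id[ip.input_id]
            enrich[cond] = (
                ip.target_counts[dom].sum() / inp.target_counts[dom].sum()
            )
        assert enrich["B"] / enrich["A"] == pytest.approx(0.5, rel=0.05)

    def test_inputs_unaffected_by_occupancy(self, genome_small, occupancy_truth):
        exp = syn.simulate_chip_experiment(
            occupancy_truth, genome_small, conditions=("A", "B"), replicates=1,
            depth=4_000_000, seed=7,
        )
        inputs = {s.condition: s for s in exp.samples if s.role == "input"}
        ratio = inputs["B"].target_total / inputs["A"].target_total
        assert ratio == pytest.approx(1.0, rel=0.02)

    def test_degenerate_parameters_rejected(self, genome_small, truth_basic):
        with pytest.raises(ValueError):
            syn.simulate_chip_experiment(
                truth_basic, genome_small, spikein_fraction=0.0, seed=0
            )
        with pytest.raises(ValueError):
            syn.simulate_chip_experiment(truth_basic, genome_small, depth=0, seed=0)


class TestCaptureC:
    @pytest.fixture(scope="class")
    @staticmethod
    def setup(genome_small):
        truth = syn.default_truth(
            genome_small, n_domains=16, n_tads=0, n_loops=0, n_hub_pairs=None,
            hub_sep=(500_000, 4_000_000), seed=1,
        )
        fragments = syn.make_fragment_map(genome_small, 500)
        hub_doms = sorted({a for a, _ in truth.hub_pairs})
        baits = IntervalSet.from_intervals(
            [
                GenomicInterval(
                    truth.domains[i].chrom,
                    truth.domains[i].midpoint - 500,
                    truth.domains[i].midpoint + 500,
                    name=f"prom{i}",
                )
                for i in hub_doms
            ]
        )
        return truth, fragments, baits

    def test_hub_partner_scores_separate_by_condition(self, setup):
        truth, fragments, baits = setup
        for cond, expect_high in [("WT", True), ("KO", False)]:
            table = syn.simulate_capturec(
                baits, fragments, truth, condition=cond, depth=100_000, seed=2
            )
            # fragments inside a partner domain of the first bait
            a, b = truth.hub_pairs[0]
            bait_name = f"prom{a}"
            dom = truth.domains[b]
            sub = table.df[
                (table.df["bait"] == bait_name)
                & (table.df["chrom"] == dom.chrom)
                & (table.df["start"] < dom.end)
                & (table.df["end"] > dom.start)
            ]
            assert len(sub) > 0
            if expect_high:
                assert (sub["score"] >= 5).all()
            else:
                assert (sub["score"] < 5).all()

    def test_total_count_matches_depth(self, setup):
        truth, fragments, baits = setup
        depth = 200_000
        table = syn.simulate_capturec(
            baits, fragments, truth, condition="WT", depth=depth, seed=3
        )
        assert abs(table.total_count - depth) < 3 * np.sqrt(depth)

    def test_zero_baits_gives_empty_table(self, setup, genome_small):
        truth, fragments, _ = setup
        empty = IntervalSet(pd.DataFrame(columns=["chrom", "start", "end"]))
        table = syn.simulate_capturec(empty, fragments, truth, depth=1000, seed=0)
        assert len(table) == 0

    def test_bait_outside_fragment_map_raises(self, setup, genome_small):
        truth, _, _ = setup
        # fragment map covering only chr1; bait on chr2
        frags = IntervalSet(
            pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [500]})
        )
        baits = IntervalSet(
            pd.DataFrame({"chrom": ["chr2"], "start": [1000], "end": [2000]})
        )
        with pytest.raises(PlacementError):
            syn.simulate_capturec(baits, frags, truth, depth=1000, seed=0)


class TestExpression:
    def test_true_log2fc_recovered_at_high_depth(self, null_expression_truth):
        truth = null_expression_truth
        truth = syn.TruthSet(
            domains=truth.domains, tads=truth.tads, loops=truth.loops,
            hub_pairs=truth.hub_pairs, hub_factors=truth.hub_factors,
            occupancy=truth.occupancy,
            gene_log2fc=np.full(200, 2.0),
            induction_log2fc=np.zeros(200),
            dependence_log2fc=np.zeros(200),
        )
        table = syn.simulate_expression(
            200, 50, truth, replicates=8, depth_mean=2000.0, seed=12
        )
        wt = table.counts.loc[table.origin == "target", table.samples_of("WT")]
        ko = table.counts.loc[table.origin == "target", table.samples_of("KO")]
        ratio = (ko.mean(axis=1) / wt.mean(axis=1)).median()
        assert ratio == pytest.approx(4.0, rel=0.05)

    def test_global_shift_scales_targets_not_spikes(self, null_expression_truth):
        table = syn.simulate_expression(
            2000, 500, null_expression_truth, global_shift=0.5, replicates=4, seed=13
        )
        t = table.counts[table.origin == "target"]
        s = table.counts[table.origin == "spike"]
        wt_cols, ko_cols = table.samples_of("WT"), table.samples_of("KO")
        assert (
            t[ko_cols].to_numpy().sum() / t[wt_cols].to_numpy().sum()
        ) == pytest.approx(0.5, rel=0.05)
        assert (
            s[ko_cols].to_numpy().sum() / s[wt_cols].to_numpy().sum()
        ) == pytest.approx(1.0, rel=0.05)

    def test_degenerate_parameters_rejected(self, null_expression_truth):
        with pytest.raises(ValueError):
            syn.simulate_expression(2000, 0, null_expression_truth, seed=0)
        with pytest.raises(ValueError):
            syn.simulate_expression(
                2000, 500, null_expression_truth, replicates=1, seed=0
            )


class TestDeterminism:
    """Identical seeds give byte-identical outputs for every sampler."""

    def test_contact_matrix(self, genome_small, truth_basic):
        a = syn.simulate_contact_matrix(genome_small, truth_basic, "WT", depth=500_000, seed=7)
        b = syn.simulate_contact_matrix(genome_small, truth_basic, "WT", depth=500_000, seed=7)
        for c in a:
            np.testing.assert_array_equal(a[c].counts, b[c].counts)

    def test_chip(self, genome_small, truth_basic):
        a = syn.simulate_chip_experiment(truth_basic, genome_small, depth=100_000, seed=8)
        b = syn.simulate_chip_experiment(truth_basic, genome_small, depth=100_000, seed=8)
        for sa, sb in zip(a.samples, b.samples):
            np.testing.assert_array_equal(sa.target_counts, sb.target_counts)
            np.testing.assert_array_equal(sa.spike_counts, sb.spike_counts)

    def test_expression(self, null_expression_truth):
        a = syn.simulate_expression(2000, 500, null_expression_truth, seed=9)
        b = syn.simulate_expression(2000, 500, null_expression_truth, seed=9)
        pd.testing.assert_frame_equal(a.counts, b.counts)
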