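"""Synthetic paired-cohort generator: event model, count model, cohort."""

import numpy as np
import pytest

from pairedcn.core import ConfigurationError
from pairedcn.simulate import (BiasParams, CohortConfig, FLAT_BIAS,
                               annotate_bins, derive_relapse,
                               emit_binned_counts, expected_counts,
                               simulate_cn_profile, simulate_paired_cohort)


UNIFORM = np.full(7, 1 / 7)


class TestCNProfile:
    def test_zero_budget_gives_flat_genome(self, toy):
        truth = simulate_cn_profile(toy, UNIFORM, 0, seed=1, baseline_ploidy=2)
        assert len(truth.segments) == len(toy.chrom_names)
        assert (truth.segments["cn"] == 2).all()
        assert truth.tumour_ploidy == 2.0

    def test_segments_tile_genome_exactly(self, toy):
        truth = simulate_cn_profile(toy, UNIFORM, 15, seed=2)
        seg = truth.segments
        total = (seg["end"] - seg["start"]).sum()
        assert total == toy.genome_length
        for chrom, sub in seg.groupby("chrom"):
            assert sub.iloc[0]["start"] == 0
            assert (sub["start"].to_numpy()[1:] == sub["end"].to_numpy()[:-1]).all()

    def test_seed_contract(self, toy):
        a = simulate_cn_profile(toy, UNIFORM, 10, seed=7)
        b = simulate_cn_profile(toy, UNIFORM, 10, seed=7)
        c = simulate_cn_profile(toy, UNIFORM, 10, seed=8)
        assert a.segments.equals(b.segments)
        assert not a.segments.equals(c.segments)

    def test_copy_numbers_never_negative(self, toy):
        focal_del = np.zeros(7)
        focal_del[3] = 1.0
        truth = simulate_cn_profile(toy, focal_del, 40, seed=3)
        assert (truth.segments["cn"] >= 0).all()

    def test_large_segment_class_makes_longer_segments_than_focal(self, toy):
        large = np.zeros(7)
        large[0] = 1.0
        focal = np.zeros(7)
        focal[2] = 1.0
        mean_large, mean_focal = [], []
        for rep in range(10):
            tl = simulate_cn_profile(toy, large, 30, seed=100 + rep)
            tf = simulate_cn_profile(toy, focal, 30, seed=200 + rep)
            mean_large.append((tl.segments["end"] - tl.segments["start"]).mean())
            mean_focal.append((tf.segments["end"] - tf.segments["start"]).mean())
        assert np.mean(mean_large) > np.mean(mean_focal)

    def test_invalid_exposures_rejected(self, toy):
        with pytest.raises(ValueError):
            simulate_cn_profile(toy, np.full(7, 0.5), 5, seed=0)
        with pytest.raises(ValueError):
            simulate_cn_profile(toy, UNIFORM, -1, seed=0)


class TestDeriveRelapse:
    def test_none_is_identity(self, toy):
        dx = simulate_cn_profile(toy, UNIFORM, 10, seed=4)
        rl = derive_relapse(dx, "none")
        assert rl.segments[["chrom", "start", "end", "cn"]].equals(
            dx.segments[["chrom", "start", "end", "cn"]])
        assert rl.role == "relapse"
        assert rl.patient_id == dx.patient_id

    def test_planted_region_shifts_cn(self, toy):
        dx = simulate_cn_profile(toy, UNIFORM, 0, seed=0)
        rl = derive_relapse(dx, "planted_region",
                            {"chrom": "chr1", "start": 10_000_000,
                             "end": 20_000_000, "delta": 2}, layout=toy)
        inside = rl.segments.query(
            "chrom == 'chr1' and start >= 10_000_000 and end <= 20_000_000")
        outside = rl.segments.query("chrom != 'chr1' or end <= 10_000_000 "
                                    "or start >= 20_000_000")
        assert (inside["cn"] == 4).all()
        assert (outside["cn"] == 2).all()

    def test_planted_region_outside_genome_rejected(self, toy):
        dx = simulate_cn_profile(toy, UNIFORM, 0, seed=0)
        with pytest.raises(ValueError):
            derive_relapse(dx, "planted_region",
                           {"chrom": "chr1", "start": 0, "end": 10**9},
                           layout=toy)

    def test_ploidy_shift_doubles(self, toy):
        dx = simulate_cn_profile(toy, UNIFORM, 0, seed=0)
        rl = derive_relapse(dx, "ploidy_shift")
        assert rl.tumour_ploidy == pytest.approx(2 * dx.tumour_ploidy)


class TestBinnedCounts:
    def test_flat_diploid_mean_matches_depth(self, toy):
        truth = simulate_cn_profile(toy, UNIFORM, 0, seed=0, purity=1.0,
                                    depth=60.0)
        counts = emit_binned_counts(truth, toy, FLAT_BIAS, seed=1)
        mean = counts.df["count"].mean()
        se = np.sqrt(60.0 / len(counts.df))
        assert abs(mean - 60.0) < 3 * se

    def test_expected_ratio_between_states(self, toy):
        # bins at n=4 vs n=2 with rho=1 must have expectation ratio 2
        dx = simulate_cn_profile(toy, UNIFORM, 0, seed=0, purity=1.0)
        rl = derive_relapse(dx, "planted_region",
                            {"chrom": "chr1", "start": 0,
                             "end": 60_000_000, "delta": 2}, layout=toy)
        ann = annotate_bins(toy, seed=0)
        mu = expected_counts(rl, ann, FLAT_BIAS)
        chr1 = (ann["chrom"] == "chr1").to_numpy()
        in4 = chr1 & (ann["start"] < 60_000_000).to_numpy()
        in2 = ~chr1
        ratio = mu[in4].mean() / mu[in2].mean()
        assert ratio == pytest.approx(2.0, abs=1e-9)

    def test_doubling_depth_doubles_expectation(self, toy):
        from dataclasses import replace

        truth = simulate_cn_profile(toy, UNIFORM, 5, seed=0, depth=60.0)
        ann = annotate_bins(toy, seed=0)
        mu1 = expected_counts(truth, ann, BiasParams())
        mu2 = expected_counts(replace(truth, depth=120.0), ann, BiasParams())
        assert np.allclose(mu2, 2 * mu1, rtol=1e-12)

    def test_seed_contract(self, toy):
        truth = simulate_cn_profile(toy, UNIFORM, 5, seed=0)
        a = emit_binned_counts(truth, toy, seed=9)
        b = emit_binned_counts(truth, toy, seed=9)
        c = emit_binned_counts(truth, toy, seed=10)
        assert (a.df["count"] == b.df["count"]).all()
        assert (a.df["count"] != c.df["count"]).any()

    def test_negative_binomial_overdispersion(self, toy):
        truth = simulate_cn_profile(toy, UNIFORM, 0, seed=0, purity=1.0,
                                    depth=100.0)
        poisson = emit_binned_counts(truth, toy, FLAT_BIAS, seed=3)
        nb = emit_binned_counts(
            truth, toy,
            BiasParams(depth=100.0, dispersion=0.2, gc_linear=0, gc_quad=0,
                       mappability_exponent=0), seed=3)
        assert nb.df["count"].var() > 2 * poisson.df["count"].var()


class TestPairedCohort:
    def test_cohort_shape_47_pairs(self, toy):
        cohort = simulate_paired_cohort(47, seed=1, layout=toy)
        assert len(cohort.counts) == 47
        n_samples = sum(len(pair) for pair in cohort.counts.samples.values())
        assert n_samples == 94
        assert set(cohort.truths) == set(cohort.counts.samples)

    def test_minimal_cohort(self, toy):
        cohort = simulate_paired_cohort(1, seed=0, layout=toy)
        assert len(cohort.counts) == 1

    def test_unknown_config_key_rejected_with_offender(self):
        with pytest.raises(ConfigurationError, match="not_a_key"):
            CohortConfig.from_dict({"not_a_key": 1})

    def test_invalid_config_values_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(event_budget=-1)
        with pytest.raises(ConfigurationError):
            CohortConfig(purity_min=0.9, purity_max=0.5)
        with pytest.raises(ConfigurationError):
            CohortConfig(perturbation="bogus")

    def test_primary_resistant_fraction_binomial(self, toy):
        cohort = simulate_paired_cohort(
            120, {"primary_resistant_fraction": 0.1}, seed=5, layout=toy)
        n = sum(rec.primary_platinum_resistant
                for rec in cohort.clinical.values())
        # 3-sigma binomial band around 12
        assert 2 <= n <= 22

    def test_platinum_interval_rule(self, toy):
        cohort = simulate_paired_cohort(40, seed=2, layout=toy)
        for rec in cohort.clinical.values():
            expected = ("resistant" if rec.relapse_interval_months < 6
                        else "sensitive")
            assert rec.platinum_status == expected
            if rec.primary_platinum_resistant:
                assert rec.platinum_status == "resistant"
                assert rec.prior_lines == 1

    def test_exposures_on_simplex_and_truth_retained(self, toy):
        cohort = simulate_paired_cohort(3, seed=3, layout=toy)
        for pid, pair in cohort.truths.items():
            for truth in pair.values():
                assert truth.exposures.sum() == pytest.approx(1.0, abs=1e-9)
                assert (truth.exposures >= 0).all()
                assert 0 < truth.purity <= 1

    def test_determinism_of_whole_cohort(self, toy):
        a = simulate_paired_cohort(2, seed=11, layout=toy)
        b = simulate_paired_cohort(2, seed=11, layout=toy)
        for pid in a.counts.samples:
            for role in ("diagnosis", "relapse"):
                assert (a.counts.samples[pid][role].df["count"]
                        == b.counts.samples[pid][role].df["count"]).all()
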