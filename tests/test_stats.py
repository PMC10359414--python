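"""Cohort statistics: subtraction, gene events, group tests, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from pairedcn.core import PairedCNError, PairedCohort
from pairedcn.simulate import default_gene_panel, simulate_cn_profile
from pairedcn.stats import (call_gene_events, compare_event_rates,
                            compare_exposures_univariate,
                            correlate_exposures_immune, subtract_pairs)

from conftest import make_profile


def _noisy_profile(mini, rng, shift_region=None, delta=0.0, role="diagnosis"):
    """Per-bin profile with small Gaussian jitter around CN 2."""
    rows = []
    for chrom, length in mini.chromosomes:
        step = 600_000
        for lo in range(0, length, step):
            hi = min(lo + step, length)
            cn = 2.0 + rng.normal(0, 0.1)
            if (shift_region and chrom == shift_region[0]
                    and lo >= shift_region[1] and hi <= shift_region[2]):
                cn += delta
            rows.append((chrom, lo, hi, cn))
    return make_profile(rows, role=role)


class TestSubtraction:
    def test_planted_region_flagged_and_antisymmetry(self, mini):
        rng = np.random.default_rng(0)
        region = ("chr1", 0, 1_800_000)
        pairs = {}
        for i in range(20):
            dx = _noisy_profile(mini, rng)
            rl = _noisy_profile(mini, rng, shift_region=region, delta=2.0,
                                role="relapse")
            pairs[f"P{i}"] = {"diagnosis": dx, "relapse": rl}
        sub = subtract_pairs(PairedCohort(pairs), mini, alpha=0.05)
        df = sub.df
        inreg = ((df["chrom"] == "chr1") & (df["end"] <= 1_800_000))
        assert df.loc[inreg, "significant"].all()
        assert df.loc[inreg, "median_diff"].median() == pytest.approx(2.0, abs=0.2)
        # out-of-region false discoveries controlled
        fp = df.loc[~inreg, "significant"].sum()
        assert fp / max(df["significant"].sum(), 1) <= 0.05
        # label swap negates the median-difference profile exactly
        swapped = {pid: {"diagnosis": pair["relapse"],
                         "relapse": pair["diagnosis"]}
                   for pid, pair in pairs.items()}
        sub2 = subtract_pairs(PairedCohort(swapped), mini, alpha=0.05)
        assert np.allclose(sub2.df["median_diff"], -df["median_diff"],
                           atol=1e-12)
        assert np.allclose(sub2.df["p"], df["p"], atol=1e-12)

    def test_all_tied_bins_give_p_one(self, mini):
        pairs = {}
        for i in range(5):
            dx = make_profile([(c, 0, l, 2.0) for c, l in mini.chromosomes])
            rl = make_profile([(c, 0, l, 2.0) for c, l in mini.chromosomes],
                              role="relapse")
            pairs[f"P{i}"] = {"diagnosis": dx, "relapse": rl}
        sub = subtract_pairs(PairedCohort(pairs), mini)
        assert (sub.df["p"] == 1.0).all()
        assert not sub.df["significant"].any()
        assert (sub.df["median_diff"] == 0).all()

    def test_q_values_dominate_p_and_match_bh_oracle(self, mini):
        rng = np.random.default_rng(1)
        pairs = {f"P{i}": {"diagnosis": _noisy_profile(mini, rng),
                           "relapse": _noisy_profile(mini, rng, role="relapse")}
                 for i in range(6)}
        sub = subtract_pairs(PairedCohort(pairs), mini)
        df = sub.df.dropna(subset=["p"])
        assert (df["q"] >= df["p"] - 1e-12).all()
        for chrom, grp in df.groupby("chrom"):
            expected = multipletests(grp["p"].to_numpy(), method="fdr_bh")[1]
            assert np.allclose(grp["q"].to_numpy(), expected, atol=1e-12)

    def test_needs_two_pairs(self, mini):
        dx = make_profile([(c, 0, l, 2.0) for c, l in mini.chromosomes])
        rl = make_profile([(c, 0, l, 2.0) for c, l in mini.chromosomes],
                          role="relapse")
        with pytest.raises(PairedCNError):
            subtract_pairs(PairedCohort({"P0": {"diagnosis": dx, "relapse": rl}}),
                           mini)


class TestGeneEvents:
    def _panel(self):
        return pd.DataFrame({"chrom": ["chr1", "chr1"],
                             "start": [0, 1_800_000],
                             "end": [120_000, 1_920_000],
                             "gene": ["KRAS", "CCNE1"]})

    def test_threshold_rules(self):
        # ploidy 2: amplified iff CN >= 5; deleted iff CN <= 0.13
        prof = make_profile([("chr1", 0, 120_000, 10.0),
                             ("chr1", 120_000, 1_800_000, 2.0),
                             ("chr1", 1_800_000, 3_600_000, 2.0)], ploidy=2.0)
        table = call_gene_events(prof, self._panel())
        assert table.set_index("gene").loc["KRAS", "event"] == "amplified"
        assert table.set_index("gene").loc["CCNE1", "event"] == "neutral"

    def test_cn_equal_to_ploidy_is_neutral(self):
        prof = make_profile([("chr1", 0, 3_600_000, 3.4)], ploidy=3.4)
        table = call_gene_events(prof, self._panel())
        assert (table["event"] == "neutral").all()

    def test_max_rule_boundary_at_high_ploidy(self):
        # ploidy 3.4 -> amplification threshold max(5, 6.8) = 6.8
        prof = make_profile([("chr1", 0, 120_000, 6.7),
                             ("chr1", 120_000, 3_600_000, 3.4)], ploidy=3.4)
        t1 = call_gene_events(prof, self._panel())
        assert t1.set_index("gene").loc["KRAS", "event"] == "neutral"
        prof2 = make_profile([("chr1", 0, 120_000, 6.9),
                              ("chr1", 120_000, 3_600_000, 3.4)], ploidy=3.4)
        t2 = call_gene_events(prof2, self._panel())
        assert t2.set_index("gene").loc["KRAS", "event"] == "amplified"

    def test_deletion_threshold_floors_at_zero(self):
        # ploidy 1.5 -> deletion threshold max(1.5 - 1.87, 0) = 0
        prof = make_profile([("chr1", 0, 3_600_000, 0.4)], ploidy=1.5)
        table = call_gene_events(prof, self._panel())
        assert (table["event"] == "neutral").all()

    def test_length_weighted_gene_cn(self):
        prof = make_profile([("chr1", 0, 60_000, 2.0),
                             ("chr1", 60_000, 3_600_000, 4.0)], ploidy=4.0)
        table = call_gene_events(prof, self._panel())
        assert table.set_index("gene").loc["KRAS", "cn"] == pytest.approx(3.0)

    def test_gene_without_overlap_is_missing(self):
        prof = make_profile([("chr2", 0, 2_400_000, 2.0)], ploidy=2.0)
        table = call_gene_events(prof, self._panel())
        assert (table["event"] == "missing").all()

    def test_default_panel_inside_genome(self, toy):
        panel = default_gene_panel(toy)
        assert len(panel) == 18
        lengths = toy.chrom_lengths
        assert all(row.end <= lengths[row.chrom]
                   for row in panel.itertuples(index=False))


class TestFisherComparisons:
    def _table(self, n_a, k_a, n_b, k_b, gene="KRAS"):
        rows = []
        for i in range(n_a):
            rows.append((f"A{i}", gene,
                         10.0 if i < k_a else 2.0,
                         "amplified" if i < k_a else "neutral", 2.0))
        for i in range(n_b):
            rows.append((f"B{i}", gene,
                         10.0 if i < k_b else 2.0,
                         "amplified" if i < k_b else "neutral", 2.0))
        table = pd.DataFrame(rows, columns=["sample_id", "gene", "cn",
                                            "event", "ploidy"])
        groups = pd.Series({f"A{i}": "diagnosis" for i in range(n_a)}
                           | {f"B{i}": "relapse" for i in range(n_b)})
        return table, groups

    def test_printed_amplification_table(self):
        # 4/122 vs 12/127 amplified -> two-sided p = 0.07 to 2 dp
        table, groups = self._table(122, 4, 127, 12)
        res = compare_event_rates(table, groups)[0]
        assert round(res.pvalue, 2) == 0.07

    def test_identical_groups_give_p_one(self):
        table, groups = self._table(20, 5, 20, 5)
        assert compare_event_rates(table, groups)[0].pvalue == pytest.approx(1.0)

    def test_extreme_table_hypergeometric_value(self):
        # 10/10 vs 0/10 -> p = 2 / C(20,10)
        table, groups = self._table(10, 10, 10, 0)
        res = compare_event_rates(table, groups)[0]
        assert res.pvalue == pytest.approx(2 / 184756, rel=1e-9)

    def test_agreement_with_hypergeometric_enumeration(self, rng):
        """Two-sided Fisher must equal summing hypergeometric point masses
        no larger than the observed one, over random small tables."""
        for _ in range(25):
            n1, n2 = rng.integers(2, 16, 2)
            k1 = int(rng.integers(0, n1 + 1))
            k2 = int(rng.integers(0, n2 + 1))
            table, groups = self._table(n1, k1, n2, k2)
            p_pkg = compare_event_rates(table, groups)[0].pvalue
            K, N = k1 + k2, n1 + n2
            obs = sps.hypergeom.pmf(k1, N, K, n1)
            support = np.arange(max(0, K - n2), min(K, n1) + 1)
            masses = sps.hypergeom.pmf(support, N, K, n1)
            p_enum = masses[masses <= obs * (1 + 1e-9)].sum()
            assert p_pkg == pytest.approx(min(p_enum, 1.0), rel=1e-6)

    def test_bh_adjustment_across_gene_family(self):
        t1, g1 = self._table(30, 10, 30, 0, gene="KRAS")
        t2, _ = self._table(30, 5, 30, 4, gene="CCNE1")
        table = pd.concat([t1, t2], ignore_index=True)
        res = compare_event_rates(table, g1)
        by_gene = {r.label.split(":")[0]: r for r in res}
        assert by_gene["KRAS"].qvalue >= by_gene["KRAS"].pvalue
        assert by_gene["CCNE1"].qvalue == pytest.approx(1.0, abs=1e-9)

    def test_empty_group_rejected(self):
        table, _ = self._table(5, 1, 5, 1)
        groups = pd.Series({sid: "diagnosis" for sid in table["sample_id"]})
        with pytest.raises(ValueError):
            compare_event_rates(table, groups)


class TestUnivariateExposureTests:
    def _exposures(self, rng, n, shift=0.0, sig=2):
        rows = []
        for _ in range(n):
            e = rng.dirichlet(np.ones(7))
            e[sig] += shift
            rows.append(e / e.sum())
        return pd.DataFrame(rows, columns=[f"s{j + 1}" for j in range(7)])

    def test_identical_groups_p_one(self, rng):
        E = self._exposures(rng, 10)
        both = pd.concat([E, E], ignore_index=True)
        groups = ["diagnosis"] * 10 + ["relapse"] * 10
        res = compare_exposures_univariate(both, groups, paired=True,
                                           pair_keys=list(range(10)) * 2)
        assert all(r.pvalue == 1.0 for r in res)

    def test_constant_exposures_all_tied(self):
        E = pd.DataFrame(np.full((20, 7), 1 / 7),
                         columns=[f"s{j + 1}" for j in range(7)])
        res = compare_exposures_univariate(E, ["a"] * 10 + ["b"] * 10)
        assert all(r.pvalue == 1.0 for r in res)

    def test_planted_shift_power(self, rng):
        hits = 0
        for rep in range(20):
            a = self._exposures(rng, 50)
            b = self._exposures(rng, 50, shift=0.2)
            E = pd.concat([a, b], ignore_index=True)
            res = compare_exposures_univariate(E, ["a"] * 50 + ["b"] * 50)
            hits += res[2].pvalue < 0.01
        assert hits >= 18  # >= 90% power

    def test_paired_requires_keys_and_matching(self, rng):
        E = self._exposures(rng, 6)
        groups = ["a", "b"] * 3
        with pytest.raises(PairedCNError):
            compare_exposures_univariate(E, groups, paired=True)
        with pytest.raises(PairedCNError):
            compare_exposures_univariate(E, groups, paired=True,
                                         pair_keys=[1, 2, 3, 4, 5, 6])

    def test_methods_reported(self, rng):
        E = self._exposures(rng, 8)
        res = compare_exposures_univariate(E, ["a"] * 4 + ["b"] * 4)
        assert all(r.method == "mann-whitney" for r in res)


class TestImmuneCorrelations:
    def test_monotone_density_gives_perfect_rank_correlation(self, rng):
        E = pd.DataFrame(rng.dirichlet(np.ones(7), size=20),
                         columns=[f"s{j + 1}" for j in range(7)],
                         index=[f"S{i}" for i in range(20)])
        dens = pd.DataFrame({"CD3_tumour": np.exp(3 * E["s3"])}, index=E.index)
        res = correlate_exposures_immune(E[["s3"]], dens)
        spearman = [r for r in res if r.method == "spearman"][0]
        assert spearman.statistic == pytest.approx(1.0)
        kendall = [r for r in res if r.method == "kendall"][0]
        assert kendall.statistic == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self, rng):
        E = pd.DataFrame(rng.dirichlet(np.ones(7), size=15),
                         columns=[f"s{j + 1}" for j in range(7)],
                         index=[f"S{i}" for i in range(15)])
        dens = pd.DataFrame({"CD8_stroma": -E["s1"]}, index=E.index)
        res = correlate_exposures_immune(E[["s1"]], dens)
        spearman = [r for r in res if r.method == "spearman"][0]
        assert spearman.statistic == pytest.approx(-1.0)

    def test_constant_density_reported_missing(self, rng):
        E = pd.DataFrame(rng.dirichlet(np.ones(7), size=10),
                         columns=[f"s{j + 1}" for j in range(7)],
                         index=[f"S{i}" for i in range(10)])
        dens = pd.DataFrame({"CD3_tumour": np.ones(10)}, index=E.index)
        res = correlate_exposures_immune(E[["s2"]], dens)
        assert all(np.isnan(r.statistic) for r in res)

    def test_requires_three_overlapping_samples(self, rng):
        E = pd.DataFrame(rng.dirichlet(np.ones(7), size=5),
                         columns=[f"s{j + 1}" for j in range(7)],
                         index=[f"S{i}" for i in range(5)])
        dens = pd.DataFrame({"CD3_tumour": [1.0, 2.0]}, index=["S0", "S1"])
        with pytest.raises(PairedCNError):
            correlate_exposures_immune(E, dens)
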