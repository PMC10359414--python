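"""Cohort-level inference on paired absolute copy-number profiles.

Covers the genome-wide paired subtraction analysis (per-bin Mann-Whitney U
with chromosome-wise Benjamini-Hochberg correction), ploidy-aware focal
gene event calling with Fisher group comparisons, per-signature two-group
tests, and exposure-immune density correlations. The compositional ILR
model lives in :mod:`pairedcn.composition`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AbsoluteProfile, PairedCNError, PairedCohort, segments_to_bins

__all__ = [
    "TestResult", "SubtractionProfile", "subtract_pairs", "call_gene_events",
    "compare_event_rates", "compare_exposures_univariate",
    "correlate_exposures_immune",
]


@dataclass(frozen=True)
class TestResult:
    """One statistical comparison: statistic, raw p, optional adjusted q."""

    label: str
    method: str
    statistic: float
    pvalue: float
    qvalue: float = float("nan")
    n_per_group: tuple = ()

    def __post_init__(self):
        if np.isfinite(self.pvalue) and not (0 <= self.pvalue <= 1):
            raise ValueError("p-value outside [0, 1]")
        if np.isfinite(self.qvalue) and self.qvalue < self.pvalue - 1e-12:
            raise ValueError("q-value below p-value")


@dataclass
class SubtractionProfile:
    """Per-bin relapse-minus-diagnosis summary across pairs.

    df columns: chrom, start, end, median_diff, p, q, significant.
    """

    df: pd.DataFrame
    alpha: float

    @property
    def significant_fraction(self) -> float:
        ok = self.df["p"].notna()
        return float(self.df.loc[ok, "significant"].mean()) if ok.any() else 0.0


def _mannwhitney_bins(dx: np.ndarray, rl: np.ndarray) -> np.ndarray:
    """Vectorised two-sided Mann-Whitney U p-values per bin (column)."""
    p = np.full(dx.shape[1], np.nan)
    complete = ~(np.isnan(dx).any(axis=0) | np.isnan(rl).any(axis=0))
    # bins where every value is identical are pure ties: p = 1
    both = np.vstack([dx, rl])
    tied = complete & (np.nanmax(both, axis=0) == np.nanmin(both, axis=0))
    p[tied] = 1.0
    todo = complete & ~tied
    if todo.any():
        res = stats.mannwhitneyu(dx[:, todo], rl[:, todo], axis=0,
                                 alternative="two-sided", method="asymptotic")
        p[todo] = res.pvalue
    return np.clip(p, 0.0, 1.0)


def subtract_pairs(pairs: PairedCohort, layout, alpha: float = 0.05) -> SubtractionProfile:
    """Genome-wide subtraction analysis across diagnosis/relapse pairs.

    Per bin: two-sided Mann-Whitney U of diagnosis vs relapse absolute CN
    across patients, BH-corrected within each chromosome; the reported
    profile is median(relapse) - median(diagnosis). Positive values mean a
    copy-number increase at relapse. Patients missing a bin are dropped
    bin-wise.
    """
    if len(pairs) < 2:
        raise PairedCNError("need at least 2 pairs")
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    bins = layout.bins()
    dx_rows, rl_rows = [], []
    for pid, dx, rl in pairs.pairs():
        for profile, rows in ((dx, dx_rows), (rl, rl_rows)):
            binned = segments_to_bins(profile.segments, layout)
            if len(binned) != len(bins):
                raise PairedCNError(f"patient {pid}: inconsistent bin grid")
            rows.append(binned["value"].to_numpy(np.float64))
    DX = np.vstack(dx_rows)
    RL = np.vstack(rl_rows)

    p = _mannwhitney_bins(DX, RL)
    q = np.full_like(p, np.nan)
    chroms = bins["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        sel = (chroms == chrom) & np.isfinite(p)
        if sel.any():
            q[sel] = multipletests(p[sel], method="fdr_bh")[1]

    out = bins.copy()
    out["median_diff"] = np.nanmedian(RL, axis=0) - np.nanmedian(DX, axis=0)
    out["p"] = p
    out["q"] = q
    out["significant"] = np.isfinite(q) & (q < alpha)
    return SubtractionProfile(df=out, alpha=alpha)


def call_gene_events(profile: AbsoluteProfile, panel: pd.DataFrame,
                     amp_min: float = 5.0, amp_ploidy_factor: float = 2.0,
                     del_offset: float = 1.87) -> pd.DataFrame:
    """Focal event calls for one sample over a gene panel.

    Gene CN is the length-weighted mean of overlapping segments. A gene is
    amplified iff CN >= max(amp_min, amp_ploidy_factor * ploidy), deleted
    iff CN <= max(ploidy - del_offset, 0) (a sub-single-copy loss), else
    neutral. Genes with no overlapping segment get a missing value.

    Returns rows (sample_id, gene, cn, event, ploidy).
    """
    seg = profile.segments.df
    rows = []
    for gene in panel.itertuples(index=False):
        sub = seg.loc[(seg["chrom"] == gene.chrom)
                      & (seg["end"] > gene.start) & (seg["start"] < gene.end)]
        if len(sub) == 0:
            rows.append((profile.sample_id, gene.gene, np.nan, "missing",
                         profile.ploidy))
            continue
        overlap = (np.minimum(sub["end"].to_numpy(), gene.end)
                   - np.maximum(sub["start"].to_numpy(), gene.start))
        cn = float(np.average(sub["value"].to_numpy(float), weights=overlap))
        amp_thr = max(amp_min, amp_ploidy_factor * profile.ploidy)
        del_thr = max(profile.ploidy - del_offset, 0.0)
        if cn >= amp_thr:
            event = "amplified"
        elif cn <= del_thr:
            event = "deleted"
        else:
            event = "neutral"
        rows.append((profile.sample_id, gene.gene, cn, event, profile.ploidy))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "cn", "event", "ploidy"])


def compare_event_rates(table: pd.DataFrame, grouping: pd.Series,
                        event: str = "amplified",
                        genes: list | None = None) -> list:
    """Per-gene two-sided Fisher exact tests of event rates between two
    groups, BH-adjusted across the gene family.

    `table` is the concatenated per-sample output of call_gene_events;
    `grouping` maps sample_id -> group label (two levels).
    """
    groups = pd.Series(grouping)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("grouping must have exactly two levels")
    merged = table.merge(groups.rename("group"), left_on="sample_id",
                         right_index=True)
    merged = merged.loc[merged["event"] != "missing"]
    genes = genes or sorted(merged["gene"].unique())
    results = []
    for gene in genes:
        sub = merged.loc[merged["gene"] == gene]
        counts = []
        for lvl in levels:
            g = sub.loc[sub["group"] == lvl]
            if len(g) == 0:
                raise PairedCNError(f"gene {gene}: empty group {lvl!r}")
            hits = int((g["event"] == event).sum())
            counts.append((hits, len(g) - hits))
        odds, p = stats.fisher_exact([counts[0], counts[1]], alternative="two-sided")
        results.append((gene, odds, p, (counts[0][0] + counts[0][1],
                                        counts[1][0] + counts[1][1])))
    qs = multipletests([r[2] for r in results], method="fdr_bh")[1]
    return [TestResult(label=f"{gene}:{event}", method="fisher-exact",
                       statistic=float(odds), pvalue=float(p), qvalue=float(q),
                       n_per_group=n)
            for (gene, odds, p, n), q in zip(results, qs)]


def _safe_two_sample_p(a: np.ndarray, b: np.ndarray, paired: bool) -> tuple:
    if paired:
        d = b - a
        if np.allclose(d, 0.0):
            return 0.0, 1.0
        res = stats.wilcoxon(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    if np.nanmax(np.concatenate([a, b])) == np.nanmin(np.concatenate([a, b])):
        return float(len(a) * len(b) / 2), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def compare_exposures_univariate(exposures: pd.DataFrame, grouping,
                                 paired: bool = False,
                                 pair_keys=None, adjust: bool = False) -> list:
    """One two-group test per signature, unadjusted by default (BH optional).

    Unpaired: two-sided Mann-Whitney U. Paired: two-sided Wilcoxon
    signed-rank, with `pair_keys` aligning the two groups patient-wise.
    """
    groups = np.asarray(grouping)
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError("grouping must have exactly two levels")
    a_idx = np.flatnonzero(groups == levels[0])
    b_idx = np.flatnonzero(groups == levels[1])
    if paired:
        if pair_keys is None:
            raise PairedCNError("paired test requires pair_keys")
        keys = np.asarray(pair_keys)
        ka, kb = keys[a_idx], keys[b_idx]
        if sorted(ka) != sorted(kb) or len(set(ka)) != len(ka):
            raise PairedCNError("pairing keys do not form matched pairs")
        b_idx = b_idx[np.argsort(kb)][np.argsort(np.argsort(ka))]
    results = []
    for sig in exposures.columns:
        col = exposures[sig].to_numpy(float)
        a, b = col[a_idx], col[b_idx]
        statistic, p = _safe_two_sample_p(a, b, paired)
        results.append(TestResult(
            label=str(sig),
            method="wilcoxon-signed-rank" if paired else "mann-whitney",
            statistic=statistic, pvalue=p, n_per_group=(len(a), len(b))))
    if adjust:
        qs = multipletests([r.pvalue for r in results], method="fdr_bh")[1]
        results = [TestResult(r.label, r.method, r.statistic, r.pvalue,
                              float(q), r.n_per_group)
                   for r, q in zip(results, qs)]
    return results


def correlate_exposures_immune(exposures: pd.DataFrame,
                               densities: pd.DataFrame) -> list:
    """Kendall tau and Spearman rho of each signature against each immune
    marker/compartment column, unadjusted p-values.

    `densities` is indexed by sample_id with one column per
    marker/compartment (e.g. CD3_tumour); correlations use the samples
    present in both tables. Constant vectors give missing results.
    """
    common = exposures.index.intersection(densities.index)
    if len(common) < 3:
        raise PairedCNError("need >= 3 overlapping samples")
    E = exposures.loc[common]
    D = densities.loc[common]
    results = []
    for sig in E.columns:
        x = E[sig].to_numpy(float)
        for marker in D.columns:
            y = D[marker].to_numpy(float)
            label = f"{sig}~{marker}"
            if np.nanstd(x) == 0 or np.nanstd(y) == 0:
                for method in ("kendall", "spearman"):
                    results.append(TestResult(label=label, method=method,
                                              statistic=float("nan"),
                                              pvalue=float("nan"),
                                              n_per_group=(len(common),)))
                continue
            tau, p_t = stats.kendalltau(x, y)
            rho, p_s = stats.spearmanr(x, y)
            results.append(TestResult(label=label, method="kendall",
                                      statistic=float(tau), pvalue=float(p_t),
                                      n_per_group=(len(common),)))
            results.append(TestResult(label=label, method="spearman",
                                      statistic=float(rho), pvalue=float(p_s),
                                      n_per_group=(len(common),)))
    return results
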