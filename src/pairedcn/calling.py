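"""Absolute copy-number calling from binned shallow-WGS read counts.

Three stages, each an sklearn-style estimator with a thin functional
wrapper:

1. GC/mappability bias correction and median normalisation
   (``BiasCorrector`` / :func:`correct_bias`) producing a relative profile;
2. penalized changepoint segmentation on the log scale
   (``ProfileSegmenter`` / :func:`segment_profile`);
3. grid search over purity rho and tumour ploidy psi minimising the
   length-weighted squared distance of back-transformed segment values to
   the nearest non-negative integer (``PurityPloidyFitter`` /
   :func:`fit_purity_ploidy`), with quantitative QC.

The mixture inversion is

    n = ( r * [rho*psi + 2(1-rho)] - 2(1-rho) ) / rho

where r is the relative copy number normalised so that its length-weighted
genome mean is 1, psi is tumour ploidy and the non-tumour fraction is
modelled as diploid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .core import (AbsoluteProfile, BinnedCounts, DegenerateFitError,
                   PairedCNError, QCError, RelativeProfile, SegmentTable)
from .segmentation import default_penalty, pelt_l2

__all__ = [
    "BiasCorrector", "ProfileSegmenter", "PurityPloidyFitter",
    "correct_bias", "segment_profile", "to_absolute", "fit_purity_ploidy",
    "call_ploidy_change", "DEFAULT_PURITY_GRID", "DEFAULT_PLOIDY_GRID",
]

DEFAULT_PURITY_GRID = np.round(np.arange(0.20, 1.0 + 1e-9, 0.05), 10)
DEFAULT_PLOIDY_GRID = np.round(np.arange(1.6, 8.0 + 1e-9, 0.05), 10)


class BiasCorrector(BaseEstimator):
    """Two-stage median-binning GC then mappability correction.

    The GC and mappability factors are estimated from counts first
    normalised by their chromosome's median count (a coarse copy-number
    proxy): without this, a genome of widely separated copy levels makes
    the per-quantile count distribution multimodal and the quantile
    medians jump between levels, distorting the correction. The estimated
    factors are then applied to the raw counts, which are finally
    median-normalised to 1 over unmasked bins.

    Parameters
    ----------
    n_gc_bins, n_map_bins : int
        Number of quantile bins for each covariate fit.
    min_mappability : float
        Bins below this mappability are masked and excluded everywhere.
    min_bins : int
        Minimum unmasked bins required.
    """

    def __init__(self, n_gc_bins: int = 20, n_map_bins: int = 10,
                 min_mappability: float = 0.5, min_bins: int = 100):
        self.n_gc_bins = n_gc_bins
        self.n_map_bins = n_map_bins
        self.min_mappability = min_mappability
        self.min_bins = min_bins

    @staticmethod
    def _quantile_median_fit(values: np.ndarray, covariate: np.ndarray,
                             n_bins: int) -> np.ndarray:
        """Per-bin expected level from quantile-binned medians of `covariate`."""
        qs = np.quantile(covariate, np.linspace(0, 1, n_bins + 1))
        qs[0], qs[-1] = -np.inf, np.inf
        idx = np.clip(np.searchsorted(qs, covariate, side="right") - 1, 0, n_bins - 1)
        fit = np.ones_like(values)
        for b in range(n_bins):
            sel = idx == b
            if sel.any():
                med = np.median(values[sel])
                fit[sel] = med if med > 0 else 1.0
        return fit

    def transform(self, counts: BinnedCounts) -> RelativeProfile:
        df = counts.df
        raw = df["count"].to_numpy(np.float64)
        gc = df["gc"].to_numpy(np.float64)
        mapp = df["mappability"].to_numpy(np.float64)
        mask = (mapp < self.min_mappability) | ~np.isfinite(raw)
        if (~mask).sum() < self.min_bins:
            raise PairedCNError("too few unmasked bins for bias correction")
        ok = ~mask
        # coarse copy proxy: per-chromosome median of unmasked counts
        proxy = np.ones_like(raw)
        chroms = df["chrom"].to_numpy()
        for chrom in pd.unique(chroms):
            sel = (chroms == chrom) & ok
            if sel.any():
                med = np.median(raw[sel])
                proxy[chroms == chrom] = med if med > 0 else 1.0
        level = raw / proxy
        r = raw.copy()
        gc_fit = self._quantile_median_fit(level[ok], gc[ok], self.n_gc_bins)
        r[ok] = raw[ok] / gc_fit
        map_fit = self._quantile_median_fit(level[ok] / gc_fit, mapp[ok],
                                            self.n_map_bins)
        r[ok] = r[ok] / map_fit
        med = np.median(r[ok])
        if med <= 0:
            raise PairedCNError("median corrected count is zero; cannot normalise")
        r = r / med
        r[mask] = np.nan
        out = df[["chrom", "start", "end"]].copy()
        out["ratio"] = r
        return RelativeProfile(sample_id=counts.sample_id, role=counts.role,
                               df=out, mask=mask)


def correct_bias(counts: BinnedCounts, **kwargs) -> RelativeProfile:
    """GC/mappability-correct and median-normalise binned counts."""
    return BiasCorrector(**kwargs).transform(counts)


class ProfileSegmenter(BaseEstimator):
    """Penalized L2 changepoint segmentation of a relative profile.

    Detection runs per chromosome on a variance-stabilising sqrt scale
    (counts are near-Poisson at ~0.1x, so sqrt makes the noise level
    uniform across copy-number states, unlike log2 whose noise blows up
    in low-copy regions); reported segment values are linear-scale means
    of member bins. With penalty=None a BIC-like default
    (2 * sigma^2 * log n, robust sigma) is used per chromosome.
    """

    def __init__(self, penalty: float | None = None, min_size: int = 2):
        self.penalty = penalty
        self.min_size = min_size

    def transform(self, rel: RelativeProfile) -> SegmentTable:
        if self.penalty is not None and self.penalty <= 0:
            raise ValueError("penalty must be positive")
        rows = []
        for chrom, sub in rel.df.groupby("chrom", sort=False):
            keep = np.isfinite(sub["ratio"].to_numpy())
            sub = sub.loc[keep]
            if len(sub) == 0:
                continue
            ratio = sub["ratio"].to_numpy(np.float64)
            signal = np.sqrt(np.maximum(ratio, 0))
            pen = self.penalty if self.penalty is not None else default_penalty(signal)
            breaks = pelt_l2(signal, penalty=pen, min_size=min(self.min_size, len(signal)))
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            lo = 0
            for hi in breaks:
                rows.append((chrom, int(starts[lo]), int(ends[hi - 1]),
                             float(ratio[lo:hi].mean()), int(hi - lo)))
                lo = hi
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value", "n_bins"])
        return SegmentTable(df, space="relative")


def segment_profile(rel: RelativeProfile, penalty: float | None = None,
                    **kwargs) -> SegmentTable:
    """Piecewise-constant segmentation of a relative copy-number profile."""
    return ProfileSegmenter(penalty=penalty, **kwargs).transform(rel)


def to_absolute(r, purity: float, tumour_ploidy: float):
    """Invert the purity/ploidy mixture: relative -> absolute copy number.

    May return negative values for noisy low ratios; clipping happens only
    at reporting time.
    """
    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    if tumour_ploidy <= 0:
        raise ValueError("tumour_ploidy must be positive")
    r = np.asarray(r, dtype=np.float64)
    denom = purity * tumour_ploidy + 2 * (1 - purity)
    out = (r * denom - 2 * (1 - purity)) / purity
    return float(out) if out.ndim == 0 else out


class PurityPloidyFitter(BaseEstimator):
    """Grid search for the purity/ploidy pair best explaining a segmentation.

    For every (rho, psi) on the grid, segment values (rescaled internally to
    length-weighted mean 1, the scale the mixture model is written in) are
    transformed to absolute space and scored by the length-weighted mean
    squared distance to the nearest non-negative integer. Grid points
    scoring within a relative band of the minimum (score <= best * (1 +
    tie_tolerance)) are treated as statistically equivalent, and the most
    parsimonious is reported: lowest ploidy first, then highest purity.
    The band scales with the noise floor, so for noiseless profiles (best
    score ~ 0) only exact ties compete.

    The tie handling matters: an integer genome shifted up by c copies
    (n -> n + c) is an exact alternative fit at higher purity and ploidy
    psi + c, and with count noise such lattice alternatives score within
    noise of the truth. Preferring the lowest-ploidy equivalent fit
    recovers the truth whenever the genome anchors the lattice — a
    homozygous-deletion (state 0) segment blocks downshifts (its shifted
    value -1 contributes its genome fraction to the score, which must
    exceed tie_tolerance) and any odd state blocks halving.

    Fitted attributes: purity_, ploidy_, score_, qc_, profile_.
    """

    def __init__(self, purity_grid=None, ploidy_grid=None,
                 max_gof: float = 0.05, min_integer_fraction: float = 0.5,
                 integer_tolerance: float = 0.3, tie_tolerance: float = 0.5):
        self.purity_grid = purity_grid
        self.ploidy_grid = ploidy_grid
        self.max_gof = max_gof
        self.min_integer_fraction = min_integer_fraction
        self.integer_tolerance = integer_tolerance
        self.tie_tolerance = tie_tolerance

    @staticmethod
    def _score_grid(values, weights, rhos, psis):
        """Length-weighted MSE to nearest non-negative integer, all grid points.

        Returns array of shape (len(rhos), len(psis)).
        """
        r = values[None, None, :]
        rho = rhos[:, None, None]
        psi = psis[None, :, None]
        denom = rho * psi + 2 * (1 - rho)
        n = (r * denom - 2 * (1 - rho)) / rho
        resid = n - np.maximum(np.round(n), 0)
        w = weights / weights.sum()
        return np.einsum("ijk,k->ij", resid * resid, w)

    def fit(self, segments: SegmentTable, y=None):
        values = segments.values
        weights = segments.lengths
        if len(values) == 0:
            raise DegenerateFitError("empty segment table")
        distinct = np.unique(np.round(values, 6))
        if len(distinct) < 2:
            raise DegenerateFitError(
                "flat profile: purity/ploidy are unidentifiable; manual review needed")
        rhos = np.asarray(self.purity_grid if self.purity_grid is not None
                          else DEFAULT_PURITY_GRID, dtype=float)
        psis = np.asarray(self.ploidy_grid if self.ploidy_grid is not None
                          else DEFAULT_PLOIDY_GRID, dtype=float)
        # mixture model is written for mean-normalised ratios
        scale = np.average(values, weights=weights)
        if scale <= 0:
            raise DegenerateFitError("non-positive mean segment value")
        scores = self._score_grid(values / scale, weights, rhos, psis)
        best = scores.min()
        band = best * (1.0 + self.tie_tolerance) + 1e-12
        ties = np.argwhere(scores <= band)
        # lowest ploidy first, then highest purity
        order = np.lexsort((-rhos[ties[:, 0]], psis[ties[:, 1]]))
        i, j = ties[order[0]]
        self.purity_, self.ploidy_ = float(rhos[i]), float(psis[j])
        self.score_ = float(scores[i, j])
        abs_values = to_absolute(values / scale, self.purity_, self.ploidy_)
        dist = np.abs(abs_values - np.maximum(np.round(abs_values), 0))
        frac_integer = float(np.average(dist <= self.integer_tolerance, weights=weights))
        self.qc_ = {
            "goodness_of_fit": self.score_,
            "fraction_genome_near_integer": frac_integer,
            "pass": bool(self.score_ <= self.max_gof
                         and frac_integer >= self.min_integer_fraction),
        }
        seg_df = segments.df.copy()
        seg_df["value"] = abs_values
        self.segments_ = SegmentTable(seg_df, space="absolute")
        return self

    def profile(self, sample_id: str = "", role: str = "") -> AbsoluteProfile:
        return AbsoluteProfile(sample_id=sample_id, role=role,
                               purity=self.purity_, ploidy=self.ploidy_,
                               segments=self.segments_, qc=dict(self.qc_))


def fit_purity_ploidy(segments: SegmentTable, sample_id: str = "",
                      role: str = "", **kwargs) -> AbsoluteProfile:
    """Fit purity/ploidy by grid search and return the absolute profile."""
    fitter = PurityPloidyFitter(**kwargs)
    fitter.fit(segments)
    return fitter.profile(sample_id=sample_id, role=role)


def call_ploidy_change(diagnosis: AbsoluteProfile, relapse: AbsoluteProfile,
                       threshold: float = 0.5) -> str:
    """Classify the diagnosis-to-relapse ploidy change.

    Returns 'increased', 'decreased' or 'stable' against `threshold`
    (copies). Both profiles must pass QC.
    """
    for p in (diagnosis, relapse):
        if not p.qc_pass:
            raise QCError(f"sample {p.sample_id} failed QC: {p.qc}")
    delta = relapse.ploidy - diagnosis.ploidy
    if delta > threshold:
        return "increased"
    if delta < -threshold:
        return "decreased"
    return "stable"
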