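"""Core domain containers and package exceptions.

Containers are thin dataclasses around pandas DataFrames with the column
contracts used throughout the pipeline. All genomic intervals are 0-based,
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PairedCNError", "SchemaError", "ConfigurationError", "DegenerateFitError",
    "QCError", "BinnedCounts", "RelativeProfile", "SegmentTable",
    "AbsoluteProfile", "GroundTruth", "ClinicalRecord", "PairedCohort",
    "segments_to_bins",
]


class PairedCNError(Exception):
    """Base class for package errors."""


class SchemaError(PairedCNError):
    """A table violated its declared schema."""


class ConfigurationError(PairedCNError):
    """Invalid configuration keys or values."""


class DegenerateFitError(PairedCNError):
    """Purity/ploidy fit is unidentifiable (e.g. flat profile)."""


class QCError(PairedCNError):
    """An operation required a QC-passing profile and did not get one."""


def _check_sorted_intervals(df: pd.DataFrame, what: str) -> None:
    if (df["end"] <= df["start"]).any():
        bad = df.index[df["end"] <= df["start"]][0]
        raise SchemaError(f"{what}: end <= start at row {bad}")
    for _, sub in df.groupby("chrom", sort=False):
        if not sub["start"].is_monotonic_increasing:
            raise SchemaError(f"{what}: intervals not sorted by start")


@dataclass
class BinnedCounts:
    """Per-bin raw read counts with GC/mappability annotations for one sample.

    df columns: chrom, start, end, gc, mappability, count.
    """

    sample_id: str
    role: str
    df: pd.DataFrame

    def __post_init__(self):
        required = ["chrom", "start", "end", "gc", "mappability", "count"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"BinnedCounts missing columns: {missing}")
        _check_sorted_intervals(self.df, "BinnedCounts")
        for col in ("gc", "mappability"):
            vals = self.df[col].to_numpy(float)
            if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                raise SchemaError(f"BinnedCounts: {col} outside [0, 1]")
        if (self.df["count"].to_numpy(float) < 0).any():
            raise SchemaError("BinnedCounts: negative counts")

    @property
    def n_bins(self) -> int:
        return len(self.df)


@dataclass
class RelativeProfile:
    """Bias-corrected, median-normalised relative copy number per bin.

    df columns: chrom, start, end, ratio. `mask` marks excluded bins
    (True = masked out).
    """

    sample_id: str
    role: str
    df: pd.DataFrame
    mask: np.ndarray

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if len(self.mask) != len(self.df):
            raise SchemaError("RelativeProfile: mask length mismatch")

    @property
    def unmasked(self) -> pd.DataFrame:
        return self.df.loc[~self.mask]


@dataclass
class SegmentTable:
    """Piecewise-constant segments: chrom, start, end, value, n_bins.

    `space` flags whether `value` is relative or absolute copy number.
    """

    df: pd.DataFrame
    space: str = "relative"

    def __post_init__(self):
        required = ["chrom", "start", "end", "value", "n_bins"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise SchemaError(f"SegmentTable missing columns: {missing}")
        if self.space not in ("relative", "absolute"):
            raise SchemaError(f"invalid segment space {self.space!r}")
        _check_sorted_intervals(self.df, "SegmentTable")

    @property
    def lengths(self) -> np.ndarray:
        return (self.df["end"] - self.df["start"]).to_numpy(np.float64)

    @property
    def values(self) -> np.ndarray:
        return self.df["value"].to_numpy(np.float64)

    def length_weighted_mean(self) -> float:
        w = self.lengths
        return float(np.average(self.values, weights=w))


@dataclass
class AbsoluteProfile:
    """Fitted absolute copy-number profile with purity/ploidy and QC."""

    sample_id: str
    role: str
    purity: float
    ploidy: float
    segments: SegmentTable
    qc: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0, 1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if self.segments.space != "absolute":
            raise ValueError("AbsoluteProfile requires absolute-space segments")

    @property
    def qc_pass(self) -> bool:
        return bool(self.qc.get("pass", True))


def segments_to_bins(segments: SegmentTable, layout) -> pd.DataFrame:
    """Expand a segment table to the layout's bin grid.

    Returns the layout bins with a `value` column carrying the covering
    segment's value (NaN where no segment covers the bin midpoint).
    """
    bins = layout.bins()
    values = np.full(len(bins), np.nan)
    mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
    for chrom, seg in segments.df.groupby("chrom", sort=False):
        sel = (bins["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts = seg["start"].to_numpy()
        ends = seg["end"].to_numpy()
        vals = seg["value"].to_numpy(np.float64)
        idx = np.searchsorted(starts, mid[sel], side="right") - 1
        ok = (idx >= 0) & (mid[sel] < ends[np.clip(idx, 0, len(ends) - 1)])
        out = np.full(sel.sum(), np.nan)
        out[ok] = vals[idx[ok]]
        values[sel] = out
    bins = bins.copy()
    bins["value"] = values
    return bins


@dataclass
class GroundTruth:
    """Known simulation truth for one sample."""

    patient_id: str
    sample_id: str
    role: str
    purity: float
    tumour_ploidy: float
    segments: pd.DataFrame  # chrom, start, end, cn (integer states)
    exposures: np.ndarray
    depth: float

    def __post_init__(self):
        self.exposures = np.asarray(self.exposures, dtype=float)
        if abs(self.exposures.sum() - 1.0) > 1e-9:
            raise ValueError("exposures must sum to 1")
        if (self.exposures < 0).any():
            raise ValueError("exposures must be non-negative")
        cn = self.segments["cn"].to_numpy()
        if (cn < 0).any() or not np.allclose(cn, np.round(cn)):
            raise ValueError("truth copy numbers must be non-negative integers")

    @property
    def segment_table(self) -> SegmentTable:
        df = self.segments.rename(columns={"cn": "value"}).copy()
        df["value"] = df["value"].astype(float)
        if "n_bins" not in df.columns:
            df["n_bins"] = 0
        return SegmentTable(df[["chrom", "start", "end", "value", "n_bins"]],
                            space="absolute")


@dataclass
class ClinicalRecord:
    """Per-patient clinical annotations used for cohort stratification."""

    patient_id: str
    platinum_status: str  # sensitive | resistant
    primary_platinum_resistant: bool
    prior_lines: int
    diagnosis_to_registration: float  # months
    tissue_site: str
    brca_status: str  # mutant | wildtype
    relapse_interval_months: float = float("nan")

    def __post_init__(self):
        if self.platinum_status not in ("sensitive", "resistant"):
            raise ValueError("platinum_status must be sensitive/resistant")
        if self.prior_lines < 1:
            raise ValueError("prior_lines must be >= 1")
        # Platinum sensitivity rule: resistant iff relapse < 6 months after
        # the last platinum-based chemotherapy.
        if np.isfinite(self.relapse_interval_months):
            expected = "resistant" if self.relapse_interval_months < 6 else "sensitive"
            if self.platinum_status != expected:
                raise ValueError("platinum_status inconsistent with relapse interval")


@dataclass
class PairedCohort:
    """Patient-keyed diagnosis/relapse collection.

    samples: {patient_id: {"diagnosis": obj, "relapse": obj}} holding any
    per-sample payload (BinnedCounts, AbsoluteProfile, ...).
    clinical: {patient_id: ClinicalRecord}.
    """

    samples: dict
    clinical: dict = field(default_factory=dict)

    def __post_init__(self):
        for pid, pair in self.samples.items():
            if set(pair) != {"diagnosis", "relapse"}:
                raise ValueError(f"patient {pid}: needs one diagnosis and one relapse")

    @property
    def patients(self) -> list:
        return list(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def pairs(self):
        for pid, pair in self.samples.items():
            yield pid, pair["diagnosis"], pair["relapse"]
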