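"""Intra-tumour heterogeneity (ITH) from absolute copy-number profiles.

ITH is the length-weighted average distance of segment copy numbers from
the nearest non-negative integer state:

    ith = sum_seg len(seg) * |cn(seg) - nearest_int(cn(seg))| / sum_seg len(seg)

A fully clonal (integer) genome has ith = 0; the per-segment distance is
bounded by 0.5, so ith <= 0.5. Exact half-integers tie to the lower state
(the distance is 0.5 either way). Lengths are in bp; masked bins never
reach the segment table so they carry no weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AbsoluteProfile, PairedCNError, QCError, SegmentTable
from .simulate import GroundTruth

__all__ = ["ITHResult", "compute_ith", "compute_delta_ith"]


@dataclass(frozen=True)
class ITHResult:
    sample_id: str
    role: str
    ith: float

    def __post_init__(self):
        if self.ith < 0:
            raise ValueError("ith must be non-negative")


def _nearest_state_distance(values: np.ndarray) -> np.ndarray:
    # np.round half-to-even would report x.5 against the even neighbour;
    # floor(x + 0.5) ties to the lower state explicitly. Distance is 0.5
    # either way; only the reported state differs.
    nearest = np.maximum(np.floor(values + 0.5), 0.0)
    return np.abs(values - nearest)


def compute_ith(profile: AbsoluteProfile, require_qc: bool = True) -> ITHResult:
    """Length-weighted mean distance from integer copy states."""
    if require_qc and not profile.qc_pass:
        raise QCError(f"profile {profile.sample_id} failed QC")
    seg = profile.segments
    if len(seg.df) == 0:
        raise PairedCNError("empty segment table")
    dist = _nearest_state_distance(seg.values)
    ith = float(np.average(dist, weights=seg.lengths))
    return ITHResult(sample_id=profile.sample_id, role=profile.role, ith=ith)


def compute_delta_ith(diagnosis: ITHResult, relapse: ITHResult) -> float:
    """ITH change between diagnosis and relapse of the same patient."""
    if diagnosis.role != "diagnosis" or relapse.role != "relapse":
        raise PairedCNError(
            f"role mismatch: got ({diagnosis.role!r}, {relapse.role!r}), "
            "expected (diagnosis, relapse)")
    return relapse.ith - diagnosis.ith


def _profile_from_truth(truth: GroundTruth) -> AbsoluteProfile:
    """Wrap simulation ground truth as a QC-passing absolute profile.

    Used for oracle paths that bypass count noise and fitting.
    """
    return AbsoluteProfile(
        sample_id=truth.sample_id, role=truth.role, purity=truth.purity,
        ploidy=truth.tumour_ploidy, segments=truth.segment_table,
        qc={"goodness_of_fit": 0.0, "fraction_genome_near_integer": 1.0,
            "pass": True},
    )
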