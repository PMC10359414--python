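"""Synthetic paired diagnosis/relapse cohort generator.

Emulates the inputs of a shallow-WGS (~0.1x) copy-number study: paired
tumour genomes with known purity, ploidy, integer segment structure and
signature exposures, plus binned read counts with GC/mappability bias and
clinical labels assigned by the platinum-interval rule (resistant iff
relapse < 6 months after the last platinum-based chemotherapy).

Every stochastic operation takes an explicit seed; there is no global RNG
state. Simulation starts at binned counts — no reads, no alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .core import (BinnedCounts, ClinicalRecord, ConfigurationError,
                   GroundTruth, PairedCohort)
from .genome import GenomeLayout, toy_layout

__all__ = [
    "BiasParams", "CohortConfig", "SimulatedCohort",
    "simulate_signature_definitions", "simulate_cn_profile", "derive_relapse",
    "emit_binned_counts", "simulate_paired_cohort", "annotate_bins",
    "default_gene_panel", "calibrate_signature_definitions",
    "SIGNATURE_EVENT_STYLES",
]

N_SIGNATURES = 7

# Event style behind each synthetic signature. Styles are chosen so the
# seven signatures produce contrasting values of the six copy-number
# features (e.g. the first style makes few breakpoints and large segments;
# focal styles make many short segments and high change-points).
SIGNATURE_EVENT_STYLES = (
    "large_segment",    # s1: few breakpoints, large segments, +/-1
    "whole_arm",        # s2: arm-level gain/loss
    "focal_amp",        # s3: short high-level amplifications
    "focal_del",        # s4: short deletions
    "oscillating",      # s5: chains alternating between two states
    "chromothripsis",   # s6: localised shattering
    "whole_chromosome", # s7: whole-chromosome gain/loss
)


@dataclass(frozen=True)
class BiasParams:
    """Bin-level count model parameters.

    Expected count per bin:
        depth * [rho*n + 2(1-rho)] / [rho*psi + 2(1-rho)]
              * gc_bias(gc) * mappability**mappability_exponent
    with gc_bias(g) = max(1 + a1*(g-0.45) + a2*(g-0.45)^2, 0.05).
    Counts are Poisson when dispersion == 0, else negative binomial with
    Var = mu + dispersion * mu^2.

    depth defaults to 60 reads/bin: 0.1x coverage of 30 kb bins with
    50 bp single-end reads (0.1 * 30000 / 50).
    """

    depth: float = 60.0
    dispersion: float = 0.0
    gc_linear: float = 0.8
    gc_quad: float = -6.0
    mappability_exponent: float = 1.0

    def gc_bias(self, gc: np.ndarray) -> np.ndarray:
        d = np.asarray(gc, dtype=float) - 0.45
        return np.maximum(1.0 + self.gc_linear * d + self.gc_quad * d * d, 0.05)


FLAT_BIAS = BiasParams(gc_linear=0.0, gc_quad=0.0, mappability_exponent=0.0)


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition knobs for :func:`simulate_paired_cohort`."""

    event_budget: int = 10
    tetraploid_fraction: float = 0.25
    purity_min: float = 0.35
    purity_max: float = 0.95
    exposure_alpha: float = 1.5
    within_patient_clr_sd: float = 0.15
    perturbation: str = "none"          # none | planted_region | ploidy_shift
    perturbation_params: dict = field(default_factory=dict)
    platinum_resistant_fraction: float = 0.24
    primary_resistant_fraction: float = 0.09
    brca_mutant_fraction: float = 0.19
    bias: BiasParams = field(default_factory=BiasParams)

    def __post_init__(self):
        if self.event_budget < 0:
            raise ConfigurationError("event_budget must be >= 0")
        if not (0 < self.purity_min <= self.purity_max <= 1):
            raise ConfigurationError("purity range must satisfy 0 < min <= max <= 1")
        for name in ("tetraploid_fraction", "platinum_resistant_fraction",
                     "primary_resistant_fraction", "brca_mutant_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.perturbation not in ("none", "planted_region", "ploidy_shift"):
            raise ConfigurationError(f"unknown perturbation {self.perturbation!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {unknown}")
        d = dict(d)
        if "bias" in d and isinstance(d["bias"], dict):
            d["bias"] = BiasParams(**d["bias"])
        return cls(**d)


def simulate_signature_definitions(n_components: int, n_signatures: int,
                                   seed: int, identity: bool = False,
                                   max_retries: int = 20) -> np.ndarray:
    """Random column-stochastic signature-definition matrix (K x S).

    Columns are sparse-ish Dirichlet draws, retried until the matrix has
    full column rank. With identity=True (requires K == S) returns the
    identity, making exposures directly readable from encodings.
    """
    if not (n_components >= n_signatures >= 2):
        raise ValueError("need n_components >= n_signatures >= 2")
    if identity:
        if n_components != n_signatures:
            raise ValueError("identity option requires square matrix")
        return np.eye(n_components)
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        raw = rng.gamma(shape=0.3, scale=1.0, size=(n_components, n_signatures))
        raw = np.maximum(raw, 1e-12)
        S = raw / raw.sum(axis=0, keepdims=True)
        if np.linalg.matrix_rank(S) == n_signatures:
            return S
    raise RuntimeError("failed to draw a full-rank signature matrix")


# ---------------------------------------------------------------------------
# copy-number profile simulation (bin-resolution event model)
# ---------------------------------------------------------------------------

def _chrom_bin_slices(layout: GenomeLayout) -> dict:
    out, offset = {}, 0
    for name in layout.chrom_names:
        nb = layout.n_bins(name)
        out[name] = slice(offset, offset + nb)
        offset += nb
    return out


def _apply_event(cn: np.ndarray, layout: GenomeLayout, style: str,
                 rng: np.random.Generator) -> None:
    """Mutate the per-bin integer copy-number array in place."""
    bs = layout.bin_size
    slices = _chrom_bin_slices(layout)
    chrom = rng.choice(layout.chrom_names)
    sl = slices[chrom]
    n_chrom = sl.stop - sl.start
    cen_bin = int(layout.arm_boundaries.get(chrom, 0)) // bs
    arms = [(0, cen_bin), (cen_bin, n_chrom)] if 0 < cen_bin < n_chrom else [(0, n_chrom)]
    a0, a1 = arms[rng.integers(len(arms))]
    arm_len = a1 - a0

    def local(start, stop, delta):
        lo, hi = sl.start + max(start, 0), sl.start + min(stop, n_chrom)
        if hi > lo:
            cn[lo:hi] = np.maximum(cn[lo:hi] + delta, 0)

    if style == "large_segment":
        length = max(int(arm_len * rng.uniform(0.3, 0.8)), 1)
        start = a0 + int(rng.integers(0, max(arm_len - length, 0) + 1))
        local(start, start + length, rng.choice([-1, 1]))
    elif style == "whole_arm":
        local(a0, a1, rng.choice([-1, 1]))
    elif style == "focal_amp":
        length = max(int(rng.uniform(0.3e6, 3e6) / bs), 1)
        start = a0 + int(rng.integers(0, max(arm_len - length, 0) + 1))
        local(start, start + length, int(rng.integers(3, 9)))
    elif style == "focal_del":
        length = max(int(rng.uniform(0.3e6, 3e6) / bs), 1)
        start = a0 + int(rng.integers(0, max(arm_len - length, 0) + 1))
        local(start, start + length, -int(rng.integers(1, 3)))
    elif style == "oscillating":
        n_blocks = int(rng.integers(4, 11))
        block = max(int(rng.uniform(0.5e6, 2e6) / bs), 1)
        start = a0 + int(rng.integers(0, max(arm_len - n_blocks * block, 0) + 1))
        for b in range(n_blocks):
            if b % 2 == 1:
                local(start + b * block, start + (b + 1) * block, 1)
    elif style == "chromothripsis":
        window = max(int(rng.uniform(10e6, 30e6) / bs), 4)
        window = min(window, arm_len)
        start = a0 + int(rng.integers(0, max(arm_len - window, 0) + 1))
        n_pieces = int(rng.integers(8, 21))
        cuts = np.sort(rng.choice(np.arange(1, window), size=min(n_pieces - 1, window - 1),
                                  replace=False))
        bounds = np.concatenate([[0], cuts, [window]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            local(start + lo, start + hi, int(rng.integers(-1, 3)))
    elif style == "whole_chromosome":
        delta = int(rng.choice([-1, 1]))
        cn[sl] = np.maximum(cn[sl] + delta, 0)
    else:
        raise ValueError(f"unknown event style {style!r}")


def _bins_to_segments(cn: np.ndarray, layout: GenomeLayout) -> pd.DataFrame:
    """Merge equal adjacent bins into a segment table (exact genome tiling)."""
    rows = []
    slices = _chrom_bin_slices(layout)
    bs = layout.bin_size
    for chrom, length in layout.chromosomes:
        sub = cn[slices[chrom]]
        change = np.flatnonzero(np.diff(sub)) + 1
        bounds = np.concatenate([[0], change, [len(sub)]])
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(lo * bs), int(min(hi * bs, length)),
                         int(sub[lo]), int(hi - lo)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cn", "n_bins"])


def simulate_cn_profile(layout: GenomeLayout, exposures: np.ndarray,
                        event_budget: int, seed: int,
                        baseline_ploidy: int = 2, purity: float = 1.0,
                        depth: float = 60.0, patient_id: str = "P0",
                        sample_id: str | None = None,
                        role: str = "diagnosis") -> GroundTruth:
    """Simulate an integer copy-number genome driven by signature exposures.

    Event classes are drawn proportional to the exposure vector, one class
    per signature (see SIGNATURE_EVENT_STYLES). Losses are clipped at zero.
    """
    exposures = np.asarray(exposures, dtype=float)
    if exposures.shape != (N_SIGNATURES,):
        raise ValueError(f"exposures must have length {N_SIGNATURES}")
    if (exposures < 0).any() or abs(exposures.sum() - 1) > 1e-9:
        raise ValueError("exposures must be a simplex vector")
    if event_budget < 0:
        raise ValueError("event_budget must be >= 0")
    rng = np.random.default_rng(seed)
    cn = np.full(layout.n_bins(), int(baseline_ploidy), dtype=np.int64)
    for _ in range(int(event_budget)):
        style = SIGNATURE_EVENT_STYLES[rng.choice(N_SIGNATURES, p=exposures)]
        _apply_event(cn, layout, style, rng)
    segments = _bins_to_segments(cn, layout)
    lengths = (segments["end"] - segments["start"]).to_numpy(float)
    ploidy = float(np.average(segments["cn"].to_numpy(float), weights=lengths))
    return GroundTruth(
        patient_id=patient_id,
        sample_id=sample_id or f"{patient_id}-{role}",
        role=role, purity=float(purity), tumour_ploidy=ploidy,
        segments=segments, exposures=exposures, depth=float(depth),
    )


def derive_relapse(diagnosis: GroundTruth, perturbation: str = "none",
                   params: dict | None = None, seed: int = 0,
                   layout: GenomeLayout | None = None) -> GroundTruth:
    """Derive the relapse genome of a patient from its diagnosis genome.

    perturbation:
      none          -> identical segments
      planted_region-> params {chrom, start, end, delta}: CN shifted by
                       delta inside the declared interval
      ploidy_shift  -> all states scaled toward a doubled genome
    """
    params = params or {}
    seg = diagnosis.segments.copy()
    if perturbation == "none":
        pass
    elif perturbation == "planted_region":
        chrom, start, end = params["chrom"], int(params["start"]), int(params["end"])
        delta = int(params.get("delta", 2))
        if layout is not None:
            if chrom not in layout.chrom_names or end > layout.chrom_lengths[chrom] or start < 0:
                raise ValueError("planted interval outside genome")
        if start >= end:
            raise ValueError("planted interval is empty")
        seg = _shift_region(seg, chrom, start, end, delta)
    elif perturbation == "ploidy_shift":
        seg["cn"] = seg["cn"].to_numpy() * 2
    else:
        raise ValueError(f"unknown perturbation {perturbation!r}")
    lengths = (seg["end"] - seg["start"]).to_numpy(float)
    ploidy = float(np.average(seg["cn"].to_numpy(float), weights=lengths))
    return GroundTruth(
        patient_id=diagnosis.patient_id,
        sample_id=f"{diagnosis.patient_id}-relapse",
        role="relapse", purity=diagnosis.purity, tumour_ploidy=ploidy,
        segments=seg.reset_index(drop=True), exposures=diagnosis.exposures,
        depth=diagnosis.depth,
    )


def _shift_region(seg: pd.DataFrame, chrom: str, start: int, end: int,
                  delta: int) -> pd.DataFrame:
    """Shift CN by delta in [start, end) of chrom, splitting segments."""
    rows = []
    for row in seg.itertuples(index=False):
        if row.chrom != chrom or row.end <= start or row.start >= end:
            rows.append((row.chrom, row.start, row.end, row.cn))
            continue
        if row.start < start:
            rows.append((row.chrom, row.start, start, row.cn))
        lo, hi = max(row.start, start), min(row.end, end)
        rows.append((row.chrom, lo, hi, max(row.cn + delta, 0)))
        if row.end > end:
            rows.append((row.chrom, end, row.end, row.cn))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn"])
    out["n_bins"] = 0
    return out


# ---------------------------------------------------------------------------
# binned read counts
# ---------------------------------------------------------------------------

def annotate_bins(layout: GenomeLayout, seed: int = 0) -> pd.DataFrame:
    """Per-bin GC fraction and mappability for a layout.

    GC is a smoothed random walk around 0.45 (emulating regional GC
    structure); mappability is near 1 with a low tail.
    """
    rng = np.random.default_rng(seed)
    bins = layout.bins()
    n = len(bins)
    # GC must vary mostly bin-to-bin (as it does at 30 kb): a GC track as
    # smooth as the segment structure would confound bias correction with
    # copy number.
    walk = np.cumsum(rng.normal(0, 0.0008, size=n))
    kernel = np.ones(25) / 25
    smooth = np.convolve(walk - walk.mean(), kernel, mode="same")
    gc = np.clip(0.45 + smooth + rng.normal(0, 0.03, size=n), 0.25, 0.65)
    mappability = np.clip(rng.beta(50, 2, size=n), 0.0, 1.0)
    bins["gc"] = gc
    bins["mappability"] = mappability
    return bins


def expected_counts(truth: GroundTruth, annotations: pd.DataFrame,
                    bias: BiasParams) -> np.ndarray:
    """Expected reads per bin under the purity/ploidy mixture model."""
    rho, psi = truth.purity, truth.tumour_ploidy
    cn_bins = _truth_cn_per_bin(truth, annotations)
    tumour_frac = (rho * cn_bins + 2 * (1 - rho)) / (rho * psi + 2 * (1 - rho))
    mu = truth.depth * tumour_frac
    mu = mu * bias.gc_bias(annotations["gc"].to_numpy())
    mu = mu * annotations["mappability"].to_numpy() ** bias.mappability_exponent
    return mu


def _truth_cn_per_bin(truth: GroundTruth, bins: pd.DataFrame) -> np.ndarray:
    cn = np.full(len(bins), np.nan)
    mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
    for chrom, seg in truth.segments.groupby("chrom", sort=False):
        sel = (bins["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        starts, ends = seg["start"].to_numpy(), seg["end"].to_numpy()
        vals = seg["cn"].to_numpy(float)
        idx = np.searchsorted(starts, mid[sel], side="right") - 1
        ok = (idx >= 0) & (mid[sel] < ends[np.clip(idx, 0, len(ends) - 1)])
        out = np.full(sel.sum(), np.nan)
        out[ok] = vals[idx[ok]]
        cn[sel] = out
    if np.isnan(cn).any():
        raise ValueError("truth segments do not tile the genome")
    return cn


def emit_binned_counts(truth: GroundTruth, layout: GenomeLayout,
                       bias: BiasParams | None = None, seed: int = 0,
                       annotations: pd.DataFrame | None = None) -> BinnedCounts:
    """Draw noisy binned read counts for one sample.

    Counts are Poisson(mu) when bias.dispersion == 0, else gamma-Poisson
    (negative binomial) with Var = mu + dispersion * mu^2.
    """
    bias = bias or BiasParams()
    if truth.depth <= 0:
        raise ValueError("depth must be positive")
    if annotations is None:
        annotations = annotate_bins(layout, seed=0)
    rng = np.random.default_rng(seed)
    mu = expected_counts(truth, annotations, bias)
    if bias.dispersion > 0:
        lam = mu * rng.gamma(shape=1.0 / bias.dispersion,
                             scale=bias.dispersion, size=len(mu))
        counts = rng.poisson(lam)
    else:
        counts = rng.poisson(mu)
    df = annotations[["chrom", "start", "end", "gc", "mappability"]].copy()
    df["count"] = counts
    return BinnedCounts(sample_id=truth.sample_id, role=truth.role, df=df)


# ---------------------------------------------------------------------------
# paired cohort
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCohort:
    """Everything a downstream test needs: counts, truth and clinical."""

    layout: GenomeLayout
    counts: PairedCohort
    truths: dict          # patient_id -> {"diagnosis": GroundTruth, "relapse": ...}
    clinical: dict        # patient_id -> ClinicalRecord
    annotations: pd.DataFrame
    config: CohortConfig

    def clinical_frame(self) -> pd.DataFrame:
        rows = []
        for pid, rec in self.clinical.items():
            rows.append({
                "patient_id": pid, "platinum_status": rec.platinum_status,
                "primary_platinum_resistant": rec.primary_platinum_resistant,
                "prior_lines": rec.prior_lines,
                "diagnosis_to_registration": rec.diagnosis_to_registration,
                "tissue_site": rec.tissue_site, "brca_status": rec.brca_status,
                "relapse_interval_months": rec.relapse_interval_months,
            })
        return pd.DataFrame(rows)


_TISSUES = ("abdominal", "lymph node", "pelvic", "peritoneal", "other")


def _simulate_clinical(patient_id: str, cfg: CohortConfig,
                       rng: np.random.Generator) -> ClinicalRecord:
    primary = bool(rng.random() < cfg.primary_resistant_fraction)
    if primary:
        resistant, prior_lines = True, 1
    else:
        residual = max(cfg.platinum_resistant_fraction - cfg.primary_resistant_fraction, 0.0)
        resistant = bool(rng.random() < residual / max(1 - cfg.primary_resistant_fraction, 1e-12))
        prior_lines = 1 + int(rng.poisson(0.9 if resistant else 0.5))
    interval = float(rng.uniform(1, 6)) if resistant else float(6 + rng.lognormal(2.3, 0.7))
    return ClinicalRecord(
        patient_id=patient_id,
        platinum_status="resistant" if resistant else "sensitive",
        primary_platinum_resistant=primary,
        prior_lines=prior_lines,
        diagnosis_to_registration=float(np.round(rng.lognormal(3.4, 0.5), 1)),
        tissue_site=str(rng.choice(_TISSUES)),
        brca_status="mutant" if rng.random() < cfg.brca_mutant_fraction else "wildtype",
        relapse_interval_months=interval,
    )


def _sample_exposures(base: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    z = np.log(base) + rng.normal(0, sd, size=len(base))
    e = np.exp(z - z.max())
    return e / e.sum()


def simulate_paired_cohort(n_patients: int, config: CohortConfig | dict | None = None,
                           seed: int = 0, layout: GenomeLayout | None = None
                           ) -> SimulatedCohort:
    """Simulate a full paired cohort: one diagnosis and one relapse per patient.

    Ground truth (purity, ploidy, segments, exposures) is retained for
    parameter-recovery tests. Clinical labels follow the platinum-interval
    rule and the configured resistant fractions.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if config is None:
        config = CohortConfig()
    elif isinstance(config, dict):
        config = CohortConfig.from_dict(config)
    layout = layout or toy_layout()
    rng = np.random.default_rng(seed)
    annotations = annotate_bins(layout, seed=int(rng.integers(2**31)))

    samples, truths, clinical = {}, {}, {}
    for i in range(n_patients):
        pid = f"CASE-{i + 1:03d}"
        clinical[pid] = _simulate_clinical(pid, config, rng)
        base = rng.dirichlet(np.full(N_SIGNATURES, config.exposure_alpha))
        baseline = 4 if rng.random() < config.tetraploid_fraction else 2
        purity_dx = float(rng.uniform(config.purity_min, config.purity_max))
        purity_rl = float(rng.uniform(config.purity_min, config.purity_max))
        e_dx = _sample_exposures(base, config.within_patient_clr_sd, rng)
        dx = simulate_cn_profile(
            layout, e_dx, config.event_budget, seed=int(rng.integers(2**31)),
            baseline_ploidy=baseline, purity=purity_dx, depth=config.bias.depth,
            patient_id=pid, sample_id=f"{pid}-diagnosis", role="diagnosis")
        rl = derive_relapse(dx, config.perturbation, config.perturbation_params,
                            seed=int(rng.integers(2**31)), layout=layout)
        rl = replace(rl, purity=purity_rl,
                     exposures=_sample_exposures(base, config.within_patient_clr_sd, rng))
        truths[pid] = {"diagnosis": dx, "relapse": rl}
        samples[pid] = {
            "diagnosis": emit_binned_counts(dx, layout, config.bias,
                                            seed=int(rng.integers(2**31)),
                                            annotations=annotations),
            "relapse": emit_binned_counts(rl, layout, config.bias,
                                          seed=int(rng.integers(2**31)),
                                          annotations=annotations),
        }
    return SimulatedCohort(layout=layout, counts=PairedCohort(samples, clinical),
                           truths=truths, clinical=clinical,
                           annotations=annotations, config=config)


# ---------------------------------------------------------------------------
# fixtures for downstream stages
# ---------------------------------------------------------------------------

# 18 genes frequently altered in HGSC (real names; coordinates are synthetic
# positions on the reduced toy genome, NOT their genomic loci).
_PANEL_GENES = (
    "TP53", "BRCA1", "BRCA2", "KRAS", "CCNE1", "MYC", "MECOM", "AKT1",
    "AKT2", "AKT3", "CCND1", "CCND2", "CDK12", "NF1", "RB1", "PTEN",
    "PIK3CA", "TERT",
)


def default_gene_panel(layout: GenomeLayout | None = None,
                       gene_width: int = 120_000) -> pd.DataFrame:
    """Synthetic 18-gene HGSC panel laid out evenly across the genome.

    Gene names are the field's usual suspects; the intervals are synthetic
    stand-ins placed deterministically on the working layout so the panel
    is always inside the genome.
    """
    layout = layout or toy_layout()
    per_chrom = int(np.ceil(len(_PANEL_GENES) / len(layout.chrom_names)))
    rows, gi = [], 0
    for chrom, length in layout.chromosomes:
        for k in range(per_chrom):
            if gi >= len(_PANEL_GENES):
                break
            start = int(length * (k + 1) / (per_chrom + 1))
            start -= start % layout.bin_size
            rows.append((chrom, start, min(start + gene_width, length),
                         _PANEL_GENES[gi]))
            gi += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def simulate_recovery_profile(layout: GenomeLayout, purity: float,
                              ploidy: int, seed: int, n_segments: int = 24):
    """Noiseless relative profile with known purity and exact integer-mean
    ploidy, for purity/ploidy recovery checks.

    The genome has >= 5 distinct integer states, a guaranteed
    homozygous-deletion (state 0) region anchoring the copy-number lattice,
    and length-weighted mean copy number exactly `ploidy`. Returns
    (relative SegmentTable, per-bin true integer states).

    The relative values are the exact mixture-model expectations
    (rho*n + 2(1-rho)) / (rho*psi + 2(1-rho)); no count noise.
    """
    from .core import SegmentTable  # avoid import cycle at module load

    if not (0 < purity <= 1):
        raise ValueError("purity must be in (0, 1]")
    if ploidy < 2:
        raise ValueError("ploidy must be an integer >= 2")
    rng = np.random.default_rng(seed)
    nb = layout.n_bins()
    states = sorted({0, ploidy - 1, ploidy, ploidy + 1, ploidy + 2})
    for _ in range(100):
        cuts = np.sort(rng.choice(np.arange(1, nb), size=n_segments - 1,
                                  replace=False))
        bounds = np.concatenate([[0], cuts, [nb]])
        cn = np.empty(nb, dtype=np.int64)
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            cn[lo:hi] = rng.choice(states)
        # pin a state-0 anchor (~2% of genome), then balance the rest so the
        # mean is exactly `ploidy`
        anchor = max(nb // 50, 1)
        cn[:anchor] = 0
        delta = ploidy * nb - int(cn.sum())
        guard = 0
        while delta != 0 and guard < 200:
            # contiguous block adjustment keeps the segment count small
            step = 1 if delta > 0 else -1
            k = int(min(abs(delta), (nb - anchor) // 4))
            start = int(rng.integers(anchor, nb - k)) if k < nb - anchor else anchor
            idx = np.arange(start, start + max(k, 1))
            ok = cn[idx] + step >= 1  # never disturb the zero anchor states
            cn[idx[ok]] += step
            delta = ploidy * nb - int(cn.sum())
            guard += 1
        if delta == 0 and len(np.unique(cn)) >= 5:
            break
    else:
        raise RuntimeError("could not construct a balanced recovery profile")

    denom = purity * ploidy + 2 * (1 - purity)
    seg_df = _bins_to_segments(cn, layout).rename(columns={"cn": "value"})
    seg_df["value"] = (purity * seg_df["value"] + 2 * (1 - purity)) / denom
    seg = SegmentTable(seg_df[["chrom", "start", "end", "value", "n_bins"]],
                       space="relative")
    return seg, cn


def calibrate_signature_definitions(component_model, layout: GenomeLayout,
                                    seed: int = 0, n_reps: int = 8,
                                    event_budget: int = 10,
                                    baseline_ploidy: int = 2,
                                    return_mass: bool = False):
    """Monte-Carlo signature definitions consistent with the event model.

    For each signature, simulates genomes with a one-hot exposure vector,
    extracts the six copy-number features from the true segments, encodes
    them against `component_model` and averages the encodings. Returns a
    column-stochastic (K x 7) matrix; with return_mass=True also returns
    the mean total encoding mass per pure genome for each class, which
    converts NNLS feature-mass shares back to event-count shares.
    """
    from .heterogeneity import _profile_from_truth  # local import, no cycle
    from .signatures import encode_sample, extract_features

    rng = np.random.default_rng(seed)
    cols, mass = [], []
    for j in range(N_SIGNATURES):
        e = np.zeros(N_SIGNATURES)
        e[j] = 1.0
        acc = np.zeros(component_model.n_components)
        k = 0
        draws = 0
        while k < n_reps and draws < 4 * n_reps:
            draws += 1
            truth = simulate_cn_profile(layout, e, event_budget,
                                        seed=int(rng.integers(2**31)),
                                        baseline_ploidy=baseline_ploidy)
            if truth.tumour_ploidy <= 0:
                continue  # a loss-heavy draw wiped the genome
            profile = _profile_from_truth(truth)
            v = encode_sample(extract_features(profile, layout), component_model)
            if v.sum() > 0:
                acc += v
                k += 1
        if acc.sum() == 0:
            raise RuntimeError(f"signature {j}: no feature mass generated")
        mass.append(acc.sum() / k)
        cols.append(acc / acc.sum())
    S = np.column_stack(cols)
    if np.linalg.matrix_rank(S, tol=1e-10) < N_SIGNATURES:
        raise RuntimeError("calibrated definitions are rank deficient")
    if return_mass:
        return S, np.asarray(mass)
    return S
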