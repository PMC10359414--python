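"""End-to-end orchestration: simulate -> fit -> signatures -> ith -> compare
-> test-composition, with per-stage outputs and a JSON run summary.

Each stage reads only its declared inputs and writes its own files, so a
stage can be re-run in isolation and reproduces its outputs bit-for-bit
given the same seeds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calling import correct_bias, fit_purity_ploidy, segment_profile
from .composition import fit_global_abundance_model
from .core import ConfigurationError, PairedCohort
from .genome import hg19_layout, toy_layout
from .heterogeneity import compute_delta_ith, compute_ith
from .io import (write_binned_counts, write_clinical, write_exposures,
                 write_gene_panel, write_segments, write_yaml)
from .signatures import (encode_sample, extract_features, quantify_exposures,
                         synthetic_component_model)
from .simulate import (CohortConfig, calibrate_signature_definitions,
                       default_gene_panel, simulate_paired_cohort)
from .stats import call_gene_events, compare_event_rates, subtract_pairs

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for a full pipeline run."""

    seed: int = 0
    n_patients: int = 12
    layout: str = "toy"          # toy | hg19
    alpha: float = 0.05
    zero_floor: float = 1e-3
    segment_penalty: float | None = None
    require_qc: bool = False     # demo cohorts keep all fits
    cohort: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ConfigurationError("alpha must be in (0, 1)")
        if self.zero_floor <= 0:
            raise ConfigurationError("zero_floor must be positive")
        if self.layout not in ("toy", "hg19"):
            raise ConfigurationError(f"unknown layout {self.layout!r}")
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        CohortConfig.from_dict(self.cohort)  # validates keys

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {unknown}")
        return cls(**d)

    def make_layout(self):
        return toy_layout() if self.layout == "toy" else hg19_layout()


def fit_sample(counts, penalty=None):
    """counts -> absolute profile (bias correction, segmentation, grid fit)."""
    rel = correct_bias(counts)
    segments = segment_profile(rel, penalty=penalty)
    return fit_purity_ploidy(segments, sample_id=counts.sample_id,
                             role=counts.role)


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage on a simulated cohort; returns the JSON summary."""
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(filename=out / "run.log", level=logging.INFO)
    summary = {"version": __version__, "seed": config.seed,
               "n_patients": config.n_patients, "stages": {}}
    try:
        layout = config.make_layout()
        # --- simulate -----------------------------------------------------
        cohort = simulate_paired_cohort(config.n_patients,
                                        CohortConfig.from_dict(config.cohort),
                                        seed=config.seed, layout=layout)
        sim_dir = out / "simulate"
        sim_dir.mkdir(exist_ok=True)
        for pid, dx, rl in cohort.counts.pairs():
            for c in (dx, rl):
                write_binned_counts(c, sim_dir / f"{c.sample_id}.counts.tsv")
        for pid, pair in cohort.truths.items():
            for truth in pair.values():
                write_segments(truth.segment_table,
                               sim_dir / f"{truth.sample_id}.truth.tsv")
        write_clinical(cohort.clinical_frame(), sim_dir / "clinical.csv")
        summary["stages"]["simulate"] = {"samples": 2 * len(cohort.counts)}

        # --- fit ----------------------------------------------------------
        fit_dir = out / "fit"
        fit_dir.mkdir(exist_ok=True)
        profiles, qc_pass = {}, 0
        for pid, dx, rl in cohort.counts.pairs():
            pair = {}
            for c in (dx, rl):
                profile = fit_sample(c, penalty=config.segment_penalty)
                write_segments(profile.segments, fit_dir / f"{c.sample_id}.segments.tsv")
                write_yaml({"sample_id": c.sample_id, "purity": profile.purity,
                            "ploidy": profile.ploidy, "qc": profile.qc},
                           fit_dir / f"{c.sample_id}.fit.yaml")
                qc_pass += int(profile.qc_pass)
                pair[c.role] = profile
            profiles[pid] = pair
        summary["stages"]["fit"] = {"qc_pass": qc_pass,
                                    "total": 2 * len(profiles)}
        if config.require_qc:
            profiles = {pid: pair for pid, pair in profiles.items()
                        if pair["diagnosis"].qc_pass and pair["relapse"].qc_pass}

        # --- signatures ----------------------------------------------------
        model = synthetic_component_model()
        S = calibrate_signature_definitions(model, layout, seed=config.seed,
                                            n_reps=4)
        np.savetxt(out / "signature_definitions.tsv", S, delimiter="\t")
        rows, residuals = {}, {}
        for pid, pair in profiles.items():
            for profile in pair.values():
                v = encode_sample(extract_features(profile, layout), model)
                e = quantify_exposures(v, S, sample_id=profile.sample_id)
                rows[profile.sample_id] = e.exposures
                residuals[profile.sample_id] = e.residual
        exposures = pd.DataFrame.from_dict(
            rows, orient="index",
            columns=[f"s{i + 1}" for i in range(S.shape[1])])
        write_exposures(exposures, out / "exposures.tsv",
                        residuals=pd.Series(residuals))
        summary["stages"]["signatures"] = {"samples": len(exposures)}

        # --- ith ------------------------------------------------------------
        ith_rows = []
        for pid, pair in profiles.items():
            idx = compute_ith(pair["diagnosis"], require_qc=False)
            irl = compute_ith(pair["relapse"], require_qc=False)
            ith_rows.append({"patient_id": pid, "ith_dx": idx.ith,
                             "ith_rel": irl.ith,
                             "delta": compute_delta_ith(idx, irl)})
        ith_df = pd.DataFrame(ith_rows)
        ith_df.to_csv(out / "ith.tsv", sep="\t", index=False, float_format="%.6g")
        summary["stages"]["ith"] = {"mean_delta": float(ith_df["delta"].mean())}

        # --- compare ---------------------------------------------------------
        sub = subtract_pairs(PairedCohort(profiles, cohort.clinical), layout,
                             alpha=config.alpha)
        sub.df.to_csv(out / "subtraction.tsv", sep="\t", index=False,
                      float_format="%.6g")
        panel = default_gene_panel(layout)
        write_gene_panel(panel, out / "gene_panel.bed")
        events = pd.concat([call_gene_events(p, panel)
                            for pair in profiles.values() for p in pair.values()],
                           ignore_index=True)
        events.to_csv(out / "gene_events.tsv", sep="\t", index=False,
                      float_format="%.6g")
        roles = {p.sample_id: p.role for pair in profiles.values()
                 for p in pair.values()}
        fisher = compare_event_rates(events, pd.Series(roles))
        pd.DataFrame([vars(t) for t in fisher]).to_csv(
            out / "event_tests.tsv", sep="\t", index=False, float_format="%.6g")
        summary["stages"]["compare"] = {
            "significant_bin_fraction": sub.significant_fraction,
            "gene_tests": len(fisher)}

        # --- test-composition -------------------------------------------------
        sample_ids = list(exposures.index)
        groups = [roles[s] for s in sample_ids]
        patients = [s.rsplit("-", 1)[0] for s in sample_ids]
        fit = fit_global_abundance_model(exposures, groups, patients,
                                         zero_floor=config.zero_floor)
        summary["stages"]["test_composition"] = {
            "wald_statistic": fit.wald_statistic, "df": fit.df,
            "pvalue": fit.pvalue, "warnings": fit.warnings_}
        summary["status"] = "ok"
    except Exception as exc:
        summary["status"] = "failed"
        summary["error"] = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        summary["runtime_s"] = round(time.time() - t0, 2)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
    return summary
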