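"""Table I/O with strict schema validation.

All genomic tables are plain text: BED-like TSV for intervals and
segments, TSV for bins and exposures, CSV for clinical data, YAML for
configuration and fit reports. Coordinates are 0-based, half-open
everywhere. Floats are serialised at 6 significant digits; numeric
round-trips are therefore comparison-with-tolerance, while determinism
checks can compare bytes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BinnedCounts, SchemaError, SegmentTable

__all__ = [
    "write_binned_counts", "read_binned_counts", "write_segments",
    "read_segments", "write_exposures", "read_exposures", "write_clinical",
    "read_clinical", "read_gene_panel", "write_gene_panel", "write_yaml",
    "read_yaml", "read_manifest",
]

_FLOAT_FMT = "%.6g"


def _require_columns(df: pd.DataFrame, required: list, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")


def _check_intervals(df: pd.DataFrame, path) -> None:
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise SchemaError(f"{path}: end <= start at line {bad[0] + 2}")
    for chrom, sub in df.groupby("chrom", sort=False):
        if not sub["start"].is_monotonic_increasing:
            first = sub.index[sub["start"].diff() < 0][0]
            raise SchemaError(f"{path}: unsorted intervals at line {first + 2} "
                              f"(chromosome {chrom})")


def write_binned_counts(counts: BinnedCounts, path) -> None:
    counts.df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_binned_counts(path, sample_id: str | None = None,
                       role: str = "") -> BinnedCounts:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["chrom", "start", "end", "gc", "mappability", "count"], path)
    _check_intervals(df, path)
    if sample_id is None:
        sample_id = Path(path).name.removesuffix(".tsv").removesuffix(".counts")
    return BinnedCounts(sample_id=sample_id, role=role, df=df)


def write_segments(segments: SegmentTable, path) -> None:
    segments.df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_segments(path, space: str = "absolute") -> SegmentTable:
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, ["chrom", "start", "end", "value"], path)
    if "n_bins" not in df.columns:
        df["n_bins"] = 0
    _check_intervals(df, path)
    return SegmentTable(df, space=space)


def write_exposures(exposures: pd.DataFrame, path,
                    residuals: pd.Series | None = None) -> None:
    out = exposures.copy()
    if residuals is not None:
        out["residual"] = residuals
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_exposures(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    sig_cols = [c for c in df.columns if c != "residual"]
    sums = df[sig_cols].sum(axis=1)
    bad = sums.index[(sums - 1.0).abs() > 1e-3]
    if len(bad):
        line = df.index.get_loc(bad[0]) + 2
        raise SchemaError(f"{path}: exposures at line {line} sum to "
                          f"{sums[bad[0]]:.4g}, violating the simplex invariant")
    if (df[sig_cols].to_numpy() < -1e-9).any():
        raise SchemaError(f"{path}: negative exposure values")
    return df[sig_cols]


def write_clinical(clinical: pd.DataFrame, path) -> None:
    clinical.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ["patient_id", "platinum_status"], path)
    bad = ~df["platinum_status"].isin(["sensitive", "resistant"])
    if bad.any():
        raise SchemaError(f"{path}: invalid platinum_status at line "
                          f"{df.index[bad][0] + 2}")
    return df


def write_gene_panel(panel: pd.DataFrame, path) -> None:
    panel[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", index=False, header=False)


def read_gene_panel(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "gene"])
    _check_intervals(df, path)
    return df


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(obj), fh, sort_keys=True)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return [_to_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def read_manifest(path) -> pd.DataFrame:
    """Cohort manifest CSV: patient_id, sample_id, role, path columns.

    (patient_id, role) pairs must be unique; referenced paths must exist.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["patient_id", "sample_id", "role"], path)
    dup = df.duplicated(subset=["patient_id", "role"])
    if dup.any():
        raise SchemaError(f"{path}: duplicate (patient_id, role) at line "
                          f"{df.index[dup][0] + 2}")
    base = Path(path).parent
    path_cols = [c for c in df.columns if c.endswith("_path")]
    for col in path_cols:
        for i, p in df[col].items():
            if pd.isna(p):
                continue
            candidate = Path(p)
            if not candidate.is_absolute():
                candidate = base / candidate
            if not candidate.exists():
                raise SchemaError(f"{path}: line {i + 2}: missing file {p}")
    return df
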