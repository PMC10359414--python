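import numpy as np
import pandas as pd
import pytest

from pairedcn.core import AbsoluteProfile, SegmentTable
from pairedcn.genome import GenomeLayout, toy_layout


@pytest.fixture(scope="session")
def toy():
    return toy_layout()


@pytest.fixture(scope="session")
def mini():
    """Two tiny chromosomes (200 bins total) for fast unit tests."""
    return GenomeLayout(
        chromosomes=(("chr1", 3_600_000), ("chr2", 2_400_000)),
        bin_size=30_000,
        arm_boundaries={"chr1": 1_800_000, "chr2": 1_200_000},
    )


def make_segments(rows, space="absolute"):
    """rows: (chrom, start, end, value[, n_bins])"""
    recs = []
    for r in rows:
        chrom, start, end, value = r[:4]
        n_bins = r[4] if len(r) > 4 else max((end - start) // 30_000, 1)
        recs.append((chrom, start, end, float(value), n_bins))
    df = pd.DataFrame(recs, columns=["chrom", "start", "end", "value", "n_bins"])
    return SegmentTable(df, space=space)


def make_profile(rows, sample_id="S", role="diagnosis", purity=1.0,
                 ploidy=None, qc_pass=True):
    seg = make_segments(rows)
    if ploidy is None:
        ploidy = max(seg.length_weighted_mean(), 1e-6)
    return AbsoluteProfile(sample_id=sample_id, role=role, purity=purity,
                           ploidy=ploidy, segments=seg,
                           qc={"pass": qc_pass, "goodness_of_fit": 0.0,
                               "fraction_genome_near_integer": 1.0})


@pytest.fixture
def rng():
    return np.random.default_rng(0)
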