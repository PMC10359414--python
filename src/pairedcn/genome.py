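"""Genome layouts: chromosomes, arms and fixed-width bins.

All coordinates in this package are 0-based, half-open (BED convention).
The default working genome is a reduced 3-chromosome, 300 Mb layout that
keeps whole-pipeline runs desk-scale; an hg19-like layout with the 22
autosomes is available for full-scale work.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeLayout", "toy_layout", "hg19_layout"]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome sizes, centromere positions and a fixed bin width.

    Parameters
    ----------
    chromosomes : list of (name, length) tuples
        Ordered chromosome names and lengths in bp. Lengths must be
        multiples of nothing in particular, but at least one bin each.
    bin_size : int
        Bin width in bp (default 30 kb, the working resolution for
        ~0.1x shallow WGS copy-number profiling).
    arm_boundaries : dict
        Centromere position per chromosome, in bp. Arms partition each
        chromosome as [0, cen) and [cen, length).
    """

    chromosomes: tuple
    bin_size: int = 30_000
    arm_boundaries: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name, length in self.chromosomes:
            if length < self.bin_size:
                raise ValueError(f"chromosome {name} shorter than one bin")
            cen = self.arm_boundaries.get(name)
            if cen is not None and not (0 < cen < length):
                raise ValueError(f"centromere of {name} outside chromosome")

    @property
    def chrom_names(self) -> list:
        return [name for name, _ in self.chromosomes]

    @property
    def chrom_lengths(self) -> dict:
        return dict(self.chromosomes)

    @property
    def genome_length(self) -> int:
        return int(sum(length for _, length in self.chromosomes))

    def n_bins(self, chrom: str | None = None) -> int:
        if chrom is not None:
            return int(np.ceil(self.chrom_lengths[chrom] / self.bin_size))
        return int(sum(self.n_bins(c) for c in self.chrom_names))

    def bins(self) -> pd.DataFrame:
        """Tile the genome into bins; the last bin of a chromosome is
        truncated at the chromosome end."""
        rows = []
        for name, length in self.chromosomes:
            starts = np.arange(0, length, self.bin_size, dtype=np.int64)
            ends = np.minimum(starts + self.bin_size, length)
            rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(rows, ignore_index=True)

    def arms(self, chrom: str) -> list:
        """Return [(start, end), ...] for the p and q arm of `chrom`."""
        length = self.chrom_lengths[chrom]
        cen = self.arm_boundaries.get(chrom)
        if cen is None:
            return [(0, length)]
        return [(0, int(cen)), (int(cen), length)]

    def arm_of(self, chrom: str, pos: int) -> int:
        """Index (0 = p, 1 = q) of the arm containing `pos`."""
        cen = self.arm_boundaries.get(chrom)
        if cen is None:
            return 0
        return 0 if pos < cen else 1


def toy_layout(bin_size: int = 30_000) -> GenomeLayout:
    """Reduced 3-chromosome, 300 Mb test genome (10,000 bins at 30 kb).

    Chromosome lengths are exact multiples of the default bin size so
    every bin has full width.
    """
    return GenomeLayout(
        chromosomes=(("chr1", 120_000_000), ("chr2", 100_020_000), ("chr3", 79_980_000)),
        bin_size=bin_size,
        arm_boundaries={"chr1": 60_000_000, "chr2": 45_000_000, "chr3": 35_010_000},
    )


# GRCh37 autosome lengths (bp) and approximate centromere midpoints.
_HG19_CHROMS = (
    ("chr1", 249_250_621), ("chr2", 243_199_373), ("chr3", 198_022_430),
    ("chr4", 191_154_276), ("chr5", 180_915_260), ("chr6", 171_115_067),
    ("chr7", 159_138_663), ("chr8", 146_364_022), ("chr9", 141_213_431),
    ("chr10", 135_534_747), ("chr11", 135_006_516), ("chr12", 133_851_895),
    ("chr13", 115_169_878), ("chr14", 107_349_540), ("chr15", 102_531_392),
    ("chr16", 90_354_753), ("chr17", 81_195_210), ("chr18", 78_077_248),
    ("chr19", 59_128_983), ("chr20", 63_025_520), ("chr21", 48_129_895),
    ("chr22", 51_304_566),
)
_HG19_CEN = {
    "chr1": 125_000_000, "chr2": 93_300_000, "chr3": 91_000_000,
    "chr4": 50_400_000, "chr5": 48_400_000, "chr6": 61_000_000,
    "chr7": 59_900_000, "chr8": 45_600_000, "chr9": 49_000_000,
    "chr10": 40_200_000, "chr11": 53_700_000, "chr12": 35_800_000,
    "chr13": 17_900_000, "chr14": 17_600_000, "chr15": 19_000_000,
    "chr16": 36_600_000, "chr17": 24_000_000, "chr18": 17_200_000,
    "chr19": 26_500_000, "chr20": 27_500_000, "chr21": 13_200_000,
    "chr22": 14_700_000,
}


def hg19_layout(bin_size: int = 30_000) -> GenomeLayout:
    """GRCh37 autosomes at the given bin size."""
    return GenomeLayout(chromosomes=_HG19_CHROMS, bin_size=bin_size,
                        arm_boundaries=dict(_HG19_CEN))
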