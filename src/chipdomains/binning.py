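"""Stage 1: count uniquely-mapping reads into uniform genomic bins.

Reads below the MAPQ cutoff (default 30) are discarded, as are unmapped,
secondary and supplementary alignments, so that each surviving read is
counted exactly once.  Every read increments the bin containing its
0-based leftmost aligned coordinate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

logger = logging.getLogger(__name__)

DEFAULT_MIN_MAPQ = 30
DEFAULT_BIN_WIDTH = 1000


class ChromSizesError(ValueError):
    """Malformed or inconsistent chromosome-sizes input."""


@dataclass(frozen=True)
class ChromSizes:
    """Ordered map of chromosome name to length in bp.

    Lengths are strictly positive and names unique.
    """

    entries: dict[str, int]

    def __post_init__(self) -> None:
        for name, length in self.entries.items():
            if length <= 0:
                raise ChromSizesError(f"non-positive length for {name}: {length}")

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __getitem__(self, name: str) -> int:
        return self.entries[name]

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def n_bins(self, name: str, bin_width: int) -> int:
        return math.ceil(self.entries[name] / bin_width)


@dataclass
class BinnedCounts:
    """Per-chromosome read counts over uniform bins.

    ``counts[i]`` covers bases ``[i * bin_width, (i + 1) * bin_width)``;
    the final bin may be truncated by the chromosome end.
    """

    chromosome: str
    bin_width: int
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if (self.counts < 0).any():
            raise ValueError("negative bin count")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Parse a UCSC-style two-column chrom.sizes file.

    Each non-empty line holds a chromosome name and an integer length,
    whitespace-separated; entries are returned in file order.
    """
    entries: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ChromSizesError(
                    f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}"
                )
            name = fields[0]
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ChromSizesError(
                    f"{path}:{lineno}: length is not an integer: {fields[1]!r}"
                ) from exc
            if name in entries:
                raise ChromSizesError(f"{path}:{lineno}: duplicate chromosome {name}")
            entries[name] = length
    if not entries:
        raise ChromSizesError(f"{path}: no chromosomes found")
    return ChromSizes(entries)


def assign_read_to_bin(read_position: int, bin_width: int) -> int:
    """Bin index of a read from its 0-based leftmost aligned coordinate."""
    if read_position < 0:
        raise ValueError("read position must be non-negative")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    return read_position // bin_width


def _read_passes(read: pysam.AlignedSegment, min_mapq: int) -> bool:
    return (
        not read.is_unmapped
        and not read.is_secondary
        and not read.is_supplementary
        and read.mapping_quality >= min_mapq
    )


def count_reads(
    bam_path: str | Path,
    chrom_sizes: ChromSizes,
    bin_width: int = DEFAULT_BIN_WIDTH,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> tuple[dict[str, BinnedCounts], int]:
    """Count filtered reads into bins for every chromosome in ``chrom_sizes``.

    Returns the per-chromosome :class:`BinnedCounts` plus the total number
    of counted reads (the read depth used for normalization).  Chromosomes
    present in the BAM but absent from ``chrom_sizes`` are skipped with a
    warning; paired-end mates are counted independently.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    counts: dict[str, BinnedCounts] = {
        name: BinnedCounts(
            name, bin_width, np.zeros(chrom_sizes.n_bins(name, bin_width), dtype=np.int64)
        )
        for name in chrom_sizes
    }
    total = 0
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if not bam.has_index():
            raise OSError(f"{bam_path}: BAM index required (coordinate-sorted input)")
        for ref in bam.references:
            if ref not in chrom_sizes:
                logger.warning("chromosome %s in %s absent from chrom sizes; skipped", ref, bam_path)
        for name in chrom_sizes:
            if name not in bam.references:
                continue
            vec = counts[name].counts
            length = chrom_sizes[name]
            for read in bam.fetch(name):
                if not _read_passes(read, min_mapq):
                    continue
                pos = read.reference_start
                if pos >= length:
                    logger.warning(
                        "read at %s:%d beyond declared length %d; skipped", name, pos, length
                    )
                    continue
                vec[pos // bin_width] += 1
                total += 1
    return counts, total


def write_counts(counts: dict[str, BinnedCounts], path: str | Path) -> None:
    """Persist binned counts as three-column text (chrom, 0-based bin start, count)."""
    with open(path, "w") as fh:
        for name, bc in counts.items():
            for i, c in enumerate(bc.counts):
                fh.write(f"{name}\t{i * bc.bin_width}\t{int(c)}\n")


def read_counts_table(path: str | Path, chrom_sizes: ChromSizes, bin_width: int) -> dict[str, BinnedCounts]:
    """Load binned counts written by :func:`write_counts`."""
    counts = {
        name: BinnedCounts(
            name, bin_width, np.zeros(chrom_sizes.n_bins(name, bin_width), dtype=np.int64)
        )
        for name in chrom_sizes
    }
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, start, count = line.split()
            counts[name].counts[int(start) // bin_width] = int(count)
    return counts
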