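"""Stage 2 preprocessing: depth normalization, control subtraction, truncation.

Raw ChIP and control bin counts are scaled to a common depth tier, the
normalized control is subtracted from the normalized ChIP, bins with no
reads in either dataset are dropped, and the surviving differences are
clamped into a fixed range (default [-10, 200]) so repetitive-region
pile-ups do not dominate the variance estimates downstream.

With a matched control the retained differences form an approximately
normal null centered on 0, right-skewed by true enrichment; the HMM
models exactly this series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binning import BinnedCounts

DEFAULT_CEILING = 200.0
DEFAULT_FLOOR = -10.0


@dataclass
class ObservationSeries:
    """Normalized, truncated per-bin values kept for HMM fitting.

    ``bin_indices`` maps each value back to its genomic bin index and is
    strictly increasing; bins excluded during preprocessing are simply
    absent.
    """

    chromosome: str
    values: np.ndarray = field(repr=False)
    bin_indices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.bin_indices = np.asarray(self.bin_indices, dtype=np.int64)
        if self.values.shape != self.bin_indices.shape:
            raise ValueError("values and bin_indices must have the same length")
        if self.bin_indices.size and (np.diff(self.bin_indices) <= 0).any():
            raise ValueError("bin_indices must be strictly increasing")

    def __len__(self) -> int:
        return self.values.size


def select_divisor(min_total_reads: int) -> int:
    """Depth-tier divisor from the smaller dataset's total read count.

    Totals under 1e7, 1e8 or 1e9 reads use divisors 1e6, 1e7 or 1e8
    respectively; beyond that the pattern continues by powers of ten.
    """
    if min_total_reads <= 0:
        raise ValueError("total read count must be positive")
    if min_total_reads < 10_000_000:
        return 1_000_000
    if min_total_reads < 100_000_000:
        return 10_000_000
    if min_total_reads < 1_000_000_000:
        return 100_000_000
    return 10 ** (len(str(min_total_reads)) - 1)


def normalize_counts(counts: BinnedCounts, total_reads: int, divisor: int) -> np.ndarray:
    """Scale raw counts to reads-per-divisor depth: raw * divisor / total."""
    if total_reads <= 0:
        raise ValueError("total read count must be positive")
    return counts.counts.astype(np.float64) * (divisor / total_reads)


def subtract_and_filter(
    chip_norm: np.ndarray,
    control_norm: np.ndarray,
    chip_raw: BinnedCounts,
    control_raw: BinnedCounts,
) -> ObservationSeries:
    """Control-subtracted values at bins with at least one read in either dataset.

    Bins with zero raw reads in both ChIP and control carry no evidence
    (typically unmappable sequence) and are excluded from the series.
    """
    n = len(chip_norm)
    if not (len(control_norm) == chip_raw.n_bins == control_raw.n_bins == n):
        raise ValueError("chip/control vectors must have identical lengths")
    keep = (chip_raw.counts + control_raw.counts) >= 1
    values = np.asarray(chip_norm, dtype=np.float64) - np.asarray(control_norm, dtype=np.float64)
    return ObservationSeries(chip_raw.chromosome, values[keep], np.flatnonzero(keep))


def truncate(
    series: ObservationSeries,
    ceiling: float = DEFAULT_CEILING,
    floor: float = DEFAULT_FLOOR,
) -> ObservationSeries:
    """Clamp every value into [floor, ceiling]; bin indices are unchanged."""
    if ceiling <= floor:
        raise ValueError(f"ceiling ({ceiling}) must exceed floor ({floor})")
    return ObservationSeries(
        series.chromosome,
        np.clip(series.values, floor, ceiling),
        series.bin_indices.copy(),
    )


def prepare_observations(
    chip_raw: BinnedCounts,
    control_raw: BinnedCounts,
    chip_total: int,
    control_total: int,
    ceiling: float = DEFAULT_CEILING,
    floor: float = DEFAULT_FLOOR,
) -> ObservationSeries:
    """Full with-control preprocessing for one chromosome.

    Both datasets share the divisor chosen from the smaller total, so the
    two depths are expressed on the same scale before subtraction.
    """
    divisor = select_divisor(min(chip_total, control_total))
    chip_norm = normalize_counts(chip_raw, chip_total, divisor)
    control_norm = normalize_counts(control_raw, control_total, divisor)
    series = subtract_and_filter(chip_norm, control_norm, chip_raw, control_raw)
    return truncate(series, ceiling=ceiling, floor=floor)


def prepare_no_control(
    chip_raw: BinnedCounts,
    total_reads: int,
    ceiling: float = DEFAULT_CEILING,
) -> ObservationSeries:
    """No-control preprocessing: normalized ChIP counts alone.

    Zero-count bins are excluded and the floor is 0, since counts cannot
    go negative without a subtracted control.
    """
    divisor = select_divisor(total_reads)
    norm = normalize_counts(chip_raw, total_reads, divisor)
    keep = chip_raw.counts >= 1
    series = ObservationSeries(chip_raw.chromosome, norm[keep], np.flatnonzero(keep))
    return truncate(series, ceiling=ceiling, floor=0.0)
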