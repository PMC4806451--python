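"""Known-truth synthetic inputs at two levels.

``simulate_observations`` samples an observation series directly from a
specified two-state Gaussian HMM — the exact generative model the fitter
assumes — for parameter-recovery and decoding tests.

``simulate_reads`` builds toy sequencing experiments: a control sample of
reads placed uniformly along each chromosome, and a treatment sample with
the same uniform background plus (i) a constant enrichment factor inside
planted domains and (ii) sharp Gaussian pile-ups at planted summits.
Read counts per region are Poisson, positions independent, reads 50 bp
single-end, with a seeded mix of high and sub-threshold MAPQ values so
the quality filter is exercised.  Output is a coordinate-sorted, indexed
BAM plus plain-text truth files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .binning import ChromSizes
from .hmm import GaussianEmission, HMMParams
from .normalize import ObservationSeries

READ_LENGTH = 50
DEFAULT_ENRICHMENT = 8.0
DEFAULT_SUMMIT_READS = 1500
DEFAULT_SUMMIT_SD = 50.0
# fraction of reads given MAPQ below the default threshold of 30
LOW_MAPQ_FRACTION = 0.1
HIGH_MAPQ, LOW_MAPQ = 60, 20


def default_generating_params(
    depleted_mean: float = 0.0,
    depleted_sd: float = 5.0,
    enriched_mean: float = 15.0,
    enriched_sd: float = 5.0,
    self_transition: float = 0.95,
) -> HMMParams:
    """A well-separated two-state model on the scale of normalized bin counts.

    The depleted state is N(0, 5) — the null scale of control-subtracted
    counts on typical datasets — and the enriched state N(15, 5).
    """
    p = self_transition
    return HMMParams(
        prior=np.array([0.5, 0.5]),
        transitions=np.array([[p, 1 - p], [1 - p, p]]),
        emissions=(
            GaussianEmission(depleted_mean, depleted_sd),
            GaussianEmission(enriched_mean, enriched_sd),
        ),
    )


def simulate_observations(
    params: HMMParams, n_bins: int, seed: int, chromosome: str = "sim"
) -> tuple[ObservationSeries, np.ndarray]:
    """Sample (series, true state path) from a two-state Gaussian HMM."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    rng = np.random.default_rng(seed)
    states = np.empty(n_bins, dtype=np.int8)
    states[0] = rng.choice(2, p=params.prior)
    for b in range(1, n_bins):
        states[b] = rng.choice(2, p=params.transitions[states[b - 1]])
    means = np.array([e.mean for e in params.emissions])
    sds = np.array([e.sd for e in params.emissions])
    values = rng.normal(means[states], sds[states])
    series = ObservationSeries(chromosome, values, np.arange(n_bins))
    return series, states


@dataclass(frozen=True)
class DepthConfig:
    """Read-depth knobs for the read-level simulator."""

    treatment_reads: int = 100_000
    control_reads: int = 100_000
    enrichment: float = DEFAULT_ENRICHMENT
    summit_reads: int = DEFAULT_SUMMIT_READS
    summit_sd: float = DEFAULT_SUMMIT_SD


@dataclass
class TruthSet:
    """Planted truth for a synthetic experiment, reproducible from its seed."""

    chrom_sizes: ChromSizes
    enriched_intervals: list[tuple[str, int, int]]
    peak_summits: list[tuple[str, int]]
    seed: int
    depth: DepthConfig = field(default_factory=DepthConfig)

    def __post_init__(self) -> None:
        for chrom, start, end in self.enriched_intervals:
            if not (0 <= start < end <= self.chrom_sizes[chrom]):
                raise ValueError(f"interval [{start}, {end}) outside {chrom}")
        for chrom, pos in self.peak_summits:
            if not 0 <= pos < self.chrom_sizes[chrom]:
                raise ValueError(f"summit {pos} outside {chrom}")

    def enriched_mask(self, chrom: str) -> np.ndarray:
        mask = np.zeros(self.chrom_sizes[chrom], dtype=bool)
        for c, start, end in self.enriched_intervals:
            if c == chrom:
                mask[start:end] = True
        return mask


def default_truth_set(seed: int = 0) -> TruthSet:
    """The standard synthetic genome: 2 x 2 Mb, five domains, five summits.

    Domain widths span 10-50 kb on bin-aligned boundaries; summits sit in
    otherwise-background sequence, well away from the domains.
    """
    sizes = ChromSizes({"chrS1": 2_000_000, "chrS2": 2_000_000})
    intervals = [
        ("chrS1", 200_000, 210_000),
        ("chrS1", 600_000, 620_000),
        ("chrS1", 1_200_000, 1_250_000),
        ("chrS2", 300_000, 330_000),
        ("chrS2", 1_500_000, 1_540_000),
    ]
    summits = [
        ("chrS1", 900_500),
        ("chrS1", 1_700_250),
        ("chrS2", 100_750),
        ("chrS2", 800_500),
        ("chrS2", 1_200_250),
    ]
    return TruthSet(sizes, intervals, summits, seed)


def expected_null_sd(truth: TruthSet, bin_width: int = 1000, depth: DepthConfig | None = None) -> float:
    """Analytic sd of the normalized ChIP-minus-control null differences.

    Bin counts are Poisson with rate ``reads * bin_width / genome``; after
    scaling both datasets to reads-per-divisor depth the difference in a
    background bin has variance ``divisor^2 * bin_width * (1/Nt + 1/Nc) /
    genome``.  Deep genome-scale experiments land near sd 5 — the regime
    the default truncation window [-10, 200] was designed for — while a
    small toy genome at toy depth sits far higher.
    """
    from .normalize import select_divisor

    depth = depth or truth.depth
    sizes = truth.chrom_sizes
    genome = sum(sizes[c] for c in sizes)
    divisor = select_divisor(min(depth.treatment_reads, depth.control_reads))
    var = divisor**2 * bin_width * (1 / depth.treatment_reads + 1 / depth.control_reads) / genome
    return float(np.sqrt(var))


def recommended_truncation(
    truth: TruthSet, bin_width: int = 1000, depth: DepthConfig | None = None
) -> tuple[float, float]:
    """Truncation window scaled to the experiment's null noise.

    The stock defaults -10 and 200 are -2x and 40x the sd of the null
    differences on typical genome-scale data (sd ~ 5).  This applies the
    same ratios to the analytic null sd of a given synthetic design, so
    the floor clips two-sd depletions and the ceiling still curbs
    repetitive-region pile-ups without flattening real enrichment.
    Returns ``(ceiling, floor)``.
    """
    sd = expected_null_sd(truth, bin_width, depth)
    return 40.0 * sd, -2.0 * sd


def _write_bam(path: Path, chrom_sizes: ChromSizes, placements: dict[str, np.ndarray], rng) -> None:
    """Write coordinate-sorted single-end 50 bp reads with a seeded MAPQ mix."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": chrom_sizes[name]} for name in chrom_sizes],
    }
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for tid, name in enumerate(chrom_sizes):
            positions = np.sort(placements.get(name, np.empty(0, dtype=np.int64)))
            mapqs = np.where(
                rng.random(positions.size) < LOW_MAPQ_FRACTION, LOW_MAPQ, HIGH_MAPQ
            )
            for i, (pos, mapq) in enumerate(zip(positions, mapqs)):
                a = pysam.AlignedSegment()
                a.query_name = f"{name}_{i}"
                a.reference_id = tid
                a.reference_start = int(pos)
                a.mapping_quality = int(mapq)
                a.cigarstring = f"{READ_LENGTH}M"
                a.query_sequence = "A" * READ_LENGTH
                a.flag = 0
                bam.write(a)
    pysam.index(str(path))


def _uniform_positions(rng, n: int, length: int) -> np.ndarray:
    return rng.integers(0, length - READ_LENGTH, size=n)


def simulate_reads(
    truth: TruthSet, out_dir: str | Path, depth: DepthConfig | None = None
) -> tuple[Path, Path]:
    """Generate treatment and control BAMs with planted enrichment.

    Control reads are uniform per chromosome (depth split in proportion to
    length).  Treatment reads are uniform background at a rate chosen so
    background + ``enrichment`` x background inside domains + summit reads
    add up to ``treatment_reads``, in expectation.  All counts are Poisson
    draws from one seeded generator, so identical seeds give byte-identical
    BAMs.
    """
    depth = depth or truth.depth
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.seed)
    sizes = truth.chrom_sizes
    genome = sum(sizes[c] for c in sizes)

    # control: uniform everywhere
    control: dict[str, np.ndarray] = {}
    for name in sizes:
        n = rng.poisson(depth.control_reads * sizes[name] / genome)
        control[name] = _uniform_positions(rng, n, sizes[name])

    # treatment: background rate b satisfying
    #   b*genome + (enrichment-1)*b*enriched_bp + summit_reads = treatment_reads
    enriched_bp = sum(end - start for _, start, end in truth.enriched_intervals)
    n_summit_total = depth.summit_reads * len(truth.peak_summits)
    bg_rate = (depth.treatment_reads - n_summit_total) / (
        genome + (depth.enrichment - 1.0) * enriched_bp
    )
    if bg_rate <= 0:
        raise ValueError("summit reads exceed the treatment read budget")
    treatment: dict[str, list[np.ndarray]] = {name: [] for name in sizes}
    for name in sizes:
        n_bg = rng.poisson(bg_rate * sizes[name])
        treatment[name].append(_uniform_positions(rng, n_bg, sizes[name]))
    for chrom, start, end in truth.enriched_intervals:
        n_extra = rng.poisson((depth.enrichment - 1.0) * bg_rate * (end - start))
        treatment[chrom].append(rng.integers(start, max(start + 1, end - READ_LENGTH), size=n_extra))
    for chrom, pos in truth.peak_summits:
        n = rng.poisson(depth.summit_reads)
        centers = rng.normal(pos, depth.summit_sd, size=n)
        starts = np.rint(centers - READ_LENGTH / 2).astype(np.int64)
        starts = np.clip(starts, 0, sizes[chrom] - READ_LENGTH)
        treatment[chrom].append(starts)
    placements = {name: np.concatenate(parts) for name, parts in treatment.items()}

    treatment_path = out_dir / "treatment.bam"
    control_path = out_dir / "control.bam"
    _write_bam(treatment_path, sizes, placements, rng)
    _write_bam(control_path, sizes, control, rng)
    write_truth_files(truth, out_dir)
    return treatment_path, control_path


def write_truth_files(truth: TruthSet, out_dir: str | Path) -> None:
    """Persist the planted truth: chrom.sizes, BEDs, and a JSON manifest."""
    out_dir = Path(out_dir)
    with open(out_dir / "genome.chrom.sizes", "w") as fh:
        for name in truth.chrom_sizes:
            fh.write(f"{name}\t{truth.chrom_sizes[name]}\n")
    with open(out_dir / "truth_domains.bed", "w") as fh:
        for chrom, start, end in truth.enriched_intervals:
            fh.write(f"{chrom}\t{start}\t{end}\ttruth_domain\n")
    with open(out_dir / "truth_summits.bed", "w") as fh:
        for chrom, pos in truth.peak_summits:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\ttruth_summit\n")
    manifest = {
        "seed": truth.seed,
        "read_length": READ_LENGTH,
        "depth": {
            "treatment_reads": truth.depth.treatment_reads,
            "control_reads": truth.depth.control_reads,
            "enrichment": truth.depth.enrichment,
            "summit_reads": truth.depth.summit_reads,
            "summit_sd": truth.depth.summit_sd,
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
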