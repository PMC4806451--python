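"""Shared fixtures: tiny hand-built BAMs and the standard synthetic genome.

All alignment files are generated at test time with pysam; nothing binary
is stored in the repository.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam
import pytest

from chipdomains import ChromSizes, DomainCaller, RunConfig
from chipdomains.simulate import default_truth_set, recommended_truncation, simulate_reads


def make_bam(
    path: Path,
    chrom_sizes: ChromSizes,
    reads: list[tuple[str, int, int]],
    read_length: int = 50,
    flags: dict[int, int] | None = None,
) -> Path:
    """Write an indexed BAM from (chrom, 0-based pos, mapq) triples.

    ``flags`` optionally overrides the SAM flag of the read at a given
    list index (e.g. to mark it secondary or unmapped).
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": name, "LN": chrom_sizes[name]} for name in chrom_sizes],
    }
    tids = {name: i for i, name in enumerate(chrom_sizes)}
    order = sorted(range(len(reads)), key=lambda i: (tids[reads[i][0]], reads[i][1]))
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i in order:
            chrom, pos, mapq = reads[i]
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.reference_id = tids[chrom]
            a.reference_start = pos
            a.mapping_quality = mapq
            a.cigarstring = f"{read_length}M"
            a.query_sequence = "A" * read_length
            a.flag = (flags or {}).get(i, 0)
            bam.write(a)
    pysam.index(str(path))
    return path


@pytest.fixture
def tiny_sizes() -> ChromSizes:
    return ChromSizes({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture(scope="session")
def synthetic_experiment(tmp_path_factory):
    """The standard synthetic genome with its fitted pipeline results.

    2 chromosomes x 2 Mb, five planted 10-50 kb domains, five summits,
    8x enrichment, ~200k reads, seed 1.  The truncation window is set by
    the noise-scaled rule (floor/ceiling at -2x/40x the analytic null sd)
    since the toy depth puts the null far above the genome-scale sd the
    stock window assumes.  Session-scoped: the pipeline runs once.
    """
    out = tmp_path_factory.mktemp("synthetic")
    truth = default_truth_set(seed=1)
    treatment, control = simulate_reads(truth, out)
    ceiling, floor = recommended_truncation(truth)
    config = RunConfig(max_count=ceiling, min_count=floor, seed=1)
    caller = DomainCaller.from_bam(treatment, truth.chrom_sizes, control, config)
    results = caller.fit()
    return {
        "truth": truth,
        "treatment": treatment,
        "control": control,
        "dir": out,
        "config": config,
        "caller": caller,
        "results": results,
    }


def base_recovery(truth, domains) -> tuple[float, float]:
    """(fraction of planted enriched bases recovered, background FP fraction).

    Bases within 1.5 kb of a planted summit are excluded from the
    background denominator: the summit pile-ups are real planted signal,
    so calling their bins enriched is correct, not a false positive.
    """
    tp = fp = planted = background = 0
    for chrom in truth.chrom_sizes:
        called = np.zeros(truth.chrom_sizes[chrom], dtype=bool)
        for d in domains:
            if d.chromosome == chrom:
                called[d.start : d.end] = True
        mask = truth.enriched_mask(chrom)
        summit_zone = np.zeros_like(mask)
        for c, pos in truth.peak_summits:
            if c == chrom:
                summit_zone[max(0, pos - 1500) : pos + 1500] = True
        bg = ~mask & ~summit_zone
        planted += int(mask.sum())
        background += int(bg.sum())
        tp += int((called & mask).sum())
        fp += int((called & bg).sum())
    return tp / planted, fp / background
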