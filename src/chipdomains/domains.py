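"""Stage 3: turn decoded bins into BED domain calls.

Contiguous runs of confidently-enriched bins become domains; a bin that
was excluded during preprocessing (no reads in either dataset) breaks a
run, since it carries no evidence of enrichment.  Domains are clamped to
the declared chromosome sizes.  Two BED flavours are written: a BED4 of
merged domains, and a BED9 of individual bins shaded by posterior
probability for display in the UCSC genome browser (>0.9 black, then
sequentially lighter greys for >0.8 and >0.7).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

from .binning import ChromSizes
from .hmm import ENRICHED, PosteriorTrack

DEFAULT_MIN_POSTERIOR = 0.9

# posterior shading tiers: (exclusive lower bound, RGB)
_COLOR_TIERS = (
    (0.9, (0, 0, 0)),
    (0.8, (120, 120, 120)),
    (0.7, (180, 180, 180)),
)


@dataclass(frozen=True)
class DomainCall:
    """A maximal run of confidently-enriched bins.

    ``min_posterior`` is the minimum enriched-state posterior over the
    member bins — the weakest link, i.e. the confidence of the whole call.
    """

    chromosome: str
    start: int
    end: int
    min_posterior: float
    n_bins: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")


def bins_to_domains(
    track: PosteriorTrack,
    bin_width: int,
    min_posterior: float = DEFAULT_MIN_POSTERIOR,
    bridge_gaps: int = 0,
) -> list[DomainCall]:
    """Group confident enriched bins into maximal consecutive runs.

    Bins with ``state == enriched`` and posterior strictly above
    ``min_posterior`` are merged when their genomic bin indices are
    consecutive; a gap of more than ``bridge_gaps`` missing bins (default
    0: any gap) starts a new domain.
    """
    calls: list[DomainCall] = []
    run: list[tuple[int, float]] = []

    def flush() -> None:
        if run:
            first, last = run[0][0], run[-1][0]
            calls.append(
                DomainCall(
                    track.chromosome,
                    first * bin_width,
                    (last + 1) * bin_width,
                    min(p for _, p in run),
                    len(run),
                )
            )
            run.clear()

    for idx, state, post in zip(track.bin_indices, track.state, track.posterior):
        if state != ENRICHED or not post > min_posterior:
            flush()
            continue
        if run and idx - run[-1][0] > 1 + bridge_gaps:
            flush()
        run.append((int(idx), float(post)))
    flush()
    return calls


def clamp_to_chrom(call: DomainCall, chrom_sizes: ChromSizes) -> DomainCall | None:
    """Clamp a call to [0, chromosome length); fully-outside calls -> None."""
    if call.chromosome not in chrom_sizes:
        raise KeyError(f"unknown chromosome {call.chromosome}")
    length = chrom_sizes[call.chromosome]
    start = max(call.start, 0)
    end = min(call.end, length)
    if start >= end:
        return None
    if (start, end) == (call.start, call.end):
        return call
    return replace(call, start=start, end=end)


def write_domains_bed(calls: list[DomainCall], path: str | Path) -> None:
    """BED4 of domain calls; the name field carries n_bins and min posterior."""
    ordered = sorted(calls, key=lambda c: (c.chromosome, c.start))
    with open(path, "w") as fh:
        for c in ordered:
            name = f"dom|{c.n_bins}|{c.min_posterior:.17g}"
            fh.write(f"{c.chromosome}\t{c.start}\t{c.end}\t{name}\n")


def read_domains_bed(path: str | Path) -> list[DomainCall]:
    """Parse a BED produced by :func:`write_domains_bed` back into calls."""
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, name = line.rstrip("\n").split("\t")[:4]
            _, n_bins, min_post = name.split("|")
            calls.append(DomainCall(chrom, int(start), int(end), float(min_post), int(n_bins)))
    return calls


def posterior_color(posterior: float) -> tuple[int, int, int] | None:
    """Browser shade for a bin posterior; None below the lowest tier (0.7)."""
    for lower, rgb in _COLOR_TIERS:
        if posterior > lower:
            return rgb
    return None


def write_colored_bins_bed(
    track: PosteriorTrack,
    bin_width: int,
    chrom_sizes: ChromSizes,
    path: str | Path,
    append: bool = False,
    header: bool = True,
) -> None:
    """BED9 of enriched bins shaded by posterior probability.

    Bins at posterior <= 0.7 are omitted.  Coordinates are clamped to the
    chromosome length (the last bin may be truncated).
    """
    length = chrom_sizes[track.chromosome]
    with open(path, "a" if append else "w") as fh:
        if header:
            fh.write('track name="enriched bins" itemRgb="On"\n')
        for idx, state, post in zip(track.bin_indices, track.state, track.posterior):
            if state != ENRICHED:
                continue
            rgb = posterior_color(float(post))
            if rgb is None:
                continue
            start = int(idx) * bin_width
            end = min(start + bin_width, length)
            if start >= length:
                continue
            score = min(1000, math.floor(float(post) * 1000))
            fh.write(
                f"{track.chromosome}\t{start}\t{end}\tp={post:.4f}\t{score}\t.\t"
                f"{start}\t{end}\t{rgb[0]},{rgb[1]},{rgb[2]}\n"
            )
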