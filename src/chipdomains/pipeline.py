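"""The full domain-calling pipeline as a fit-able model object.

``DomainCaller.from_bam(...)`` binds the input files and configuration;
``fit()`` runs binning, normalization, per-chromosome HMM estimation
(with the average-parameter fallback for chromosomes that fail to
converge), posterior decoding, and domain assembly, returning a
:class:`DomainCallerResults` that holds everything and writes the BED
outputs and the run report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import binning, domains as domains_mod, hmm, normalize
from .binning import BinnedCounts, ChromSizes
from .domains import DomainCall
from .hmm import FitResult, PosteriorTrack
from .normalize import ObservationSeries

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunables of a domain-calling run, with the shipped defaults."""

    bin_width: int = binning.DEFAULT_BIN_WIDTH
    min_mapq: int = binning.DEFAULT_MIN_MAPQ
    max_count: float = normalize.DEFAULT_CEILING
    min_count: float = normalize.DEFAULT_FLOOR
    min_posterior: float = domains_mod.DEFAULT_MIN_POSTERIOR
    flank: int = 100
    bridge_gaps: int = 0
    tol: float = hmm.DEFAULT_TOL
    max_iter: int = hmm.DEFAULT_MAX_ITER
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        if self.max_count <= self.min_count:
            raise ValueError("max_count must exceed min_count")
        if not 0.5 < self.min_posterior < 1:
            raise ValueError("min_posterior must be in (0.5, 1)")


class DomainCaller:
    """Two-state HMM enrichment caller bound to ChIP (+ optional control) data.

    Construct from BAM paths with :meth:`from_bam`, or directly from
    per-chromosome binned counts (useful for testing and for re-running
    the model stage without re-reading alignments).
    """

    def __init__(
        self,
        chip_counts: dict[str, BinnedCounts],
        chip_total: int,
        chrom_sizes: ChromSizes,
        control_counts: dict[str, BinnedCounts] | None = None,
        control_total: int | None = None,
        config: RunConfig | None = None,
    ):
        if (control_counts is None) != (control_total is None):
            raise ValueError("control counts and total must be given together")
        self.chip_counts = chip_counts
        self.chip_total = chip_total
        self.control_counts = control_counts
        self.control_total = control_total
        self.chrom_sizes = chrom_sizes
        self.config = config or RunConfig()
        self.has_control = control_counts is not None

    @classmethod
    def from_bam(
        cls,
        treatment: str | Path,
        chrom_sizes: ChromSizes | str | Path,
        control: str | Path | None = None,
        config: RunConfig | None = None,
    ) -> "DomainCaller":
        config = config or RunConfig()
        if not isinstance(chrom_sizes, ChromSizes):
            chrom_sizes = binning.read_chrom_sizes(chrom_sizes)
        chip_counts, chip_total = binning.count_reads(
            treatment, chrom_sizes, config.bin_width, config.min_mapq
        )
        control_counts = control_total = None
        if control is not None:
            control_counts, control_total = binning.count_reads(
                control, chrom_sizes, config.bin_width, config.min_mapq
            )
        return cls(chip_counts, chip_total, chrom_sizes, control_counts, control_total, config)

    def observations(self) -> dict[str, ObservationSeries]:
        """Stage-2 preprocessing for every chromosome (empty series dropped)."""
        cfg = self.config
        out: dict[str, ObservationSeries] = {}
        for name in self.chrom_sizes:
            if self.has_control:
                series = normalize.prepare_observations(
                    self.chip_counts[name],
                    self.control_counts[name],
                    self.chip_total,
                    self.control_total,
                    ceiling=cfg.max_count,
                    floor=cfg.min_count,
                )
            else:
                series = normalize.prepare_no_control(
                    self.chip_counts[name], self.chip_total, ceiling=cfg.max_count
                )
            if len(series) == 0:
                logger.warning("%s: no informative bins; chromosome skipped", name)
                continue
            out[name] = series
        return out

    def fit(self) -> "DomainCallerResults":
        """Run per-chromosome EM, fall back to averaged parameters, decode."""
        cfg = self.config
        observations = self.observations()
        fits: dict[str, FitResult] = {}
        for name, series in observations.items():
            fits[name] = hmm.fit_chromosome(
                series, tol=cfg.tol, max_iter=cfg.max_iter, seed=cfg.seed
            )
            if not fits[name].converged:
                logger.warning("%s: EM did not converge; will use averaged parameters", name)
        if not any(f.converged for f in fits.values()):
            raise RuntimeError("no chromosome could be fit")
        fallback = hmm.average_params(list(fits.values()))

        tracks: dict[str, PosteriorTrack] = {}
        used_params: dict[str, hmm.HMMParams] = {}
        for name, series in observations.items():
            params = fits[name].params if fits[name].converged else fallback
            used_params[name] = params
            tracks[name] = hmm.decode(series, params)

        calls: list[DomainCall] = []
        for name, track in tracks.items():
            for call in domains_mod.bins_to_domains(
                track, cfg.bin_width, cfg.min_posterior, cfg.bridge_gaps
            ):
                clamped = domains_mod.clamp_to_chrom(call, self.chrom_sizes)
                if clamped is not None:
                    calls.append(clamped)
        return DomainCallerResults(self, observations, fits, fallback, used_params, tracks, calls)


@dataclass
class DomainCallerResults:
    """Everything a domain-calling run produced, plus writers for the outputs."""

    model: DomainCaller
    observations: dict[str, ObservationSeries] = field(repr=False)
    fits: dict[str, FitResult] = field(repr=False)
    fallback_params: hmm.HMMParams = field(repr=False)
    params_by_chrom: dict[str, hmm.HMMParams] = field(repr=False)
    tracks: dict[str, PosteriorTrack] = field(repr=False)
    domains: list[DomainCall] = field(repr=False)

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    def write_outputs(self, prefix: str | Path) -> dict[str, Path]:
        """Write <prefix>_domains.bed, <prefix>_bins.bed and <prefix>_report.txt."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "domains": prefix.parent / f"{prefix.name}_domains.bed",
            "bins": prefix.parent / f"{prefix.name}_bins.bed",
            "report": prefix.parent / f"{prefix.name}_report.txt",
        }
        domains_mod.write_domains_bed(self.domains, paths["domains"])
        first = True
        for name in self.model.chrom_sizes:
            if name not in self.tracks:
                continue
            domains_mod.write_colored_bins_bed(
                self.tracks[name],
                self.model.config.bin_width,
                self.model.chrom_sizes,
                paths["bins"],
                append=not first,
                header=first,
            )
            first = False
        with open(paths["report"], "w") as fh:
            fh.write(self.summary() + "\n")
        return paths

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "chipdomains run report",
            "=" * 60,
            f"control dataset      {'yes' if self.model.has_control else 'no'}",
            f"bin width            {cfg.bin_width}",
            f"min MAPQ             {cfg.min_mapq}",
            f"truncation           [{cfg.min_count}, {cfg.max_count}]",
            f"min posterior        {cfg.min_posterior}",
            f"chip reads counted   {self.model.chip_total}",
        ]
        if self.model.has_control:
            lines.append(f"control reads        {self.model.control_total}")
        lines.append(f"domains called       {self.n_domains}")
        lines.append("-" * 60)
        lines.append(
            f"{'chrom':<10}{'bins':>8}{'conv':>6}{'loglik':>14}"
            f"{'mu_dep':>9}{'sd_dep':>9}{'mu_enr':>9}{'sd_enr':>9}"
        )
        for name, fit in self.fits.items():
            p = hmm.canonical_params(self.params_by_chrom[name])
            conv = "yes" if fit.converged else "avg"
            llf = f"{fit.llf:.2f}" if fit.loglik_trace.size else "-"
            lines.append(
                f"{name:<10}{len(self.observations[name]):>8}{conv:>6}{llf:>14}"
                f"{p.emissions[0].mean:>9.3f}{p.emissions[0].sd:>9.3f}"
                f"{p.emissions[1].mean:>9.3f}{p.emissions[1].sd:>9.3f}"
            )
        return "\n".join(lines)
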