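# Methods

## Model

Each chromosome's observation series is the per-bin difference between
depth-normalized ChIP and control read counts, restricted to informative
bins and truncated to a fixed window. A two-state hidden Markov model
with Gaussian emissions is fitted to this series: state 0 ("depleted")
models the null — on deep, genome-scale data the differences form an
approximately normal distribution centered on 0 with standard deviation
around 5 — and state 1 ("enriched") models the right tail produced by
real signal. The Markov chain encodes the expectation that enrichment is
spatially coherent: a bin inside a domain makes its neighbours more
likely to be enriched too, which is what lets the same model capture
both 200 bp peaks (one or two confident bins) and 100 kb domains (long
self-transition runs) without a mode switch.

Assumptions worth stating explicitly:

- emissions are Gaussian given the state — adequate for subtracted,
  truncated counts at moderate depth, not for raw counts;
- bins are conditionally independent given the state path (no
  autocorrelation beyond the chain itself);
- nothing is assumed about read geometry around binding sites (no
  strand cross-correlation, no fragment model);
- the two labels are exchangeable, so enrichment must be identified
  *after* fitting; the enriched state is the one with the larger fitted
  variance (true signal both shifts and spreads the distribution), with
  the larger mean as tie-break. This removes the label-inversion failure
  mode that two-state segmenters are otherwise prone to.

## Pipeline stages and defaults

| parameter | default | units | rationale |
| --- | --- | --- | --- |
| bin width | 1000 | bp | resolves domains and presence/absence of TF binding; lower it (≈200 bp) for sharper peak coordinates |
| min MAPQ | 30 | phred | removes multi-mappers and poor alignments; makes zero-read bins a proxy for unmappable sequence |
| depth divisor | 10⁶ / 10⁷ / 10⁸ | reads | chosen from the smaller dataset's total (<10⁷, <10⁸, <10⁹ respectively; pattern continues by powers of ten) so both datasets land on one scale |
| truncation window | [−10, 200] | normalized reads | −10 ≈ −2 null sd (admits two-sd depletions), 200 curbs repetitive pile-ups while passing real enrichment; user-adjustable |
| min posterior | 0.9 | probability | domain calls keep only the black (highest-confidence) shading tier |
| EM tolerance / cap | 10⁻⁴ / 500 | log-lik / iterations | ordinary EM practice; exposed in `RunConfig` |
| initial transitions | self 0.9 | probability | domains persist across bins; only the emission initialization is moment-based |
| peak flank | 100 | bp | 200 bp refined peaks, the scale of a binding footprint |

Initialization sets the depleted emission to the series' empirical mean
and sd and the enriched emission to three times the mean with the same
sd; the prior is uniform. Zero-mean series leave the two states
coincident at initialization and EM separates them (or fails and is
flagged). Estimation is per chromosome; a chromosome whose EM does not
converge (including emission-sd collapse below 10⁻⁶, which is treated as
failure rather than continued) is retried from three seeded
perturbations of the emission means (±1 empirical sd) and, if still
unconverged, decoded with the element-wise average of the other
chromosomes' parameters (aligned enriched-to-enriched before averaging).
Decoding is per-bin MAP over the smoothed forward–backward posteriors —
the posterior is the quantity the output shades by, so the smoothed
marginal, not the Viterbi path, is the right object.

## Numerics

The forward recursion divides each step by the previous step's total, so
the per-step scales multiply to the marginal likelihood and their logs
accumulate into the log-likelihood. On top of that, per-bin emission
densities are rescaled by their row maximum before entering the
recursion (the rescale folds into the scale term); this keeps the
recursion finite even when an outlying observation underflows both
states' densities. Gradients of the likelihood are never needed: fitting
is pure Baum–Welch, whose M-step is closed-form. Ties in decoding
(posterior exactly 0.5) go to depleted — the conservative call; ties in
variance go to the larger mean. Degenerate inputs (constant or
length-<2 series) are flagged, not fitted.

## Synthetic data

Two generators, both seeded and deterministic:

- `simulate_observations` draws a series directly from a specified HMM
  (default: N(0, 5) vs N(15, 5), self-transitions 0.95 — the null at its
  documented genome-scale sd). Used for oracle, recovery and invariance
  tests.
- `simulate_reads` builds toy experiments: uniform control reads,
  treatment reads at a uniform background rate with an 8× rate inside
  planted domains and Gaussian pile-ups (sd 50 bp, ~1500 reads) at
  planted summits; 50 bp single-end reads, Poisson region counts, 10% of
  reads below the MAPQ threshold so the filter does real work. The
  standard genome is 2 chromosomes × 2 Mb with five 10–50 kb domains,
  five summits and ~200k reads total — sized so the full pipeline runs
  in seconds.

One scale consequence of the toy design is handled explicitly: the
normalized null-difference sd is divisor·√(binw·(1/N_chip+1/N_ctl)/G),
which is ≈5 for genome-scale experiments but ≈70 for a 4 Mb genome at
200k reads. The stock truncation window [−10, 200] (−2σ and 40σ at σ≈5)
would therefore clamp most toy null bins to the floor and degenerate the
Gaussian fit. `recommended_truncation` applies the same −2σ/40σ ratios
to the analytic σ of a given design, and the end-to-end tests use it;
the pipeline defaults themselves are unchanged.

What the generator does **not** emulate: mappability structure and
repeats (so zero-bin exclusion barely triggers), GC bias, PCR
duplicates, fragment-length effects, strand structure, and
overdispersion beyond Poisson. Passing the end-to-end tests therefore
shows the pipeline's machinery is correct and well-calibrated on its own
model; it does not certify performance on real libraries, where the
null is wider-tailed and enrichment less clean.

## Design choices

- One EM implementation with a seeded retry ladder, instead of two
  alternative fitting libraries tried in sequence: a single correct
  Baum–Welch covers both, and retries from perturbed starts address the
  rare non-convergence case the second library existed for.
- Preprocessing-excluded bins break domain contiguity (they carry no
  evidence; bridging them would inflate widths). `--bridge-gaps N`
  optionally spans up to N missing bins.
- Reads are binned by leftmost aligned coordinate — each read counted
  exactly once, deterministically; paired mates count independently.
- The domains BED name field carries `n_bins` and the minimum per-bin
  posterior at full precision, so the BED round-trips exactly.
- Grey shades for the 0.8 and 0.7 posterior tiers are RGB (120,120,120)
  and (180,180,180).

## Limitations

Sequential per-chromosome fitting (independence would permit
parallelism); no local background model, so copy-number variation can
masquerade as enrichment; no FDR calibration — the confidence currency
is the posterior probability itself; >2 states and non-Gaussian
emissions are out of scope.
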