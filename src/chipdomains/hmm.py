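"""Two-state Gaussian-emission hidden Markov model for binned ChIP-seq data.

The observation series for a chromosome — normalized, truncated,
control-subtracted bin counts O_1..O_B — is modelled by a two-state HMM
whose joint likelihood factorizes as

    P(O_{1:B}, S_{1:B} | Theta)
      = P(S_1 = i) P(O_1 | S_1 = i)
        * prod_b P(S_{b+1} = j | S_b = i) P(O_{b+1} | S_{b+1} = j)

with Gaussian emissions per state.  One state models depleted background
(differences centered near 0), the other enriched signal.  Parameters are
estimated by Baum-Welch EM using a scaled forward recursion — each forward
vector is divided by the previous step's total, so the per-step scales
multiply to the marginal likelihood and the log-likelihood accumulates
without underflow.  Per-bin states are decoded from the smoothed
forward-backward posteriors (per-bin MAP), which are also what the BED
output shades by confidence.

Because the two state labels are arbitrary, the enriched state is
identified after fitting as the one capturing the higher variance
(enrichment skews and spreads the observation distribution); this guards
against the label-inversion failure mode of HMM segmenters.

The model-fitting surface follows the statsmodels idiom:
``TwoStateHMM(values).fit()`` returns a :class:`TwoStateHMMResults`
carrying the estimates, the log-likelihood trace and a ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .normalize import ObservationSeries

DEFAULT_TOL = 1e-4
DEFAULT_MAX_ITER = 500
SD_FLOOR = 1e-6
DEFAULT_SELF_TRANSITION = 0.9
N_RETRIES = 3

DEPLETED, ENRICHED = 0, 1
STATE_NAMES = ("depleted", "enriched")

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


class DegenerateSeriesError(ValueError):
    """Series too short or constant: no two-state model can be initialized."""


class EmissionCollapseError(FloatingPointError):
    """A state's emission density became non-finite (sd underflow)."""


@dataclass(frozen=True)
class GaussianEmission:
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError(f"emission sd must be positive, got {self.sd}")

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=np.float64) - self.mean) / self.sd
        return -0.5 * z * z - math.log(self.sd) - _LOG_SQRT_2PI


@dataclass(frozen=True)
class HMMParams:
    """Prior, transition matrix and per-state Gaussian emissions.

    Index 0 is the nominal depleted state and index 1 the nominal
    enriched state; the binding is only resolved for real after fitting
    by :func:`resolve_enriched_state`.
    """

    prior: np.ndarray
    transitions: np.ndarray
    emissions: tuple[GaussianEmission, GaussianEmission]

    def __post_init__(self) -> None:
        object.__setattr__(self, "prior", np.asarray(self.prior, dtype=np.float64))
        object.__setattr__(self, "transitions", np.asarray(self.transitions, dtype=np.float64))
        if self.prior.shape != (2,) or self.transitions.shape != (2, 2):
            raise ValueError("expected a 2-state model")
        if not np.isclose(self.prior.sum(), 1.0):
            raise ValueError("prior must sum to 1")
        if not np.allclose(self.transitions.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if (self.prior < 0).any() or (self.transitions < 0).any():
            raise ValueError("probabilities must be non-negative")

    def swap_states(self) -> "HMMParams":
        """Exchange the two state labels (prior, transition rows/cols, emissions)."""
        return HMMParams(
            self.prior[::-1].copy(),
            self.transitions[::-1, ::-1].copy(),
            (self.emissions[1], self.emissions[0]),
        )

    def emission_logpdf(self, values: np.ndarray) -> np.ndarray:
        """B x 2 matrix of per-state emission log-densities."""
        out = np.column_stack([e.logpdf(values) for e in self.emissions])
        if not np.isfinite([e.sd for e in self.emissions]).all() or np.isnan(out).any():
            raise EmissionCollapseError("non-finite emission density")
        return out


@dataclass
class FitResult:
    params: HMMParams
    converged: bool
    loglik_trace: np.ndarray = field(repr=False)
    n_iterations: int = 0

    @property
    def llf(self) -> float:
        return float(self.loglik_trace[-1]) if self.loglik_trace.size else float("nan")


@dataclass
class PosteriorTrack:
    """Per-bin decoded state and the posterior probability of that state."""

    chromosome: str
    bin_indices: np.ndarray = field(repr=False)
    state: np.ndarray = field(repr=False)
    posterior: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.bin_indices.size


def init_params(series: ObservationSeries) -> HMMParams:
    """Moment-based starting parameters.

    The enriched state starts at three times the empirical mean with the
    empirical sd; the depleted state starts at the empirical mean and sd.
    The prior is uniform and self-transitions start at 0.9, reflecting
    that domains persist across neighbouring bins.
    """
    if len(series) < 2:
        raise DegenerateSeriesError(f"{series.chromosome}: fewer than 2 observations")
    mean = float(series.values.mean())
    sd = float(series.values.std(ddof=0))
    if sd <= 0:
        raise DegenerateSeriesError(f"{series.chromosome}: zero variance")
    p = DEFAULT_SELF_TRANSITION
    return HMMParams(
        prior=np.array([0.5, 0.5]),
        transitions=np.array([[p, 1 - p], [1 - p, p]]),
        emissions=(GaussianEmission(mean, sd), GaussianEmission(3.0 * mean, sd)),
    )


def _scaled_passes(values: np.ndarray, params: HMMParams):
    """Scaled forward and backward recursions.

    Returns (loglik, alpha_hat, log_scales, beta_hat, emission_probs)
    where alpha_hat rows are the normalized forward variables, beta_hat
    the compatibly-scaled backward variables, and emission_probs the
    per-bin emission densities rescaled by their row maximum (the rescale
    folds into the scales, keeping the recursion finite for outliers).
    """
    B = values.size
    log_e = params.emission_logpdf(values)
    log_e_max = log_e.max(axis=1)
    e = np.exp(log_e - log_e_max[:, None])  # row max = 1, no underflow to all-zero

    alpha_hat = np.empty((B, 2))
    log_scales = np.empty(B)
    a = params.prior * e[0]
    c = a.sum()
    if c <= 0 or not np.isfinite(c):
        raise EmissionCollapseError("forward scale vanished at bin 0")
    alpha_hat[0] = a / c
    log_scales[0] = math.log(c) + log_e_max[0]
    T = params.transitions
    for b in range(1, B):
        a = e[b] * (alpha_hat[b - 1] @ T)
        c = a.sum()
        if c <= 0 or not np.isfinite(c):
            raise EmissionCollapseError(f"forward scale vanished at bin {b}")
        alpha_hat[b] = a / c
        log_scales[b] = math.log(c) + log_e_max[b]

    beta_hat = np.empty((B, 2))
    beta_hat[B - 1] = 1.0
    for b in range(B - 2, -1, -1):
        v = T @ (e[b + 1] * beta_hat[b + 1])
        s = v.sum()
        if s <= 0 or not np.isfinite(s):
            raise EmissionCollapseError(f"backward scale vanished at bin {b}")
        beta_hat[b] = v / s

    loglik = float(log_scales.sum())
    return loglik, alpha_hat, log_scales, beta_hat, e


def log_forward(series: ObservationSeries, params: HMMParams):
    """Scaled forward recursion.

    Returns ``(log_likelihood, scaled_forward, log_scales)`` with
    ``log_likelihood == log_scales.sum()`` and scaled_forward rows the
    normalized forward variables P(S_b | O_{1:b}).
    """
    loglik, alpha_hat, log_scales, _, _ = _scaled_passes(series.values, params)
    return loglik, alpha_hat, log_scales


def forward_backward(series: ObservationSeries, params: HMMParams) -> np.ndarray:
    """Smoothed per-bin state posteriors P(S_b | O_{1:B}), rows summing to 1."""
    _, alpha_hat, _, beta_hat, _ = _scaled_passes(series.values, params)
    gamma = alpha_hat * beta_hat
    return gamma / gamma.sum(axis=1, keepdims=True)


def em_fit(
    series: ObservationSeries,
    init: HMMParams,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> FitResult:
    """Baum-Welch EM from the given start.

    Iterates expectation (forward-backward responsibilities) and
    maximization (closed-form prior/transition/Gaussian updates) until the
    log-likelihood improves by less than ``tol`` or ``max_iter`` is hit.
    A state whose sd collapses below ``SD_FLOOR`` signals convergence
    failure rather than continuing with a degenerate density.
    """
    values = series.values
    B = values.size
    if B < 2:
        raise DegenerateSeriesError(f"{series.chromosome}: fewer than 2 observations")
    params = init
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        try:
            loglik, alpha_hat, _, beta_hat, e = _scaled_passes(values, params)
        except EmissionCollapseError:
            return FitResult(params, False, np.asarray(trace), n_iter - 1)
        trace.append(loglik)

        gamma = alpha_hat * beta_hat
        gamma /= gamma.sum(axis=1, keepdims=True)
        # xi[i, j] summed over b: responsibilities for each transition
        eb = e[1:] * beta_hat[1:]            # (B-1, 2)
        xi_sum = np.zeros((2, 2))
        num = alpha_hat[:-1, :, None] * params.transitions[None, :, :] * eb[:, None, :]
        num /= num.sum(axis=(1, 2), keepdims=True)
        xi_sum = num.sum(axis=0)

        prior = gamma[0]
        occupancy = gamma[:-1].sum(axis=0)
        if (occupancy <= 0).any():  # a state lost all responsibility
            return FitResult(params, False, np.asarray(trace), n_iter)
        trans = xi_sum / occupancy[:, None]
        trans /= trans.sum(axis=1, keepdims=True)
        weights = gamma.sum(axis=0)
        means = gamma.T @ values / weights
        sds = np.sqrt(
            np.einsum("bj,bj->j", gamma, (values[:, None] - means[None, :]) ** 2) / weights
        )
        if (sds < SD_FLOOR).any() or not np.isfinite(sds).all():
            return FitResult(params, False, np.asarray(trace), n_iter)
        params = HMMParams(
            prior / prior.sum(),
            trans,
            (GaussianEmission(means[0], sds[0]), GaussianEmission(means[1], sds[1])),
        )
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
    return FitResult(params, converged, np.asarray(trace), n_iter)


def fit_chromosome(
    series: ObservationSeries,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    n_retries: int = N_RETRIES,
    seed: int = 0,
) -> FitResult:
    """Fit one chromosome, retrying from perturbed starts on failure.

    The first attempt starts from the moment-based initialization; each
    retry perturbs the two emission means by +/- one empirical sd (seeded,
    reproducible).  A result that never converges is returned flagged so
    the caller can fall back to the average of the other chromosomes'
    parameters.
    """
    try:
        init = init_params(series)
    except DegenerateSeriesError:
        dummy = HMMParams(
            np.array([0.5, 0.5]),
            np.array([[0.9, 0.1], [0.1, 0.9]]),
            (GaussianEmission(0.0, 1.0), GaussianEmission(1.0, 1.0)),
        )
        return FitResult(dummy, False, np.asarray([]), 0)
    result = em_fit(series, init, tol=tol, max_iter=max_iter)
    if result.converged:
        return result
    rng = np.random.default_rng(seed)
    sd = float(series.values.std(ddof=0))
    for _ in range(n_retries):
        jitter = rng.uniform(-sd, sd, size=2)
        perturbed = replace(
            init,
            emissions=(
                GaussianEmission(init.emissions[0].mean + jitter[0], init.emissions[0].sd),
                GaussianEmission(init.emissions[1].mean + jitter[1], init.emissions[1].sd),
            ),
        )
        retry = em_fit(series, perturbed, tol=tol, max_iter=max_iter)
        if retry.converged:
            return retry
        if retry.loglik_trace.size and (
            not result.loglik_trace.size or retry.llf > result.llf
        ):
            result = retry
    return result


def resolve_enriched_state(params: HMMParams) -> int:
    """Index of the enriched state: the one capturing the higher variance.

    Enriched bins are both shifted and spread by real signal, so the
    wider emission marks enrichment regardless of which label EM happened
    to assign.  Equal variances fall back to the larger mean.
    """
    v0, v1 = params.emissions[0].sd ** 2, params.emissions[1].sd ** 2
    if v0 != v1:
        return int(v1 > v0)
    return int(params.emissions[1].mean >= params.emissions[0].mean)


def canonical_params(params: HMMParams) -> HMMParams:
    """Return params with the enriched state at index 1 (swapping if inverted)."""
    if resolve_enriched_state(params) == ENRICHED:
        return params
    return params.swap_states()


def average_params(results: list[FitResult]) -> HMMParams:
    """Element-wise mean of converged per-chromosome parameters.

    Each result is first aligned so its enriched (higher-variance) state
    sits at index 1; averaging then pairs enriched with enriched even if
    some chromosomes fit with inverted labels.  Transition rows are
    re-normalized after averaging.
    """
    converged = [r for r in results if r.converged]
    if not converged:
        raise RuntimeError("no chromosome could be fit; cannot average parameters")
    aligned = [canonical_params(r.params) for r in converged]
    prior = np.mean([p.prior for p in aligned], axis=0)
    trans = np.mean([p.transitions for p in aligned], axis=0)
    trans /= trans.sum(axis=1, keepdims=True)
    means = np.mean([[p.emissions[0].mean, p.emissions[1].mean] for p in aligned], axis=0)
    sds = np.mean([[p.emissions[0].sd, p.emissions[1].sd] for p in aligned], axis=0)
    return HMMParams(
        prior / prior.sum(),
        trans,
        (GaussianEmission(means[0], sds[0]), GaussianEmission(means[1], sds[1])),
    )


def decode(series: ObservationSeries, params: HMMParams) -> PosteriorTrack:
    """Per-bin MAP decoding from the smoothed posteriors.

    Each bin gets the more probable state and that state's posterior, with
    labels mapped so state 1 means enriched.  Exact ties go to depleted —
    the conservative call.
    """
    post = forward_backward(series, params)
    enriched_idx = resolve_enriched_state(params)
    p_enriched = post[:, enriched_idx]
    state = (p_enriched > 0.5).astype(np.int8)  # tie (==0.5) -> depleted
    posterior = np.where(state == ENRICHED, p_enriched, 1.0 - p_enriched)
    return PosteriorTrack(series.chromosome, series.bin_indices.copy(), state, posterior)


class TwoStateHMM:
    """Two-state Gaussian HMM for one chromosome's observation series.

    Parameters
    ----------
    series : ObservationSeries or array-like
        Normalized, truncated per-bin values.  A bare array is wrapped
        with consecutive bin indices.

    Examples
    --------
    >>> res = TwoStateHMM([0.1, -0.3, 14.8, 15.2, 0.2]).fit()
    >>> res.converged
    True
    """

    def __init__(self, series, chromosome: str = "chr"):
        if isinstance(series, ObservationSeries):
            self.series = series
        else:
            values = np.asarray(series, dtype=np.float64)
            self.series = ObservationSeries(chromosome, values, np.arange(values.size))

    def fit(
        self,
        start_params: HMMParams | None = None,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        n_retries: int = N_RETRIES,
        seed: int = 0,
    ) -> "TwoStateHMMResults":
        if start_params is not None:
            fit = em_fit(self.series, start_params, tol=tol, max_iter=max_iter)
        else:
            fit = fit_chromosome(
                self.series, tol=tol, max_iter=max_iter, n_retries=n_retries, seed=seed
            )
        return TwoStateHMMResults(self, fit)

    def loglike(self, params: HMMParams) -> float:
        return log_forward(self.series, params)[0]


class TwoStateHMMResults:
    """Fitted two-state HMM: estimates, trace, posteriors and summary."""

    def __init__(self, model: TwoStateHMM, fit: FitResult):
        self.model = model
        self._fit = fit
        self.params = fit.params
        self.converged = fit.converged
        self.loglik_trace = fit.loglik_trace
        self.n_iterations = fit.n_iterations

    @property
    def llf(self) -> float:
        return self._fit.llf

    @property
    def enriched_state(self) -> int:
        return resolve_enriched_state(self.params)

    def posteriors(self) -> np.ndarray:
        return forward_backward(self.model.series, self.params)

    def decode(self) -> PosteriorTrack:
        return decode(self.model.series, self.params)

    def summary(self) -> str:
        p = self.params
        enriched = self.enriched_state
        lines = [
            "Two-state Gaussian HMM",
            "=" * 46,
            f"chromosome       {self.model.series.chromosome}",
            f"observations     {len(self.model.series)}",
            f"converged        {self.converged}",
            f"iterations       {self.n_iterations}",
            f"log-likelihood   {self.llf:.4f}",
            "-" * 46,
            f"{'state':<12}{'mean':>10}{'sd':>10}{'self-trans':>12}",
        ]
        for j in (0, 1):
            label = "enriched" if j == enriched else "depleted"
            lines.append(
                f"{label:<12}{p.emissions[j].mean:>10.4f}{p.emissions[j].sd:>10.4f}"
                f"{p.transitions[j, j]:>12.4f}"
            )
        lines.append(f"prior            [{p.prior[0]:.4f}, {p.prior[1]:.4f}]")
        return "\n".join(lines)
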