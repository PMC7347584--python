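"""Bayesian two-group trait comparison via Gibbs sampling.

Fits the linear model

    value = mu_NC * 1[group == NC] + mu_VT * 1[group == VT]
            (+ beta * (covariate - mean covariate)) + e,      e ~ N(0, sigma2)

with bounded flat priors on all unknowns, by a two-block Gibbs sampler:

1. the location vector is drawn from its multivariate-normal full
   conditional, truncated to the prior bounds by rejection;
2. sigma2 is drawn from its scaled-inverse-chi-square full conditional
   (flat prior on sigma2 within bounds, rejecting draws outside them).

The quantity of interest is the group contrast D = mu_NC - mu_VT, recorded
at every saved iteration.  Posterior summaries follow directly from the
saved draws: the contrast mean, the directional posterior probability P0,
the shortest (highest-density) interval, a batch-means Monte Carlo
standard error, and the Geweke Z convergence statistic.  A difference is
declared *relevant* when |D| exceeds a threshold R (one third of the
pooled trait standard deviation by default) and P0 > 0.8.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from transgen.errors import ConfigError, DesignError, FitError

logger = logging.getLogger(__name__)

#: Default prior bounds: effectively non-informative but proper.
LOCATION_BOUNDS = (-1e6, 1e6)
SIGMA2_BOUNDS = (1e-12, 1e12)

_MAX_REJECT_PER_DRAW = 100_000


@dataclass(frozen=True)
class GibbsConfig:
    """Chain length, thinning, prior bounds and seed for one Gibbs run.

    The saved chain has exactly ``(n_iter - burn_in) // thin`` draws; the
    constructor requires the division to be exact so the bookkeeping is
    unambiguous.
    """

    n_iter: int = 60_000
    burn_in: int = 10_000
    thin: int = 10
    prior_bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_iter <= 0 or self.burn_in < 0:
            raise ConfigError("n_iter must be positive and burn_in non-negative")
        if self.burn_in >= self.n_iter:
            raise ConfigError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ConfigError("thin must be >= 1")
        if (self.n_iter - self.burn_in) % self.thin != 0:
            raise ConfigError("(n_iter - burn_in) must be divisible by thin")
        for name, (lo, hi) in dict(self.prior_bounds).items():
            if not lo < hi:
                raise ConfigError(f"prior bound for {name!r} has low >= high")

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin

    def bounds_for(self, name: str) -> tuple[float, float]:
        if name in self.prior_bounds:
            return tuple(self.prior_bounds[name])  # type: ignore[return-value]
        if name == "sigma2":
            return SIGMA2_BOUNDS
        return self.prior_bounds.get("location", LOCATION_BOUNDS)


@dataclass
class PosteriorChain:
    """Saved Gibbs draws for one two-group comparison."""

    samples_D: np.ndarray
    samples_sigma2: np.ndarray
    samples_beta: Optional[np.ndarray]
    config_used: GibbsConfig

    def __post_init__(self) -> None:
        self.samples_D = np.asarray(self.samples_D, dtype=float)
        self.samples_sigma2 = np.asarray(self.samples_sigma2, dtype=float)
        if self.samples_beta is not None:
            self.samples_beta = np.asarray(self.samples_beta, dtype=float)
            if self.samples_beta.shape != self.samples_D.shape:
                raise ValueError("samples_beta length differs from samples_D")
        if self.samples_sigma2.shape != self.samples_D.shape:
            raise ValueError("samples_sigma2 length differs from samples_D")
        if np.any(self.samples_sigma2 <= 0):
            raise ValueError("sigma2 draws must be positive")


@dataclass(frozen=True)
class PosteriorSummary:
    """Point and interval summaries of one saved contrast chain.

    ``geweke_z`` is NaN when the statistic is undefined (constant chain).
    """

    D_mean: float
    P0: float
    hpd_low: float
    hpd_high: float
    mcse: float
    geweke_z: float
    n_saved: int


@dataclass(frozen=True)
class RelevanceDecision:
    R: float
    relevant: bool
    criterion_trace: Mapping[str, float]


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def _gibbs_linear(
    X: np.ndarray,
    y: np.ndarray,
    contrast: np.ndarray,
    theta_lo: np.ndarray,
    theta_hi: np.ndarray,
    config: GibbsConfig,
    beta_col: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    """Run the two-block Gibbs sampler for a fixed-effects linear model.

    Because the flat-prior location full conditional is centred on the OLS
    solution for every sigma2, the whole chain reduces to a scalar sigma2
    recursion plus a vectorised location reconstruction; the sequential
    fallback with explicit rejection is only entered when a draw actually
    escapes the prior bounds.
    """
    n, p = X.shape
    if n - p <= 0:
        raise FitError("zero residual degrees of freedom")
    # sigma2 | theta ~ SSE / chisq(n): the scaled-inverse-chi-square full
    # conditional under the scale-invariant prior, which makes the marginal
    # posterior of any location contrast exactly location-scale t with
    # n - p degrees of freedom (the analytic flat-prior reference).
    nu = n

    XtX = X.T @ X
    XtX_inv = np.linalg.inv(XtX)
    L = np.linalg.cholesky(XtX_inv)
    theta_hat = XtX_inv @ (X.T @ y)
    resid = y - X @ theta_hat
    sse_min = float(resid @ resid)
    if sse_min <= 0:
        # Perfect fit: residual variance collapses; refuse rather than emit
        # a degenerate chain.
        raise FitError("residual sum of squares is zero; model is saturated")

    rng = np.random.default_rng(config.seed)
    n_iter = config.n_iter
    Z = rng.standard_normal((n_iter, p))
    C = rng.chisquare(nu, n_iter)
    q = np.einsum("ij,ij->i", Z, Z)
    s2_lo, s2_hi = config.bounds_for("sigma2")

    # Fast path: ignore bounds, then verify.
    sig_for_theta = np.empty(n_iter)
    s2 = np.empty(n_iter)
    cur = sse_min / (n - p)
    q_list = q.tolist()
    c_list = C.tolist()
    for t in range(n_iter):
        sig_for_theta[t] = cur
        cur = (sse_min + cur * q_list[t]) / c_list[t]
        s2[t] = cur
    LZ = Z @ L.T
    theta = theta_hat[None, :] + np.sqrt(sig_for_theta)[:, None] * LZ

    in_bounds = (
        np.all(theta >= theta_lo[None, :])
        and np.all(theta <= theta_hi[None, :])
        and np.all(s2 >= s2_lo)
        and np.all(s2 <= s2_hi)
    )
    if not in_bounds:
        theta, s2 = _gibbs_linear_bounded(
            theta_hat, L, sse_min, n, p, nu, theta_lo, theta_hi,
            (s2_lo, s2_hi), Z, C, rng,
        )

    idx = slice(config.burn_in, n_iter, config.thin)
    samples_D = theta[idx] @ contrast
    samples_sigma2 = s2[idx]
    samples_beta = theta[idx, beta_col] if beta_col is not None else None
    return samples_D, samples_sigma2, samples_beta


def _gibbs_linear_bounded(
    theta_hat: np.ndarray,
    L: np.ndarray,
    sse_min: float,
    n: int,
    p: int,
    nu: int,
    theta_lo: np.ndarray,
    theta_hi: np.ndarray,
    s2_bounds: tuple[float, float],
    Z: np.ndarray,
    C: np.ndarray,
    rng: np.random.Generator,
    ) -> tuple[np.ndarray, np.ndarray]:
    """Sequential sampler honouring the prior bounds by rejection."""
    s2_lo, s2_hi = s2_bounds
    n_iter = Z.shape[0]
    theta = np.empty((n_iter, p))
    s2 = np.empty(n_iter)
    cur = sse_min / (n - p)
    n_reject = 0
    for t in range(n_iter):
        z = Z[t]
        sd = math.sqrt(cur)
        th = theta_hat + sd * (L @ z)
        tries = 0
        while np.any(th < theta_lo) or np.any(th > theta_hi):
            n_reject += 1
            tries += 1
            if tries > _MAX_REJECT_PER_DRAW:
                raise FitError("location prior bounds reject virtually all draws")
            z = rng.standard_normal(p)
            th = theta_hat + sd * (L @ z)
        theta[t] = th
        sse_t = sse_min + cur * float(z @ z)
        c = C[t]
        cand = sse_t / c
        tries = 0
        while not (s2_lo <= cand <= s2_hi):
            n_reject += 1
            tries += 1
            if tries > _MAX_REJECT_PER_DRAW:
                raise FitError("sigma2 prior bounds reject virtually all draws")
            cand = sse_t / rng.chisquare(nu)
        cur = cand
        s2[t] = cur
    if n_reject > 0.5 * n_iter:
        logger.warning(
            "Gibbs chain rejected %d proposals over %d iterations (>50%%); "
            "prior bounds may be too tight", n_reject, n_iter,
        )
    return theta, s2


def fit_two_group_model(
    table: pd.DataFrame,
    trait: str,
    generation: str,
    use_covariate: bool = False,
    config: Optional[GibbsConfig] = None,
) -> PosteriorChain:
    """Fit the two-group model for one trait within one generation.

    ``table`` is a long-format trait table with columns ``animal_id``,
    ``group`` (NC/VT), ``generation``, ``trait``, ``value`` and, when
    ``use_covariate`` is requested, ``covariate``.  Returns the saved
    chain of the NC - VT contrast (plus sigma2 and, if fitted, the
    covariate slope).  Deterministic given ``config.seed``.
    """
    config = config or GibbsConfig()
    sub = table[(table["trait"] == trait) & (table["generation"] == generation)]
    if sub.empty:
        raise DesignError(f"no rows for trait {trait!r} in generation {generation!r}")
    values = sub["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise DesignError("trait values must be finite")
    is_vt = (sub["group"] == "VT").to_numpy()
    is_nc = (sub["group"] == "NC").to_numpy()
    if not np.array_equal(is_vt | is_nc, np.ones(len(sub), dtype=bool)):
        raise DesignError("group labels must be NC or VT")
    if is_nc.sum() < 2 or is_vt.sum() < 2:
        raise DesignError("each group needs at least 2 observations")

    cols = [is_nc.astype(float), is_vt.astype(float)]
    names = ["mu_NC", "mu_VT"]
    beta_col = None
    if use_covariate:
        if "covariate" not in sub.columns or sub["covariate"].isna().any():
            raise DesignError("covariate requested but missing for some rows")
        cov = sub["covariate"].to_numpy(dtype=float)
        cols.append(cov - cov.mean())
        names.append("beta")
        beta_col = 2
    X = np.column_stack(cols)
    contrast = np.zeros(X.shape[1])
    contrast[0], contrast[1] = 1.0, -1.0  # NC - VT

    theta_lo = np.array([config.bounds_for(nm)[0] for nm in names])
    theta_hi = np.array([config.bounds_for(nm)[1] for nm in names])

    samples_D, samples_sigma2, samples_beta = _gibbs_linear(
        X, values, contrast, theta_lo, theta_hi, config, beta_col=beta_col,
    )
    return PosteriorChain(samples_D, samples_sigma2, samples_beta, config)


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------


def hpd_interval(samples: Sequence[float], prob: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous window of sorted draws containing ``prob`` mass.

    Among all windows of ``ceil(prob * n)`` consecutive order statistics the
    narrowest is returned; the first wins on ties.
    """
    if not 0.0 < prob < 1.0:
        raise ValueError("prob must lie strictly between 0 and 1")
    x = np.sort(np.asarray(samples, dtype=float))
    n = x.size
    w = math.ceil(prob * n)
    if n < w + 1:
        raise ValueError(f"need at least {w + 1} samples for prob={prob}, got {n}")
    widths = x[w - 1:] - x[: n - w + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + w - 1])


def _batch_means_lrv(x: np.ndarray) -> float:
    """Long-run variance (spectral density at zero) via batch means."""
    n = x.size
    n_batches = max(2, int(math.sqrt(n)))
    m = n // n_batches
    if m < 1:
        return float(np.var(x, ddof=1)) if n > 1 else 0.0
    bm = x[: n_batches * m].reshape(n_batches, m).mean(axis=1)
    if np.all(bm == bm[0]):
        return 0.0
    return float(m * np.var(bm, ddof=1))


def geweke_z(samples: Sequence[float], frac_a: float = 0.1, frac_b: float = 0.5) -> float:
    """Geweke convergence Z: early-window vs late-window mean comparison.

    Window variances use the batch-means spectral estimator.  Returns NaN
    (undefined-flagged) when both windows have zero variance.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    n_a = int(n * frac_a)
    n_b = int(n * frac_b)
    if n_a < 10 or n_b < 10:
        raise ValueError("both Geweke windows must contain at least 10 samples")
    a = x[:n_a]
    b = x[n - n_b:]
    va = _batch_means_lrv(a)
    vb = _batch_means_lrv(b)
    denom_sq = va / n_a + vb / n_b
    if denom_sq == 0.0:
        return float("nan")
    return float((a.mean() - b.mean()) / math.sqrt(denom_sq))


def mc_se_batch_means(samples: Sequence[float], n_batches: int = 50) -> float:
    """Monte Carlo standard error of the chain mean by batch means."""
    x = np.asarray(samples, dtype=float)
    if n_batches < 10:
        raise ValueError("need at least 10 batches")
    m = x.size // n_batches
    if m < 10:
        raise ValueError("need batches of at least 10 samples")
    bm = x[: n_batches * m].reshape(n_batches, m).mean(axis=1)
    return float(np.std(bm, ddof=1) / math.sqrt(n_batches))


def summarize_posterior(chain: PosteriorChain, prob: float = 0.95) -> PosteriorSummary:
    """Collapse a saved contrast chain into its reporting summary.

    P0 is the fraction of draws sharing the sign of the posterior mean;
    draws exactly at zero are excluded from the numerator.  A zero posterior
    mean reports the positive side (deterministic tie-break).
    """
    d = np.asarray(chain.samples_D, dtype=float)
    n = d.size
    if n == 0:
        raise ValueError("empty chain")
    d_mean = float(d.mean())
    side = 1.0 if d_mean >= 0 else -1.0
    p0 = float(np.count_nonzero(np.sign(d) == side) / n)
    if np.all(d == d[0]):
        hpd_low = hpd_high = float(d[0])
        mcse = 0.0
        gz = float("nan")
    else:
        hpd_low, hpd_high = hpd_interval(d, prob)
        n_batches = 50 if n >= 500 else 10
        mcse = mc_se_batch_means(d, n_batches=n_batches)
        gz = geweke_z(d)
    return PosteriorSummary(
        D_mean=d_mean, P0=p0, hpd_low=hpd_low, hpd_high=hpd_high,
        mcse=mcse, geweke_z=gz, n_saved=n,
    )


# ---------------------------------------------------------------------------
# Relevance rule
# ---------------------------------------------------------------------------


def relevant_value(values: Sequence[float]) -> float:
    """Relevance threshold R: one third of the pooled sample SD (ddof=1)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values to compute R")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        logger.warning("all trait values identical; relevance threshold R = 0")
    return sd / 3.0


def decide_relevance(summary: PosteriorSummary, R: float) -> RelevanceDecision:
    """Apply the decision rule: relevant iff |D_mean| > R and P0 > 0.8."""
    if R < 0:
        raise ValueError("R must be non-negative")
    abs_d = abs(summary.D_mean)
    relevant = bool(abs_d > R and summary.P0 > 0.8)
    return RelevanceDecision(
        R=float(R),
        relevant=relevant,
        criterion_trace={"abs_D": abs_d, "P0": summary.P0},
    )
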