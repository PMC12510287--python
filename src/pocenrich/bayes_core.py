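"""Beta-binomial inference and Go/No-Go/Consider decision rules.

The design treats the number of responses ``r`` among ``n`` patients as
binomial with response rate ``p`` and places a Jeffreys ``Beta(0.5, 0.5)``
prior on ``p``, so that ``p | data ~ Beta(0.5 + r, 0.5 + n - r)``.

Final-analysis decisions follow the dual-criterion (TV/LRV) framework:

* **No-Go** if ``P(p > TV | data) <= alpha_TV`` — the posterior gives little
  credence to reaching the target value;
* otherwise **Go** if ``P(p > LRV | data) >= alpha_LRV`` — the response rate
  clears the lower reference value with high confidence;
* otherwise **Consider**.

At an interim with ``n`` of ``N`` patients observed, the predictive
probability of success ``PrGo`` is the beta-binomial posterior predictive
probability that the final data will satisfy the Go criterion.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.special import betaln

__all__ = [
    "BetaParams",
    "EfficacyCriteria",
    "FinalOutcome",
    "posterior",
    "prob_exceeds",
    "final_decision",
    "predictive_pmf",
    "predictive_prob_go",
]


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a (possibly degenerate) beta posterior.

    A degenerate posterior arises from an improper ``Beta(0, 0)`` prior with
    ``r = 0`` (point mass at 0) or ``r = n`` (point mass at 1): the limit of
    ``Beta(eps, n - r)`` / ``Beta(r, eps)`` as ``eps -> 0``.  Degenerate
    posteriors are flagged rather than carrying zero shapes.

    Parameters
    ----------
    alpha, beta_
        Beta shape parameters; both strictly positive unless degenerate.
    degenerate_at
        When not ``None``, the posterior is a point mass at this value
        (0.0 or 1.0) and the shapes are not meaningful.
    """

    alpha: float
    beta_: float
    degenerate_at: float | None = None

    def __post_init__(self) -> None:
        if self.degenerate_at is None:
            if not (self.alpha > 0 and self.beta_ > 0):
                raise ValueError(
                    "proper beta shapes must be strictly positive; "
                    f"got alpha={self.alpha}, beta_={self.beta_}"
                )
        elif self.degenerate_at not in (0.0, 1.0):
            raise ValueError("a degenerate posterior must sit at 0 or 1")

    @property
    def is_degenerate(self) -> bool:
        return self.degenerate_at is not None


@dataclass(frozen=True)
class EfficacyCriteria:
    """Dual-criterion efficacy thresholds for the final analysis.

    Parameters
    ----------
    TV
        Target value: the desired response-rate level.
    LRV
        Lower reference value: the minimal acceptable response rate.
    alpha_TV
        No-Go if ``P(p > TV) <= alpha_TV``.
    alpha_LRV
        Go if ``P(p > LRV) >= alpha_LRV``.
    """

    TV: float
    LRV: float
    alpha_TV: float
    alpha_LRV: float

    def __post_init__(self) -> None:
        if not (0.0 < self.LRV < self.TV < 1.0):
            raise ValueError(f"need 0 < LRV < TV < 1; got LRV={self.LRV}, TV={self.TV}")
        if not (0.0 < self.alpha_TV < 1.0 and 0.0 < self.alpha_LRV < 1.0):
            raise ValueError("alpha_TV and alpha_LRV must lie strictly in (0, 1)")


class FinalOutcome(enum.Enum):
    """Terminal development recommendation at an analysis."""

    GO = "Go"
    NO_GO = "No Go"
    CONSIDER = "Consider"


def _validate_counts(r: int, n: int) -> None:
    if r < 0 or n < 0:
        raise ValueError(f"counts must be non-negative; got r={r}, n={n}")
    if r > n:
        raise ValueError(f"responses cannot exceed patients; got r={r} > n={n}")


def posterior(r: int, n: int, prior_a: float = 0.5, prior_b: float = 0.5) -> BetaParams:
    """Beta posterior of the response rate after ``r`` responses in ``n`` patients.

    Returns ``Beta(prior_a + r, prior_b + n - r)``.  With an improper prior
    (``prior_a = prior_b = 0``) and ``r = 0`` or ``r = n``, one shape is zero
    and the posterior is returned as a point mass at 0 or 1 respectively.
    """
    _validate_counts(r, n)
    if prior_a < 0 or prior_b < 0:
        raise ValueError("prior shapes must be non-negative")
    a = prior_a + r
    b = prior_b + n - r
    if a == 0.0 and b == 0.0:
        raise ValueError("posterior with both shapes zero is undefined (no data, improper prior)")
    if a == 0.0:
        return BetaParams(alpha=float("nan"), beta_=float("nan"), degenerate_at=0.0)
    if b == 0.0:
        return BetaParams(alpha=float("nan"), beta_=float("nan"), degenerate_at=1.0)
    return BetaParams(alpha=a, beta_=b)


def prob_exceeds(post: BetaParams, threshold: float) -> float:
    """Posterior upper-tail probability ``P(p > threshold)``.

    Uses the regularized incomplete beta function (survival function of the
    beta distribution).  A degenerate posterior at ``v`` returns the
    indicator of ``v > threshold``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1]; got {threshold}")
    if post.is_degenerate:
        return 1.0 if post.degenerate_at > threshold else 0.0
    return float(stats.beta.sf(threshold, post.alpha, post.beta_))


@lru_cache(maxsize=65536)
def _go_tail(r: int, n: int, LRV: float) -> float:
    """P(p > LRV | Beta(0.5 + r, 0.5 + n - r)), cached over the count grid."""
    return float(stats.beta.sf(LRV, 0.5 + r, 0.5 + n - r))


def final_decision(r: int, n: int, crit: EfficacyCriteria) -> FinalOutcome:
    """Go/No-Go/Consider decision from ``r`` responses in ``n`` patients.

    The No-Go (futility) condition is checked first; when both tails would
    qualify (possible since TV > LRV), the stop wins.
    """
    _validate_counts(r, n)
    if n < 1:
        raise ValueError("final decision needs at least one patient")
    post = posterior(r, n)
    if prob_exceeds(post, crit.TV) <= crit.alpha_TV:
        return FinalOutcome.NO_GO
    if prob_exceeds(post, crit.LRV) >= crit.alpha_LRV:
        return FinalOutcome.GO
    return FinalOutcome.CONSIDER


def predictive_pmf(r_obs: int, n_obs: int, m_future: int) -> np.ndarray:
    """Posterior predictive mass function of the future response count.

    Given ``r_obs`` responses in ``n_obs`` patients under the Jeffreys prior,
    the number of responses ``r'`` among ``m_future`` further patients is
    beta-binomial::

        P(r') = C(m, r') * B(a + r', b + m - r') / B(a, b)

    with ``(a, b) = (0.5 + r_obs, 0.5 + n_obs - r_obs)``.

    Returns
    -------
    ndarray of shape ``(m_future + 1,)`` summing to 1.
    """
    _validate_counts(r_obs, n_obs)
    if m_future < 0:
        raise ValueError("future sample size must be non-negative")
    if m_future == 0:
        return np.ones(1)
    a = 0.5 + r_obs
    b = 0.5 + n_obs - r_obs
    rp = np.arange(m_future + 1)
    # log pmf via gammaln-based log-beta keeps small tails accurate
    log_pmf = (
        np.array([math.lgamma(m_future + 1) - math.lgamma(k + 1) - math.lgamma(m_future - k + 1) for k in rp])
        + betaln(a + rp, b + m_future - rp)
        - betaln(a, b)
    )
    pmf = np.exp(log_pmf)
    return pmf / pmf.sum()


@lru_cache(maxsize=65536)
def _predictive_prob_go_cached(
    r_obs: int, n_obs: int, N_total: int, LRV: float, alpha_LRV: float
) -> float:
    m = N_total - n_obs
    pmf = predictive_pmf(r_obs, n_obs, m)
    total = 0.0
    for r_fut in range(m + 1):
        if _go_tail(r_obs + r_fut, N_total, LRV) >= alpha_LRV:
            total += pmf[r_fut]
    return min(total, 1.0)


def predictive_prob_go(r_obs: int, n_obs: int, N_total: int, crit: EfficacyCriteria) -> float:
    """Predictive probability of a final-analysis Go (PrGo).

    Sums, over all future response counts ``r'`` up to ``N_total - n_obs``,
    the beta-binomial predictive mass of ``r'`` times the indicator that the
    final posterior ``Beta(0.5 + r_obs + r', 0.5 + N_total - r_obs - r')``
    satisfies the Go criterion ``P(p > LRV) >= alpha_LRV``.  Only the Go
    criterion enters the success indicator.

    At ``n_obs = N_total`` this is the indicator of the Go criterion on the
    current data.
    """
    _validate_counts(r_obs, n_obs)
    if n_obs > N_total:
        raise ValueError(f"n_obs={n_obs} exceeds total sample size N_total={N_total}")
    return _predictive_prob_go_cached(r_obs, n_obs, N_total, crit.LRV, crit.alpha_LRV)
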