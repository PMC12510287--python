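"""Biomarker cutoff estimation and declaration rules.

A candidate cutoff splits patients into biomarker-negative (``x <= c``) and
biomarker-positive (``x > c``) subgroups.  The cutoff estimate is the
least-squares step fit: among all candidate cutoffs (midpoints between
consecutive distinct biomarker order statistics) that keep at least a
fraction ``pp`` of the sample above the cutoff, pick the one minimizing the
residual sum of squares of the two-level step (subgroup response means).

A cutoff is *declared* — i.e., judged real enough to act on at the interim —
by one of three rules:

* ``PROBABILITY_BASED`` (the design's rule): the posterior probability that
  the subgroup response-rate difference exceeds ``diffthr`` must exceed
  ``pthr``, with independent improper-prior beta posteriors
  ``p1 ~ Beta(r1, n1 - r1)``, ``p0 ~ Beta(r0, n0 - r0)``.
* ``NAIVE_STEP``: the response rate above the fitted cutoff must reach
  ``min_resp_rate`` (no between-group comparison).
* ``NAIVE``: some upper tail of the biomarker containing at least ``pp`` of
  the sample has a response rate reaching ``min_resp_rate`` (no step fit).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate, stats

__all__ = [
    "Cohort",
    "CutoffApproach",
    "CutoffRule",
    "CutoffResult",
    "fit_step_cutoff",
    "prob_response_diff",
    "declare_cutoff",
]


@dataclass(frozen=True)
class Cohort:
    """Per-patient biomarker values and binary responses.

    Row order is preserved but carries no meaning; all operations sort
    internally by biomarker value.
    """

    biomarker: np.ndarray
    response: np.ndarray

    def __post_init__(self) -> None:
        bmk = np.asarray(self.biomarker, dtype=float)
        resp = np.asarray(self.response)
        if bmk.ndim != 1 or resp.ndim != 1 or bmk.shape != resp.shape:
            raise ValueError("biomarker and response must be parallel 1-d arrays")
        if bmk.size < 1:
            raise ValueError("a cohort must contain at least one patient")
        if not np.all(np.isfinite(bmk)):
            raise ValueError("biomarker values must be finite")
        if not np.isin(resp, (0, 1)).all():
            raise ValueError("responses must be binary 0/1")
        object.__setattr__(self, "biomarker", bmk)
        object.__setattr__(self, "response", resp.astype(np.int64))

    @property
    def size(self) -> int:
        return int(self.biomarker.size)

    @property
    def n_responses(self) -> int:
        return int(self.response.sum())


class CutoffApproach(enum.Enum):
    PROBABILITY_BASED = "probability_based"
    NAIVE = "naive"
    NAIVE_STEP = "naive_step"


@dataclass(frozen=True)
class CutoffRule:
    """Parameters of a cutoff-declaration rule.

    Parameters
    ----------
    approach
        Which declaration rule to apply.
    pp
        Minimum fraction of the sample required above the cutoff.
    diffthr
        Minimum response-rate difference between subgroups
        (``PROBABILITY_BASED`` only).
    pthr
        Posterior-probability threshold for the difference
        (``PROBABILITY_BASED`` only).
    min_resp_rate
        Response-rate floor for the two naive comparator rules.
    """

    approach: CutoffApproach = CutoffApproach.PROBABILITY_BASED
    pp: float = 0.10
    diffthr: float = 0.10
    pthr: float = 0.80
    min_resp_rate: float = 0.15

    def __post_init__(self) -> None:
        for name in ("pp", "diffthr", "min_resp_rate"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1); got {v}")
        # pthr = 1 is admissible and never declares (the posterior probability
        # cannot exceed 1), which gives a clean "rule off" configuration
        if not (0.0 < self.pthr <= 1.0):
            raise ValueError(f"pthr must lie in (0, 1]; got {self.pthr}")


@dataclass(frozen=True)
class CutoffResult:
    """Outcome of a cutoff fit / declaration attempt.

    ``declared`` is False when no admissible split exists or the rule's
    evidence requirement fails; the fitted split (if any) is still reported.
    """

    declared: bool
    cutoff: float | None
    n_plus: int
    r_plus: int
    n_minus: int
    r_minus: int
    sse: float
    prob_diff: float | None = None

    def __post_init__(self) -> None:
        if self.declared and self.cutoff is None:
            raise ValueError("a declared cutoff must carry a cutoff value")
        if self.r_plus > self.n_plus or self.r_minus > self.n_minus:
            raise ValueError("subgroup responses cannot exceed subgroup sizes")


#: sentinel result when no admissible candidate split exists
_NO_CANDIDATE = None


def fit_step_cutoff(cohort: Cohort, pp: float) -> CutoffResult | None:
    """Least-squares step-function cutoff estimate.

    Candidate cutoffs are midpoints between consecutive distinct biomarker
    order statistics, with ``n_plus >= 1`` and ``n_minus >= 1``.  For each
    candidate the fitted step is (mean response below, mean response above)
    and the criterion is the residual sum of squares; ties break toward the
    smallest cutoff (largest biomarker-positive group).  The fit itself is
    unconstrained; the requirement that at least a fraction ``pp`` of the
    sample lie above the cutoff is enforced afterwards on the chosen split,
    so a best split leaving too few patients above yields no admissible
    cutoff rather than the runner-up split.

    Returns ``None`` when there is no admissible cutoff (all biomarker
    values tied, or the optimal split fails the ``pp`` constraint).  The
    ``declared`` flag of the returned result is always False; declaration is
    a separate step.
    """
    n = cohort.size
    if n < 2:
        return _NO_CANDIDATE
    order = np.argsort(cohort.biomarker, kind="stable")
    x = cohort.biomarker[order]
    y = cohort.response[order].astype(float)

    cum = np.concatenate(([0.0], np.cumsum(y)))  # cum[k] = responses among k smallest
    total = cum[-1]
    sumsq = total  # y is 0/1 so sum(y^2) = sum(y)

    best: tuple[float, float, int] | None = None  # (sse, cutoff, k)
    for k in range(1, n):  # k patients at/below the split
        if x[k] == x[k - 1]:
            continue  # split would fall on tied values
        n_plus = n - k
        r_minus = cum[k]
        r_plus = total - r_minus
        # SSE of the two-level step around subgroup means, for 0/1 outcomes:
        # sum(y^2) - r_minus^2/k - r_plus^2/(n-k)
        sse = sumsq - r_minus**2 / k - r_plus**2 / n_plus
        cutoff = 0.5 * (x[k - 1] + x[k])
        if best is None or sse < best[0] - 1e-12:
            best = (sse, cutoff, k)
        # ties: keep the earlier (smaller) cutoff — already first encountered

    if best is None:
        return _NO_CANDIDATE
    sse, cutoff, k = best
    if (n - k) / n < pp:
        return _NO_CANDIDATE
    r_minus = int(round(cum[k]))
    return CutoffResult(
        declared=False,
        cutoff=float(cutoff),
        n_plus=n - k,
        r_plus=int(round(total)) - r_minus,
        n_minus=k,
        r_minus=r_minus,
        sse=max(float(sse), 0.0),
    )


@lru_cache(maxsize=65536)
def _prob_response_diff_cached(r1: int, n1: int, r0: int, n0: int, diffthr: float) -> float:
    def point_mass(r: int, n: int) -> float | None:
        if r == 0:
            return 0.0
        if r == n:
            return 1.0
        return None

    v1 = point_mass(r1, n1)
    v0 = point_mass(r0, n0)
    if v1 is not None and v0 is not None:
        return 1.0 if v1 - v0 > diffthr else 0.0
    if v1 is not None:
        # P(p0 < v1 - diffthr)
        return float(stats.beta.cdf(v1 - diffthr, r0, n0 - r0)) if v1 - diffthr > 0 else 0.0
    if v0 is not None:
        # P(p1 > v0 + diffthr)
        t = v0 + diffthr
        return float(stats.beta.sf(t, r1, n1 - r1)) if t < 1 else 0.0

    a0, b0 = r0, n0 - r0
    a1, b1 = r1, n1 - r1
    upper = 1.0 - diffthr

    def integrand(x: float) -> float:
        return stats.beta.pdf(x, a0, b0) * stats.beta.sf(x + diffthr, a1, b1)

    val, _ = integrate.quad(integrand, 0.0, upper, epsabs=1e-9, epsrel=1e-9, limit=200)
    return float(min(max(val, 0.0), 1.0))


def prob_response_diff(r1: int, n1: int, r0: int, n0: int, diffthr: float) -> float:
    """Posterior probability that the subgroup response-rate difference exceeds ``diffthr``.

    ``P(p1 - p0 > diffthr | data)`` with independent improper-prior beta
    posteriors ``p1 ~ Beta(r1, n1 - r1)`` and ``p0 ~ Beta(r0, n0 - r0)``.
    Boundary counts (``r = 0`` or ``r = n``) give degenerate posteriors —
    point masses at 0 or 1, the limit of the improper posterior.  Computed by
    deterministic quadrature (survival function of ``p1`` integrated against
    the density of ``p0``) to absolute accuracy well below 1e-6.
    """
    if n1 < 1 or n0 < 1:
        raise ValueError("both subgroups need at least one patient")
    if not (0 <= r1 <= n1 and 0 <= r0 <= n0):
        raise ValueError("subgroup responses must lie within subgroup sizes")
    return _prob_response_diff_cached(r1, n1, r0, n0, float(diffthr))


def _min_responses(min_resp_rate: float, n_plus: int) -> int:
    """Response-count threshold: at least ``min_resp_rate`` of ``n_plus``."""
    return math.ceil(min_resp_rate * n_plus - 1e-9)


def declare_cutoff(cohort: Cohort, rule: CutoffRule) -> CutoffResult:
    """Attempt to declare a biomarker cutoff on a cohort under a rule.

    See the module docstring for the three rules.  A failed step fit (no
    admissible candidate) yields ``declared = False``.
    """
    if cohort.size < 2:
        raise ValueError("cutoff declaration needs at least two patients")

    if rule.approach is CutoffApproach.NAIVE:
        return _declare_naive(cohort, rule)

    fit = fit_step_cutoff(cohort, rule.pp)
    if fit is None:
        return CutoffResult(
            declared=False, cutoff=None, n_plus=0, r_plus=0,
            n_minus=cohort.size, r_minus=cohort.n_responses, sse=float("nan"),
        )

    if rule.approach is CutoffApproach.NAIVE_STEP:
        declared = fit.r_plus >= _min_responses(rule.min_resp_rate, fit.n_plus)
        return CutoffResult(
            declared=declared,
            cutoff=fit.cutoff,
            n_plus=fit.n_plus,
            r_plus=fit.r_plus,
            n_minus=fit.n_minus,
            r_minus=fit.r_minus,
            sse=fit.sse,
        )

    # PROBABILITY_BASED
    pdiff = prob_response_diff(fit.r_plus, fit.n_plus, fit.r_minus, fit.n_minus, rule.diffthr)
    return CutoffResult(
        declared=pdiff > rule.pthr,
        cutoff=fit.cutoff,
        n_plus=fit.n_plus,
        r_plus=fit.r_plus,
        n_minus=fit.n_minus,
        r_minus=fit.r_minus,
        sse=fit.sse,
        prob_diff=pdiff,
    )


def _declare_naive(cohort: Cohort, rule: CutoffRule) -> CutoffResult:
    """Naive rule: declare if any upper biomarker tail covering at least
    ``pp`` of the sample (and leaving at least one patient below) holds
    enough responses.  The largest qualifying tail — the smallest cutoff —
    is reported; no step function is fitted."""
    n = cohort.size
    order = np.argsort(cohort.biomarker, kind="stable")
    x = cohort.biomarker[order]
    y = cohort.response[order]
    suffix_resp = np.concatenate((np.cumsum(y[::-1])[::-1], [0]))  # responses among x[k:]
    for k in range(1, n):  # tail of size n - k, largest tail first
        n_plus = n - k
        if n_plus / n < rule.pp:
            break
        if x[k] == x[k - 1]:
            continue  # tail boundary must separate distinct values
        r_plus = int(suffix_resp[k])
        if r_plus >= _min_responses(rule.min_resp_rate, n_plus):
            return CutoffResult(
                declared=True,
                cutoff=0.5 * (x[k - 1] + x[k]),
                n_plus=n_plus,
                r_plus=r_plus,
                n_minus=k,
                r_minus=int(y[:k].sum()),
                sse=float("nan"),
            )
    return CutoffResult(
        declared=False, cutoff=None, n_plus=0, r_plus=0, n_minus=n,
        r_minus=int(y.sum()), sse=float("nan"),
    )
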