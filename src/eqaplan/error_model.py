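"""Bayesian binomial error-rate model and literature-summary intervals.

The error rate of a test performed ``n`` times per year with ``k`` observed
errors is modeled with a Beta posterior under a noninformative prior:

* ``uniform``  — Beta(1, 1) prior, posterior Beta(k+1, n−k+1)
* ``jeffreys`` — Beta(½, ½) prior, posterior Beta(k+½, n−k+½)

The planner asks the inverse question: the smallest annual volume ``n``
such that, with zero observed errors, the one-sided 95% upper credible
bound of the error rate stays at or below a threshold (1% by default).
Under the uniform prior the bound has the closed form
``1 − (1 − level)**(1/(n+1))`` and the continuous solution for the default
query is ``ln(0.05)/ln(0.99) − 1 ≈ 297.07``; nearest-integer rounding of
that solution gives 297 (a strict-ceiling mode giving 298 is available).

The module also provides the t-based confidence interval of a mean error
rate reported as (n, mean, SD) summary statistics in the literature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from scipy import optimize, stats

__all__ = [
    "ErrorRatePosterior",
    "ThresholdQuery",
    "MetaErrorRow",
    "InfeasibleThresholdError",
    "posterior",
    "upper_credible_bound",
    "min_volume_for_threshold",
    "t_confidence_interval",
    "PRIORS",
    "SIDEDNESS",
]

PRIORS = ("uniform", "jeffreys")
SIDEDNESS = ("one_sided_upper", "two_sided")


class InfeasibleThresholdError(ValueError):
    """The credible bound cannot reach the requested threshold."""


@dataclass(frozen=True)
class ErrorRatePosterior:
    """Beta posterior of a binomial error rate under a noninformative prior."""

    prior: str
    n: int
    k: int
    alpha: float
    beta: float


@dataclass(frozen=True)
class ThresholdQuery:
    """Question: which annual volume bounds the error rate below a threshold?"""

    max_error_rate: float
    credible_level: float = 0.95
    sidedness: str = "one_sided_upper"
    prior: str = "uniform"
    k: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.max_error_rate < 1.0:
            raise ValueError("max_error_rate must be in (0, 1)")
        if not 0.0 < self.credible_level < 1.0:
            raise ValueError("credible_level must be in (0, 1)")
        if self.sidedness not in SIDEDNESS:
            raise ValueError(f"sidedness must be one of {SIDEDNESS}")
        if self.prior not in PRIORS:
            raise ValueError(f"prior must be one of {PRIORS}")
        if self.k < 0:
            raise ValueError("k must be >= 0")


@dataclass(frozen=True)
class MetaErrorRow:
    """One literature row: scenario count, mean error rate (%) and SD (%)."""

    label: str
    n_scenarios: int
    mean_pct: float
    sd_pct: float

    def __post_init__(self) -> None:
        if self.n_scenarios < 1:
            raise ValueError("n_scenarios must be >= 1")
        if self.sd_pct < 0:
            raise ValueError("sd_pct must be >= 0")


def _shapes(n: float, k: float, prior: str) -> tuple[float, float]:
    if prior == "uniform":
        return k + 1.0, n - k + 1.0
    if prior == "jeffreys":
        return k + 0.5, n - k + 0.5
    raise ValueError(f"prior must be one of {PRIORS}")


def posterior(n: int, k: int, prior: str = "uniform") -> ErrorRatePosterior:
    """Beta posterior for ``k`` errors in ``n`` analyses."""
    if n < 0 or k < 0:
        raise ValueError("n and k must be non-negative")
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    alpha, beta = _shapes(n, k, prior)
    return ErrorRatePosterior(prior=prior, n=n, k=k, alpha=alpha, beta=beta)


def _quantile_level(level: float, sidedness: str) -> float:
    if sidedness == "one_sided_upper":
        return level
    if sidedness == "two_sided":
        return 1.0 - (1.0 - level) / 2.0
    raise ValueError(f"sidedness must be one of {SIDEDNESS}")


def upper_credible_bound(
    p: ErrorRatePosterior,
    level: float = 0.95,
    sidedness: str = "one_sided_upper",
) -> float:
    """Posterior quantile below which the error rate lies with probability ``level``.

    For the uniform prior with zero observed errors the closed form
    ``1 − (1 − q)**(1/(n+1))`` is used (q being the quantile level); it
    agrees with the numeric Beta quantile to well below 1e−9.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    q = _quantile_level(level, sidedness)
    if p.prior == "uniform" and p.k == 0:
        return 1.0 - (1.0 - q) ** (1.0 / (p.n + 1.0))
    return float(stats.beta.ppf(q, p.alpha, p.beta))


def _bound_at(n: float, query: ThresholdQuery) -> float:
    # continuous-n version of upper_credible_bound, used by the solver
    q = _quantile_level(query.credible_level, query.sidedness)
    if query.prior == "uniform" and query.k == 0:
        return 1.0 - (1.0 - q) ** (1.0 / (n + 1.0))
    alpha, beta = _shapes(n, query.k, query.prior)
    return float(stats.beta.ppf(q, alpha, beta))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def min_volume_for_threshold(query: ThresholdQuery, rounding: str = "nearest") -> int:
    """Minimum annual number of analyses for a bounded error rate.

    Solves ``upper bound(n) = max_error_rate`` for continuous ``n`` and
    rounds the solution to an integer.  The default ``nearest`` rounding
    reproduces the published 297-test threshold for the default query
    (1% threshold, 95% one-sided, uniform prior, k = 0); ``ceil`` is the
    strict convention and yields 298 there.
    """
    if rounding not in ("nearest", "ceil"):
        raise ValueError("rounding must be 'nearest' or 'ceil'")
    theta = query.max_error_rate
    q = _quantile_level(query.credible_level, query.sidedness)
    if query.prior == "uniform" and query.k == 0:
        # closed form: 1 − (1−q)^(1/(n+1)) = θ  ⇒  n = ln(1−q)/ln(1−θ) − 1
        n_star = math.log(1.0 - q) / math.log(1.0 - theta) - 1.0
        n_star = max(n_star, 0.0)
    else:
        lo = float(query.k)
        if _bound_at(lo, query) <= theta:
            n_star = lo
        else:
            hi = max(lo + 1.0, 8.0)
            while _bound_at(hi, query) > theta:
                hi *= 2.0
                if hi > 1e12:
                    raise InfeasibleThresholdError(
                        f"bound never reaches threshold {theta} (prior={query.prior}, "
                        f"k={query.k}, level={query.credible_level})"
                    )
            n_star = float(
                optimize.brentq(lambda n: _bound_at(n, query) - theta, lo, hi, xtol=1e-9)
            )
    n_int = _round_half_up(n_star) if rounding == "nearest" else math.ceil(n_star - 1e-12)
    return max(n_int, query.k, 0)


def t_confidence_interval(row: MetaErrorRow, level: float = 0.95) -> tuple[float, float]:
    """Symmetric t-based CI of the mean error rate from summary statistics.

    ``mean ± t((1+level)/2, n−1) · sd/√n``, both bounds in percent rounded
    half-up to two decimals.  The lower bound may be negative for tiny n.
    """
    if row.n_scenarios < 2:
        raise ValueError("confidence interval requires n_scenarios >= 2")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    tq = float(stats.t.ppf((1.0 + level) / 2.0, row.n_scenarios - 1))
    half = tq * row.sd_pct / math.sqrt(row.n_scenarios)

    def round2(x: float) -> float:
        return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))

    return round2(row.mean_pct - half), round2(row.mean_pct + half)
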