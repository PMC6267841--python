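"""Sample-size formulas for two-arm multi-centre trials with block randomisation.

All formulas target the two-sided level-``alpha`` Wald test of a treatment
effect ``mu`` on a continuous outcome, analysed with a random-intercept
model (residual variance ``sigma2``, between-centre variance ``tau2``),
under centre-stratified permuted-block randomisation with a k:1 ratio.

Four named methods are provided:

``lower``
    The classical single-stratum formula; ignores incomplete-block
    imbalance and is a lower bound for the required size.
``mc_equal``
    Assumes equally sized centres; searches the final-block size ``r₁``
    self-consistently.
``mc_unequal``
    Uses the average expected imbalance over final-block sizes 1..b
    (uniform ``r_j``), appropriate when centre sizes are unpredictable.
``upper``
    Uses the worst-case expected imbalance E(Δ² | r = b/(k+1)); the most
    conservative size.

The general formula solves ``(q_{1−α/2}+q_{1−β})² = μ²/Var(μ̂)`` for N with

    Var(μ̂) = σ²(k+1)²/(kN) + τ²(k+1)²/N² · Σ_j E(Δ²|r_j),

a quadratic in N whose positive root gives ``n_raw``; results are rounded
up to the next integer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.stats import norm

from .randomisation import (
    BlockScheme,
    expected_imbalance,
    max_expected_imbalance,
    mean_expected_imbalance,
)

__all__ = [
    "DesignSpec",
    "SampleSizeResult",
    "design_from_icc",
    "n_lower",
    "n_mc_general",
    "n_mc_equal",
    "n_mc_unequal",
    "n_upper",
    "all_methods",
]


@dataclass(frozen=True)
class DesignSpec:
    """Planning parameters of a two-arm multi-centre trial.

    Parameters
    ----------
    mu : float
        Assumed treatment effect (difference of arm means), non-zero.
    sigma2 : float
        Residual (within-centre) variance σ² > 0.
    tau2 : float
        Between-centre variance τ² ≥ 0 of the random intercepts.
    alpha : float
        Two-sided type-I error rate.
    beta : float
        Type-II error rate; power is 1 − β.
    k : int
        Allocation parameter (k patients to arm 1 per patient to arm 2).
    b : int
        Block length of the permuted-block randomisation.
    c : int
        Number of study centres.
    """

    mu: float
    sigma2: float
    tau2: float
    alpha: float = 0.05
    beta: float = 0.2
    k: int = 1
    b: int = 6
    c: int = 1

    def __post_init__(self) -> None:
        # mu == 0 is tolerated so the simulator can run null (type-I error)
        # scenarios; the sample-size formulas themselves insist on mu != 0.
        # sigma2 == 0 is tolerated so the simulator can run noise-free checks;
        # the sample-size formulas themselves insist on sigma2 > 0.
        if self.sigma2 < 0:
            raise ValueError(f"residual variance sigma2 must be non-negative, got {self.sigma2}")
        if self.tau2 < 0:
            raise ValueError(f"between-centre variance tau2 must be non-negative, got {self.tau2}")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not 0 < self.beta < 1:
            raise ValueError(f"beta must lie in (0, 1), got {self.beta}")
        if not (isinstance(self.c, (int, np.integer)) and self.c >= 1):
            raise ValueError(f"number of centres c must be a positive integer, got {self.c!r}")
        BlockScheme(self.b, self.k)  # validates b, k

    @property
    def scheme(self) -> BlockScheme:
        return BlockScheme(self.b, self.k)

    @property
    def icc(self) -> float:
        """Intraclass correlation ρ = τ²/(τ² + σ²)."""
        return self.tau2 / (self.tau2 + self.sigma2)

    @property
    def quantile_sum(self) -> float:
        """q_{1−α/2} + q_{1−β}, the normal quantile sum of the power equation."""
        return float(norm.ppf(1 - self.alpha / 2) + norm.ppf(1 - self.beta))


def design_from_icc(
    mu: float,
    sigma: float,
    icc: float,
    alpha: float = 0.05,
    beta: float = 0.2,
    k: int = 1,
    b: int = 6,
    c: int = 1,
) -> DesignSpec:
    """Build a :class:`DesignSpec` from a residual SD and an intraclass correlation.

    With ρ = τ²/(τ² + σ²) and residual SD ``sigma``, the between-centre
    variance is τ² = ρσ²/(1 − ρ).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if not 0 <= icc < 1:
        raise ValueError(f"icc must lie in [0, 1), got {icc}")
    sigma2 = sigma**2
    tau2 = icc * sigma2 / (1 - icc)
    return DesignSpec(mu=mu, sigma2=sigma2, tau2=tau2, alpha=alpha, beta=beta, k=k, b=b, c=c)


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a sample-size calculation.

    ``n_total`` is ``ceil(n_raw)``; ``sum_expected_imbalance`` is the
    Σ_j E(Δ²|r_j) plugged into the general formula; ``r1_star`` records the
    self-consistent final-block size of the equal-centres search.
    """

    method: str
    n_total: int
    n_raw: float
    sum_expected_imbalance: float
    r1_star: Optional[int] = None

    def to_dict(self) -> dict:
        d = {
            "method": self.method,
            "n_total": self.n_total,
            "n_raw": self.n_raw,
            "sum_expected_imbalance": self.sum_expected_imbalance,
        }
        if self.r1_star is not None:
            d["r1_star"] = self.r1_star
        return d


def _n_raw_general(design: DesignSpec, sum_expected_imbalance: float) -> float:
    if design.sigma2 <= 0:
        raise ValueError("sample-size formulas require a positive residual variance sigma2")
    if design.mu == 0:
        raise ValueError("sample-size formulas require a non-zero treatment effect mu")
    q = design.quantile_sum
    k = design.k
    a = (q / design.mu) ** 2
    half = design.sigma2 * (k + 1) ** 2 / (2 * k)
    inner = half**2 + (
        design.tau2 * (k + 1) ** 2 * design.mu**2 * sum_expected_imbalance / q**2
    )
    return a * (half + math.sqrt(inner))


def n_lower(design: DesignSpec) -> SampleSizeResult:
    """Single-stratum lower boundary, independent of τ², b and c."""
    if design.sigma2 <= 0:
        raise ValueError("sample-size formulas require a positive residual variance sigma2")
    if design.mu == 0:
        raise ValueError("sample-size formulas require a non-zero treatment effect mu")
    n_raw = design.sigma2 * (design.k + 1) ** 2 / design.k * (design.quantile_sum / design.mu) ** 2
    return SampleSizeResult("lower", math.ceil(n_raw), n_raw, 0.0)


def n_mc_general(design: DesignSpec, sum_expected_imbalance: float) -> SampleSizeResult:
    """General multi-centre formula for a caller-supplied Σ_j E(Δ²|r_j)."""
    if sum_expected_imbalance < 0:
        raise ValueError("sum_expected_imbalance must be non-negative")
    n_raw = _n_raw_general(design, sum_expected_imbalance)
    return SampleSizeResult("mc_custom", math.ceil(n_raw), n_raw, sum_expected_imbalance)


def n_mc_unequal(design: DesignSpec) -> SampleSizeResult:
    """Unequal-centres formula: S = c times the mean expected imbalance over r = 1..b."""
    s = design.c * mean_expected_imbalance(design.scheme)
    res = n_mc_general(design, s)
    return replace(res, method="mc_unequal")


def n_upper(design: DesignSpec) -> SampleSizeResult:
    """Upper boundary: S = c times the worst-case expected imbalance E(Δ²|b/(k+1))."""
    s = design.c * max_expected_imbalance(design.scheme)
    res = n_mc_general(design, s)
    return replace(res, method="upper")


def n_mc_equal(design: DesignSpec) -> SampleSizeResult:
    """Equal-centres formula with self-consistent final-block size.

    For each candidate r₁ in 1..b the formula is evaluated with
    S = c·E(Δ²|r₁); the kept candidate minimises
    ``|((N(r₁)/c) mod b) − r₁|`` on the unrounded N with real-valued
    modulus, so the assumed final-block size agrees with the size the
    resulting N would actually produce.  Ties go to the smallest N.
    """
    best: tuple[float, float, int, float] | None = None
    for r1 in range(1, design.b + 1):
        s = design.c * expected_imbalance(design.scheme, r1)
        n_raw = _n_raw_general(design, s)
        dist = abs((n_raw / design.c) % design.b - r1)
        key = (dist, n_raw)
        if best is None or key < (best[0], best[1]):
            best = (dist, n_raw, r1, s)
    _, n_raw, r1_star, s = best
    return SampleSizeResult("mc_equal", math.ceil(n_raw), n_raw, s, r1_star=r1_star)


_METHODS = {
    "lower": n_lower,
    "equal": n_mc_equal,
    "unequal": n_mc_unequal,
    "upper": n_upper,
}


def all_methods(design: DesignSpec) -> list[SampleSizeResult]:
    """Run the four named methods; results ordered lower ≤ unequal ≤ upper."""
    return [fn(design) for fn in _METHODS.values()]


def by_method(design: DesignSpec, method: str) -> SampleSizeResult:
    """Dispatch one of {lower, equal, unequal, upper} by name."""
    try:
        return _METHODS[method](design)
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}") from None
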