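"""Estimation and testing for the random-intercept multi-centre model.

The treatment effect is estimated by the difference of overall arm means,
which stays unbiased even when some centres recruited for one arm only.
Variance components come from closed-form quadratic (method-of-moments)
estimators rather than REML/ML: σ̂² pools within-cell sample variances
over arm-centre cells, τ̂² averages, over the two arms, the sample
variance of centre means around the arm mean.  The effect estimator's
variance is

    Var(μ̂) = σ²·N/(N₁N₂) + τ²·Σ_j (n₁j/N₁ − n₂j/N₂)²,

and H₀: μ = 0 is tested by the normal-approximation Wald statistic
T = μ̂ / sqrt(est. Var), rejecting when |T| strictly exceeds q_{1−α/2}.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .simulation import TrialDataset

__all__ = [
    "AnalysisResult",
    "estimate_effect",
    "estimate_variance_components",
    "var_mu_hat",
    "wald_test",
]


@dataclass(frozen=True)
class AnalysisResult:
    """Result of one random-intercept Wald analysis."""

    mu_hat: float
    sigma2_hat: float
    tau2_hat: float
    var_mu_hat: float
    t_stat: float
    p_value: float
    reject: bool
    alpha: float

    def to_dict(self) -> dict:
        return {
            "mu_hat": self.mu_hat,
            "sigma2_hat": self.sigma2_hat,
            "tau2_hat": self.tau2_hat,
            "var_mu_hat": self.var_mu_hat,
            "t_stat": self.t_stat,
            "p_value": self.p_value,
            "reject": self.reject,
            "alpha": self.alpha,
        }


def _cell_stats(data: TrialDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per (arm, centre) cell counts, sums and sums of squares.

    Returns arrays of shape (2, c) indexed by arm-1 and centre-1.
    """
    c = data.n_centres if data.n_centres else int(data.centre.max())
    idx = (data.arm - 1) * c + (data.centre - 1)
    size = 2 * c
    counts = np.bincount(idx, minlength=size).reshape(2, c)
    sums = np.bincount(idx, weights=data.outcome, minlength=size).reshape(2, c)
    sumsq = np.bincount(idx, weights=data.outcome**2, minlength=size).reshape(2, c)
    return counts, sums, sumsq


def estimate_effect(data: TrialDataset) -> float:
    """Difference of overall arm means, μ̂ = Ȳ₂·· − Ȳ₁·· (each subject weighted equally)."""
    mask2 = data.arm == 2
    n2 = int(mask2.sum())
    n1 = len(data.arm) - n2
    if n1 == 0 or n2 == 0:
        raise ValueError("both treatment arms must contain at least one subject")
    return float(data.outcome[mask2].mean() - data.outcome[~mask2].mean())


def estimate_variance_components(data: TrialDataset) -> tuple[float, float]:
    """Quadratic-form estimators (σ̂², τ̂²).

    σ̂² averages the unbiased within-cell sample variances over all
    arm-centre cells with at least two subjects; cells with fewer are
    excluded and the divisor adjusted to the eligible-cell count.  τ̂²
    averages, over arms, the sample variance of the non-empty centre means
    around the arm mean (divisor: non-empty centre count minus one).  Both
    quadratic forms are non-negative by construction.
    """
    counts, sums, sumsq = _cell_stats(data)

    eligible = counts >= 2
    if not eligible.any():
        raise ValueError("sigma2 estimation needs at least one arm-centre cell with >= 2 subjects")
    n = counts[eligible]
    ss = sumsq[eligible] - sums[eligible] ** 2 / n
    sigma2_hat = float(np.mean(ss / (n - 1)))
    sigma2_hat = max(sigma2_hat, 0.0)  # guard tiny negative rounding

    tau2_terms = []
    for i in range(2):
        nonempty = counts[i] > 0
        ci = int(nonempty.sum())
        if ci < 2:
            raise ValueError(
                f"tau2 estimation needs >= 2 non-empty centres in arm {i + 1}, found {ci}"
            )
        cell_means = sums[i, nonempty] / counts[i, nonempty]
        arm_mean = data.outcome[data.arm == i + 1].mean()
        tau2_terms.append(np.sum((cell_means - arm_mean) ** 2) / (ci - 1))
    tau2_hat = float(np.mean(tau2_terms))
    return sigma2_hat, tau2_hat


def var_mu_hat(sigma2: float, tau2: float, n1_by_centre, n2_by_centre) -> float:
    """Variance of the arm-mean difference under the random-intercept model.

    ``n1_by_centre``/``n2_by_centre`` are the realised per-centre counts of
    arms 1 and 2.  Equals the quadratic form w'Σw with Σ the block-diagonal
    exchangeable covariance σ²I + τ²J per centre and w the ±1/N_i contrast.
    """
    n1 = np.asarray(n1_by_centre, dtype=float)
    n2 = np.asarray(n2_by_centre, dtype=float)
    N1, N2 = n1.sum(), n2.sum()
    if N1 <= 0 or N2 <= 0:
        raise ValueError("both arms must contain at least one subject")
    N = N1 + N2
    return float(sigma2 * N / (N1 * N2) + tau2 * np.sum((n1 / N1 - n2 / N2) ** 2))


def wald_test(data: TrialDataset, alpha: float = 0.05) -> AnalysisResult:
    """Normal-approximation Wald test of H₀: μ = 0 at two-sided level ``alpha``.

    Plugs the moment estimates σ̂², τ̂² and the realised arm-by-centre
    counts into the variance formula.  Rejection requires |T| to strictly
    exceed q_{1−α/2}.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    mu_hat = estimate_effect(data)
    sigma2_hat, tau2_hat = estimate_variance_components(data)
    counts, _, _ = _cell_stats(data)
    v = var_mu_hat(sigma2_hat, tau2_hat, counts[0], counts[1])
    if v <= 0:
        raise ValueError("estimated Var(mu_hat) is not positive; data degenerate")
    t = mu_hat / np.sqrt(v)
    p = float(2 * norm.sf(abs(t)))
    reject = bool(abs(t) > norm.ppf(1 - alpha / 2))
    return AnalysisResult(
        mu_hat=mu_hat,
        sigma2_hat=sigma2_hat,
        tau2_hat=tau2_hat,
        var_mu_hat=v,
        t_stat=float(t),
        p_value=p,
        reject=reject,
        alpha=alpha,
    )
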