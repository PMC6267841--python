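"""Monte-Carlo power and type-I error estimation for multi-centre designs.

Each replicate allocates subjects to centres, randomises them in permuted
blocks within centre, simulates random-intercept outcomes, and applies the
normal-approximation Wald test.  The rejection fraction estimates power
(or the type-I error when the generating effect is zero).  Replicate
streams are spawned deterministically from the master seed, so results
are reproducible and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .inference import wald_test
from .samplesize import DesignSpec, by_method
from .simulation import allocate, allocate_equal, simulate_trial

__all__ = ["PowerEstimate", "estimate_power", "power_grid"]

DEFAULT_N_SIM = 10_000


@dataclass(frozen=True)
class PowerEstimate:
    """Estimated rejection probability with its Monte-Carlo standard error."""

    power: float
    n_sim: int
    mc_se: float
    alpha: float
    N_used: int
    scheme: str
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "power": self.power,
            "n_sim": self.n_sim,
            "mc_se": self.mc_se,
            "alpha": self.alpha,
            "N_used": self.N_used,
            "scheme": self.scheme,
            "seed": self.seed,
        }


def estimate_power(
    design: DesignSpec,
    n_total: int,
    scheme: str = "unequal1",
    n_sim: int = DEFAULT_N_SIM,
    seed: int | None = None,
    mu0: float = 0.0,
) -> PowerEstimate:
    """Estimate power of the Wald test at total sample size ``n_total``.

    ``scheme`` picks the subject-to-centre allocation (equal, unequal1,
    unequal2).  The random allocation schemes redraw centre sizes every
    replicate; the equal split is computed once.  Setting ``design.mu = 0``
    turns the estimate into an empirical type-I error rate.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    if n_total < max(4, design.c):
        raise ValueError(
            f"n_total={n_total} is infeasible for c={design.c} centres (need >= max(4, c))"
        )
    master = np.random.default_rng(seed)
    fixed_alloc = allocate_equal(n_total, design.c) if scheme == "equal" else None

    rejections = 0
    for rep_rng in master.spawn(n_sim):
        alloc = fixed_alloc if fixed_alloc is not None else allocate(
            scheme, n_total, design.c, rep_rng
        )
        data = simulate_trial(design, alloc, mu0=mu0, rng=rep_rng, keep_truth=False)
        rejections += wald_test(data, alpha=design.alpha).reject

    p = rejections / n_sim
    return PowerEstimate(
        power=p,
        n_sim=n_sim,
        mc_se=float(np.sqrt(p * (1 - p) / n_sim)),
        alpha=design.alpha,
        N_used=int(n_total),
        scheme=scheme,
        seed=seed,
    )


def power_grid(
    designs: Sequence[DesignSpec],
    methods: Sequence[str],
    scheme: str = "unequal1",
    n_sim: int = DEFAULT_N_SIM,
    seed: int | None = None,
) -> pd.DataFrame:
    """Power for every (design, sample-size method) combination.

    For each design the named method ({lower, equal, unequal, upper})
    determines N, whose power is then simulated.  Returns a long-format
    table with one row per combination; deterministic given ``seed``
    (each cell gets its own derived seed).
    """
    designs = list(designs)
    methods = list(methods)
    if not designs or not methods:
        raise ValueError("designs and methods must be non-empty")
    ss = np.random.SeedSequence(seed)
    cell_seeds = ss.generate_state(len(designs) * len(methods)) >> 1  # keep below 2^31

    rows = []
    i = 0
    for design in designs:
        for method in methods:
            res = by_method(design, method)
            est = estimate_power(
                design, res.n_total, scheme=scheme, n_sim=n_sim, seed=int(cell_seeds[i])
            )
            rows.append(
                {
                    "mu": design.mu,
                    "sigma2": design.sigma2,
                    "tau2": design.tau2,
                    "icc": design.icc,
                    "b": design.b,
                    "c": design.c,
                    "k": design.k,
                    "method": method,
                    "N": res.n_total,
                    "scheme": scheme,
                    "power": est.power,
                    "mc_se": est.mc_se,
                    "n_sim": est.n_sim,
                }
            )
            i += 1
    return pd.DataFrame(rows)
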