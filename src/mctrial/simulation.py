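"""Trial simulator: random-intercept outcomes under stratified block randomisation.

Subjects are first distributed over centres (equally, or by one of two
multinomial schemes), then randomised within each centre by permuted
blocks, and finally given outcomes from the random-intercept model

    Y = μ₀ + u_j + μ·1{arm 2} + ε,   u_j ~ N(0, τ²),  ε ~ N(0, σ²).

Each centre draws its randomisation list from an independent stream
spawned from the master seed, mirroring stratified randomisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .randomisation import BlockScheme, random_block_sequence
from .samplesize import DesignSpec

__all__ = [
    "CentreAllocation",
    "TrialDataset",
    "allocate_equal",
    "allocate_unequal",
    "allocate",
    "simulate_trial",
]

SCHEMES = ("equal", "unequal1", "unequal2", "custom")


@dataclass(frozen=True)
class CentreAllocation:
    """Number of subjects recruited by each of ``c`` centres."""

    n_by_centre: np.ndarray = field(repr=False)
    scheme: str = "custom"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.n_by_centre, dtype=int)
        if arr.ndim != 1 or (arr < 0).any():
            raise ValueError("n_by_centre must be a 1-d array of non-negative integers")
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}; choose from {SCHEMES}")
        object.__setattr__(self, "n_by_centre", arr)

    @property
    def n_total(self) -> int:
        return int(self.n_by_centre.sum())

    @property
    def n_centres(self) -> int:
        return int(self.n_by_centre.size)


@dataclass(frozen=True)
class TrialDataset:
    """Subject-level records of one simulated trial.

    ``centre`` holds 1-based centre ids, ``arm`` labels in {1, 2} and
    ``outcome`` the continuous responses.  ``truth`` retains the generating
    parameters (mu0, mu, sigma2, tau2, u_by_centre) for testing.
    """

    centre: np.ndarray = field(repr=False)
    arm: np.ndarray = field(repr=False)
    outcome: np.ndarray = field(repr=False)
    n_centres: int = 0
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        if not (len(self.centre) == len(self.arm) == len(self.outcome)):
            raise ValueError("centre, arm and outcome must have equal length")

    @property
    def n_total(self) -> int:
        return int(len(self.outcome))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"centre": self.centre, "arm": self.arm, "outcome": self.outcome})


def allocate_equal(n_total: int, c: int) -> CentreAllocation:
    """Distribute ``n_total`` subjects as evenly as possible over ``c`` centres.

    The first ``n_total mod c`` centres get ``floor(N/c) + 1`` subjects, the
    rest ``floor(N/c)``.
    """
    if c < 1:
        raise ValueError("need at least one centre")
    if n_total < c:
        raise ValueError(f"n_total={n_total} smaller than the number of centres c={c}")
    base, m = divmod(n_total, c)
    n = np.full(c, base, dtype=int)
    n[:m] += 1
    return CentreAllocation(n, scheme="equal")


def allocate_unequal(
    n_total: int, c: int, variant: int = 1, rng: np.random.Generator | int | None = None
) -> CentreAllocation:
    """Draw random centre sizes from a multinomial distribution.

    Variant 1 uses equal cell probabilities 1/c; variant 2 first draws c
    iid Uniform(0,1) weights, normalises them, and uses those as cell
    probabilities.  Centres may come out empty; they are retained.
    """
    if n_total < 1 or c < 1:
        raise ValueError("n_total and c must be positive")
    if variant not in (1, 2):
        raise ValueError(f"variant must be 1 or 2, got {variant!r}")
    rng = np.random.default_rng(rng)
    if variant == 1:
        p = np.full(c, 1.0 / c)
    else:
        w = rng.random(c)
        p = w / w.sum()
    n = rng.multinomial(n_total, p)
    return CentreAllocation(n, scheme=f"unequal{variant}")


def allocate(
    scheme: str, n_total: int, c: int, rng: np.random.Generator | int | None = None
) -> CentreAllocation:
    """Dispatch an allocation scheme by name: equal, unequal1 or unequal2."""
    if scheme == "equal":
        return allocate_equal(n_total, c)
    if scheme in ("unequal1", "unequal2"):
        return allocate_unequal(n_total, c, variant=int(scheme[-1]), rng=rng)
    raise ValueError(f"unknown allocation scheme {scheme!r}")


def simulate_trial(
    design: DesignSpec,
    allocation: CentreAllocation,
    mu0: float = 0.0,
    rng: np.random.Generator | int | None = None,
    keep_truth: bool = True,
) -> TrialDataset:
    """Simulate one trial under the random-intercept model.

    Every centre receives an independent permuted-block randomisation list
    (k:1 within complete blocks) drawn from its own child stream of the
    master generator.  The degenerate case σ² = τ² = 0 is permitted and
    yields noiseless outcomes, which is useful in tests.
    """
    if allocation.n_centres != design.c:
        raise ValueError(
            f"allocation has {allocation.n_centres} centres but the design specifies c={design.c}"
        )
    rng = np.random.default_rng(rng)
    scheme = BlockScheme(design.b, design.k)
    n_by_centre = allocation.n_by_centre
    c = allocation.n_centres

    u = rng.normal(0.0, np.sqrt(design.tau2), size=c) if design.tau2 > 0 else np.zeros(c)
    # one independent randomisation stream per centre (stratified lists)
    centre_rngs = rng.spawn(c)

    arms = np.empty(allocation.n_total, dtype=int)
    centres = np.repeat(np.arange(1, c + 1), n_by_centre)
    pos = 0
    for j in range(c):
        nj = int(n_by_centre[j])
        if nj == 0:
            continue
        arms[pos : pos + nj] = random_block_sequence(scheme, nj, centre_rngs[j])
        pos += nj

    eps = rng.normal(0.0, np.sqrt(design.sigma2), size=allocation.n_total) if design.sigma2 > 0 else 0.0
    outcome = mu0 + u[centres - 1] + design.mu * (arms == 2) + eps

    truth = None
    if keep_truth:
        truth = {
            "mu0": mu0,
            "mu": design.mu,
            "sigma2": design.sigma2,
            "tau2": design.tau2,
            "u_by_centre": u,
        }
    return TrialDataset(centre=centres, arm=arms, outcome=np.asarray(outcome, dtype=float),
                        n_centres=c, truth=truth)
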