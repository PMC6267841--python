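"""Permuted-block randomisation and the exact distribution of treatment imbalance.

Centre-stratified permuted-block randomisation allocates subjects in
consecutive blocks of fixed length ``b``; within each block exactly
``kb/(k+1)`` subjects go to arm 1 and ``b/(k+1)`` to arm 2 (a k:1 ratio),
in uniformly random order.  Complete blocks are perfectly balanced, so the
only source of within-centre imbalance is the final, possibly incomplete
block holding ``r = n_j mod b`` subjects.

For a centre the squared imbalance is ``Δ² = (n1/k − n2)²`` where ``n1``,
``n2`` are the per-arm counts.  Conditional on ``r``, the arm-1 count ``j``
among the first ``r`` entries of a uniformly drawn balanced block tuple is
hypergeometric (population ``b``, ``kb/(k+1)`` arm-1 members, draw ``r``),
which gives the exact conditional law of ``Δ²`` used by the sample-size
formulas.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

__all__ = [
    "BlockScheme",
    "ImbalanceDistribution",
    "enumerate_block_tuples",
    "imbalance_distribution",
    "expected_imbalance",
    "mean_expected_imbalance",
    "max_expected_imbalance",
    "random_block_sequence",
]

#: largest block length accepted by the brute-force tuple enumeration
ENUMERATION_CAP = 20

#: tolerance for merging Δ² support points that coincide up to rounding
_SUPPORT_MERGE_TOL = 1e-9


@dataclass(frozen=True)
class BlockScheme:
    """A permuted-block design: block length ``b`` and allocation parameter ``k``.

    ``k`` patients are assigned to arm 1 for every patient assigned to
    arm 2; ``b`` must be divisible by ``k + 1`` so that every complete
    block realises the ratio exactly.
    """

    b: int
    k: int = 1

    def __post_init__(self) -> None:
        if not (isinstance(self.b, (int, np.integer)) and self.b >= 1):
            raise ValueError(f"block length b must be a positive integer, got {self.b!r}")
        if not (isinstance(self.k, (int, np.integer)) and self.k >= 1):
            raise ValueError(f"allocation parameter k must be a positive integer, got {self.k!r}")
        if self.b % (self.k + 1) != 0:
            raise ValueError(
                f"block length b={self.b} must be divisible by k+1={self.k + 1} "
                "so complete blocks realise the k:1 allocation exactly"
            )

    @property
    def n_arm1(self) -> int:
        """Arm-1 count per complete block, ``kb/(k+1)``."""
        return self.k * self.b // (self.k + 1)

    @property
    def n_arm2(self) -> int:
        """Arm-2 count per complete block, ``b/(k+1)``."""
        return self.b // (self.k + 1)

    @property
    def max_imbalance(self) -> float:
        """Upper bound ``m* = b²/(k+1)²`` of the squared imbalance Δ²."""
        return (self.b / (self.k + 1)) ** 2


@dataclass(frozen=True)
class ImbalanceDistribution:
    """Exact pmf of the squared imbalance Δ² given ``r`` subjects in the final block."""

    scheme: BlockScheme
    r: int
    support: np.ndarray = field(repr=False)
    probs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "support", np.asarray(self.support, dtype=float))
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=float))
        if self.support.shape != self.probs.shape:
            raise ValueError("support and probs must have equal length")

    @property
    def mean(self) -> float:
        """Plain expectation E(Δ² | r) = Σ p(ℓ|r)·ℓ."""
        return float(np.dot(self.support, self.probs))

    def as_dict(self) -> dict[float, float]:
        return {float(s): float(p) for s, p in zip(self.support, self.probs)}


def _check_r(scheme: BlockScheme, r: int) -> None:
    if not (isinstance(r, (int, np.integer)) and 1 <= r <= scheme.b):
        raise ValueError(f"r must be an integer in [1, b={scheme.b}], got {r!r}")


def enumerate_block_tuples(scheme: BlockScheme) -> list[tuple[int, ...]]:
    """All arm-label tuples of one complete block, i.e. length-``b`` tuples over
    {1, 2} with exactly ``kb/(k+1)`` ones.

    Cardinality is ``C(b, b/(k+1))``.  Intended as an exact-enumeration oracle
    for small blocks; rejects ``b`` beyond :data:`ENUMERATION_CAP` (use the
    hypergeometric path in :func:`imbalance_distribution` instead).
    """
    if scheme.b > ENUMERATION_CAP:
        raise ValueError(
            f"b={scheme.b} exceeds the enumeration cap {ENUMERATION_CAP}; "
            "use imbalance_distribution (hypergeometric) for large blocks"
        )
    tuples = []
    for ones in itertools.combinations(range(scheme.b), scheme.n_arm1):
        t = [2] * scheme.b
        for pos in ones:
            t[pos] = 1
        tuples.append(tuple(t))
    return tuples


def imbalance_distribution(scheme: BlockScheme, r: int) -> ImbalanceDistribution:
    """Exact conditional pmf of Δ² given ``r`` subjects in the final block.

    With ``j`` arm-1 subjects among the first ``r`` entries of a uniformly
    drawn balanced tuple, ``Δ = j/k − (r − j)`` and
    ``j ~ Hypergeom(b, kb/(k+1), r)``.  Support points whose Δ² coincide
    (within 1e-9) are merged.
    """
    _check_r(scheme, r)
    j = np.arange(max(0, r - scheme.n_arm2), min(scheme.n_arm1, r) + 1)
    pj = hypergeom.pmf(j, scheme.b, scheme.n_arm1, r)
    delta_sq = (j / scheme.k - (r - j)) ** 2

    order = np.argsort(delta_sq)
    delta_sq, pj = delta_sq[order], pj[order]
    support: list[float] = []
    probs: list[float] = []
    for d, p in zip(delta_sq, pj):
        if support and abs(d - support[-1]) <= _SUPPORT_MERGE_TOL:
            probs[-1] += p
        else:
            support.append(float(d))
            probs.append(float(p))
    return ImbalanceDistribution(scheme=scheme, r=int(r), support=np.array(support), probs=np.array(probs))


def expected_imbalance(scheme: BlockScheme, r: int) -> float:
    """Conditional expectation E(Δ² | r), the plain mean of the Δ² pmf.

    For k=1 this equals the closed form ``r(b−r)/(b−1)``.
    """
    return imbalance_distribution(scheme, r).mean


def mean_expected_imbalance(scheme: BlockScheme) -> float:
    """Average of E(Δ² | r) over r = 1..b (uniform final-block size).

    The complete-block term r=b contributes zero.  For k=1 the closed form is
    ``(b+1)/6``.
    """
    return sum(expected_imbalance(scheme, r) for r in range(1, scheme.b + 1)) / scheme.b


def max_expected_imbalance(scheme: BlockScheme) -> float:
    """Most conservative conditional expectation, E(Δ² | r = b/(k+1))."""
    return expected_imbalance(scheme, scheme.n_arm2)


def random_block_sequence(
    scheme: BlockScheme, n: int, rng: np.random.Generator | int | None = None
) -> np.ndarray:
    """Randomise ``n`` subjects in permuted blocks; returns an array of arm labels.

    Builds ``ceil(n/b)`` independent uniformly permuted complete blocks and
    truncates to ``n`` entries, so the final block is the leading prefix of a
    permuted complete block (the incomplete block).  Deterministic given a
    seeded generator.
    """
    if not (isinstance(n, (int, np.integer)) and n >= 1):
        raise ValueError(f"n must be a positive integer, got {n!r}")
    rng = np.random.default_rng(rng)
    n_blocks = math.ceil(n / scheme.b)
    base = np.repeat([1, 2], [scheme.n_arm1, scheme.n_arm2])
    blocks = np.tile(base, (n_blocks, 1))
    # permute each block independently
    perm = np.argsort(rng.random((n_blocks, scheme.b)), axis=1)
    blocks = np.take_along_axis(blocks, perm, axis=1)
    return blocks.ravel()[:n].copy()
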