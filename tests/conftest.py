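"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: the
imbalance pmf is tabulated by brute-force enumeration of balanced block
tuples, and the effect-estimator variance by building the full
block-diagonal covariance matrix.
"""

from collections import Counter

import numpy as np
import pytest
from scipy.linalg import block_diag

from mctrial import BlockScheme, design_from_icc, enumerate_block_tuples


def pmf_by_enumeration(b: int, k: int, r: int) -> dict[float, float]:
    """Exact Δ²|r pmf by enumerating every balanced tuple's length-r prefix."""
    tuples = enumerate_block_tuples(BlockScheme(b, k))
    counts: Counter = Counter()
    for t in tuples:
        j = sum(1 for x in t[:r] if x == 1)
        delta_sq = (j / k - (r - j)) ** 2
        counts[round(delta_sq, 9)] += 1
    total = len(tuples)
    return {d: c / total for d, c in sorted(counts.items())}


def var_by_matrix(sigma2: float, tau2: float, n1, n2) -> float:
    """w'Σw with Σ block-diagonal exchangeable per centre and w the ±1/N_i contrast."""
    n1, n2 = np.asarray(n1, int), np.asarray(n2, int)
    N1, N2 = n1.sum(), n2.sum()
    blocks, w = [], []
    for a, b_ in zip(n1, n2):
        nj = int(a + b_)
        if nj == 0:
            continue
        blocks.append(sigma2 * np.eye(nj) + tau2 * np.ones((nj, nj)))
        w.extend([-1.0 / N1] * int(a) + [1.0 / N2] * int(b_))
    sigma = block_diag(*blocks)
    w = np.array(w)
    return float(w @ sigma @ w)


@pytest.fixture
def example_design():
    """The worked example's planning parameters: mu=1, sigma=4, rho=0.5, b=6, c=23."""
    return design_from_icc(mu=1.0, sigma=4.0, icc=0.5, alpha=0.05, beta=0.2, k=1, b=6, c=23)
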