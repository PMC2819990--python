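"""Probability of a motif reaching its observed support or higher.

Two routes are provided. The heuristic route averages the per-protein
occurrence probabilities and applies a binomial upper tail (``p_mu``). The
exact route keeps each protein's own occurrence probability and evaluates
the upper tail of the resulting Poisson-binomial distribution (``p_v``),
computed by an O(N^2) dynamic programme over the success-count distribution
rather than by enumerating the C(N, k) success combinations — the same
mathematical object at tractable cost, which is what makes the exact
significance schemes routinely computable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import fsum, prod
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .motif_model import Motif
from .sequence_data import InvalidInputError

__all__ = [
    "SupportResult",
    "mean_success_probability",
    "binomial_tail",
    "poisson_binomial_pmf",
    "exact_support_probability",
    "brute_force_support_probability",
]

_BRUTE_FORCE_MAX_N = 20


def _check_probs(vector: Sequence[float]) -> np.ndarray:
    v = np.asarray(vector, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise InvalidInputError("probability vector must be non-empty and 1-D")
    if np.any((v < 0.0) | (v > 1.0)):
        raise InvalidInputError("probabilities must lie in [0, 1]")
    return v


def mean_success_probability(p1plus_vector: Sequence[float]) -> float:
    """Arithmetic mean of the per-protein occurrence probabilities."""
    return float(np.mean(_check_probs(p1plus_vector)))


def binomial_tail(k: int, N: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(N, p), via the regularized incomplete beta.

    ``scipy.stats.binom.sf`` evaluates the survival function through
    ``betainc``; it agrees with exact summation to full precision for the
    dataset sizes used here.
    """
    if not (0 <= k <= N):
        raise InvalidInputError(f"support k={k} outside [0, N={N}]")
    if not (0.0 <= p <= 1.0):
        raise InvalidInputError(f"probability p={p} outside [0, 1]")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, N, p))


def poisson_binomial_pmf(p1plus_vector: Sequence[float]) -> np.ndarray:
    """Distribution of the success count over independent unequal Bernoulli trials.

    Returns an array of length N+1 with entry j = P(X = j), built by
    convolving one trial at a time. Zero-probability trials are exact no-ops:
    a protein that cannot contain the motif never contributes a success.
    """
    v = _check_probs(p1plus_vector)
    dist = np.zeros(v.size + 1)
    dist[0] = 1.0
    top = 0
    for p in v:
        if p == 0.0:
            continue
        dist[1 : top + 2] = dist[1 : top + 2] * (1.0 - p) + dist[: top + 1] * p
        dist[0] *= 1.0 - p
        top += 1
    return dist


def exact_support_probability(k: int, p1plus_vector: Sequence[float]) -> float:
    """Poisson-binomial upper tail P(X >= k) with per-protein probabilities."""
    v = _check_probs(p1plus_vector)
    if not (0 <= k <= v.size):
        raise InvalidInputError(f"support k={k} outside [0, N={v.size}]")
    if k == 0:
        return 1.0
    pmf = poisson_binomial_pmf(v)
    # Sum the tail from the small top entries down to limit cancellation.
    return float(min(fsum(pmf[:k - 1:-1]), 1.0))


def brute_force_support_probability(k: int, p1plus_vector: Sequence[float]) -> float:
    """Literal enumeration over all success subsets of size >= k.

    Exponential in N (guarded at N <= 20); retained purely as an independent
    oracle for :func:`exact_support_probability`.
    """
    v = list(_check_probs(p1plus_vector))
    N = len(v)
    if N > _BRUTE_FORCE_MAX_N:
        raise InvalidInputError(
            f"brute-force enumeration refused for N={N} > {_BRUTE_FORCE_MAX_N}"
        )
    if not (0 <= k <= N):
        raise InvalidInputError(f"support k={k} outside [0, N={N}]")
    terms = []
    idx = range(N)
    for size in range(k, N + 1):
        for successes in combinations(idx, size):
            s = set(successes)
            terms.append(
                prod(v[i] if i in s else 1.0 - v[i] for i in idx)
            )
    return float(min(fsum(terms), 1.0))


@dataclass
class SupportResult:
    """A motif's occurrence evidence in a dataset.

    ``k`` proteins out of ``N`` contain the motif; ``p1plus_vector`` holds
    the per-protein occurrence probabilities the support statistics are
    computed from. ``p_v`` is present only when the exact scheme was
    requested.
    """

    motif: Motif
    k: int
    N: int
    p1plus_vector: np.ndarray
    p_mu: float
    p_v: Optional[float] = None

    def __post_init__(self) -> None:
        self.p1plus_vector = _check_probs(self.p1plus_vector)
        if not (0 <= self.k <= self.N):
            raise InvalidInputError(f"support k={self.k} outside [0, N={self.N}]")
        if self.N != self.p1plus_vector.size:
            raise InvalidInputError("p1plus_vector length must equal N")

    @property
    def p1plus_mean(self) -> float:
        return mean_success_probability(self.p1plus_vector)
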