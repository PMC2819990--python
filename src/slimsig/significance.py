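"""Dataset-level significance of a motif p-value.

A motif's support p-value answers "how likely is THIS motif to recur this
often by chance?". Discovery, however, scans an entire motif space, so the
reportable quantity is "how likely is ANY motif in the space to reach a
p-value this small?". Two corrections are offered:

* the heuristic ``Sig = 1 - (1 - p)^R``, which treats all R motifs in the
  space as equally able to reach p (conservative: many motifs can never
  score that low);
* the exact ``Sig' = 1 - prod_m (1 - p'_m)``, where ``p'_m`` is each motif's
  own probability of attaining a p-value <= p — the tail of its support
  distribution at the smallest support that qualifies.

Because a fixed motif's occurrence probability is invariant under residue
permutation, ``p'`` is constant within each residue-multiset grouping, and
the product over all a^l ordered motifs collapses to a product over
C(a+l-1, l) groupings raised to their multiplicities (computed in
log-space). Each correction combines with either support scheme (binomial
``p_mu`` or Poisson-binomial ``p_v``), giving the four schemes Sig, Sig_v,
Sig' and Sig'_v.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .motif_model import (
    Motif,
    UnsupportedMotifError,
    count_support,
    motif_probability,
    parse_motif,
    prob_one_or_more,
)
from .motif_space import (
    ResidueGrouping,
    enumerate_groupings,
    motif_space_size,
)
from .sequence_data import (
    FrequencyModel,
    InvalidInputError,
    SequenceDataset,
    compute_frequencies,
)
from .support_stats import (
    SupportResult,
    binomial_tail,
    exact_support_probability,
    mean_success_probability,
)

__all__ = [
    "SCHEMES",
    "SCHEME_LABELS",
    "SignificanceReport",
    "sig",
    "p_prime",
    "sig_prime",
    "sig_prime_brute_force",
    "evaluate_support",
    "evaluate_all_schemes",
]

SCHEMES = ("sig", "sig_v", "sig_prime", "sig_prime_v")
SCHEME_LABELS = {
    "sig": "Sig",
    "sig_v": "Sig_v",
    "sig_prime": "Sig'",
    "sig_prime_v": "Sig'_v",
}

# Support-set membership: a motif's own (k, p) must land in its own support
# set despite floating-point round trips, so the threshold test carries a
# relative-plus-tiny-absolute slack.
_TIE_REL = 1e-12
_TIE_ABS = 1e-300


@dataclass
class SignificanceReport:
    """Significance of a motif p-value under one scheme, with its provenance.

    ``R`` is the motif-space size used by the heuristic schemes; ``factors``
    lists (grouping, p', weight) triples for the exact schemes, where weight
    is the number of ordered motifs the grouping stands for.
    """

    scheme: str
    p: float
    value: float
    N: int
    l: int
    a: int
    x_max: int = 0
    R: Optional[int] = None
    factors: List[Tuple[str, float, int]] = field(default_factory=list)

    @property
    def label(self) -> str:
        return SCHEME_LABELS[self.scheme]


def sig(p: float, l: int, a: int, x_max: int = 0) -> float:
    """Heuristic significance ``1 - (1 - p)^R`` with ``R = a^l (x_max+1)^(l-1)``.

    Evaluated in log space (``-expm1(R log1p(-p))``) so small p survive.
    """
    if not (0.0 <= p <= 1.0):
        raise InvalidInputError(f"p={p} outside [0, 1]")
    if p == 0.0:
        return 0.0
    if p == 1.0:
        return 1.0
    R = motif_space_size(l, a, x_max)
    return -math.expm1(R * math.log1p(-p))


def _qualifies(tail: float, p: float) -> bool:
    return tail <= p * (1.0 + _TIE_REL) + _TIE_ABS


def p_prime(
    p1plus_vector: Sequence[float],
    N: int,
    p: float,
    scheme: str = "sig_prime",
) -> float:
    """Probability that a motif with these occurrence probabilities attains
    a p-value <= p.

    The support tail is non-increasing in k, so the qualifying supports form
    {k*, ..., N} for a minimal k*; the answer is the tail at k* (0 when no
    support qualifies). ``scheme`` selects the binomial tail on the mean
    probability ("sig_prime") or the exact Poisson-binomial tail
    ("sig_prime_v").
    """
    if not (0.0 <= p <= 1.0):
        raise InvalidInputError(f"p={p} outside [0, 1]")
    v = np.asarray(p1plus_vector, dtype=float)
    if v.size != N:
        raise InvalidInputError(f"vector length {v.size} != N={N}")
    if scheme in ("sig_prime", "sig"):
        mean = mean_success_probability(v)
        tails = [binomial_tail(k, N, mean) for k in range(N + 1)]
    elif scheme in ("sig_prime_v", "sig_v"):
        tails = [exact_support_probability(k, v) for k in range(N + 1)]
    else:
        raise InvalidInputError(f"unknown scheme {scheme!r}")
    for t in tails:
        if _qualifies(t, p):
            return float(t)
    return 0.0


def evaluate_support(
    motif: Motif,
    dataset: SequenceDataset,
    freqs: Optional[FrequencyModel] = None,
    exact: bool = True,
) -> SupportResult:
    """Observed support and its p-value(s) for one motif in a dataset."""
    if freqs is None:
        freqs = dataset.frequency_model or compute_frequencies(dataset)
    vector = np.array([prob_one_or_more(motif, prot, freqs) for prot in dataset])
    k = count_support(motif, dataset)
    p_mu = binomial_tail(k, dataset.N, mean_success_probability(vector))
    p_v = exact_support_probability(k, vector) if exact else None
    return SupportResult(motif=motif, k=k, N=dataset.N, p1plus_vector=vector,
                         p_mu=p_mu, p_v=p_v)


# ---------------------------------------------------------------------------
# Grouped exact significance
# ---------------------------------------------------------------------------


def _span_weights(l: int, x_max: int) -> Dict[int, int]:
    """Ordered-motif span multiplicities: span -> number of wildcard layouts.

    A fixed motif with l residues and wildcard runs of 0..x_max between
    consecutive residues has span l + (total gap); the number of layouts with
    a given total gap is the number of compositions of the gap into l-1 parts
    each <= x_max.
    """
    if l == 1 or x_max == 0:
        return {l: 1}
    weights: Dict[int, int] = {}
    counts = {0: 1}
    for _ in range(l - 1):
        nxt: Dict[int, int] = {}
        for total, c in counts.items():
            for g in range(x_max + 1):
                nxt[total + g] = nxt.get(total + g, 0) + c
        counts = nxt
    for gap, c in counts.items():
        weights[l + gap] = c
    return weights


def grouping_p1plus_matrix(
    dataset: SequenceDataset,
    groupings: Sequence[ResidueGrouping],
    freqs: FrequencyModel,
    span: int,
) -> np.ndarray:
    """Per-protein occurrence probabilities for every grouping, shape (G, N).

    Entry (g, j) is the probability that protein j contains one or more
    occurrences of any ordered motif with grouping g's residue multiset and
    the given span. Residue-order invariance makes this well defined per
    protein even under per-protein frequencies.
    """
    symbols = list(dataset.alphabet.symbols)
    index = {r: i for i, r in enumerate(symbols)}
    counts = np.zeros((len(groupings), len(symbols)))
    for gi, g in enumerate(groupings):
        for r, c in g.multiset:
            counts[gi, index[r]] = c

    lengths = np.array([p.length for p in dataset])
    n = np.clip(lengths - span + 1, 0, None)  # placements per protein

    # A zero-frequency residue kills every grouping using it; keep that exact
    # (0 * log 0 must be 0 for unused residues, never NaN).
    if freqs.scope == "global":
        f = np.array([freqs.get(r) for r in symbols])
        logf_safe = np.log(np.where(f > 0, f, 1.0))
        alive = (counts @ (f == 0.0)) == 0  # (G,)
        pmotif = np.where(alive, np.exp(counts @ logf_safe), 0.0)
        pmotif = pmotif[:, None] * np.ones((1, dataset.N))
    else:
        f = np.array([[freqs.get(r, p.id) for r in symbols] for p in dataset])
        logf_safe = np.log(np.where(f > 0, f, 1.0))
        alive = (counts @ (f == 0.0).T) == 0  # (G, N)
        pmotif = np.where(alive, np.exp(counts @ logf_safe.T), 0.0)

    p1p = np.where(
        pmotif >= 1.0,
        np.where(n[None, :] > 0, 1.0, 0.0),
        -np.expm1(n[None, :] * np.log1p(-np.minimum(pmotif, 1.0 - 1e-16))),
    )
    p1p[:, n == 0] = 0.0
    p1p[pmotif == 0.0] = 0.0
    return np.clip(p1p, 0.0, 1.0)


def grouping_tail_matrix(p1p: np.ndarray, scheme: str) -> np.ndarray:
    """Support tails P(X >= k) for every grouping, shape (G, N+1).

    Binomial on the per-grouping mean probability for the ``sig_prime``
    scheme; vectorised Poisson-binomial dynamic programme for
    ``sig_prime_v``.
    """
    G, N = p1p.shape
    ks = np.arange(N + 1)
    if scheme == "sig_prime":
        mean = p1p.mean(axis=1)
        tails = stats.binom.sf(ks[None, :] - 1, N, mean[:, None])
        tails[:, 0] = 1.0
        return tails
    if scheme == "sig_prime_v":
        dist = np.zeros((G, N + 1))
        dist[:, 0] = 1.0
        for j in range(N):
            pj = p1p[:, j][:, None]
            shifted = np.zeros_like(dist)
            shifted[:, 1:] = dist[:, :-1]
            dist = dist * (1.0 - pj) + shifted * pj
        pmf = np.clip(dist, 0.0, None)
        tails = np.minimum(np.cumsum(pmf[:, ::-1], axis=1)[:, ::-1], 1.0)
        tails[:, 0] = 1.0
        return tails
    raise InvalidInputError(f"unknown exact scheme {scheme!r}")


def _p_prime_from_tails(tails: np.ndarray, p: float) -> np.ndarray:
    """Vectorised p' per grouping from a (G, N+1) tail matrix."""
    thresh = p * (1.0 + _TIE_REL) + _TIE_ABS
    mask = tails <= thresh
    any_q = mask.any(axis=1)
    kstar = mask.argmax(axis=1)
    pp = np.where(any_q, tails[np.arange(tails.shape[0]), kstar], 0.0)
    return pp


def sig_prime(
    dataset: SequenceDataset,
    observed: SupportResult,
    scheme: str = "sig_prime",
    x_max: int = 0,
    freqs: Optional[FrequencyModel] = None,
    exact_spans: bool = True,
) -> SignificanceReport:
    """Exact significance of the observed motif's p-value over the motif space.

    Iterates the non-redundant residue groupings, computes one p' per
    grouping (and per wildcard span when ``x_max > 0`` and ``exact_spans``),
    and accumulates ``sum(weight * log1p(-p'))``; the result is
    ``1 - exp(sum)``, identical to the brute-force product over all ordered
    motifs. With ``exact_spans=False`` every wildcard-spacing variant of a
    grouping is treated as sharing the contiguous-span occurrence
    probability (second-order for proteins much longer than the motif).
    """
    motif = observed.motif
    if motif.is_ambiguous():
        raise UnsupportedMotifError(
            f"exact significance is not defined for ambiguous motif "
            f"{motif.pattern()!r}; use the heuristic sig() instead"
        )
    if motif.n_anchor or motif.c_anchor:
        raise UnsupportedMotifError(
            "anchored motifs are outside the exact motif space; use sig()"
        )
    if scheme not in ("sig_prime", "sig_prime_v"):
        raise InvalidInputError(f"sig_prime called with heuristic scheme {scheme!r}")
    p = observed.p_mu if scheme == "sig_prime" else observed.p_v
    if p is None:
        raise InvalidInputError("observed SupportResult lacks p_v for sig_prime_v")
    if freqs is None:
        freqs = dataset.frequency_model or compute_frequencies(dataset)

    l, a = motif.l, dataset.alphabet.size
    groupings = list(enumerate_groupings(dataset.alphabet, l))
    weights = np.array([g.multiplicity for g in groupings], dtype=float)

    span_weights = _span_weights(l, x_max) if exact_spans else {l: (x_max + 1) ** (l - 1)}
    log_sum = 0.0
    pp_record = np.zeros(len(groupings))
    hit_one = False
    for span, w_span in span_weights.items():
        p1p = grouping_p1plus_matrix(dataset, groupings, freqs, span)
        tails = grouping_tail_matrix(p1p, scheme)
        pp = _p_prime_from_tails(tails, p)
        pp_record = np.maximum(pp_record, pp)
        if np.any(pp >= 1.0):
            hit_one = True
            break
        log_sum += float(np.sum(weights * w_span * np.log1p(-pp)))

    value = 1.0 if hit_one else -math.expm1(log_sum)
    factors = [
        (str(g), float(pp_record[i]), int(weights[i]) * sum(span_weights.values()))
        for i, g in enumerate(groupings)
    ]
    return SignificanceReport(
        scheme=scheme, p=float(p), value=float(min(max(value, 0.0), 1.0)),
        N=dataset.N, l=l, a=a, x_max=x_max,
        R=motif_space_size(l, a, x_max), factors=factors,
    )


def sig_prime_brute_force(
    dataset: SequenceDataset,
    l: int,
    p: float,
    scheme: str = "sig_prime",
    x_max: int = 0,
    freqs: Optional[FrequencyModel] = None,
) -> float:
    """Ungrouped product over every ordered motif in the space; test oracle.

    Enumerates all a^l residue assignments combined with every wildcard
    layout, computes each motif's own p' from its per-protein occurrence
    probabilities, and multiplies (1 - p') directly.
    """
    if freqs is None:
        freqs = dataset.frequency_model or compute_frequencies(dataset)
    a = dataset.alphabet.size
    if motif_space_size(l, a, x_max) > 200_000:
        raise InvalidInputError("brute-force motif space too large; use sig_prime()")
    gaps = [()] if l == 1 else list(product(range(x_max + 1), repeat=l - 1))
    log_sum = 0.0
    for residues in product(dataset.alphabet.symbols, repeat=l):
        for gap in gaps:
            pattern = residues[0] + "".join(
                "." * g + r for g, r in zip(gap, residues[1:])
            )
            m = parse_motif(pattern, dataset.alphabet)
            vec = [prob_one_or_more(m, prot, freqs) for prot in dataset]
            pp = p_prime(vec, dataset.N, p, scheme)
            if pp >= 1.0:
                return 1.0
            log_sum += math.log1p(-pp)
    return -math.expm1(log_sum)


def evaluate_all_schemes(
    dataset: SequenceDataset,
    motif: Motif,
    x_max: int = 0,
    freqs: Optional[FrequencyModel] = None,
    schemes: Optional[Sequence[str]] = None,
) -> Dict[str, SignificanceReport]:
    """The four scoring schemes for one motif, sharing one support computation.

    The heuristic schemes (Sig, Sig_v) apply the motif-space size correction
    to p_mu and p_v respectively; the exact schemes (Sig', Sig'_v) replace
    the correction with the grouped product. Ambiguous or anchored motifs
    raise for the exact schemes (the heuristic schemes still apply to them).
    ``schemes`` restricts the computation to a subset.
    """
    if freqs is None:
        freqs = dataset.frequency_model or compute_frequencies(dataset)
    wanted = list(SCHEMES) if schemes is None else list(schemes)
    observed = evaluate_support(motif, dataset, freqs, exact=True)
    l, a = motif.l, dataset.alphabet.size
    R = motif_space_size(l, a, x_max)
    out: Dict[str, SignificanceReport] = {}
    for scheme, p in (("sig", observed.p_mu), ("sig_v", observed.p_v)):
        if scheme in wanted:
            out[scheme] = SignificanceReport(
                scheme=scheme, p=float(p), value=sig(p, l, a, x_max),
                N=dataset.N, l=l, a=a, x_max=x_max, R=R,
            )
    for scheme in ("sig_prime", "sig_prime_v"):
        if scheme in wanted:
            out[scheme] = sig_prime(dataset, observed, scheme, x_max, freqs)
    return out
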