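"""End-to-end motif discovery over a protein dataset.

Candidates are generated from the proteins' own substrings (a motif absent
from every protein has support 0 and can never rank), scored under the
requested scheme, and ranked by ascending significance. Only candidate
generation is support-pruned: the exact schemes' inner product still runs
over the full non-redundant grouping space, so the multiple-testing
correction is never weakened by pruning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .motif_model import Motif, MotifPosition, parse_motif, prob_one_or_more
from .motif_space import enumerate_groupings
from .sequence_data import (
    InvalidInputError,
    SequenceDataset,
    compute_frequencies,
)
from .significance import (
    SCHEMES,
    _p_prime_from_tails,
    _span_weights,
    grouping_p1plus_matrix,
    grouping_tail_matrix,
    sig,
)
from .support_stats import (
    binomial_tail,
    exact_support_probability,
    mean_success_probability,
)

__all__ = ["DiscoveryConfig", "RankedMotif", "enumerate_candidates", "run_discovery"]


@dataclass
class DiscoveryConfig:
    """Parameters of one discovery run.

    ``x_max`` bounds the length of wildcard runs between non-wildcard
    positions; ``significance_cutoff`` is the reporting threshold (default
    0.01, the conventional discovery stringency); ``two_pass`` first screens
    with the cheap heuristic Sig at ``pass1_cutoff`` and rescoring survivors
    with the requested exact scheme.
    """

    length: int = 3
    x_max: int = 0
    min_support: int = 1
    scheme: str = "sig_prime"
    frequency_scope: str = "global"
    significance_cutoff: float = 0.01
    report_all: bool = True  # keep motifs above the cutoff in the ranking
    two_pass: bool = False
    pass1_cutoff: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise InvalidInputError("motif length must be >= 1")
        if self.min_support < 1:
            raise InvalidInputError("min_support must be >= 1")
        if not (0.0 < self.significance_cutoff <= 1.0):
            raise InvalidInputError("significance_cutoff must be in (0, 1]")
        if self.scheme not in SCHEMES:
            raise InvalidInputError(f"unknown scheme {self.scheme!r}")


@dataclass
class RankedMotif:
    """One scored motif in a discovery ranking."""

    motif: Motif
    k: int
    N: int
    p: float
    significance: float
    scheme: str
    protein_ids: Tuple[str, ...] = ()
    p_mu: Optional[float] = None
    p_v: Optional[float] = None

    @property
    def pattern(self) -> str:
        return self.motif.pattern()


def _candidate_patterns(
    dataset: SequenceDataset, l: int, x_max: int, min_support: int
) -> Dict[Tuple[Tuple[str, ...], Tuple[int, ...]], set]:
    """Map (residues, gaps) -> set of supporting protein ids.

    Gaps are the wildcard run lengths between consecutive non-wildcard
    positions. Windows containing out-of-alphabet residues at non-wildcard
    offsets are skipped (masked positions can never match).
    """
    layouts: List[Tuple[int, ...]] = []
    if l == 1:
        layouts = [()]
    else:
        def grow(prefix: Tuple[int, ...]) -> None:
            if len(prefix) == l - 1:
                layouts.append(prefix)
                return
            for g in range(x_max + 1):
                grow(prefix + (g,))

        grow(())
    support: Dict[Tuple[Tuple[str, ...], Tuple[int, ...]], set] = {}
    alpha = set(dataset.alphabet.symbols)
    for prot in dataset:
        seq = prot.residues
        L = len(seq)
        for gaps in layouts:
            offsets = [0]
            for g in gaps:
                offsets.append(offsets[-1] + 1 + g)
            span = offsets[-1] + 1
            for start in range(L - span + 1):
                residues = tuple(seq[start + o] for o in offsets)
                if not all(r in alpha for r in residues):
                    continue
                support.setdefault((residues, gaps), set()).add(prot.id)
    return {key: ids for key, ids in support.items() if len(ids) >= min_support}


def _pattern_of(residues: Sequence[str], gaps: Sequence[int]) -> str:
    out = [residues[0]]
    for g, r in zip(gaps, residues[1:]):
        out.append("." * g + r)
    return "".join(out)


def enumerate_candidates(
    dataset: SequenceDataset, l: int, x_max: int = 0, min_support: int = 1
) -> Iterator[Motif]:
    """Yield every fixed motif present in >= min_support proteins, once each."""
    found = _candidate_patterns(dataset, l, x_max, min_support)
    for residues, gaps in sorted(found):
        yield parse_motif(_pattern_of(residues, gaps), dataset.alphabet)


def run_discovery(dataset: SequenceDataset, config: DiscoveryConfig) -> List[RankedMotif]:
    """Score and rank all candidate motifs under the configured scheme.

    Deterministic for a given dataset and configuration. Ranking is by
    ascending significance, ties by ascending p, then pattern. For the exact
    schemes the grouped support-tail matrix is computed once per dataset and
    reused across candidates (each candidate differs only in its threshold
    p-value).
    """
    freqs = compute_frequencies(dataset, config.frequency_scope)
    found = _candidate_patterns(dataset, config.length, config.x_max, config.min_support)
    if not found:
        return []

    exact_scheme = config.scheme in ("sig_prime", "sig_prime_v")
    candidates: List[RankedMotif] = []
    for (residues, gaps), ids in sorted(found.items()):
        motif = parse_motif(_pattern_of(residues, gaps), dataset.alphabet)
        vec = np.array([prob_one_or_more(motif, prot, freqs) for prot in dataset])
        k = len(ids)
        if config.scheme in ("sig", "sig_prime"):
            p = binomial_tail(k, dataset.N, mean_success_probability(vec))
            p_mu, p_v = p, None
        else:
            p = exact_support_probability(k, vec)
            p_mu, p_v = None, p
        candidates.append(
            RankedMotif(
                motif=motif, k=k, N=dataset.N, p=float(p), significance=1.0,
                scheme=config.scheme, protein_ids=tuple(sorted(ids)),
                p_mu=p_mu, p_v=p_v,
            )
        )

    l, a = config.length, dataset.alphabet.size
    if not exact_scheme:
        for c in candidates:
            c.significance = sig(c.p, l, a, config.x_max)
    else:
        screen = candidates
        if config.two_pass:
            screen = [
                c for c in candidates
                if sig(c.p, l, a, config.x_max) <= config.pass1_cutoff
            ]
            for c in candidates:
                c.significance = sig(c.p, l, a, config.x_max)  # pass-1 fallback value
            if not screen:
                screen = sorted(candidates, key=lambda c: c.p)[:1]
        groupings = list(enumerate_groupings(dataset.alphabet, l))
        weights = np.array([g.multiplicity for g in groupings], dtype=float)
        tail_scheme = "sig_prime" if config.scheme == "sig_prime" else "sig_prime_v"
        span_weights = _span_weights(l, config.x_max)
        tails = []
        for span, w_span in span_weights.items():
            p1p = grouping_p1plus_matrix(dataset, groupings, freqs, span)
            tails.append((grouping_tail_matrix(p1p, tail_scheme), w_span))
        for c in screen:
            log_sum = 0.0
            for tail_matrix, w_span in tails:
                pp = _p_prime_from_tails(tail_matrix, c.p)
                if np.any(pp >= 1.0):
                    log_sum = -np.inf
                    break
                log_sum += float(np.sum(weights * w_span * np.log1p(-pp)))
            c.significance = float(-np.expm1(log_sum)) if np.isfinite(log_sum) else 1.0

    candidates.sort(key=lambda c: (c.significance, c.p, c.pattern))
    if config.report_all:
        return candidates
    return [c for c in candidates if c.significance <= config.significance_cutoff]
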