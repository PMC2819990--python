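"""Motif patterns, occurrence scanning and per-protein occurrence probabilities.

A motif is an ordered list of positions: fixed residues, ambiguous residue
classes (``[KR]``), wildcards (``.``) and variable-length wildcard spacers
(``.{i,j}``), optionally anchored to the N terminus (``^``) or C terminus
(``$``).

The occurrence model treats each of the ``n`` placement positions of a motif
in a protein as an independent Bernoulli trial with success probability
``p_motif`` (the product over non-wildcard motif positions of the summed
background frequencies of the admissible residues). The probability that a
protein contains one or more occurrences is then ``1 - (1 - p_motif)^n``.
This deliberately ignores the autocorrelation of overlapping placements of
self-overlapping motifs; it is the model implemented throughout, not an
approximation bolted on afterwards.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from functools import lru_cache
from typing import FrozenSet, List, Mapping, Optional, Sequence, Tuple, Union

from .sequence_data import Alphabet, FrequencyModel, ProteinSequence, SequenceDataset

__all__ = [
    "MotifPosition",
    "Motif",
    "parse_motif",
    "motif_probability",
    "prob_one_or_more",
    "scan_occurrences",
    "count_support",
    "MotifParseError",
    "UnsupportedMotifError",
]

FreqLike = Union[FrequencyModel, Mapping[str, float]]


class MotifParseError(ValueError):
    """Malformed motif pattern; ``position`` is the 0-based offset of the fault."""

    def __init__(self, message: str, position: int) -> None:
        super().__init__(f"{message} (at pattern offset {position})")
        self.position = position


class UnsupportedMotifError(ValueError):
    """Operation not defined for this motif class (e.g. probability of a spacer motif)."""


@dataclass(frozen=True)
class MotifPosition:
    """One motif position.

    kind: "fixed" (one residue), "ambiguous" (a set of admissible residues),
    "wildcard" (any alphabet residue) or "variable_spacer" (a run of
    ``min_span``..``max_span`` wildcards).
    """

    kind: str
    residues: FrozenSet[str] = frozenset()
    min_span: int = 1
    max_span: int = 1

    def __post_init__(self) -> None:
        if self.kind == "fixed" and len(self.residues) != 1:
            raise ValueError("fixed position requires exactly one residue")
        if self.kind == "ambiguous" and len(self.residues) < 2:
            raise ValueError("ambiguous position requires at least two residues")
        if self.kind == "variable_spacer" and not (0 <= self.min_span < self.max_span):
            raise ValueError("variable spacer requires 0 <= min_span < max_span")

    @property
    def is_wild(self) -> bool:
        return self.kind in ("wildcard", "variable_spacer")


@dataclass(frozen=True)
class Motif:
    """A parsed motif pattern."""

    positions: Tuple[MotifPosition, ...]
    n_anchor: bool = False
    c_anchor: bool = False

    @property
    def l(self) -> int:
        """Number of non-wildcard (information-bearing) positions."""
        return sum(1 for p in self.positions if not p.is_wild)

    @property
    def span_range(self) -> Tuple[int, int]:
        lo = sum(p.min_span for p in self.positions)
        hi = sum(p.max_span for p in self.positions)
        return lo, hi

    @property
    def span(self) -> int:
        """Total matched width; defined only for fixed-span motifs."""
        lo, hi = self.span_range
        if lo != hi:
            raise UnsupportedMotifError(
                f"motif {self.pattern()!r} has variable span {lo}..{hi}"
            )
        return lo

    @property
    def is_fixed_span(self) -> bool:
        lo, hi = self.span_range
        return lo == hi

    def is_ambiguous(self) -> bool:
        """True if any position is degenerate or any variable-length spacer exists."""
        return any(
            p.kind == "ambiguous" or p.kind == "variable_spacer" for p in self.positions
        )

    def pattern(self) -> str:
        """Canonical string form of the motif."""
        parts = ["^"] if self.n_anchor else []
        for p in self.positions:
            if p.kind == "fixed":
                parts.append(next(iter(p.residues)))
            elif p.kind == "ambiguous":
                parts.append("[" + "".join(sorted(p.residues)) + "]")
            elif p.kind == "wildcard":
                parts.append(".")
            else:
                parts.append(".{%d,%d}" % (p.min_span, p.max_span))
        if self.c_anchor:
            parts.append("$")
        return "".join(parts)

    def __str__(self) -> str:
        return self.pattern()


_SPACER_RE = re.compile(r"\{(\d+),(\d+)\}")


def parse_motif(pattern: str, alphabet: Optional[Alphabet] = None) -> Motif:
    """Parse a motif pattern string.

    Grammar: ``^`` (first character only), ``$`` (last only), a residue
    letter, ``.`` wildcard, ``[ABC]`` ambiguity class, ``.{i,j}`` variable
    spacer. Raises :class:`MotifParseError` with the offset of the fault.
    """
    if alphabet is None:
        alphabet = Alphabet()
    if not pattern:
        raise MotifParseError("empty pattern", 0)
    i = 0
    n_anchor = c_anchor = False
    if pattern[0] == "^":
        n_anchor = True
        i = 1
    positions: List[MotifPosition] = []
    end = len(pattern)
    if pattern.endswith("$"):
        c_anchor = True
        end -= 1
        if end <= i:
            raise MotifParseError("pattern has anchors but no positions", 0)
    while i < end:
        c = pattern[i]
        if c == "^":
            raise MotifParseError("'^' is only valid as the first character", i)
        if c == "$":
            raise MotifParseError("'$' is only valid as the last character", i)
        if c == ".":
            m = _SPACER_RE.match(pattern, i + 1)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                if lo >= hi:
                    raise MotifParseError(
                        f"variable spacer {{{lo},{hi}}} requires i < j", i + 1
                    )
                positions.append(
                    MotifPosition("variable_spacer", frozenset(), lo, hi)
                )
                i = m.end()
            else:
                if i + 1 < end and pattern[i + 1] == "{":
                    raise MotifParseError("malformed '{i,j}' quantifier", i + 1)
                positions.append(MotifPosition("wildcard"))
                i += 1
        elif c == "[":
            j = pattern.find("]", i + 1)
            if j == -1:
                raise MotifParseError("unclosed '['", i)
            residues = pattern[i + 1 : j].upper()
            if not residues:
                raise MotifParseError("empty residue class '[]'", i)
            for r in residues:
                if r not in alphabet:
                    raise MotifParseError(f"residue {r!r} not in alphabet", i)
            rset = frozenset(residues)
            if len(rset) == 1:
                positions.append(MotifPosition("fixed", rset))
            else:
                positions.append(MotifPosition("ambiguous", rset))
            i = j + 1
        elif c == "{":
            raise MotifParseError("'{i,j}' quantifier must follow '.'", i)
        else:
            r = c.upper()
            if r not in alphabet:
                raise MotifParseError(f"residue {r!r} not in alphabet", i)
            positions.append(MotifPosition("fixed", frozenset(r)))
            i += 1
    motif = Motif(tuple(positions), n_anchor, c_anchor)
    if motif.l < 1:
        raise MotifParseError("motif needs at least one non-wildcard position", 0)
    return motif


def _freq(freqs: FreqLike, residue: str, protein_id: Optional[str]) -> float:
    if isinstance(freqs, FrequencyModel):
        return freqs.get(residue, protein_id)
    return freqs.get(residue, 0.0)


def motif_probability(
    motif: Motif, freqs: FreqLike, protein_id: Optional[str] = None
) -> float:
    """Probability that the motif matches at one placement position.

    The product over non-wildcard positions of the summed background
    frequencies of the admissible residues; wildcards contribute a factor 1.
    Residues absent from the frequency mapping contribute 0, so a motif using
    a residue a protein lacks has probability 0 under per-protein frequencies.
    """
    if not motif.is_fixed_span:
        raise UnsupportedMotifError(
            f"motif {motif.pattern()!r} has a variable-length spacer; expand it "
            "into fixed-span alternatives before computing probabilities"
        )
    p = 1.0
    for pos in motif.positions:
        if pos.is_wild:
            continue
        p *= sum(_freq(freqs, r, protein_id) for r in pos.residues)
    return min(p, 1.0)


def placement_count(motif: Motif, length: int) -> int:
    """Number of placement positions ``n`` of a fixed-span motif in a protein.

    Unanchored: ``L - span + 1`` (0 when the protein is shorter than the
    motif). A single terminal anchor pins the motif to one placement when it
    fits; both anchors require the motif to cover the protein exactly.
    """
    span = motif.span
    if motif.n_anchor and motif.c_anchor:
        return 1 if length == span else 0
    if motif.n_anchor or motif.c_anchor:
        return 1 if length >= span else 0
    return max(length - span + 1, 0)


def prob_one_or_more(
    motif: Motif, protein: ProteinSequence, freqs: FreqLike
) -> float:
    """Probability that ``protein`` contains >= 1 occurrence of ``motif``.

    ``1 - (1 - p_motif)^n`` with ``n`` the placement count; monotone
    non-decreasing in protein length and in ``p_motif``.
    """
    pid = protein.id if isinstance(freqs, FrequencyModel) else None
    p = motif_probability(motif, freqs, pid)
    n = placement_count(motif, protein.length)
    if n <= 0 or p == 0.0:
        return 0.0
    return -math.expm1(n * math.log1p(-p)) if p < 1.0 else 1.0


@lru_cache(maxsize=4096)
def _compiled(pattern_key: str, symbols: Tuple[str, ...]) -> "re.Pattern[str]":
    return re.compile(pattern_key)


def _regex_body(motif: Motif, alphabet: Alphabet) -> str:
    # Wildcards match alphabet residues only: positions holding out-of-alphabet
    # characters (X, masked residues) match nothing, including wildcards.
    wild = "[" + re.escape("".join(alphabet.symbols)) + "]"
    parts = [r"\A"] if motif.n_anchor else []
    for pos in motif.positions:
        if pos.kind == "fixed":
            parts.append(re.escape(next(iter(pos.residues))))
        elif pos.kind == "ambiguous":
            parts.append("[" + re.escape("".join(sorted(pos.residues))) + "]")
        elif pos.kind == "wildcard":
            parts.append(wild)
        else:
            parts.append(wild + "{%d,%d}" % (pos.min_span, pos.max_span))
    if motif.c_anchor:
        parts.append(r"\Z")
    return "".join(parts)


def scan_occurrences(
    motif: Motif,
    protein: ProteinSequence,
    alphabet: Optional[Alphabet] = None,
) -> List[int]:
    """0-based start offsets of all (possibly overlapping) matches.

    Variable spacers match at each admissible span; a start offset is
    reported once regardless of how many spans match there.
    """
    if alphabet is None:
        alphabet = Alphabet.from_sequences([protein.residues])
    body = _regex_body(motif, alphabet)
    rx = _compiled("(?=" + body + ")", alphabet.symbols)
    return [m.start() for m in rx.finditer(protein.residues)]


def count_support(motif: Motif, dataset: SequenceDataset) -> int:
    """Support ``k``: the number of proteins with at least one occurrence."""
    body = _regex_body(motif, dataset.alphabet)
    rx = _compiled(body, dataset.alphabet.symbols)
    return sum(1 for p in dataset if rx.search(p.residues) is not None)
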