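"""Protein dataset containers and background residue-frequency models.

Every probability in this package is computed against a background frequency
model: either one global frequency table for the whole dataset, or one table
per protein (which makes motif occurrence probabilities protein-specific,
reflecting each protein's own composition and length).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Optional, Sequence, Tuple

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "Alphabet",
    "ProteinSequence",
    "FrequencyModel",
    "SequenceDataset",
    "compute_frequencies",
    "InvalidInputError",
]

STANDARD_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class InvalidInputError(ValueError):
    """Raised for malformed datasets, sequences or probability vectors."""


@dataclass(frozen=True)
class Alphabet:
    """An ordered residue alphabet of size ``a``.

    Default is the 20 standard amino acids; any non-empty set of unique
    single-character symbols is accepted (e.g. a two-letter alphabet for
    toy datasets).
    """

    symbols: Tuple[str, ...] = tuple(STANDARD_AMINO_ACIDS)

    def __post_init__(self) -> None:
        if len(self.symbols) == 0:
            raise InvalidInputError("alphabet must contain at least one symbol")
        if len(set(self.symbols)) != len(self.symbols):
            raise InvalidInputError("alphabet symbols must be unique")
        for s in self.symbols:
            if len(s) != 1:
                raise InvalidInputError(f"alphabet symbol {s!r} is not a single character")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def __contains__(self, residue: str) -> bool:
        return residue in self.symbols

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "Alphabet":
        """Infer an alphabet from the residues actually observed."""
        seen = sorted({c for seq in sequences for c in seq.upper()})
        return cls(tuple(seen))


@dataclass(frozen=True)
class ProteinSequence:
    """One protein: an identifier and its residue string.

    Sequences are stored uppercase. Terminal anchor characters are never
    part of a sequence; they belong to motif patterns only.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())

    @property
    def length(self) -> int:
        return len(self.residues)

    def composition(self, alphabet: Optional[Alphabet] = None) -> Counter:
        """Counts of residues, restricted to ``alphabet`` if given."""
        counts = Counter(self.residues)
        if alphabet is not None:
            counts = Counter({r: c for r, c in counts.items() if r in alphabet})
        return counts


@dataclass(frozen=True)
class FrequencyModel:
    """Background residue frequencies, global or per-protein.

    ``frequencies`` maps residue -> probability under global scope, or
    protein id -> (residue -> probability) under per-protein scope. A residue
    absent from a mapping has frequency 0: a protein entirely lacking W has
    zero probability of containing any W-bearing motif, which is exactly the
    behaviour masking relies on.
    """

    scope: str  # "global" | "per-protein"
    frequencies: Mapping

    def __post_init__(self) -> None:
        if self.scope not in ("global", "per-protein"):
            raise InvalidInputError(f"unknown frequency scope {self.scope!r}")
        maps = [self.frequencies] if self.scope == "global" else list(self.frequencies.values())
        for m in maps:
            total = sum(m.values())
            if m and abs(total - 1.0) > 1e-9:
                raise InvalidInputError(f"frequencies sum to {total!r}, expected 1")
            for r, p in m.items():
                if not (0.0 <= p <= 1.0):
                    raise InvalidInputError(f"frequency of {r!r} is {p!r}, outside [0, 1]")

    def get(self, residue: str, protein_id: Optional[str] = None) -> float:
        """Frequency of ``residue`` (for ``protein_id`` under per-protein scope)."""
        if self.scope == "global":
            return self.frequencies.get(residue, 0.0)
        if protein_id is None:
            raise InvalidInputError("per-protein frequency model requires a protein id")
        return self.frequencies[protein_id].get(residue, 0.0)

    def mapping_for(self, protein_id: Optional[str] = None) -> Mapping[str, float]:
        if self.scope == "global":
            return self.frequencies
        if protein_id is None:
            raise InvalidInputError("per-protein frequency model requires a protein id")
        return self.frequencies[protein_id]


@dataclass
class SequenceDataset:
    """An ordered collection of unrelated proteins treated as independent trials.

    The unit of the support statistics is one protein; callers who wish to
    correct for homology should pass one representative per evolutionary
    cluster as the dataset.
    """

    proteins: Sequence[ProteinSequence]
    alphabet: Alphabet = field(default_factory=Alphabet)
    frequency_model: Optional[FrequencyModel] = None

    def __post_init__(self) -> None:
        self.proteins = list(self.proteins)
        ids = [p.id for p in self.proteins]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise InvalidInputError(f"duplicate protein id {dup!r} in dataset")

    @property
    def N(self) -> int:
        return len(self.proteins)

    def __len__(self) -> int:
        return self.N

    def __iter__(self) -> Iterator[ProteinSequence]:
        return iter(self.proteins)

    @classmethod
    def from_strings(
        cls,
        sequences: Sequence[str],
        alphabet: Optional[Alphabet] = None,
        ids: Optional[Sequence[str]] = None,
    ) -> "SequenceDataset":
        """Build a dataset from bare residue strings (ids default to seq1..seqN)."""
        if ids is None:
            ids = [f"seq{i + 1}" for i in range(len(sequences))]
        proteins = [ProteinSequence(i, s) for i, s in zip(ids, sequences)]
        if alphabet is None:
            alphabet = Alphabet.from_sequences(sequences)
        return cls(proteins, alphabet)


def compute_frequencies(
    dataset: SequenceDataset,
    scope: str = "global",
    pseudocount: float = 0.0,
) -> FrequencyModel:
    """Normalised residue counts over the dataset (global) or per protein.

    Residues outside the dataset alphabet are excluded from the counts (the
    masking convention: such positions can never match a motif position).
    ``pseudocount`` is added to every alphabet symbol's count before
    normalising; the default of 0 preserves true zero probabilities, which
    the exact support statistics rely on.
    """
    if dataset.N == 0:
        raise InvalidInputError("cannot compute frequencies of an empty dataset")
    for p in dataset:
        if p.length == 0:
            raise InvalidInputError(f"protein {p.id!r} has an empty sequence")

    def normalise(counts: Counter, owner: str) -> Dict[str, float]:
        table = {r: counts.get(r, 0) + pseudocount for r in dataset.alphabet}
        total = sum(table.values())
        if total <= 0:
            raise InvalidInputError(
                f"no alphabet residues found in {owner} (all residues outside the alphabet?)"
            )
        return {r: c / total for r, c in table.items() if c > 0}

    if scope == "global":
        counts: Counter = Counter()
        for p in dataset:
            counts.update(p.composition(dataset.alphabet))
        return FrequencyModel("global", normalise(counts, "dataset"))
    if scope == "per-protein":
        per = {
            p.id: normalise(p.composition(dataset.alphabet), f"protein {p.id!r}")
            for p in dataset
        }
        return FrequencyModel("per-protein", per)
    raise InvalidInputError(f"unknown frequency scope {scope!r}")
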