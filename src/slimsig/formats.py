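"""Shared I/O plumbing: FASTA ingestion, TSV dialects, config files, logging."""

from __future__ import annotations

import hashlib
import logging
import sys
from io import StringIO
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

from Bio import SeqIO

from .discovery import RankedMotif
from .sequence_data import (
    Alphabet,
    FrequencyModel,
    InvalidInputError,
    ProteinSequence,
    SequenceDataset,
)

__all__ = [
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_frequency_table",
    "write_frequency_table",
    "write_results",
    "read_results",
    "read_config",
    "dataset_digest",
    "get_logger",
]

RESULT_COLUMNS = [
    "motif", "l", "k", "N", "p_mu", "p_v",
    "sig", "sig_v", "sig_prime", "sig_prime_v", "proteins",
]

log = logging.getLogger("slimsig")


class FastaParseError(InvalidInputError):
    """Malformed FASTA input."""


def get_logger(level: Union[int, str] = "INFO", stream=None) -> logging.Logger:
    """Configure and return the package logger (stderr by default)."""
    if not log.handlers:
        handler = logging.StreamHandler(stream or sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(message)s")
        )
        log.addHandler(handler)
    log.setLevel(level)
    return log


def read_fasta(
    path: Union[str, Path], alphabet: Optional[Alphabet] = None
) -> SequenceDataset:
    """Parse a multi-record FASTA file into a dataset.

    Record ids are the first whitespace-delimited token of the header.
    Duplicate ids and empty records are rejected; input order is preserved.
    The alphabet is inferred from the observed residues when not supplied.
    """
    path = Path(path)
    text = path.read_text().replace("\r\n", "\n")
    if not text.strip():
        raise FastaParseError(f"{path}: empty file")
    if not text.lstrip().startswith(">"):
        raise FastaParseError(f"{path}: not FASTA (first record lacks '>')")
    records = list(SeqIO.parse(StringIO(text), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    proteins: List[ProteinSequence] = []
    seen = set()
    for i, rec in enumerate(records, start=1):
        if not rec.id:
            raise FastaParseError(f"{path}: record {i} has an empty header id")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate id {rec.id!r} (record {i})")
        seq = str(rec.seq).strip()
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has no sequence")
        seen.add(rec.id)
        proteins.append(ProteinSequence(rec.id, seq))
    if alphabet is None:
        alphabet = Alphabet.from_sequences([p.residues for p in proteins])
    return SequenceDataset(proteins, alphabet)


def write_fasta(dataset: SequenceDataset, path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in dataset:
            fh.write(f">{p.id}\n")
            for i in range(0, p.length, width):
                fh.write(p.residues[i : i + width] + "\n")


def read_frequency_table(path: Union[str, Path]) -> FrequencyModel:
    """Two-column TSV (residue, probability) -> global frequency model."""
    freqs: Dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise InvalidInputError(f"{path}:{lineno}: expected 'residue<TAB>probability'")
        residue, prob = parts
        if residue in freqs:
            raise InvalidInputError(f"{path}:{lineno}: duplicate residue {residue!r}")
        freqs[residue.upper()] = float(prob)
    return FrequencyModel("global", freqs)


def write_frequency_table(model: FrequencyModel, path: Union[str, Path]) -> None:
    if model.scope != "global":
        raise InvalidInputError("only global frequency models are written as TSV")
    with open(path, "w") as fh:
        for residue in sorted(model.frequencies):
            fh.write(f"{residue}\t{model.frequencies[residue]:.10g}\n")


def _fmt(value: Optional[float]) -> str:
    return "NA" if value is None else f"{value:.6g}"


def write_results(ranked: Sequence[RankedMotif], path: Union[str, Path]) -> None:
    """TSV of a discovery ranking; one header line, floats at 6 significant digits.

    Scheme columns the run did not compute are rendered as ``NA``; the
    active scheme's significance fills its own column.
    """
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in ranked:
            values = {
                "sig": None, "sig_v": None, "sig_prime": None, "sig_prime_v": None,
                r.scheme: r.significance,
            }
            fh.write(
                "\t".join(
                    [
                        r.pattern,
                        str(r.motif.l),
                        str(r.k),
                        str(r.N),
                        _fmt(r.p_mu),
                        _fmt(r.p_v),
                        _fmt(values["sig"]),
                        _fmt(values["sig_v"]),
                        _fmt(values["sig_prime"]),
                        _fmt(values["sig_prime_v"]),
                        ";".join(r.protein_ids),
                    ]
                )
                + "\n"
            )


def read_results(path: Union[str, Path]) -> List[Dict[str, object]]:
    """Read a results TSV back into a list of row dicts (floats parsed, NA -> None)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise InvalidInputError(f"{path}: empty results file")
    header = lines[0].split("\t")
    rows: List[Dict[str, object]] = []
    float_cols = {"p_mu", "p_v", "sig", "sig_v", "sig_prime", "sig_prime_v"}
    int_cols = {"l", "k", "N"}
    for line in lines[1:]:
        parts = line.split("\t")
        row: Dict[str, object] = {}
        for col, val in zip(header, parts):
            if col in float_cols:
                row[col] = None if val == "NA" else float(val)
            elif col in int_cols:
                row[col] = int(val)
            else:
                row[col] = val
        rows.append(row)
    return rows


def read_config(path: Union[str, Path]) -> Dict[str, str]:
    """Flat ``key=value`` configuration file; '#' comments and blanks ignored."""
    config: Dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise InvalidInputError(f"{path}:{lineno}: expected 'key=value'")
        key, _, value = line.partition("=")
        config[key.strip()] = value.strip()
    return config


def dataset_digest(dataset: SequenceDataset) -> str:
    """Stable content hash of a dataset (ids + sequences), for run logs."""
    h = hashlib.sha256()
    for p in dataset:
        h.update(p.id.encode())
        h.update(b"\x00")
        h.update(p.residues.encode())
        h.update(b"\x01")
    return h.hexdigest()[:16]
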