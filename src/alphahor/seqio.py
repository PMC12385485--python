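"""Sequence and annotation I/O with fixed coordinate conventions.

All coordinates inside the package are 0-based, half-open (BED-style).
Genome-browser style 1-based inclusive positions are converted only at the
I/O boundary via :func:`from_one_based` / :func:`to_one_based`.

FASTA parsing is delegated to Biopython; this module only canonicalizes the
alphabet (uppercase; anything outside ``{A,C,G,T,N}`` becomes ``N``) and
enforces the package's error contract.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

_VALID = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the alphabet {A,C,G,T,N}."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


def from_one_based(pos: int) -> int:
    """Convert a 1-based inclusive position to a 0-based start."""
    return pos - 1


def to_one_based(start: int) -> int:
    """Convert a 0-based start back to a 1-based inclusive position."""
    return start + 1


def canonicalize(seq: str) -> str:
    """Uppercase and map non-ACGTN symbols to N."""
    up = seq.upper()
    if set(up) <= _VALID:
        return up
    return "".join(c if c in _VALID else "N" for c in up)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path: Path):
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fasta(path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) FASTA file into SequenceRecords.

    Records are returned in file order; sequences are canonicalized.
    An empty file raises ``ValueError("no sequences")``; text before the
    first header raises with the offending line number.
    """
    path = Path(path)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise ValueError(
                    f"{path}: malformed FASTA header at line {lineno}: "
                    f"expected '>' before sequence data"
                )
            break
    with _open_text(path) as fh:
        records = [
            SequenceRecord(id=rec.id, sequence=canonicalize(str(rec.seq)))
            for rec in SeqIO.parse(fh, "fasta")
        ]
    if not records:
        raise ValueError(f"{path}: no sequences")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_bed(
    intervals: Sequence[Interval],
    path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED6 lines; the name column carries monomer / HOR copy labels.

    Input must already be sorted by (seq_id, start): sorting is the caller's
    responsibility so that the name/score parallels are unambiguous.
    """
    keys = [(iv.seq_id, iv.start) for iv in intervals]
    if keys != sorted(keys):
        raise ValueError("intervals must be sorted by (seq_id, start)")
    names = names if names is not None else ["." for _ in intervals]
    scores = scores if scores is not None else [0 for _ in intervals]
    with open(path, "w") as fh:
        for iv, name, score in zip(intervals, names, scores):
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{iv.strand}\n")


def write_tsv(table: pd.DataFrame, path) -> None:
    """Write a DataFrame as a headered TSV with deterministic byte output."""
    table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
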