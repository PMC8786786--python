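"""Sequence I/O and translation primitives.

Thin wrappers around Biopython's parsers that return the package's own
lightweight records.  Two alphabets are recognised: ``DNA`` (A, C, G, T, N)
and ``PROTEIN`` (the 20 standard residues plus X and ``*``).  FASTA is
written wrapped at 60 columns; FASTQ is Sanger Phred+33.  Gzip-compressed
input is handled transparently on read (by file suffix).
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence, Union

from Bio.Data.CodonTable import standard_dna_table
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

DNA = "DNA"
PROTEIN = "PROTEIN"

DNA_LETTERS = frozenset("ACGTN")
PROTEIN_LETTERS = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: codon -> amino acid for the standard genetic code; stops are '*'
CODON_TABLE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TABLE[_stop] = "*"


class ParseError(ValueError):
    """Raised for malformed sequence files."""


@dataclass
class SeqRecord:
    """One sequence: identifier, residues and a declared alphabet."""

    id: str
    residues: str
    alphabet: str = DNA
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        letters = DNA_LETTERS if self.alphabet == DNA else PROTEIN_LETTERS
        bad = set(self.residues) - letters
        if bad:
            raise ValueError(
                f"record {self.id!r}: letters {sorted(bad)} not in {self.alphabet} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ReadPair:
    """A sequencing read with quality, optionally with its mate."""

    r1: SeqRecord
    q1: str
    r2: Optional[SeqRecord] = None
    q2: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.q1) != len(self.r1.residues):
            raise ParseError(f"read {self.r1.id!r}: quality length != sequence length")
        if self.r2 is not None:
            assert self.q2 is not None
            if len(self.q2) != len(self.r2.residues):
                raise ParseError(f"read {self.r2.id!r}: quality length != sequence length")


PathLike = Union[str, Path]


def _open_text(path: PathLike) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def guess_alphabet(residues: str) -> str:
    return DNA if set(residues.upper()) <= DNA_LETTERS else PROTEIN


def read_fasta(path: PathLike, alphabet: Optional[str] = None) -> list[SeqRecord]:
    """Read a FASTA file into a list of records (file order preserved).

    Wrapped sequence lines are joined and residues uppercased.  The alphabet
    is guessed per record unless given.  Duplicate identifiers within one
    file are an error.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    with _open_text(path) as handle:
        try:
            for title, seq in SimpleFastaParser(handle):
                name = title.split(None, 1)
                rid = name[0] if name else ""
                desc = name[1] if len(name) > 1 else ""
                if not rid:
                    raise ParseError(f"{path}: record {len(records) + 1} has an empty header")
                if not seq:
                    raise ParseError(f"{path}: record {rid!r} has no sequence")
                if rid in seen:
                    raise ParseError(f"{path}: duplicate record id {rid!r}")
                seen.add(rid)
                seq = seq.upper()
                records.append(
                    SeqRecord(rid, seq, alphabet or guess_alphabet(seq), desc)
                )
        except ValueError as exc:
            if isinstance(exc, ParseError):
                raise
            raise ParseError(f"{path}: {exc}") from exc
    return records


def write_fasta(records: Iterable[SeqRecord], path: PathLike, width: int = 60) -> None:
    with open(path, "wt") as out:
        for rec in records:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


def _iter_fastq(path: PathLike) -> Iterator[tuple[str, str, str]]:
    with _open_text(path) as handle:
        try:
            yield from FastqGeneralIterator(handle)
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc


def read_fastq(path_r1: PathLike, path_r2: Optional[PathLike] = None) -> list[ReadPair]:
    """Read single or paired FASTQ; paired files are zipped by position."""
    pairs: list[ReadPair] = []
    if path_r2 is None:
        for title, seq, qual in _iter_fastq(path_r1):
            rid = title.split()[0]
            if len(qual) != len(seq):
                raise ParseError(f"{path_r1}: read {rid!r} quality/sequence length mismatch")
            pairs.append(ReadPair(SeqRecord(rid, seq, DNA), qual))
        return pairs

    it1, it2 = _iter_fastq(path_r1), _iter_fastq(path_r2)
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            break
        if rec1 is None or rec2 is None:
            raise ParseError(
                f"paired FASTQ files {path_r1} / {path_r2} have unequal record counts"
            )
        t1, s1, q1 = rec1
        t2, s2, q2 = rec2
        pairs.append(
            ReadPair(
                SeqRecord(t1.split()[0], s1, DNA),
                q1,
                SeqRecord(t2.split()[0], s2, DNA),
                q2,
            )
        )
    return pairs


def write_fastq(pairs: Sequence[ReadPair], path_r1: PathLike, path_r2: Optional[PathLike] = None) -> None:
    """Write pairs back out; mate files only when ``path_r2`` given."""
    with open(path_r1, "wt") as o1:
        for p in pairs:
            o1.write(f"@{p.r1.id}\n{p.r1.residues}\n+\n{p.q1}\n")
    if path_r2 is not None:
        with open(path_r2, "wt") as o2:
            for p in pairs:
                if p.r2 is None:
                    raise ValueError(f"read {p.r1.id!r} has no mate; cannot write paired output")
                o2.write(f"@{p.r2.id}\n{p.r2.residues}\n+\n{p.q2}\n")


def _check_dna(dna: str) -> str:
    dna = dna.upper()
    bad = set(dna) - DNA_LETTERS
    if bad:
        raise ValueError(f"not a DNA sequence: letters {sorted(bad)}")
    return dna


def reverse_complement(dna: str) -> str:
    """Reverse complement; N maps to N.  An involution."""
    return _check_dna(dna).translate(_COMPLEMENT)[::-1]


def translate(dna: str, frame: int = 0, strand: str = "+") -> str:
    """Translate one frame with the standard genetic code.

    Stops are ``*``; any codon containing N becomes X; the trailing partial
    codon is dropped.  Minus-strand frames are numbered from the 5' end of
    the reverse complement.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame!r}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    work = _check_dna(dna)
    if strand == "-":
        work = reverse_complement(work)
    out = []
    for i in range(frame, len(work) - 2, 3):
        codon = work[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X"))
    return "".join(out)


def six_frame(dna: str) -> dict[tuple[str, int], str]:
    """All six frame translations keyed by (strand, frame)."""
    return {
        (strand, frame): translate(dna, frame, strand)
        for strand in ("+", "-")
        for frame in (0, 1, 2)
    }
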