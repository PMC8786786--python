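"""Six-frame ORF extraction and the PG-content candidate filter.

ORFs are stop-to-stop by default: a maximal stop-free codon run in any of
the six frames, so peptides lacking an initiator methionine are kept (low
complexity transcripts are frequently assembled without their 5' end).  An
ATG-anchored mode is available behind ``require_start``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import DNA, SeqRecord, translate


@dataclass
class OrfCandidate:
    """A translated open reading frame with source coordinates.

    ``start``/``end`` are 1-based inclusive nucleotide positions on the
    forward strand of the source sequence.  ``stop_flanked`` records whether
    the run ended at a stop codon (False means it was truncated by the
    sequence end, i.e. potentially a partial CDS).
    """

    source_id: str
    strand: str
    frame: int
    start: int
    end: int
    peptide: str
    has_initiator_met: bool
    stop_flanked: bool = True

    @property
    def is_partial(self) -> bool:
        return not (self.has_initiator_met and self.stop_flanked)

    @property
    def orf_id(self) -> str:
        return f"{self.source_id}|{self.strand}{self.frame}|{self.start}-{self.end}"


def find_orfs(record: SeqRecord, min_aa: int = 50, require_start: bool = False) -> list[OrfCandidate]:
    """Every maximal stop-free stretch in each of the 6 frames, translated.

    ``has_initiator_met`` is True iff the reported peptide begins with M.
    With ``require_start`` peptides are trimmed to their first M (runs
    without one are dropped).
    """
    if min_aa < 1:
        raise ValueError(f"min_aa must be >= 1, got {min_aa}")
    if record.alphabet != DNA:
        raise ValueError(f"record {record.id!r} is not DNA")
    seq = record.residues
    length = len(seq)
    orfs: list[OrfCandidate] = []
    for strand in ("+", "-"):
        for frame in (0, 1, 2):
            pep = translate(seq, frame, strand)
            i = 0
            n = len(pep)
            while i < n:
                if pep[i] == "*":
                    i += 1
                    continue
                j = i
                while j < n and pep[j] != "*":
                    j += 1
                run = pep[i:j]
                aa_start = i
                if require_start:
                    met = run.find("M")
                    if met < 0:
                        i = j + 1
                        continue
                    run = run[met:]
                    aa_start = i + met
                if len(run) >= min_aa:
                    # nt span on the translated (working) strand
                    ws = frame + 3 * aa_start
                    we = frame + 3 * (aa_start + len(run))
                    if strand == "+":
                        start, end = ws + 1, we
                    else:
                        start, end = length - we + 1, length - ws
                    orfs.append(
                        OrfCandidate(
                            source_id=record.id,
                            strand=strand,
                            frame=frame,
                            start=start,
                            end=end,
                            peptide=run,
                            has_initiator_met=run.startswith("M"),
                            stop_flanked=j < n,
                        )
                    )
                i = j + 1
    return orfs


def pg_percent(peptide: str) -> float:
    """100 * (#P + #G) / length, on the peptide as given."""
    if not peptide:
        raise ValueError("empty peptide")
    return 100.0 * (peptide.count("P") + peptide.count("G")) / len(peptide)


def pg_filter(orfs: Iterable[OrfCandidate], threshold_pct: float = 20.0) -> list[OrfCandidate]:
    """Retain ORFs whose PG% strictly exceeds the threshold (default 20)."""
    return [orf for orf in orfs if pg_percent(orf.peptide) > threshold_pct]
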