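"""Global pairwise alignment with region-partitioned identity.

Alignment itself is delegated to Biopython's PairwiseAligner configured as
a Needleman-Wunsch with affine gaps and free end gaps (match +5 /
mismatch -4, gap open 10, gap extend 0.5 for DNA — the defaults of the
EMBOSS-style global aligners this mirrors).  On top of it sit the analyses
particular to orthologue comparison of low-complexity genes: per-region
identity (signal vs mature vs intron) and frameshift-generating gaps
(coding-region gaps whose length is not a multiple of three).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio import Align

from .seqio import DNA_LETTERS


@dataclass
class AlignParams:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 10.0
    gap_extend: float = 0.5
    end_gaps_free: bool = True
    name: str = "dna-full"


@dataclass
class GlobalAlignment:
    gapped_a: str
    gapped_b: str
    score: float
    params: AlignParams

    def __post_init__(self) -> None:
        if len(self.gapped_a) != len(self.gapped_b):
            raise ValueError("gapped sequences differ in length")

    @property
    def columns(self) -> int:
        return len(self.gapped_a)

    @property
    def identity_pct(self) -> float:
        same = sum(a == b and a != "-" for a, b in zip(self.gapped_a, self.gapped_b))
        return 100.0 * same / self.columns


def _is_dna(s: str) -> bool:
    return set(s.upper()) <= DNA_LETTERS


def global_align(
    a: str, b: str, params: Optional[AlignParams] = None, check_alphabet: bool = True
) -> GlobalAlignment:
    """Optimal global alignment of two same-alphabet sequences.

    The first optimal alignment in the aligner's deterministic enumeration
    order is reported, so ties break reproducibly.
    """
    a, b = a.upper(), b.upper()
    if check_alphabet and _is_dna(a) != _is_dna(b):
        raise ValueError("cannot align sequences from different alphabets")
    params = params or AlignParams()
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    # Biopython convention: open score applies to the first gap position
    aligner.open_gap_score = -(params.gap_open)
    aligner.extend_gap_score = -(params.gap_extend)
    if params.end_gaps_free:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # older Biopython
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    alignments = aligner.align(a, b)
    best = alignments[0]
    return GlobalAlignment(
        gapped_a=str(best[0]),
        gapped_b=str(best[1]),
        score=float(best.score),
        params=params,
    )


@dataclass
class RegionIdentityReport:
    """Identity percent and aligned-column count per region label."""

    identity: dict[str, float]
    columns: dict[str, int]
    identical: dict[str, int]
    frameshift_gaps: list[tuple[int, int]] = field(default_factory=list)


def _column_regions(
    aln: GlobalAlignment, regions: Mapping[str, tuple[int, int]]
) -> list[Optional[str]]:
    """Assign each alignment column to the region covering its a-residue.

    Columns where a has a gap inherit the enclosing region (the label of
    the last a-residue seen; leading gap columns take the first residue's
    label).
    """
    length_a = sum(c != "-" for c in aln.gapped_a)
    for label, (s, e) in regions.items():
        if not (1 <= s <= e <= length_a):
            raise ValueError(f"region {label!r} {s}..{e} outside sequence a (length {length_a})")

    def region_of(pos: int) -> Optional[str]:
        for label, (s, e) in regions.items():
            if s <= pos <= e:
                return label
        return None

    labels: list[Optional[str]] = []
    apos = 0
    pending_leading = 0
    for ca in aln.gapped_a:
        if ca != "-":
            apos += 1
            lab = region_of(apos)
            if pending_leading:
                labels.extend([lab] * pending_leading)
                pending_leading = 0
            labels.append(lab)
        else:
            if apos == 0:
                pending_leading += 1
            else:
                labels.append(region_of(apos))
    if pending_leading:
        labels.extend([None] * pending_leading)
    return labels


def region_identity(
    aln: GlobalAlignment, regions: Mapping[str, tuple[int, int]]
) -> RegionIdentityReport:
    """Per-region identity over the columns assigned to each region.

    ``regions`` maps labels to 1-based inclusive intervals on the ungapped
    sequence a.  The denominator is every aligned column assigned to the
    region, gap columns included.  A ``full`` entry covers all columns.
    """
    labels = _column_regions(aln, regions)
    cols: dict[str, int] = {lab: 0 for lab in regions}
    same: dict[str, int] = {lab: 0 for lab in regions}
    cols["full"] = aln.columns
    same["full"] = 0
    for lab, ca, cb in zip(labels, aln.gapped_a, aln.gapped_b):
        identical = ca == cb and ca != "-"
        if identical:
            same["full"] += 1
        if lab is not None:
            cols[lab] += 1
            if identical:
                same[lab] += 1
    identity = {
        lab: (100.0 * same[lab] / cols[lab]) if cols[lab] else 0.0 for lab in cols
    }
    return RegionIdentityReport(identity=identity, columns=cols, identical=same)


def frameshift_gaps(
    aln: GlobalAlignment, coding_regions: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Maximal gap runs inside coding regions whose length mod 3 != 0.

    Returns (position, length) pairs; the position is on a's ungapped
    coordinates (for gaps in a, the a-position preceding the gap).  Both
    deletion runs (gap in b) and insertion runs (gap in a) are reported.
    """

    def in_coding(pos: int) -> bool:
        return any(s <= pos <= e for s, e in coding_regions)

    out: list[tuple[int, int]] = []
    apos = 0
    i = 0
    n = aln.columns
    while i < n:
        ca, cb = aln.gapped_a[i], aln.gapped_b[i]
        if cb == "-" and ca != "-":
            start_apos = apos + 1
            length = 0
            while i < n and aln.gapped_b[i] == "-" and aln.gapped_a[i] != "-":
                apos += 1
                length += 1
                i += 1
            if length % 3 and in_coding(start_apos):
                out.append((start_apos, length))
        elif ca == "-" and cb != "-":
            anchor = apos  # a-position before the inserted run
            length = 0
            while i < n and aln.gapped_a[i] == "-" and aln.gapped_b[i] != "-":
                length += 1
                i += 1
            if length % 3 and in_coding(max(anchor, 1)):
                out.append((max(anchor, 1), length))
        else:
            apos += 1
            i += 1
    return out


def genomic_span(start: int, end: int) -> tuple[int, str]:
    """Length in nt of a 1-based inclusive interval, plus a 'x.y kb' string."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    length = end - start + 1
    return length, f"{length / 1000:.1f} kb"
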