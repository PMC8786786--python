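"""k-mer read baiting: select reads sharing k-mers with bait sequences.

Reproduces the targeted read-selection step used ahead of local
reassembly: every read carrying at least ``n_min`` k-mers (default k=31,
n=1) from the bait index is kept.  k-mers are canonical (the
lexicographic minimum of a k-mer and its reverse complement) because baits
derive from coding sequence while reads come off both strands.  Base
qualities play no role; raw, untrimmed reads are baited as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .seqio import ReadPair, SeqRecord, reverse_complement

PAIR_POLICIES = ("either", "both", "ignore")


@dataclass
class BaitIndex:
    k: int
    kmers: set[str]
    n_min: int = 1


def _canonical_kmers(seq: str, k: int) -> Iterable[str]:
    seq = seq.upper()
    rc = reverse_complement(seq)
    n = len(seq)
    for i in range(n - k + 1):
        fwd = seq[i : i + k]
        if "N" in fwd:
            continue
        rev = rc[n - k - i : n - i]
        yield min(fwd, rev)


def build_bait_index(baits: Sequence[SeqRecord], k: int = 31, n_min: int = 1) -> BaitIndex:
    """Index every canonical k-mer of every bait (k-mers containing N skipped)."""
    if not baits:
        raise ValueError("no bait sequences given")
    if k < 11 or k % 2 == 0:
        raise ValueError(f"k must be odd and >= 11, got {k}")
    if all(len(b.residues) < k for b in baits):
        raise ValueError(f"all baits are shorter than k={k}")
    kmers: set[str] = set()
    for bait in baits:
        kmers.update(_canonical_kmers(bait.residues, k))
    return BaitIndex(k=k, kmers=kmers, n_min=n_min)


def match_count(read: SeqRecord, index: BaitIndex) -> int:
    """Number of the read's canonical k-mers present in the index."""
    if len(read.residues) < index.k:
        return 0
    return sum(1 for km in _canonical_kmers(read.residues, index.k) if km in index.kmers)


def bait_reads(
    pairs: Sequence[ReadPair], index: BaitIndex, pair_policy: str = "either"
) -> list[ReadPair]:
    """Select read pairs matching the bait index; input order preserved.

    Policies: ``either`` keeps a pair when either mate matches (the default,
    suited to paired reassembly), ``both`` requires both mates, ``ignore``
    judges R1 only.
    """
    if pair_policy not in PAIR_POLICIES:
        raise ValueError(f"pair_policy must be one of {PAIR_POLICIES}, got {pair_policy!r}")
    selected: list[ReadPair] = []
    for pair in pairs:
        m1 = match_count(pair.r1, index) >= index.n_min
        m2 = match_count(pair.r2, index) >= index.n_min if pair.r2 is not None else False
        if pair_policy == "either":
            keep = m1 or m2
        elif pair_policy == "both":
            keep = m1 and (pair.r2 is None or m2)
        else:
            keep = m1
        if keep:
            selected.append(pair)
    return selected
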