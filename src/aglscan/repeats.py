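"""Tandem repeat detection, repeat properties and codon usage.

The detector finds arrays of adjacent, near-identical units within one
sequence and scores them with Psim, the mean identity of the units to their
column-majority consensus.  Candidate unit lengths (periods) come from
k-mer occurrence distances; each candidate array is grown unit by unit
while new units stay above the Psim threshold.  The working thresholds in
this domain are Psim 1.0 for mature proteins (perfect arrays) and 0.7 for
the corresponding coding DNA, where codon degeneracy loosens the repeat.

Repeat units in the (P%, G%) plane are classified into elastic,
intermediate ("interchangeable") and amyloid zones bounded by two
piecewise-linear curves.  The default zone file shipped with the package
is a calibration chosen so that well-characterised exemplar repeats fall
in their reported zones; it is config, not a measured constant.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

import edlib

from .seqio import CODON_TABLE

_KMER_K = {"protein": 3, "dna": 5}


@dataclass
class TandemRepeatRegion:
    """A detected repeat array; positions are 1-based inclusive."""

    seq_id: str
    start: int
    end: int
    unit_length: int
    copies: int                 # full units only; a partial terminal unit
    units: list[str]            # extends the span but is not a copy
    consensus: str
    psim: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class RepeatProperties:
    p_pct: float
    g_pct: float
    zwitterionic: bool
    zone: str


@dataclass
class PropertyZones:
    """Two boundary polylines in the (G%, P%) plane.

    Each curve is a list of ``(g_pct, p_pct)`` vertices with strictly
    increasing G%; between/beyond vertices the boundary is linear/flat.
    Points on or above the upper curve are elastic; strictly below the
    lower curve, amyloid; otherwise intermediate.
    """

    amyloid_intermediate: list[tuple[float, float]]
    intermediate_elastic: list[tuple[float, float]]

    def __post_init__(self) -> None:
        for name, curve in (
            ("amyloid_intermediate", self.amyloid_intermediate),
            ("intermediate_elastic", self.intermediate_elastic),
        ):
            if len(curve) < 2:
                raise ValueError(f"zone boundary {name} needs >= 2 vertices")
            gs = [g for g, _ in curve]
            if any(b <= a for a, b in zip(gs, gs[1:])):
                raise ValueError(f"zone boundary {name} vertices must have increasing G%")
        for g in range(0, 101, 1):
            if _polyline_y(self.intermediate_elastic, float(g)) < _polyline_y(
                self.amyloid_intermediate, float(g)
            ):
                raise ValueError("zone boundaries cross: elastic curve below amyloid curve")


def _polyline_y(curve: Sequence[tuple[float, float]], x: float) -> float:
    if x <= curve[0][0]:
        return curve[0][1]
    for (x0, y0), (x1, y1) in zip(curve, curve[1:]):
        if x <= x1:
            t = (x - x0) / (x1 - x0)
            return y0 + t * (y1 - y0)
    return curve[-1][1]


def default_zones() -> PropertyZones:
    """Zone boundaries shipped with the package (a documented calibration)."""
    text = resources.files("aglscan.data").joinpath("zones_default.json").read_text()
    raw = json.loads(text)
    return PropertyZones(
        amyloid_intermediate=[tuple(v) for v in raw["amyloid_intermediate"]],
        intermediate_elastic=[tuple(v) for v in raw["intermediate_elastic"]],
    )


def classify_zone(p_pct: float, g_pct: float, zones: Optional[PropertyZones] = None) -> str:
    """Point-in-region test against the configured boundary curves."""
    if not (0 <= p_pct <= 100 and 0 <= g_pct <= 100):
        raise ValueError(f"percentages out of range: P={p_pct}, G={g_pct}")
    zones = zones or default_zones()
    if p_pct >= _polyline_y(zones.intermediate_elastic, g_pct):
        return "elastic"
    if p_pct < _polyline_y(zones.amyloid_intermediate, g_pct):
        return "amyloid"
    return "intermediate"


def _unit_identity(unit: str, consensus: str) -> float:
    """Global-alignment identity of a unit to the consensus.

    Edit-distance based, so single-residue indels cost one mismatch rather
    than derailing the comparison.
    """
    if unit == consensus:
        return 1.0
    dist = edlib.align(unit, consensus, mode="NW", task="distance")["editDistance"]
    return max(0.0, 1.0 - dist / len(consensus))


def _majority_consensus(units: Sequence[str]) -> str:
    length = len(units[0])
    cols = []
    for i in range(length):
        counts = Counter(u[i] for u in units if i < len(u))
        # deterministic tie-break: highest count, then lexicographic
        cols.append(min(counts, key=lambda c: (-counts[c], c)))
    return "".join(cols)


def _candidate_periods(seq: str, k: int, max_period: int) -> list[int]:
    occ: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        occ.setdefault(seq[i : i + k], []).append(i)
    support: Counter[int] = Counter()
    for positions in occ.values():
        if len(positions) < 2:
            continue
        if len(positions) > 200:
            pairs = zip(positions, positions[1:])
        else:
            pairs = (
                (positions[a], positions[b])
                for a in range(len(positions))
                for b in range(a + 1, len(positions))
            )
        for p0, p1 in pairs:
            d = p1 - p0
            if 1 <= d <= max_period:
                support[d] += 1
    return sorted(d for d, c in support.items() if c >= 2)


def _grow_array(seq: str, anchor: int, period: int, psim_min: float) -> tuple[int, list[str]]:
    """Grow a unit array around ``anchor`` in steps of ``period``.

    Returns (start_index, units).  Each appended unit must align to the
    running column-majority consensus with identity >= psim_min.
    """
    units = [seq[anchor : anchor + period]]
    start = anchor
    consensus = units[0]
    # extend right
    while True:
        nxt = seq[start + len(units) * period : start + (len(units) + 1) * period]
        if len(nxt) < period or _unit_identity(nxt, consensus) < psim_min:
            break
        units.append(nxt)
        consensus = _majority_consensus(units)
    # extend left
    while start - period >= 0:
        prv = seq[start - period : start]
        if _unit_identity(prv, consensus) < psim_min:
            break
        units.insert(0, prv)
        start -= period
        consensus = _majority_consensus(units)
    return start, units


def detect_repeats(
    seq: str,
    alphabet: str = "protein",
    psim_min: float = 1.0,
    min_copies: int = 2,
    filter_overlaps: bool = False,
    seq_id: str = "seq",
    max_period: Optional[int] = None,
) -> list[TandemRepeatRegion]:
    """Detect tandem repeat arrays in one sequence.

    Smallest qualifying period wins when several explain the same span at
    equal Psim.  With ``filter_overlaps`` the highest-scoring
    (copies x unit_length x psim) regions are retained greedily and any
    region overlapping an accepted one is discarded.
    """
    if not (0 < psim_min <= 1):
        raise ValueError(f"psim_min must be in (0, 1], got {psim_min}")
    if min_copies < 2:
        raise ValueError(f"min_copies must be >= 2, got {min_copies}")
    seq = seq.upper()
    if alphabet not in _KMER_K:
        raise ValueError(f"alphabet must be 'protein' or 'dna', got {alphabet!r}")
    k = _KMER_K[alphabet]
    n = len(seq)
    if max_period is None:
        max_period = n // 2
    # periods below the k-mer size are seeded by direct adjacent-unit scan
    small = [
        p
        for p in range(1, min(k, max_period + 1))
        if any(seq[s : s + p] == seq[s + p : s + 2 * p] for s in range(n - 2 * p + 1))
    ]
    periods = sorted(set(small) | set(_candidate_periods(seq, k, max_period)))
    regions: list[TandemRepeatRegion] = []
    for period in periods:
        w = min(k, period)
        covered: list[tuple[int, int]] = []
        for s in range(n - period - w + 1):
            if seq[s : s + w] != seq[s + period : s + period + w]:
                continue
            if any(a <= s < b for a, b in covered):
                continue
            start, units = _grow_array(seq, s, period, psim_min)
            if len(units) < min_copies:
                continue
            consensus = _majority_consensus(units)
            psim = sum(_unit_identity(u, consensus) for u in units) / len(units)
            if psim < psim_min:
                continue
            end = start + len(units) * period  # exclusive, full units
            all_units = list(units)
            # partial terminal unit: extends the span, not the copy count
            rest = seq[end : min(end + period - 1, n)]
            if rest:
                match = sum(a == b for a, b in zip(rest, consensus))
                if match / len(rest) >= psim_min:
                    all_units.append(rest)
                    end += len(rest)
            covered.append((start, end))
            regions.append(
                TandemRepeatRegion(
                    seq_id=seq_id,
                    start=start + 1,
                    end=end,
                    unit_length=period,
                    copies=len(units),
                    units=all_units,
                    consensus=consensus,
                    psim=psim,
                )
            )
    regions = _drop_redundant(regions)
    if filter_overlaps:
        regions = _greedy_filter(regions)
    regions.sort(key=lambda r: (r.start, r.unit_length))
    return regions


def _drop_redundant(regions: list[TandemRepeatRegion]) -> list[TandemRepeatRegion]:
    """Subsumption rule: a region whose span lies inside a kept region of
    equal-or-higher psim is redundant (the larger array explains it); for
    identical spans the widest-span-then-smallest-period ordering makes the
    smallest qualifying period win."""
    def subsumed(reg: TandemRepeatRegion, other: TandemRepeatRegion) -> bool:
        if not (other.start <= reg.start and other.end >= reg.end):
            return False
        if other.psim < reg.psim - 1e-12:
            return False
        # a fragment too short to hold two of the container's units carries
        # no period information of its own (e.g. a doublet inside an array)
        if other.unit_length >= reg.unit_length and reg.span < 2 * other.unit_length:
            return True
        # a period-multiple of a container at the same (or better) psim
        return reg.unit_length % other.unit_length == 0

    kept: list[TandemRepeatRegion] = []
    for reg in sorted(regions, key=lambda r: (-r.span, r.unit_length, r.start)):
        if not any(subsumed(reg, other) for other in kept):
            kept.append(reg)
    return kept


def _greedy_filter(regions: list[TandemRepeatRegion]) -> list[TandemRepeatRegion]:
    ranked = sorted(
        regions,
        key=lambda r: (-(r.copies * r.unit_length * r.psim), r.start, r.unit_length),
    )
    accepted: list[TandemRepeatRegion] = []
    for reg in ranked:
        if all(reg.end < a.start or reg.start > a.end for a in accepted):
            accepted.append(reg)
    return accepted


def repeat_properties(
    region: TandemRepeatRegion,
    zones: Optional[PropertyZones] = None,
    on: str = "consensus",
) -> RepeatProperties:
    """P%/G%, zwitterionic flag and property zone of a repeat.

    Percentages are computed on the consensus unit by default (``on`` may
    be "consensus" or "region" for the full repeat span).  A repeat is
    zwitterionic iff its unit carries at least one acidic (D/E) and one
    basic (K/R) residue.
    """
    if on == "consensus":
        text = region.consensus
    elif on == "region":
        text = "".join(region.units)
    else:
        raise ValueError(f"on must be 'consensus' or 'region', got {on!r}")
    p_pct = 100.0 * text.count("P") / len(text)
    g_pct = 100.0 * text.count("G") / len(text)
    unit = region.consensus
    zwit = any(aa in unit for aa in "DE") and any(aa in unit for aa in "KR")
    return RepeatProperties(
        p_pct=p_pct,
        g_pct=g_pct,
        zwitterionic=zwit,
        zone=classify_zone(p_pct, g_pct, zones),
    )


@dataclass
class CodonUsageTable:
    """Per-amino-acid codon counts and fractions within a CDS interval."""

    counts: dict[str, dict[str, int]]

    @property
    def fractions(self) -> dict[str, dict[str, float]]:
        out: dict[str, dict[str, float]] = {}
        for aa, codons in self.counts.items():
            total = sum(codons.values())
            out[aa] = {c: k / total for c, k in codons.items()}
        return out


def codon_usage(
    cds: str,
    interval_nt: Optional[tuple[int, int]] = None,
    frame_offset: Optional[int] = None,
) -> CodonUsageTable:
    """Codon counts grouped by encoded amino acid within a CDS interval.

    ``interval_nt`` is 1-based inclusive on the CDS; the interval must be
    in frame (length divisible by 3) unless an explicit ``frame_offset``
    shifts it, in which case any trailing partial codon is dropped.
    """
    cds = cds.upper()
    if interval_nt is None:
        interval_nt = (1, len(cds))
    start, end = interval_nt
    if not (1 <= start <= end <= len(cds)):
        raise ValueError(f"interval {interval_nt} outside CDS of length {len(cds)}")
    sub = cds[start - 1 : end]
    if frame_offset is None:
        if len(sub) % 3:
            raise ValueError(
                f"interval length {len(sub)} not divisible by 3; pass frame_offset explicitly"
            )
        frame_offset = 0
    sub = sub[frame_offset:]
    counts: dict[str, dict[str, int]] = {}
    for i in range(0, len(sub) - 2, 3):
        codon = sub[i : i + 3]
        aa = CODON_TABLE.get(codon, "X")
        counts.setdefault(aa, {})
        counts[aa][codon] = counts[aa].get(codon, 0) + 1
    return CodonUsageTable(counts=counts)
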