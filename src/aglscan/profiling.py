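"""Protein composition profiling, pI/MW, property flags and signal regions.

The composition statistics mirror how secreted low-complexity proteins are
summarised in practice: residue percentages on the mature protein (after
removing the N-terminal ER signal peptide and the C-terminal GPI-anchor
propeptide), aggregate PGA%, acidic DE% and basic KR%, molecular weight and
isoelectric point.

Signal regions come from two sources and are never silently mixed: imported
predictor summaries (authoritative; ``provenance="imported"``) or the
built-in sequence heuristics (``provenance="heuristic"``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: average residue (i.e. water-free) masses in Daltons
RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)

#: Bjellqvist pKa set (the ExPASy convention).  ``positive`` groups gain a
#: proton below their pKa, ``negative`` groups lose one above it.  The set
#: is held in one table so an alternative convention (e.g. EMBOSS) can be
#: swapped in via the ``pka`` argument of :func:`isoelectric_point`.
PKA_BJELLQVIST = {
    "positive": {"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
}

#: Kyte-Doolittle hydropathy
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2, "X": 0.0,
}

# small residues accepted at the (-3, -1) positions of an ER cleavage site
_ER_SMALL = frozenset("AGSCTV")
# small residues accepted at the GPI omega and omega+2 positions
_GPI_SMALL = frozenset("GASNDC")


@dataclass
class CompositionProfile:
    """Residue percentages plus MW/pI for one protein."""

    length: int
    mw: float
    pi: float
    pct: dict[str, float]          # residue -> percent (full precision)
    pga_pct: float
    pg_pct: float
    de_pct: float
    kr_pct: float
    nterm_q: bool


@dataclass
class ProfileFlags:
    """Threshold flags recomputable from a CompositionProfile alone."""

    high_single_aa: frozenset[str]
    pga_ge_40: bool
    de_ge_8: bool
    kr_ge_8: bool
    pi_class: str                  # acidic / neutral / basic


@dataclass
class RegionAnnotation:
    """ER-signal, GPI omega and intron intervals on one sequence.

    ``er_signal`` is the 1-based inclusive interval ``(1, c)`` of the signal
    peptide (cleavage after residue ``c``); ``gpi_omega`` is the omega
    residue position.  The mature protein is ``er_end+1 .. omega-1``.
    """

    er_signal: Optional[tuple[int, int]] = None
    gpi_omega: Optional[int] = None
    introns: list[tuple[int, int]] = field(default_factory=list)
    provenance: str = "imported"

    def __post_init__(self) -> None:
        if self.er_signal is not None and self.gpi_omega is not None:
            if self.er_signal[1] >= self.gpi_omega:
                raise ValueError(
                    f"ER signal end {self.er_signal[1]} must precede GPI omega {self.gpi_omega}"
                )

    def mature_interval(self, length: int) -> tuple[int, int]:
        start = self.er_signal[1] + 1 if self.er_signal else 1
        end = self.gpi_omega - 1 if self.gpi_omega else length
        return start, end


def _validate_protein(protein: str) -> str:
    protein = protein.upper()
    if not protein:
        raise ValueError("empty protein sequence")
    if "*" in protein:
        raise ValueError("protein contains a stop character '*'")
    bad = set(protein) - set(AA20) - {"X"}
    if bad:
        raise ValueError(f"not a protein sequence: letters {sorted(bad)}")
    return protein


def molecular_weight(protein: str, strict: bool = True) -> float:
    """Average molecular weight: sum of residue masses plus one water.

    X is an error in strict mode; otherwise it contributes the mean residue
    mass.
    """
    protein = _validate_protein(protein)
    total = WATER_MASS
    for aa in protein:
        if aa == "X":
            if strict:
                raise ValueError("sequence contains X; pass strict=False for a mean-mass estimate")
            total += MEAN_RESIDUE_MASS
        else:
            total += RESIDUE_MASS[aa]
    return total


def charge_at_ph(protein: str, ph: float, pka: Mapping[str, Mapping[str, float]] = PKA_BJELLQVIST) -> float:
    """Net charge under the Henderson-Hasselbalch model (termini included)."""
    protein = _validate_protein(protein)
    pos, neg = pka["positive"], pka["negative"]
    charge = 1.0 / (1.0 + 10 ** (ph - pos["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (neg["Cterm"] - ph))
    for aa, pk in pos.items():
        if aa != "Nterm":
            charge += protein.count(aa) / (1.0 + 10 ** (ph - pk))
    for aa, pk in neg.items():
        if aa != "Cterm":
            charge -= protein.count(aa) / (1.0 + 10 ** (pk - ph))
    return charge


def isoelectric_point(
    protein: str,
    tol: float = 0.005,
    pka: Mapping[str, Mapping[str, float]] = PKA_BJELLQVIST,
) -> float:
    """pH where the model net charge crosses zero; bisection on [0, 14]."""
    protein = _validate_protein(protein)
    lo, hi = 0.0, 14.0
    # net charge is monotone decreasing in pH
    if charge_at_ph(protein, lo, pka) < 0:
        return lo
    if charge_at_ph(protein, hi, pka) > 0:
        return hi
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if charge_at_ph(protein, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def composition(protein: str) -> CompositionProfile:
    """Full composition profile of a protein.

    Percentages are 100*count/length at full precision (round for display);
    X counts toward length but toward no residue percentage.
    """
    protein = _validate_protein(protein)
    n = len(protein)
    pct = {aa: 100.0 * protein.count(aa) / n for aa in AA20}
    return CompositionProfile(
        length=n,
        mw=molecular_weight(protein, strict=False),
        pi=isoelectric_point(protein),
        pct=pct,
        pga_pct=pct["P"] + pct["G"] + pct["A"],
        pg_pct=pct["P"] + pct["G"],
        de_pct=pct["D"] + pct["E"],
        kr_pct=pct["K"] + pct["R"],
        nterm_q=protein[0] == "Q",
    )


#: the residue panel reported for high single-residue content: the
#: disorder-promoting / hydroxylation-relevant residues
KEY_RESIDUE_PANEL = frozenset("PGASTNQ")


def flag_profile(
    profile: CompositionProfile,
    single_aa_min: float = 15.0,
    pga_min: float = 40.0,
    charged_min: float = 8.0,
    pi_acidic_below: float = 6.0,
    pi_basic_above: float = 7.5,
    panel: frozenset[str] = KEY_RESIDUE_PANEL,
) -> ProfileFlags:
    """Apply the reporting thresholds (all comparisons non-strict >=).

    ``high_single_aa`` is restricted to the key-residue ``panel``.
    """
    if profile.pi < pi_acidic_below:
        pi_class = "acidic"
    elif profile.pi > pi_basic_above:
        pi_class = "basic"
    else:
        pi_class = "neutral"
    return ProfileFlags(
        high_single_aa=frozenset(
            aa for aa, p in profile.pct.items() if aa in panel and p >= single_aa_min
        ),
        pga_ge_40=profile.pga_pct >= pga_min,
        de_ge_8=profile.de_pct >= charged_min,
        kr_ge_8=profile.kr_pct >= charged_min,
        pi_class=pi_class,
    )


def strip_signals(protein: str, regions: RegionAnnotation) -> str:
    """Return the mature protein between ER cleavage and omega-1.

    The GPI propeptide is removed from the omega residue onward.  If only
    one signal is annotated, only that end is trimmed.
    """
    protein = _validate_protein(protein)
    n = len(protein)
    if regions.er_signal is not None:
        s, e = regions.er_signal
        if not (1 <= s <= e <= n):
            raise ValueError(f"ER signal interval {regions.er_signal} outside sequence of length {n}")
    if regions.gpi_omega is not None and not (1 <= regions.gpi_omega <= n):
        raise ValueError(f"GPI omega {regions.gpi_omega} outside sequence of length {n}")
    start, end = regions.mature_interval(n)
    if start > end:
        raise ValueError(f"empty mature interval {start}..{end}")
    return protein[start - 1 : end]


def import_signal_predictions(
    path: Union[str, Path], dialect: str
) -> dict[str, RegionAnnotation]:
    """Parse an external signal-predictor summary into annotations.

    Two tab-separated dialects are supported:

    - ``"er"``: ``id, er_cleavage_end, call{YES,NO}``
    - ``"gpi"``: ``id, omega_pos, call{YES,NO}, score``

    Rows with call NO yield an (empty) annotation with no region, so that
    a negative prediction is still recorded as imported.
    """
    if dialect not in ("er", "gpi"):
        raise ValueError(f"unknown predictor dialect {dialect!r}")
    annotations: dict[str, RegionAnnotation] = {}
    with open(path, "rt") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or row[0].startswith("#"):
                continue
            want = 3 if dialect == "er" else 4
            if len(row) < want:
                raise ValueError(f"{path}:{lineno}: expected {want} columns, got {len(row)}")
            rid, pos_s, call = row[0], row[1], row[2].strip().upper()
            ann = RegionAnnotation(provenance="imported")
            if call == "YES":
                pos = int(pos_s)
                if dialect == "er":
                    ann.er_signal = (1, pos)
                else:
                    ann.gpi_omega = pos
            annotations[rid] = ann
    return annotations


def merge_annotations(
    er: Mapping[str, RegionAnnotation], gpi: Mapping[str, RegionAnnotation]
) -> dict[str, RegionAnnotation]:
    """Combine per-dialect imports into one annotation per id."""
    merged: dict[str, RegionAnnotation] = {}
    for rid in set(er) | set(gpi):
        merged[rid] = RegionAnnotation(
            er_signal=er[rid].er_signal if rid in er else None,
            gpi_omega=gpi[rid].gpi_omega if rid in gpi else None,
            provenance="imported",
        )
    return merged


def _window_means(values: Sequence[float], width: int) -> list[float]:
    if len(values) < width:
        return []
    acc = sum(values[:width])
    means = [acc / width]
    for i in range(width, len(values)):
        acc += values[i] - values[i - width]
        means.append(acc / width)
    return means


def heuristic_er_signal(
    protein: str,
    h_window: int = 8,
    h_min_kd: float = 1.6,
    cleave_range: tuple[int, int] = (15, 35),
    search_span: int = 40,
) -> Optional[int]:
    """Approximate ER signal-peptide call from sequence alone.

    Requires, within the first ``search_span`` residues, a hydrophobic
    h-region (an 8-aa window of mean Kyte-Doolittle >= 1.6) followed by a
    cleavage position obeying the (-3, -1) small-residue rule.  Returns the
    first qualifying cleavage position in ``cleave_range``, else None.
    Calls from this function must be recorded with provenance "heuristic".
    """
    protein = _validate_protein(protein)
    if len(protein) < 25:
        return None
    head = protein[:search_span]
    kd = [KYTE_DOOLITTLE[aa] for aa in head]
    means = _window_means(kd, h_window)
    # window ends (1-based position of last residue in each window)
    h_ends = [i + h_window for i, m in enumerate(means) if m >= h_min_kd]
    if not h_ends:
        return None
    first_h_end = min(h_ends)
    lo, hi = cleave_range
    for c in range(lo, min(hi, len(protein) - 1) + 1):
        if protein[c - 1] in _ER_SMALL and protein[c - 3] in _ER_SMALL and first_h_end <= c - 1:
            return c
    return None


def heuristic_gpi_signal(
    protein: str,
    tail_len: int = 12,
    tail_min_kd: float = 1.0,
    omega_from_end: tuple[int, int] = (17, 31),
    omega_target: int = 25,
) -> Optional[int]:
    """Approximate GPI omega-site call from sequence alone.

    Requires a hydrophobic C-terminal tail (mean KD >= 1.0 over the final
    12 aa) and a small residue at a position 17-31 from the C-terminus with
    a small residue at omega+2.  Among qualifying positions the one closest
    to 25-from-end wins (ties to the shorter distance from the terminus).
    """
    protein = _validate_protein(protein)
    n = len(protein)
    if n < 40:
        return None
    tail = protein[-tail_len:]
    if sum(KYTE_DOOLITTLE[aa] for aa in tail) / tail_len < tail_min_kd:
        return None
    best: Optional[int] = None
    best_key: Optional[tuple[int, int]] = None
    for d in range(omega_from_end[0], omega_from_end[1] + 1):
        pos = n - d + 1
        if pos < 1 or pos + 2 > n:
            continue
        if protein[pos - 1] in _GPI_SMALL and protein[pos + 1] in _GPI_SMALL:
            key = (abs(d - omega_target), d)
            if best_key is None or key < best_key:
                best, best_key = pos, key
    return best
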