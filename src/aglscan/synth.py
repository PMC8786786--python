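"""Synthetic genes, transcripts, proteins and reads with known truth.

The generator emulates the gene architecture of small secreted PG-rich
tandem-repeat proteins: a short first exon encoding the ER signal peptide
plus three codons, a single GT..AG intron immediately after it, and a
second exon carrying the mature repeat array (back-translated under a
restricted codon-usage model) followed by the C-terminal GPI-anchor
signal.  Every stochastic call takes an explicit seed; identical specs and
seeds give byte-identical output.

Signal peptides are drawn from curated templates (not random hydrophobic
strings) so that the package's built-in signal heuristics fire on them
deterministically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .profiling import RegionAnnotation
from .repeats import TandemRepeatRegion, _unit_identity
from .seqio import DNA, PROTEIN, ReadPair, SeqRecord, reverse_complement

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: restricted codon usage for back-translation; the repeat-forming residues
#: P, D and K get a single codon each (so a perfect array reuses one codon
#: per residue, the hallmark of repeats born by local DNA duplication),
#: G and A get two.
DEFAULT_CODON_BIAS: dict[str, dict[str, float]] = {
    "A": {"GCT": 0.6, "GCA": 0.4},
    "C": {"TGT": 1.0},
    "D": {"GAC": 1.0},
    "E": {"GAA": 1.0},
    "F": {"TTC": 1.0},
    "G": {"GGT": 0.7, "GGA": 0.3},
    "H": {"CAC": 1.0},
    "I": {"ATT": 1.0},
    "K": {"AAA": 1.0},
    "L": {"TTG": 1.0},
    "M": {"ATG": 1.0},
    "N": {"AAC": 1.0},
    "P": {"CCA": 1.0},
    "Q": {"CAA": 1.0},
    "R": {"AGA": 1.0},
    "S": {"TCT": 1.0},
    "T": {"ACT": 1.0},
    "V": {"GTT": 1.0},
    "W": {"TGG": 1.0},
    "Y": {"TAC": 1.0},
}


def strict_codon_bias() -> dict[str, dict[str, float]]:
    """One codon per amino acid (reproduces 100% codon usage in repeats)."""
    return {aa: {next(iter(codons)): 1.0} for aa, codons in DEFAULT_CODON_BIAS.items()}


@dataclass
class SynthSpec:
    """Study conditions for one synthetic gene / cohort."""

    seed: int
    er_len: int = 20
    gpi_len: int = 25
    unit: str = "GKAPAGGAAPGADA"
    copies: int = 5
    unit_mutation_rate: float = 0.0
    codon_bias: dict[str, dict[str, float]] = field(
        default_factory=lambda: {aa: dict(c) for aa, c in DEFAULT_CODON_BIAS.items()}
    )
    intron_len: int = 80
    n_decoys: int = 7
    read_len: int = 100
    coverage: float = 10.0
    read_error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.unit:
            raise ValueError("repeat unit must be non-empty")
        if self.copies < 2:
            raise ValueError("copies must be >= 2")
        for p in (self.unit_mutation_rate, self.read_error_rate):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if not (15 <= self.er_len <= 30):
            raise ValueError("er_len must be within 15..30 (template pool range)")
        if not (17 <= self.gpi_len <= 31):
            raise ValueError("gpi_len must be within 17..31 (omega placement range)")
        if self.intron_len < 10:
            raise ValueError("intron_len must be >= 10")


def er_signal_peptide(er_len: int) -> str:
    """Template ER signal of the requested length, cleavage after the last A.

    Layout: MKFS + poly-L h-region + FNEASA.  The FNEAS spacer blocks any
    earlier (-3, -1) small-residue cleavage site, so the heuristic cleaves
    exactly at ``er_len``.
    """
    if not (15 <= er_len <= 30):
        raise ValueError("er_len outside template range 15..30")
    return "MKFS" + "L" * (er_len - 10) + "FNEASA"


_GPI_SPACER = "KDSEEGKDEEGKDSEE"  # hydrophilic filler, cycled as needed
_GPI_TAIL = "ILLIVAAVLLVA"        # 12-aa hydrophobic membrane-passage tail


def gpi_signal_peptide(gpi_len: int) -> str:
    """Template GPI signal; the omega residue is its first position."""
    if not (17 <= gpi_len <= 31):
        raise ValueError("gpi_len outside template range 17..31")
    spacer_len = gpi_len - 3 - len(_GPI_TAIL)
    spacer = (_GPI_SPACER * 2)[:spacer_len]
    return "NAS" + spacer + _GPI_TAIL


def back_translate(protein: str, codon_bias: dict[str, dict[str, float]], rng: np.random.Generator) -> str:
    """Sample a CDS for a protein under per-amino-acid codon weights."""
    codons = []
    for aa in protein:
        if aa not in codon_bias or not codon_bias[aa]:
            raise ValueError(f"codon_bias has no codons for residue {aa!r}")
        options = sorted(codon_bias[aa])
        weights = np.array([codon_bias[aa][c] for c in options], dtype=float)
        weights /= weights.sum()
        codons.append(options[int(rng.choice(len(options), p=weights))])
    return "".join(codons)


def _mutate_protein(text: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return text
    out = list(text)
    for i, aa in enumerate(out):
        if rng.random() < rate:
            choices = [c for c in AA20 if c != aa]
            out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


@dataclass
class SynthGene:
    """One synthetic gene with exact truth annotations."""

    gene: SeqRecord                      # exon1 + intron + exon2 (DNA)
    transcript: SeqRecord                # spliced CDS incl. stop codon
    protein: SeqRecord                   # full translated protein
    protein_regions: RegionAnnotation    # aa coords on the protein
    gene_regions: dict[str, tuple[int, int]]   # nt coords on the gene
    repeat_truth: TandemRepeatRegion     # planted array, aa coords on protein


def make_agl_gene(spec: SynthSpec, name: str = "synth_agl", rng: Optional[np.random.Generator] = None) -> SynthGene:
    """Build one gene with ER signal, intron, mutated repeat array and GPI tail."""
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    er = er_signal_peptide(spec.er_len)
    gpi = gpi_signal_peptide(spec.gpi_len)
    units = [
        _mutate_protein(spec.unit, spec.unit_mutation_rate, rng)
        for _ in range(spec.copies)
    ]
    mature = "".join(units)
    protein = er + mature + gpi
    for aa in set(protein):
        if aa not in spec.codon_bias:
            raise ValueError(f"codon_bias missing amino acid {aa!r} present in protein")
    cds = back_translate(protein, spec.codon_bias, rng) + "TAA"
    exon1_nt = (spec.er_len + 3) * 3  # short first exon: ER signal + 3 codons
    intron = "GT" + "".join(
        "ACGT"[int(i)] for i in rng.integers(0, 4, spec.intron_len - 4)
    ) + "AG"
    gene = cds[:exon1_nt] + intron + cds[exon1_nt:]

    omega = spec.er_len + len(mature) + 1
    protein_regions = RegionAnnotation(
        er_signal=(1, spec.er_len),
        gpi_omega=omega,
        introns=[(exon1_nt + 1, exon1_nt + spec.intron_len)],
        provenance="imported",
    )
    er_nt = spec.er_len * 3
    # NOTE: the mature span covers the intron's gene coordinates too; the
    # intron entry precedes it, and region lookups take the first match.
    gene_regions = {
        "er_signal": (1, er_nt),
        "intron": (exon1_nt + 1, exon1_nt + spec.intron_len),
        "mature": (er_nt + 1, len(gene) - spec.gpi_len * 3 - 3),
        "gpi_signal": (len(gene) - spec.gpi_len * 3 - 2, len(gene) - 3),
    }

    consensus = spec.unit
    psim = sum(_unit_identity(u, consensus) for u in units) / len(units)
    repeat_truth = TandemRepeatRegion(
        seq_id=name,
        start=spec.er_len + 1,
        end=spec.er_len + len(mature),
        unit_length=len(spec.unit),
        copies=spec.copies,
        units=units,
        consensus=consensus,
        psim=psim,
    )
    return SynthGene(
        gene=SeqRecord(f"{name}_gene", gene, DNA),
        transcript=SeqRecord(f"{name}_cds", cds, DNA),
        protein=SeqRecord(f"{name}_prot", protein, PROTEIN),
        protein_regions=protein_regions,
        gene_regions=gene_regions,
        repeat_truth=repeat_truth,
    )


def make_decoys(
    n: int,
    length_range: tuple[int, int] = (80, 250),
    seed: int = 0,
    rng: Optional[np.random.Generator] = None,
    max_pg_pct: float = 15.0,
) -> list[SeqRecord]:
    """Random ORF-bearing transcripts whose ORF peptides stay PG-poor.

    ``length_range`` is in amino acids.  Each decoy is resampled until every
    ORF of >= 50 aa in all six frames has PG% below ``max_pg_pct``; none
    carries a planted signal peptide.
    """
    from .orfs import find_orfs, pg_percent  # local import to avoid a cycle

    if n < 0:
        raise ValueError("n must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    # P and G kept rare a priori; the post-hoc check below enforces the cap
    aa_pool = "ACDEFHIKLMNQRSTVWY"
    decoys: list[SeqRecord] = []
    for i in range(n):
        while True:
            aa_len = int(rng.integers(length_range[0], length_range[1] + 1))
            protein = "".join(
                aa_pool[int(j)] for j in rng.integers(0, len(aa_pool), aa_len)
            )
            cds = "ATG" + back_translate(protein, DEFAULT_CODON_BIAS, rng) + "TAA"
            utr5 = "".join("ACGT"[int(j)] for j in rng.integers(0, 4, 25))
            utr3 = "".join("ACGT"[int(j)] for j in rng.integers(0, 4, 25))
            transcript = utr5 + cds + utr3
            rec = SeqRecord(f"decoy_{i}", transcript, DNA)
            orfs = find_orfs(rec, min_aa=50)
            if all(pg_percent(o.peptide) < max_pg_pct for o in orfs):
                decoys.append(rec)
                break
    return decoys


_PHRED_HIGH = "I"  # Q40


def make_reads(
    records: Sequence[SeqRecord], spec: SynthSpec, rng: Optional[np.random.Generator] = None
) -> list[ReadPair]:
    """Paired reads at the requested coverage with substitution errors.

    Fragments start uniformly; R1 is the fragment's forward prefix and R2
    the reverse-complement prefix from the other end (FR orientation).
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    read_len = spec.read_len
    shortest = min(len(r.residues) for r in records)
    if read_len > shortest:
        raise ValueError(f"read_len {read_len} exceeds shortest record ({shortest} nt)")
    pairs: list[ReadPair] = []
    for rec in records:
        seq = rec.residues
        frag_len = min(len(seq), 2 * read_len + 20)
        n_pairs = max(1, math.ceil(spec.coverage * len(seq) / (2 * read_len)))
        starts = rng.integers(0, len(seq) - frag_len + 1, n_pairs)
        for idx, s in enumerate(starts):
            frag = seq[int(s) : int(s) + frag_len]
            r1 = _with_errors(frag[:read_len], spec.read_error_rate, rng)
            r2 = _with_errors(reverse_complement(frag)[:read_len], spec.read_error_rate, rng)
            rid = f"{rec.id}_rp{idx}"
            pairs.append(
                ReadPair(
                    SeqRecord(f"{rid}/1", r1, DNA),
                    _PHRED_HIGH * read_len,
                    SeqRecord(f"{rid}/2", r2, DNA),
                    _PHRED_HIGH * read_len,
                )
            )
    return pairs


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i, base in enumerate(out):
        if rng.random() < rate:
            out[i] = "ACGT"[int(rng.integers(4))] if base != "N" else "N"
    return "".join(out)


#: default planted repeat units (unit, copies); copy numbers are set so the
#: whole-ORF PG% of every planted gene clears the 20% screen, as the real
#: repeat arrays do
DEFAULT_UNIT_POOL: list[tuple[str, int]] = [
    ("GKAPAGGAAPGADA", 5),
    ("APADGK", 12),
    ("PTGDAGGAAPKGGAA", 5),
]


def make_cohort(
    spec: SynthSpec, n_agl: int = 3, units: Optional[Sequence[tuple[str, int]]] = None
) -> tuple[list[SynthGene], list[SeqRecord]]:
    """A cohort of planted genes plus decoys, all from one seed."""
    rng = np.random.default_rng(spec.seed)
    unit_pool = list(units) if units else DEFAULT_UNIT_POOL
    genes = []
    for i in range(n_agl):
        unit, copies = unit_pool[i % len(unit_pool)]
        sub = replace(spec, unit=unit, copies=copies)
        genes.append(make_agl_gene(sub, name=f"agl_{i}", rng=rng))
    decoys = make_decoys(spec.n_decoys, rng=rng)
    return genes, decoys


def truth_signal_annotations(genes: Sequence[SynthGene]) -> dict[str, RegionAnnotation]:
    """Ground-truth signal map keyed by every id a pipeline may use."""
    out: dict[str, RegionAnnotation] = {}
    for g in genes:
        ann = RegionAnnotation(
            er_signal=g.protein_regions.er_signal,
            gpi_omega=g.protein_regions.gpi_omega,
            provenance="imported",
        )
        for rid in (g.protein.id, g.transcript.id, g.gene.id):
            out[rid] = ann
    return out


def make_orthologue_gene(
    base: SynthGene,
    spec: SynthSpec,
    seed: int,
    signal_divergence: float = 0.03,
    intron_divergence: float = 0.18,
    mature_divergence: float = 0.40,
) -> SeqRecord:
    """A diverged orthologue of a synthetic gene.

    Substitutions are applied region by region at the given per-base rates,
    emulating the observed conservation ordering (signals > intron > mature
    coding sequence).
    """
    rng = np.random.default_rng(seed)
    gene = list(base.gene.residues)
    regions = base.gene_regions
    rates = {
        "er_signal": signal_divergence,
        "gpi_signal": signal_divergence,
        "intron": intron_divergence,
        "mature": mature_divergence,
    }
    intron_s, intron_e = regions["intron"]
    for label, rate in rates.items():
        s, e = regions[label]
        for i in range(s - 1, e):
            # the mature span crosses the intron's gene coordinates; the
            # intron has its own rate
            if label == "mature" and intron_s - 1 <= i < intron_e:
                continue
            if rng.random() < rate:
                gene[i] = "ACGT"[int(rng.integers(4))]
    return SeqRecord(base.gene.id + "_ortho", "".join(gene), DNA)
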