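"""End-to-end candidate discovery and five-class calling.

The orchestration mirrors how PG-rich secreted-protein surveys are run in
practice: transcripts (or supplied proteins) are scanned for ORFs, PG-poor
ORFs are dropped, signal regions are annotated (imported predictor calls
preferred, built-in heuristics as a configurable fallback), the mature
protein is profiled and searched for tandem repeats, and each candidate is
placed into one of five classes:

1. AGL: PGA > 40% (with an ER signal; bona fide AGLs are also <= 200 aa)
2. PGA in [15, 39.9]%
3. chimeric, with an "insignificant" match to the fasciclin-like PF10342
   domain (from an imported domain-hit table)
4. chimeric, other domain
5. neither ER nor GPI signal — not a secreted protein

Candidates with no ER signal are eliminated unless they are partial
sequences highly identical to an ER-bearing peer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from . import align as _align
from .orfs import OrfCandidate, find_orfs, pg_filter
from .profiling import (
    CompositionProfile,
    ProfileFlags,
    RegionAnnotation,
    composition,
    flag_profile,
    heuristic_er_signal,
    heuristic_gpi_signal,
    strip_signals,
)
from .repeats import RepeatProperties, TandemRepeatRegion, detect_repeats, repeat_properties
from .seqio import DNA, PROTEIN, SeqRecord, read_fasta


@dataclass
class Thresholds:
    pg_min: float = 20.0
    min_aa: int = 50
    pga_class1: float = 40.0
    pga_class2_low: float = 15.0
    max_len_agl: int = 200
    peer_identity: float = 90.0
    psim: float = 1.0


@dataclass
class PipelineConfig:
    """Inputs and knobs for one pipeline run."""

    input_fasta: Optional[Union[str, Path]] = None
    records: Optional[Sequence[SeqRecord]] = None
    signals: Optional[Mapping[str, RegionAnnotation]] = None
    domains: Optional[Mapping[str, str]] = None  # id -> {insignificant, other}
    thresholds: Thresholds = field(default_factory=Thresholds)
    use_heuristic_signals: bool = True
    detect_repeat_arrays: bool = True


@dataclass
class CandidateReport:
    """One row of the pipeline output."""

    id: str
    origin: str                       # orf_scan | supplied | baited_assembly
    peptide: str
    regions: RegionAnnotation
    mature: str
    profile_on_mature: bool
    profile: CompositionProfile
    flags: ProfileFlags
    repeats: list[tuple[TandemRepeatRegion, RepeatProperties]]
    class_label: Optional[int]
    is_agl: bool
    eliminated: bool
    reason: str = ""
    is_partial: bool = False


def classify_candidate(
    er_present: bool,
    gpi_present: bool,
    pga_pct: float,
    mature_len: int,
    domain_category: Optional[str] = None,
    thresholds: Optional[Thresholds] = None,
) -> tuple[Optional[int], bool]:
    """Pure five-class call from report fields.

    Returns (class_label, is_agl); the label is None for PGA below the
    class-2 floor (reported but outside classes 1-5).  PGA exactly at the
    class-1 cut goes to class 2: class 1 requires a strict PGA > 40%.
    """
    t = thresholds or Thresholds()
    if not er_present and not gpi_present:
        return 5, False
    if domain_category is not None:
        return (3 if domain_category == "insignificant" else 4), False
    if pga_pct > t.pga_class1:
        label = 1
    elif pga_pct >= t.pga_class2_low:
        label = 2
    else:
        label = None
    is_agl = label == 1 and er_present and mature_len <= t.max_len_agl
    return label, is_agl


def pairwise_identity(a: str, b: str, protein: bool = True) -> float:
    """Full-length global identity percent between two sequences."""
    params = _align.AlignParams(match=1.0, mismatch=0.0, gap_open=5.0, gap_extend=0.5,
                                name="identity") if protein else None
    aln = _align.global_align(a, b, params, check_alphabet=False)
    return aln.identity_pct


def elimination_rule(
    candidate_id: str,
    er_present: bool,
    is_partial: bool,
    peptide: str,
    peers: Sequence[tuple[str, bool, str]],
    identity_min: float = 90.0,
) -> tuple[bool, str]:
    """Keep-or-drop call for candidates without an ER signal.

    ``peers`` are (id, er_present, peptide) triples.  A no-ER candidate is
    retained only when it is a partial sequence highly identical (global
    identity >= ``identity_min``) to a peer that does carry an ER signal;
    otherwise it is eliminated as a non-secreted protein.
    """
    if er_present:
        return False, ""
    if is_partial:
        for pid, peer_er, peer_pep in peers:
            if pid == candidate_id or not peer_er:
                continue
            if pairwise_identity(peptide, peer_pep) >= identity_min:
                return False, f"partial; rescued by ER-bearing peer {pid}"
    return True, "no ER signal"


def import_blast_tab(path: Union[str, Path]) -> pd.DataFrame:
    """Parse standard 12-column tabular BLAST output for candidate seeding."""
    cols = [
        "query", "subject", "pident", "length", "mismatch", "gapopen",
        "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    rows = []
    with open(path, "rt") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, got {len(fields)}"
                )
            rows.append(fields)
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        for c in ("pident", "evalue", "bitscore"):
            df[c] = df[c].astype(float)
        for c in ("length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"):
            df[c] = df[c].astype(int)
    return df


def load_domain_table(path: Union[str, Path]) -> dict[str, str]:
    """TSV ``id, domain, category{insignificant, other}`` -> id -> category."""
    out: dict[str, str] = {}
    with open(path, "rt") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns")
            out[fields[0]] = fields[2]
    return out


def _annotate_signals(
    pep_id: str,
    peptide: str,
    signals: Optional[Mapping[str, RegionAnnotation]],
    use_heuristics: bool,
) -> RegionAnnotation:
    if signals is not None and pep_id in signals:
        return signals[pep_id]
    if not use_heuristics:
        return RegionAnnotation(provenance="imported")
    er = heuristic_er_signal(peptide) if len(peptide) >= 25 else None
    omega = heuristic_gpi_signal(peptide)
    if er is not None and omega is not None and er >= omega:
        omega = None  # inconsistent heuristic calls; trust the ER end
    return RegionAnnotation(
        er_signal=(1, er) if er else None,
        gpi_omega=omega,
        provenance="heuristic",
    )


def _candidates_from_records(
    records: Sequence[SeqRecord], t: Thresholds
) -> list[tuple[str, str, str, bool, str]]:
    """(id, peptide, origin, is_partial, strand) for DNA or protein input."""
    out = []
    for rec in records:
        if rec.alphabet == PROTEIN:
            out.append((rec.id, rec.residues, "supplied", False, "+"))
        else:
            orfs = pg_filter(find_orfs(rec, min_aa=t.min_aa), t.pg_min)
            for orf in orfs:
                out.append((orf.orf_id, orf.peptide, "orf_scan", orf.is_partial, orf.strand))
    return out


def run_pipeline(config: PipelineConfig) -> list[CandidateReport]:
    """Deterministic end-to-end run; see the module docstring for stages."""
    if config.records is None and config.input_fasta is None:
        raise ValueError("pipeline config names no input records or FASTA")
    records = list(config.records) if config.records is not None else read_fasta(config.input_fasta)
    t = config.thresholds
    candidates = _candidates_from_records(records, t)

    annotated = []
    for cid, pep, origin, partial, strand in candidates:
        base_id = cid.split("|")[0]
        regions = _annotate_signals(
            cid, pep, config.signals, config.use_heuristic_signals
        )
        # signal predictions keyed by the source record apply only to
        # forward-strand ORFs (predictors ran on the forward protein)
        if (
            config.signals is not None
            and cid not in config.signals
            and base_id in config.signals
            and strand == "+"
        ):
            regions = config.signals[base_id]
        annotated.append((cid, pep, origin, partial, regions))

    peers = [
        (cid, regions.er_signal is not None, pep)
        for cid, pep, origin, partial, regions in annotated
    ]

    reports: list[CandidateReport] = []
    for cid, pep, origin, partial, regions in annotated:
        er_present = regions.er_signal is not None
        gpi_present = regions.gpi_omega is not None
        try:
            mature = strip_signals(pep, regions)
            on_mature = er_present or gpi_present
        except ValueError:
            mature, on_mature = pep, False
        profile = composition(mature if on_mature else pep)
        flags = flag_profile(profile)
        reps: list[tuple[TandemRepeatRegion, RepeatProperties]] = []
        if config.detect_repeat_arrays:
            target = mature if on_mature else pep
            for region in detect_repeats(
                target, alphabet="protein", psim_min=t.psim, seq_id=cid
            ):
                reps.append((region, repeat_properties(region)))
        domain_cat = config.domains.get(cid) if config.domains else None
        label, is_agl = classify_candidate(
            er_present, gpi_present, profile.pga_pct, profile.length, domain_cat, t
        )
        eliminated, reason = elimination_rule(
            cid, er_present, partial, pep, peers, t.peer_identity
        )
        if eliminated:
            is_agl = False
        reports.append(
            CandidateReport(
                id=cid,
                origin=origin,
                peptide=pep,
                regions=regions,
                mature=mature,
                profile_on_mature=on_mature,
                profile=profile,
                flags=flags,
                repeats=reps,
                class_label=label,
                is_agl=is_agl,
                eliminated=eliminated,
                reason=reason,
                is_partial=partial,
            )
        )
    return reports


def reports_to_frame(reports: Sequence[CandidateReport]) -> pd.DataFrame:
    """Flatten reports to one row per candidate."""
    rows = []
    for r in reports:
        rows.append(
            {
                "id": r.id,
                "origin": r.origin,
                "length": r.profile.length,
                "mature_profile": r.profile_on_mature,
                "er_signal_end": r.regions.er_signal[1] if r.regions.er_signal else None,
                "gpi_omega": r.regions.gpi_omega,
                "signal_provenance": r.regions.provenance,
                "mw": round(r.profile.mw, 2),
                "pI": round(r.profile.pi, 1),
                "pga_pct": round(r.profile.pga_pct, 1),
                "pg_pct": round(r.profile.pg_pct, 1),
                "de_pct": round(r.profile.de_pct, 1),
                "kr_pct": round(r.profile.kr_pct, 1),
                "nterm_q": r.profile.nterm_q,
                "pi_class": r.flags.pi_class,
                "high_single_aa": ",".join(sorted(r.flags.high_single_aa)),
                "n_repeats": len(r.repeats),
                "repeat_units": ";".join(reg.consensus for reg, _ in r.repeats),
                "class_label": r.class_label,
                "is_agl": r.is_agl,
                "eliminated": r.eliminated,
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)


def write_reports(reports: Sequence[CandidateReport], tsv_path: Union[str, Path],
                  json_path: Optional[Union[str, Path]] = None) -> None:
    frame = reports_to_frame(reports)
    frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "wt") as out:
            json.dump(frame.to_dict(orient="records"), out, indent=1, default=str)
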