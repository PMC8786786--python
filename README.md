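# aglscan

Tools for discovering and characterising **AGLs** — small, secreted,
proline/glycine-rich, GPI-anchored intrinsically disordered proteins (IDPs)
of arbuscular mycorrhizal fungi — from transcript assemblies, protein
sequences and raw short reads.

These proteins are hard to mine with standard annotation pipelines: their
mature sequences are low-complexity tandem-repeat arrays that evolve by
local DNA duplication and assemble poorly from short reads, while only the
N-terminal ER signal peptide and the C-terminal GPI-anchor signal are well
conserved between species. `aglscan` packages the targeted workflow that
works for this protein family:

- **Six-frame ORF scanning** with a PG-content screen (retain ORFs with
  PG% > 20, allowing a missing initiator Met).
- **Composition profiling** of the mature protein (after removing the ER
  signal and the GPI propeptide downstream of the ω residue): residue
  percentages, PGA% / DE% / KR% aggregates, molecular weight, isoelectric
  point (Henderson–Hasselbalch model, Bjellqvist pKa set, bisection), and
  the reporting flags (single residues ≥ 15%, PGA ≥ 40%, DE or KR ≥ 8%,
  acidic/neutral/basic pI class, N-terminal Q).
- **Tandem repeat detection** scored with Psim — the mean identity of the
  repeat units to their column-majority consensus — at the working
  thresholds Psim = 1.0 for proteins and 0.7 for the coding DNA; repeat
  units are placed in the (G%, P%) plane and classified as **elastic**,
  **intermediate** (interchangeable) or **amyloid**, and flagged
  zwitterionic when they carry both acidic (D/E) and basic (K/R) residues.
- **Codon-usage tables** restricted to the repeat-coding interval of a CDS,
  exposing the restricted codon usage characteristic of repeats born by
  tandem DNA duplication.
- **k-mer read baiting** (canonical 31-mers, n ≥ 1 matches) to pull the
  reads belonging to a candidate locus out of a raw read set for targeted
  reassembly.
- **Region-partitioned global alignment** (Needleman–Wunsch, affine gaps,
  free end gaps, +5/−4/10/0.5): per-region identity for signal / intron /
  mature partitions and detection of frameshift-generating gaps (coding
  gaps whose length is not a multiple of 3).
- A **five-class candidate classifier**: 1 = AGL (PGA > 40%), 2 = PGA
  15–39.9%, 3 = chimeric with an insignificant PF10342 match, 4 = chimeric
  other, 5 = no ER or GPI signal (not secreted, eliminated unless a partial
  sequence is ≥ 90% identical to an ER-bearing peer).
- A **synthetic-data generator** producing genes with the family's
  architecture (ER-signal exon, one GT..AG intron immediately after it,
  repeat-array mature region back-translated under a restricted codon
  model, GPI tail), plus decoy transcripts and paired reads, all with exact
  truth annotations.

## Worked example

```python
from aglscan import composition, detect_repeats
from aglscan.repeats import repeat_properties

prof = composition("APADGK")          # the RiAGL1-style hexamer repeat unit
print(round(prof.pct["P"], 1), round(prof.pct["G"], 1))
# 16.7 16.7      -> one P and one G in six residues

regs = detect_repeats("GKAPAGGAAPGADA" * 5, psim_min=1.0)
r = regs[0]
print(r.unit_length, r.copies, r.psim)
# 14 5 1.0       -> five perfect copies of the 14-residue unit

props = repeat_properties(r)
print(round(props.p_pct, 1), round(props.g_pct, 1), props.zwitterionic, props.zone)
# 14.3 28.6 True elastic
```

The same from the shell, end to end on a simulated cohort:

```sh
aglscan simulate --seed 3 -o sim          # 3 planted AGL genes + 7 decoys
echo '{"input": "sim/transcripts.fasta", "out_prefix": "cand"}' > run.json
aglscan classify --config run.json
# 6 candidates, 3 called AGL
```

`cand.tsv` then holds one row per candidate with its composition, signal
annotation (imported or heuristic), repeats and class label; the three rows
with `is_agl = True` are exactly the three planted genes, each with its
planted repeat unit recovered (e.g. unit length 14, 5 copies, Psim 1.0).

Other subcommands: `aglscan orfscan`, `profile`, `repeats`, `codon-usage`,
`bait`, `region-id` — see `aglscan --help`.

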