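import itertools
import random

import pytest

from aglscan.align import (
    AlignParams,
    GlobalAlignment,
    frameshift_gaps,
    genomic_span,
    global_align,
    region_identity,
)

MATCH, MISMATCH, GAP_OPEN, GAP_EXT = 5.0, -4.0, 10.0, 0.5


def gotoh_free_end_score(a: str, b: str) -> float:
    """Independent affine-gap DP with free end gaps (overlap alignment)."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0
    for j in range(1, m + 1):
        Y[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - GAP_OPEN, X[i - 1][j] - GAP_EXT,
                          Y[i - 1][j] - GAP_OPEN)
            Y[i][j] = max(M[i][j - 1] - GAP_OPEN, Y[i][j - 1] - GAP_EXT,
                          X[i][j - 1] - GAP_OPEN)
    best = NEG
    for i in range(n + 1):
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


def exhaustive_best_score(a: str, b: str) -> float:
    """Enumerate every alignment of two short sequences and score it."""

    def alignments(i, j):
        if i == len(a) and j == len(b):
            yield "", ""
            return
        if i < len(a) and j < len(b):
            for ga, gb in alignments(i + 1, j + 1):
                yield a[i] + ga, b[j] + gb
        if i < len(a):
            for ga, gb in alignments(i + 1, j):
                yield a[i] + ga, "-" + gb
        if j < len(b):
            for ga, gb in alignments(i, j + 1):
                yield "-" + ga, b[j] + gb

    def score(ga, gb):
        total, col = 0.0, len(ga)
        runs = []  # (row, start, length) of gap runs
        for row, text in ((0, ga), (1, gb)):
            i = 0
            while i < col:
                if text[i] == "-":
                    j = i
                    while j < col and text[j] == "-":
                        j += 1
                    runs.append((row, i, j - i))
                    i = j
                else:
                    i += 1
        for i in range(col):
            if ga[i] != "-" and gb[i] != "-":
                total += MATCH if ga[i] == gb[i] else MISMATCH
        for _, start, length in runs:
            if start == 0 or start + length == col:  # end gaps free
                continue
            total -= GAP_OPEN + GAP_EXT * (length - 1)
        return total

    return max(score(ga, gb) for ga, gb in alignments(0, 0))


class TestGlobalAlign:
    def test_identical_short(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.score == 20.0
        assert aln.identity_pct == 100.0
        assert "-" not in aln.gapped_a + aln.gapped_b

    def test_self_alignment_gap_free(self):
        rng = random.Random(1)
        for _ in range(10):
            s = "".join(rng.choice("ACGT") for _ in range(rng.randint(5, 60)))
            aln = global_align(s, s)
            assert aln.gapped_a == aln.gapped_b == s

    def test_score_symmetry(self):
        rng = random.Random(2)
        for _ in range(20):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 30)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 30)))
            assert global_align(a, b).score == global_align(b, a).score

    def test_gap_removal_recovers_inputs(self):
        aln = global_align("ACGTACGTAC", "ACGTCGTAC")
        assert aln.gapped_a.replace("-", "") == "ACGTACGTAC"
        assert aln.gapped_b.replace("-", "") == "ACGTCGTAC"
        assert not any(
            ca == cb == "-" for ca, cb in zip(aln.gapped_a, aln.gapped_b)
        )

    def test_mixed_alphabets_rejected(self):
        with pytest.raises(ValueError):
            global_align("ACGT", "MKPW")

    def test_score_matches_dp_oracle_up_to_12nt(self):
        rng = random.Random(13)
        for _ in range(150):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 12)))
            assert global_align(a, b).score == pytest.approx(gotoh_free_end_score(a, b))

    def test_dp_oracle_matches_exhaustive_enumeration(self):
        rng = random.Random(17)
        for _ in range(15):
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            b = "".join(rng.choice("ACGT") for _ in range(rng.randint(1, 6)))
            assert gotoh_free_end_score(a, b) == pytest.approx(exhaustive_best_score(a, b))


def _manual_alignment(ga: str, gb: str) -> GlobalAlignment:
    return GlobalAlignment(ga, gb, 0.0, AlignParams())


class TestRegionIdentity:
    def test_identical_sequences_all_regions_100(self):
        seq = "ACGT" * 10
        aln = global_align(seq, seq)
        report = region_identity(aln, {"left": (1, 20), "right": (21, 40)})
        assert report.identity == {"left": 100.0, "right": 100.0, "full": 100.0}

    def test_region_opposite_gaps_scores_zero(self):
        aln = _manual_alignment("AAAACCCC", "AAAA----")
        report = region_identity(aln, {"head": (1, 4), "tail": (5, 8)})
        assert report.identity["head"] == 100.0
        assert report.identity["tail"] == 0.0

    def test_gap_columns_inherit_enclosing_region(self):
        # b has an insertion inside the "head" region of a
        aln = _manual_alignment("AA--CC", "AAGGCC")
        report = region_identity(aln, {"head": (1, 2), "tail": (3, 4)})
        assert report.columns["head"] == 4  # 2 residues + 2 inherited gap cols
        assert report.identity["head"] == 50.0

    def test_identical_columns_recombine(self):
        rng = random.Random(5)
        a = "".join(rng.choice("ACGT") for _ in range(120))
        b = "".join(rng.choice("ACGT") for _ in range(110))
        aln = global_align(a, b)
        regions = {"r1": (1, 40), "r2": (41, 80), "r3": (81, 120)}
        report = region_identity(aln, regions)
        assert sum(report.identical[r] for r in regions) == report.identical["full"]

    def test_region_outside_sequence_rejected(self):
        aln = global_align("ACGT", "ACGT")
        with pytest.raises(ValueError):
            region_identity(aln, {"bad": (1, 99)})

    def test_synthetic_orthologues_signal_above_mature(self):
        from aglscan.synth import SynthSpec, make_agl_gene, make_orthologue_gene

        spec = SynthSpec(seed=29)
        base = make_agl_gene(spec)
        ortho = make_orthologue_gene(base, spec, seed=31)
        aln = global_align(base.gene.residues, ortho.residues)
        report = region_identity(aln, base.gene_regions)
        er = report.identity["er_signal"]
        gpi = report.identity["gpi_signal"]
        intron = report.identity["intron"]
        mature = report.identity["mature"]
        assert min(er, gpi) > intron > mature


class TestFrameshiftGaps:
    def test_two_nt_gap_flagged(self):
        aln = _manual_alignment("ACGTACGTT", "ACG--CGTT")
        assert frameshift_gaps(aln, [(1, 9)]) == [(4, 2)]

    def test_codon_sized_gap_ignored(self):
        aln = _manual_alignment("ACGTTTACG", "ACG---ACG")
        assert frameshift_gaps(aln, [(1, 9)]) == []

    def test_four_nt_gap_flagged(self):
        aln = _manual_alignment("ACGTTTTACG", "ACG----ACG")
        assert frameshift_gaps(aln, [(1, 10)]) == [(4, 4)]

    def test_gap_outside_coding_region_ignored(self):
        aln = _manual_alignment("ACGTACGTT", "ACG--CGTT")
        assert frameshift_gaps(aln, [(7, 9)]) == []

    def test_insertion_in_a_reported(self):
        aln = _manual_alignment("ACG--CGTT", "ACGTACGTT")
        gaps = frameshift_gaps(aln, [(1, 7)])
        assert gaps == [(3, 2)]


class TestGenomicSpan:
    @pytest.mark.parametrize(
        "start,end,length,kb",
        [
            (527748, 538492, 10745, "10.7 kb"),
            (30068, 46636, 16569, "16.6 kb"),
            (5, 5, 1, "0.0 kb"),
        ],
    )
    def test_examples(self, start, end, length, kb):
        assert genomic_span(start, end) == (length, kb)

    def test_inverted_rejected(self):
        with pytest.raises(ValueError):
            genomic_span(10, 9)
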