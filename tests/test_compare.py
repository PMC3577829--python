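import itertools

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from paleomito.compare import (
    DivergenceRow,
    composition,
    global_align,
    multi_compare,
    region_divergence,
    rotate_to_start,
    transfer_annotation,
    translate_codon,
)
from paleomito.io import Region, SequenceRecord, revcomp
from paleomito.simulate import simulate_genome

dna = st.text(alphabet="ACGT", min_size=1, max_size=10)


def oracle_global_score(a, b, match=1, mismatch=-2, gap=-3):
    """Full-matrix Needleman-Wunsch written independently of the package."""
    n, m = len(a), len(b)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        D[i][0] = i * gap
    for j in range(1, m + 1):
        D[0][j] = j * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            D[i][j] = max(D[i - 1][j - 1] + s, D[i - 1][j] + gap, D[i][j - 1] + gap)
    return D[n][m]


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert aln.aligned_a == aln.aligned_b and aln.score == 8

    def test_single_deletion(self):
        aln = global_align("ACGTACGT", "ACGACGT")
        assert aln.n_columns == 8
        assert (aln.aligned_a + aln.aligned_b).count("-") == 1

    @given(dna, dna)
    @settings(max_examples=300, deadline=None)
    def test_score_equals_exhaustive_oracle(self, a, b):
        assert global_align(a, b).score == oracle_global_score(a, b)

    @given(dna, dna)
    @settings(max_examples=100, deadline=None)
    def test_alignment_rows_rebuild_inputs(self, a, b):
        aln = global_align(a, b)
        assert aln.aligned_a.replace("-", "") == a
        assert aln.aligned_b.replace("-", "") == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "ACGT")


class TestNonsynonymousClassification:
    def test_known_nonsynonymous(self):
        aln = global_align("ATGGCCTAA", "ATGACCTAA")
        (row,) = region_divergence(aln, [Region("cds", 0, 9, "+", "CDS")])
        assert (row.segregating_sites, row.nonsynonymous) == (1, 1)

    def test_known_synonymous(self):
        aln = global_align("ATGGCCTAA", "ATGGCTTAA")
        (row,) = region_divergence(aln, [Region("cds", 0, 9, "+", "CDS")])
        assert (row.segregating_sites, row.nonsynonymous) == (1, 0)

    def test_all_576_single_base_substitutions(self):
        """Exhaustive check against direct translation of both codons."""
        for codon in map("".join, itertools.product("ACGT", repeat=3)):
            for pos in range(3):
                for alt in "ACGT":
                    if alt == codon[pos]:
                        continue
                    mutated = codon[:pos] + alt + codon[pos + 1 :]
                    # oracle: translate full codons under the vertebrate
                    # mitochondrial code via an independent Biopython route
                    aa1 = str(Seq(codon).translate(table=2))
                    aa2 = str(Seq(mutated).translate(table=2))
                    expected_nonsyn = int(aa1 != aa2)
                    seq_a = "ATG" + codon + "TAA"
                    seq_b = "ATG" + mutated + "TAA"
                    aln = global_align(seq_a, seq_b)
                    (row,) = region_divergence(aln, [Region("cds", 0, 9, "+", "CDS")])
                    assert row.segregating_sites == 1
                    assert row.nonsynonymous == expected_nonsyn, (codon, pos, alt)

    def test_minus_strand_cds(self):
        # GCC (Ala) -> ACC (Thr) encoded on the minus strand
        plus_a = revcomp("ATGGCCTAA")
        plus_b = revcomp("ATGACCTAA")
        aln = global_align(plus_a, plus_b)
        (row,) = region_divergence(aln, [Region("cds", 0, 9, "-", "CDS")])
        assert (row.segregating_sites, row.nonsynonymous) == (1, 1)

    def test_frame_disrupted_cds_not_computable(self):
        aln = global_align("ATGGCCTA", "ATGACCTA")  # 8 bp: not a codon multiple
        (row,) = region_divergence(aln, [Region("cds", 0, 8, "+", "CDS")])
        assert row.nonsynonymous is None and "frame_disrupted" in row.flags


class TestRegionDivergence:
    def test_identical_regions_all_zero(self):
        s = simulate_genome(300, 71).bases
        aln = global_align(s, s)
        rows = region_divergence(aln, [Region("r1", 0, 150), Region("r2", 150, 300)])
        for row in rows:
            assert (row.segregating_sites, row.gaps, row.ambiguous) == (0, 0, 0)

    def test_n_columns_counted_ambiguous_not_segregating(self):
        a = "ACGTACGTAC"
        b = "ACGTNCGTAC"
        aln = global_align(a, b)
        (row,) = region_divergence(aln, [Region("r", 0, 10)])
        assert (row.segregating_sites, row.ambiguous) == (0, 1)

    def test_region_totals_tile_whole_alignment(self):
        import numpy as np

        rng = np.random.default_rng(72)
        a = simulate_genome(600, 73).bases
        b = list(a)
        for pos in rng.choice(600, size=12, replace=False):
            b[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[pos]]
        aln = global_align(a, "".join(b))
        halves = region_divergence(aln, [Region("h1", 0, 300), Region("h2", 300, 600)])
        whole = region_divergence(aln, [Region("all", 0, 600)])
        assert sum(r.segregating_sites for r in halves) == whole[0].segregating_sites == 12
        assert sum(r.alignment_length for r in halves) == whole[0].alignment_length

    def test_symmetry_of_counts(self):
        a = "ACGTACGTACGT"
        b = "ACCTACGTAGGT"
        r_ab = region_divergence(global_align(a, b), [Region("r", 0, 12)])[0]
        r_ba = region_divergence(global_align(b, a), [Region("r", 0, 12)])[0]
        assert r_ab.segregating_sites == r_ba.segregating_sites
        assert r_ab.gaps == r_ba.gaps


class TestTransferAnnotation:
    def test_identity_alignment_is_identity(self):
        s = simulate_genome(500, 74).bases
        aln = global_align(s, s)
        regions = [Region("g1", 10, 100, "+", "CDS"), Region("g2", 200, 260, "-", "tRNA")]
        out = transfer_annotation(regions, aln)
        assert [(r.start, r.end) for r in out] == [(10, 100), (200, 260)]

    def test_insertion_shifts_downstream_gene(self):
        s = simulate_genome(500, 75).bases
        target = s[:50] + "ACGTACGTAC" + s[50:]  # 10 bp insertion at 50
        aln = global_align(s, target)
        out = transfer_annotation([Region("g", 100, 160, "+", "CDS")], aln)
        assert (out[0].start, out[0].end) == (110, 170)

    def test_deletion_inside_cds_flags_frame(self):
        s = simulate_genome(400, 76).bases
        target = s[:120] + s[123:]  # 3 bp deletion inside the gene
        aln = global_align(s, target)
        out = transfer_annotation([Region("g", 99, 189, "+", "CDS")], aln)
        assert out[0].end - out[0].start == 87
        assert "frame_disrupted" not in out[0].flags  # 87 is a codon multiple
        target2 = s[:120] + s[122:]  # 2 bp deletion: frame broken
        aln2 = global_align(s, target2)
        out2 = transfer_annotation([Region("g", 99, 189, "+", "CDS")], aln2)
        assert "frame_disrupted" in out2[0].flags

    def test_deleted_region_flagged_missing(self):
        from paleomito.compare import PairwiseAlignment

        s = simulate_genome(300, 77).bases
        aln = PairwiseAlignment(s, s[:100] + "-" * 60 + s[160:], 0)
        out = transfer_annotation([Region("g", 110, 150, "+", "tRNA")], aln)
        assert "missing" in out[0].flags


@pytest.fixture(scope="module")
def reference():
    ref = simulate_genome(3000, 78, circular=True)
    ann = [Region("tRNA-Phe", 0, 70, "+", "tRNA")]
    return ref, ann


class TestRotateToStart:
    def test_already_anchored_identity(self, reference):
        ref, ann = reference
        out = rotate_to_start(SequenceRecord("x", ref.bases), ref, ann)
        assert out.bases == ref.bases

    def test_recovers_known_rotation(self, reference):
        ref, ann = reference
        rotated_in = SequenceRecord("x", ref.bases[1000:] + ref.bases[:1000])
        out = rotate_to_start(rotated_in, ref, ann)
        assert out.bases == ref.bases

    def test_reverse_complement_input_reoriented(self, reference):
        ref, ann = reference
        rc_in = SequenceRecord("x", revcomp(ref.bases[500:] + ref.bases[:500]))
        out = rotate_to_start(rc_in, ref, ann)
        assert out.bases == ref.bases

    def test_unalignable_anchor_rejected(self, reference):
        ref, ann = reference
        foreign = simulate_genome(3000, 79, circular=True)
        with pytest.raises(ValueError):
            rotate_to_start(foreign, ref, ann)


class TestComposition:
    def test_uniform(self):
        fracs, n = composition("ACGT")
        assert all(v == 0.25 for v in fracs.values()) and n == 0

    def test_n_excluded_from_denominator(self):
        fracs, n = composition("AAAN")
        assert fracs["A"] == 1.0 and n == 1

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            composition("NNNN")


class TestMultiCompare:
    def test_identical_genomes_no_segregating_sites(self):
        g = simulate_genome(900, 80)
        genomes = [SequenceRecord(f"g{i}", g.bases) for i in range(3)]
        res = multi_compare(genomes, [Region("r", 0, 900)])
        assert res.segregating_sites == 0

    def test_planted_substitutions_outside_excluded_regions(self):
        base = simulate_genome(1200, 81).bases
        # region layout: keep [0,800), exclude "CR" [800,1200)
        ann = [Region("genes", 0, 800), Region("CR", 800, 1200)]
        inside = [100, 300, 500, 650, 770]
        outside = [850, 1000, 1100]
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        b = list(base)
        for p in inside + outside:
            b[p] = flip[b[p]]
        genomes = [
            SequenceRecord("anchor", base),
            SequenceRecord("variant", "".join(b)),
            SequenceRecord("same", base),
        ]
        res = multi_compare(genomes, ann, exclude_regions=("CR",))
        assert res.segregating_sites == 5
        assert sorted(res.segregating_positions) == inside

    def test_pairwise_rows_in_table_cell_format(self):
        base = simulate_genome(600, 82).bases
        b = base[:50] + ("A" if base[50] != "A" else "C") + base[51:]
        res = multi_compare(
            [SequenceRecord("a", base), SequenceRecord("b", b)],
            [Region("r", 0, 600)],
        )
        (rows,) = res.pairwise.values()
        assert rows[0].cell().count("/") == 3
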