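import numpy as np
import pytest

from paleomito.assembler import (
    AssemblyParams,
    Contig,
    assemble,
    build_graph,
    canonical,
    extract_contigs,
    polish,
    _canonical_rotation,
    _least_rotation,
)
from paleomito.io import ReadPair, SequenceRecord, revcomp
from paleomito.simulate import SimConfig, SourceGenome, simulate_genome, simulate_reads


def identity_to(consensus: str, truth: str, circular: bool) -> float:
    """Fraction of matching positions after canonical rotation/orientation."""
    a = _canonical_rotation(consensus, circular)
    b = _canonical_rotation(truth, circular)
    if len(a) != len(b):
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


class TestBuildGraph:
    def test_single_read_of_length_k(self):
        params = AssemblyParams(kmer_size=31, min_contig_length=31, min_kmer_count=1)
        g = build_graph([SequenceRecord("r", "A" * 15 + "C" * 16)], params)
        assert len(g.counts) == 1 and next(iter(g.counts.values())) == 1
        # at the default cutoff of 2, the same singleton k-mer is dropped
        params2 = AssemblyParams(kmer_size=31, min_contig_length=31, min_kmer_count=2)
        g2 = build_graph([SequenceRecord("r", "A" * 15 + "C" * 16)], params2)
        assert len(g2.counts) == 0

    def test_read_and_revcomp_give_same_canonical_multiset(self):
        seq = simulate_genome(200, 3).bases
        params = AssemblyParams(min_kmer_count=1)
        g1 = build_graph([SequenceRecord("f", seq)], params)
        g2 = build_graph([SequenceRecord("r", revcomp(seq))], params)
        assert g1.counts == g2.counts

    def test_n_kmers_skipped(self):
        seq = "A" * 20 + "N" + "C" * 20
        g = build_graph([SequenceRecord("r", seq)], AssemblyParams(kmer_size=15, min_contig_length=15, min_kmer_count=1))
        assert all("N" not in k for k in g.counts)
        # each 20 bp homopolymer flank yields one distinct 15-mer, 6 times
        assert sorted(g.counts.values()) == [6, 6]

    def test_no_long_read_rejected(self):
        with pytest.raises(ValueError):
            build_graph([SequenceRecord("r", "ACGT")], AssemblyParams())


class TestExtractContigs:
    def test_empty_graph_gives_no_contigs(self):
        from paleomito.assembler import KmerGraph

        assert extract_contigs(KmerGraph({}, 31), AssemblyParams()) == []

    def test_short_path_discarded_by_length_filter(self):
        seq = simulate_genome(250, 5).bases
        params = AssemblyParams(min_kmer_count=1)
        g = build_graph([SequenceRecord("r", seq)], params)
        assert extract_contigs(g, params) == []
        params300 = AssemblyParams(min_kmer_count=1, min_contig_length=200)
        g = build_graph([SequenceRecord("r", seq)], params300)
        contigs = extract_contigs(g, params300)
        assert len(contigs) == 1 and len(contigs[0]) == 250

    def test_circular_genome_yields_one_circular_contig(self, small_circular_genome, clean_circular_reads):
        reads, _ = clean_circular_reads
        g = build_graph(reads, AssemblyParams())
        contigs = extract_contigs(g, AssemblyParams())
        assert len(contigs) == 1
        assert contigs[0].circular_hint
        assert len(contigs[0]) >= 0.99 * len(small_circular_genome)

    def test_contig_count_non_increasing_in_min_length(self, clean_circular_reads):
        reads, _ = clean_circular_reads
        counts = []
        for min_len in (300, 1000, 6000):
            params = AssemblyParams(min_contig_length=min_len)
            g = build_graph(reads, params)
            counts.append(len(extract_contigs(g, params)))
        assert counts == sorted(counts, reverse=True)


class TestLeastRotation:
    def test_known_rotation(self):
        assert _least_rotation("CAB") == 1  # "ABC"

    def test_rotation_invariance(self):
        s = simulate_genome(300, 8).bases
        rot = s[117:] + s[:117]
        assert _canonical_rotation(s, True) == _canonical_rotation(rot, True)
        assert _canonical_rotation(s, True) == _canonical_rotation(revcomp(s), True)


class TestPolish:
    def test_error_free_reads_leave_consensus_intact(self, small_circular_genome, clean_circular_reads):
        reads, _ = clean_circular_reads
        params = AssemblyParams()
        g = build_graph(reads, params)
        contigs = polish(extract_contigs(g, params), reads, params)
        assert identity_to(contigs[0].consensus, small_circular_genome.bases, True) == 1.0
        major = contigs[0].pileup.max(axis=1) / contigs[0].pileup.sum(axis=1)
        assert (major == 1.0).all()

    def test_plurality_and_depth_rules(self):
        # direct pileup-to-consensus arithmetic on a handcrafted contig
        contig = Contig("c", "ACGT" * 20)
        reads = [SequenceRecord("r%d" % i, contig.consensus) for i in range(3)]
        polished = polish([contig], reads, AssemblyParams(min_contig_length=31))
        col = polished[0].pileup[0]
        assert col.sum() == 3 and polished[0].consensus == contig.consensus

    def test_depth_below_two_gives_n(self):
        contig = Contig("c", "ACGT" * 20)
        reads = [SequenceRecord("r", contig.consensus[:40])]
        polished = polish([contig], reads, AssemblyParams(min_contig_length=31))
        # covered once -> N; uncovered -> N
        assert set(polished[0].consensus) == {"N"}


class TestAssembleEndToEnd:
    def test_paired_and_single_modes_recover_circular_genome(self, small_circular_genome, clean_circular_reads):
        reads, _ = clean_circular_reads
        pe = assemble(reads, AssemblyParams(), paired=True)
        assert len(pe) == 1 and pe[0].circular_hint
        assert identity_to(pe[0].consensus, small_circular_genome.bases, True) == 1.0

        flat = [m for p in reads for m in (p.mate1, p.mate2)]
        se = assemble(flat, AssemblyParams(), paired=False)
        assert len(se) == 1
        assert identity_to(se[0].consensus, small_circular_genome.bases, True) == 1.0

    def test_two_unlinked_sources_no_chimeras(self):
        g1 = simulate_genome(3000, 31)
        g2 = simulate_genome(3000, 32)
        cfg = SimConfig(
            seed=33, paired=False, seq_error=0.0, n_fragments=2000,
            sources=[SourceGenome(g1), SourceGenome(g2)],
        )
        reads, _ = simulate_reads(cfg)
        contigs = assemble(reads, AssemblyParams(), paired=False)
        assert len(contigs) == 2

        def matches(contig: str, genome: str) -> bool:
            # N-tolerant containment (linear-contig ends are N-masked where
            # coverage tapers below the depth-2 calling rule)
            from paleomito.compare import global_align

            for seq in (contig, revcomp(contig)):
                aln = global_align(seq, genome)
                pairs = [
                    (a, b)
                    for a, b in zip(aln.aligned_a, aln.aligned_b)
                    if a not in "-N" and b != "-"
                ]
                if pairs and sum(a == b for a, b in pairs) / len(pairs) >= 0.999:
                    return True
            return False

        for c in contigs:
            # each contig belongs entirely to exactly one source: no chimeras
            assert matches(c.consensus, g1.bases) != matches(c.consensus, g2.bases)

    def test_noisy_reads_still_give_exact_consensus(self, small_circular_genome):
        cfg = SimConfig(
            seed=34, paired=True, seq_error=0.004,
            n_fragments=int(5000 * 100 / 180),
            sources=[SourceGenome(small_circular_genome, circular=True)],
        )
        reads, _ = simulate_reads(cfg)
        contigs = assemble(reads, AssemblyParams(), paired=True)
        assert len(contigs) == 1
        assert identity_to(contigs[0].consensus, small_circular_genome.bases, True) >= 0.999

    def test_zero_reads_error(self):
        with pytest.raises(ValueError):
            assemble([], AssemblyParams())

    def test_pileup_totals_bounded_by_read_bases(self, clean_circular_reads):
        reads, _ = clean_circular_reads
        contigs = assemble(reads, AssemblyParams(), paired=True)
        total_pileup = int(contigs[0].pileup.sum())
        total_read_bases = sum(len(p.mate1) + len(p.mate2) for p in reads)
        assert total_pileup <= total_read_bases
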