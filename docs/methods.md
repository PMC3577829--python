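# Methods

`paleomito` recovers a mitochondrial genome from shotgun ancient-DNA
(aDNA) short reads without a reference assembly, and quantifies the
noise processes that make aDNA difficult: PCR duplication, exogenous
contamination, sequencing error, and postmortem cytosine deamination.
This note records the models, the parameters that matter, and the
numerical conventions, in the package's own words.

## The problem and the overall model

A degraded museum specimen yields short DNA fragments (hundreds of bp).
A shotgun library sequences everything in the extract: endogenous
nuclear DNA at low expected depth (total yield / genome size, typically
a few x), endogenous mitochondrial DNA at depth amplified by the
mitochondrion's per-cell copy number, and contaminant DNA (human
handling, fungal and bacterial colonization of the specimen).  The
pipeline exploits the copy-number asymmetry: after de novo assembly,
the mitogenome is the long contig whose average coverage is tens of
times the modal contig coverage.  Because the mitogenome is haploid,
every read-vs-consensus mismatch is then attributable to sequencing
error, library PCR error, or deamination damage — there is no true
heterozygosity to confound the error estimate.

## Read simulator

The generator draws fragments from a weighted mixture of source
genomes; a source's fragment probability is proportional to
weight x length, so `weight` is a molar copy-number ratio.  Defaults
reproduce HiSeq-era shotgun sequencing of degraded material:

| parameter | default | meaning |
|---|---|---|
| `read_length` | 90 bp | sequenced bases per read (single or paired) |
| `fragment_mean`, `fragment_sd` | 200, 25 bp | fragment size; normal truncated to mean ± 50 and >= 30 bp |
| `seq_error` | 0.004 | per-base substitution probability (uniform alternative base) |
| `damage_ct` | 0 | per-C deamination probability on the fragment template strand |
| `duplicate_rate` | 0 | probability a fragment's reads are emitted twice |
| `base_quality` | Q30 | constant quality; `low_q_fraction` mixes in Q10 calls for %Q20 exercises |

Order of operations mirrors a real library: deamination first (on the
template strand, so it appears as G->A whenever the sequencer reports
the opposite strand), then sequencing error, then duplication.
Duplicates clone the *post-error* read bases verbatim because a PCR
duplicate re-sequences the same library molecule — this is exactly the
signal an exact-sequence duplicate remover can detect.  `damage_ct`
defaults to 0 so each noise process is opted into explicitly; an
end-weighted damage mode (geometric decay from fragment ends, 10 bp
scale) exists but is off by default because the uniform model is the
simplest adequate one for rate-recovery testing.  `duplicate_rate` has
no natural default (observed duplicate fractions vary several-fold
between specimens), so it too defaults to 0.

The simulator does **not** model indel sequencing errors,
quality-dependent error rates, GC bias, fragmentation bias, or
reference-genome repeat structure (simulated genomes are uniform
random, hence essentially repeat-free at k = 31).  Passing tests on
simulated data therefore demonstrate correctness of the algorithms
under the stated noise model, not robustness to repeat-rich real
genomes; homopolymer/repeat artifacts (the cause of N stretches in real
assemblies) are out of the simulator's reach.

Every emitted read carries a truth record (source, 0-based start,
strand, injected error and damage counts, duplicate flag), which is
what downstream tests check against.

## Duplicate removal and %Q20

Duplicate identity is exact base-string equality; for pairs, both
mates must match an earlier pair mate-for-mate.  No quality information
and no reverse-complement matching by default (an RC-aware single-end
mode exists behind a flag).  %Q20 is computed per base call — the share
of calls with Phred >= 20 — not per read; the per-read reading of
"reads passing Q20" is ambiguous and the per-base definition is the one
the statistic conventionally has.

## Read mapper

Seed-and-extend: exact 15-mer seeds (stride 7) voted into diagonal
buckets, then banded semiglobal dynamic programming (band 31) around
the best diagonals, on both strands.  The cost model is mismatch 2,
insertion 3, deletion 3 per base, minimized; end gaps on the target are
free.  Acceptance requires

* similarity = matches / alignment columns >= `min_similarity`
  (0.97 for same-species mapping, 0.9 for cross-species panels), and
* aligned read fraction >= `min_length_fraction` (0.5).

Two conventions are decisions, documented because the tool this
emulates never defines them: "similarity" counts gap columns against
identity, and "overlap" is the fraction of the *read* aligned (read
bases are clipped only where a placement runs off a linear target
end).  N in either sequence costs a mismatch but is excluded from the
similarity numerator.  One best placement is reported per read; ties
break deterministically (lowest target id, then lowest target start,
then plus strand).  At 90 bp and <= 3% divergence, a single
mid-read error still leaves error-free seeds, so seeding misses are
negligible at these settings.

## Assembler

A standard de Bruijn assembler: canonical 31-mers (lexicographic
minimum of k-mer and reverse complement) counted over all reads,
k-mers below `min_kmer_count` = 2 dropped.  Graph cleaning iterates
three rules to convergence (<= 8 rounds):

1. **weak junction branches** — where two extensions compete, an
   extension at <= 1/8 the coverage of its strongest sibling and
   absolute count <= 5 is removed (error chains, not alternatives);
2. **tips** — dangling unitigs shorter than 2k hanging off a junction;
3. **bubbles** — equal-length parallel unitigs differing by <= 2
   mismatches, collapsed to the higher-coverage branch.

Maximal unambiguous paths become contigs; contigs shorter than 300 bp
are discarded.  A contig whose traversal closes on its starting k-mer,
or whose ends share a (k-1)-mer overlap, is flagged circular and
reported from a deterministic rotation (lexicographically least
rotation of the lexicographically smaller strand), so an identical
circular genome always serializes identically.

**Polish:** all reads are mapped back (0.97 / 0.5 thresholds) and
stacked into a per-site A/C/G/T pileup.  The consensus is the
plurality base per column; a column with depth < 2 or a tied plurality
becomes N.  The depth-2/tie rule is a deliberate conservative choice —
the calling rule behind published Ns in low-complexity regions is
never stated, and this rule marks exactly the columns with no
plurality evidence.  Average coverage is the mean pileup depth.

**Paired mode:** mate pairs bridge contigs; two linear contigs bridged
by >= 5 pairs are merged when their ends share an exact >= (k-1)-mer
overlap.  Scaffolding with gap characters is deliberately not done.

## Mitochondrial triage

The modal average coverage is computed over contigs after rounding
coverages to one decimal (0.1x bins; ties toward the smaller value —
binning is required for a mode over continuous values and 0.1x is the
coarsest bin that keeps a low integer mode readable).  Candidates are
contigs >= 10 kb with coverage >= 10x the mode; the longest candidate
is the putative mitogenome.  The 10-fold default is conservative
relative to observed mito enrichments (tens of fold); it is a
screening threshold, not a claim about copy number.  Confirmation of
mitochondrial identity is by alignment to a user-supplied reference
mitogenome (compare module), not by remote database search.

## Contamination profiling

Each read is mapped independently against each panel entry with that
entry's own identity threshold — strict (0.97) for the human genome so
that only genuine human DNA counts, relaxed (0.9) for cross-species
proxy panels.  A read tallies under every entry it hits, so
percentages may overlap; `unidentified` is the share hitting nothing.
An exclusive best-cost mode produces a partition when needed.  Proxy
entries (a related species standing in for an unsequenced one) are
annotated as such in the report.

## Damage assay

The error rate is mismatch bases / aligned read bases over accepted
alignments against the consensus (indel bases excluded from both
numerator and denominator; N columns excluded from the numerator).
Mismatches are split into the 12 directed categories (consensus base ->
read base) after orienting every read onto the consensus plus strand.
Rates are reported per opportunity — count / aligned consensus-X
columns — which keeps cross-category comparisons meaningful under
unequal base composition; the per-total-mismatch normalization is
emitted alongside.  The damage flag is raised when the C->T and G->A
rates are each >= 2.5x the median of the other ten rates (the
fold is configurable); diagnostics include each category's
fold-over-median and whether the combined C->T + G->A share of aligned
bases is below 1%.  Reads are assessed post-deduplication by default,
matching the pipeline order; raw reads can be passed explicitly.

## Genome comparison

Global alignment uses match +1 / mismatch -2 / gap -3 (linear), a
deliberately chosen scheme (the GUI tool this models publishes none);
traceback tie-breaks prefer substitution over a gap in the first
sequence over a gap in the second, making outputs deterministic.
Circular assemblies are rotated (and re-oriented) so position 0 is the
first base of an anchor gene — tRNA-Phe by convention — located via
the annotated reference.  Annotations transfer through alignment
columns, with endpoints snapped inward past target gaps; a transferred
CDS with length not divisible by 3 is flagged frame-disrupted, and a
fully deleted region is flagged missing.

Per-region divergence counts, per alignment column: segregating
(both bases unambiguous, non-gap, different), gap characters, and
ambiguous (N) columns — N columns are never counted as segregating.
Nonsynonymous calls apply only to CDS regions: each segregating site is
substituted, alone, into the first sequence's codon and both codons are
translated under the vertebrate mitochondrial code (translation
table 2); codons hit by more than one substitution are flagged, since
single-site evaluation is then an approximation.  Multi-genome
comparison projects every genome onto the first (anchor) genome's
coordinates through pairwise alignments rather than a full multiple
alignment — adequate and deterministic for a handful of near-identical
~17 kb sequences — and counts segregating sites only at positions where
every genome has an unambiguous, non-gap base.

## Problem sizes and determinism

The test suite and the acceptance script simulate a 16.7 kb circular
mitogenome at ~100x (about 9,300 read pairs), 8–20 kb linear genomes
for damage/contamination recovery at 1,500–2,500 fragments, and small
constructed examples for exact oracles.  These sizes give binomial
3-sigma bounds tight enough to detect rate errors of a few percent
while keeping a full run in minutes on one CPU.  All randomness flows
from explicit integer seeds through a single `numpy` generator per
simulation; every reported number is reproducible from the seed.

## Known limitations

* The assembler handles simple bubbles and tips only; tangled repeat
  structures (numts, long homopolymers) will fragment contigs rather
  than resolve them.
* The mapper reports one placement per read; coverage in genuinely
  repetitive regions is subject to the deterministic tie-break.
* Damage is modeled and assessed as a rate, not as a position-in-read
  profile; fragment-end enrichment curves are out of scope.
* Indels are neither simulated as sequencing errors nor counted in the
  error rate (substitution-only statistic).
* The contamination profiler measures mapping percentages against the
  supplied panel only; it is not a taxonomic classifier.
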