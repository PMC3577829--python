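"""Ancient-DNA shotgun read simulator with per-read ground truth.

Emulates the library a degraded museum specimen yields: short fragments
(200 +/- 50 bp by default) drawn from a mixture of source genomes — a
small circular mitogenome at high copy number over a large nuclear
background, plus optional contaminant genomes — sequenced as fixed-length
short reads (90 bp default, single- or paired-end).  Three noise
processes are modeled, in the order they occur in a real library:

1. cytosine deamination on the fragment's template strand (C->T, which
   reads as G->A whenever the sequencer reports the opposite strand),
2. per-base substitution sequencing error (uniform choice among the
   three alternative bases),
3. PCR duplication: with probability ``duplicate_rate`` a fragment's
   final read bases are emitted a second time, verbatim, flagged as a
   duplicate.  Duplicates clone the *post-error* bases because that is
   the molecule an exact-sequence duplicate remover can recognize.

Every emitted read carries a :class:`TruthRecord` so downstream stages
(deduplication, assembly, damage profiling, contamination profiling) can
be validated against known truth.  Indel sequencing errors are not
modeled (HiSeq-era substitution-dominated chemistry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .io import ReadPair, SequenceRecord, revcomp, write_fastq, write_tsv_report

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SourceGenome:
    """One genome in the simulated mixture.

    ``weight`` is relative molar abundance (copies), so the expected
    share of fragments is weight * length / sum(weight_i * length_i).
    """

    genome: SequenceRecord
    circular: bool = False
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("source weight must be positive")


@dataclass
class SimConfig:
    seed: int = 0
    read_length: int = 90
    fragment_mean: int = 200
    fragment_sd: float = 25.0
    fragment_window: int = 50  # hard truncation: mean +/- window
    paired: bool = True
    seq_error: float = 0.004
    damage_ct: float = 0.0
    damage_end_weighted: bool = False
    duplicate_rate: float = 0.0
    n_fragments: int = 10_000
    base_quality: int = 30
    low_q_fraction: float = 0.0  # fraction of base calls assigned low_q_score
    low_q_score: int = 10
    sources: list[SourceGenome] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("seq_error", "damage_ct", "duplicate_rate", "low_q_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class TruthRecord:
    """Ground truth for one emitted read."""

    read_id: str
    source_name: str
    source_start: int  # 0-based on the source plus strand (mod length if circular)
    strand: str  # strand of THIS read relative to the source plus strand
    n_seq_errors: int
    n_damage_events: int
    is_duplicate: bool


def simulate_genome(length: int, seed: int, circular: bool = False) -> SequenceRecord:
    """Uniform-random genome over {A,C,G,T}; reproducible for a fixed seed."""
    if length < 1:
        raise ValueError(f"genome length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    bases = _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")
    name = f"sim_{'circ' if circular else 'lin'}_{length}_{seed}"
    return SequenceRecord(name, bases)


def _apply_damage(template: str, p: float, rng: np.random.Generator, end_weighted: bool) -> tuple[str, int]:
    """Deaminate template-strand cytosines: C -> T with probability p."""
    if p == 0.0:
        return template, 0
    arr = np.frombuffer(template.encode("ascii"), dtype=np.uint8).copy()
    c_pos = np.flatnonzero(arr == ord("C"))
    if c_pos.size == 0:
        return template, 0
    if end_weighted:
        # probability decays geometrically from each fragment end (scale 10 bp),
        # normalized so the per-C rate at position 0 is p
        d = np.minimum(c_pos, len(arr) - 1 - c_pos)
        probs = p * np.exp(-d / 10.0)
    else:
        probs = np.full(c_pos.size, p)
    hit = rng.random(c_pos.size) < probs
    arr[c_pos[hit]] = ord("T")
    return arr.tobytes().decode("ascii"), int(hit.sum())


def _apply_seq_error(bases: str, p: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute each base with a uniform different base with probability p."""
    if p == 0.0:
        return bases, 0
    arr = np.frombuffer(bases.encode("ascii"), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < p)
    if hit.size == 0:
        return bases, 0
    for i in hit:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode("ascii"), int(hit.size)


def simulate_reads(
    config: SimConfig,
) -> tuple[list[SequenceRecord] | list[ReadPair], list[TruthRecord]]:
    """Draw fragments from the source mixture and sequence them.

    Returns reads (SequenceRecords, or ReadPairs in paired mode) and one
    TruthRecord per emitted read.  In paired mode, mate truth records are
    interleaved (mate1 then mate2 per fragment).
    """
    if not config.sources:
        raise ValueError("at least one source genome required")
    rng = np.random.default_rng(config.seed)

    weights = np.array([s.weight * len(s.genome) for s in config.sources], dtype=float)
    probs = weights / weights.sum()

    lo = max(30, config.fragment_mean - config.fragment_window)
    hi = config.fragment_mean + config.fragment_window

    reads: list = []
    truth: list[TruthRecord] = []

    def quality(n: int) -> list[int]:
        if config.low_q_fraction > 0.0:
            low = rng.random(n) < config.low_q_fraction
            return [config.low_q_score if l else config.base_quality for l in low]
        return [config.base_quality] * n

    for frag_idx in range(config.n_fragments):
        src = config.sources[rng.choice(len(config.sources), p=probs)]
        genome = src.genome.bases
        glen = len(genome)

        # truncated-normal fragment length
        while True:
            flen = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
            if lo <= flen <= hi:
                break
        flen = min(flen, glen)

        if src.circular:
            start = int(rng.integers(0, glen))
            frag_plus = (genome + genome)[start : start + flen]
        else:
            start = int(rng.integers(0, glen - flen + 1))
            frag_plus = genome[start : start + flen]

        template_strand = "+" if rng.random() < 0.5 else "-"
        template = frag_plus if template_strand == "+" else revcomp(frag_plus)

        template, n_dam = _apply_damage(
            template, config.damage_ct, rng, config.damage_end_weighted
        )

        rid = f"frag{frag_idx}"
        L = config.read_length

        if config.paired:
            m1_bases, e1 = _apply_seq_error(template[:L], config.seq_error, rng)
            m2_bases, e2 = _apply_seq_error(revcomp(template)[:L], config.seq_error, rng)
            mate2_strand = "-" if template_strand == "+" else "+"
            # per-mate start on the source plus strand
            if template_strand == "+":
                s1 = start
                s2 = (start + flen - len(m2_bases)) % glen if src.circular else start + flen - len(m2_bases)
            else:
                s1 = (start + flen - len(m1_bases)) % glen if src.circular else start + flen - len(m1_bases)
                s2 = start
            pair = ReadPair(
                SequenceRecord(f"{rid}/1", m1_bases, quality(len(m1_bases))),
                SequenceRecord(f"{rid}/2", m2_bases, quality(len(m2_bases))),
                insert_hint=flen,
            )
            reads.append(pair)
            truth.append(TruthRecord(f"{rid}/1", src.genome.id, s1 % glen, template_strand, e1, n_dam, False))
            truth.append(TruthRecord(f"{rid}/2", src.genome.id, s2 % glen, mate2_strand, e2, n_dam, False))
            if rng.random() < config.duplicate_rate:
                dup = ReadPair(
                    SequenceRecord(f"{rid}d/1", m1_bases, quality(len(m1_bases))),
                    SequenceRecord(f"{rid}d/2", m2_bases, quality(len(m2_bases))),
                    insert_hint=flen,
                )
                reads.append(dup)
                truth.append(TruthRecord(f"{rid}d/1", src.genome.id, s1 % glen, template_strand, e1, n_dam, True))
                truth.append(TruthRecord(f"{rid}d/2", src.genome.id, s2 % glen, mate2_strand, e2, n_dam, True))
        else:
            r_bases, e1 = _apply_seq_error(template[:L], config.seq_error, rng)
            if template_strand == "+":
                s1 = start
            else:
                s1 = (start + flen - len(r_bases)) % glen if src.circular else start + flen - len(r_bases)
            reads.append(SequenceRecord(rid, r_bases, quality(len(r_bases))))
            truth.append(TruthRecord(rid, src.genome.id, s1 % glen, template_strand, e1, n_dam, False))
            if rng.random() < config.duplicate_rate:
                reads.append(SequenceRecord(f"{rid}d", r_bases, quality(len(r_bases))))
                truth.append(TruthRecord(f"{rid}d", src.genome.id, s1 % glen, template_strand, e1, n_dam, True))

    return reads, truth


def write_truth_tsv(truth: Iterable[TruthRecord], path: str | Path) -> None:
    rows = [
        [t.read_id, t.source_name, t.source_start, t.strand, t.n_seq_errors, t.n_damage_events, int(t.is_duplicate)]
        for t in truth
    ]
    write_tsv_report(
        rows,
        path,
        header=["read_id", "source", "start_0based", "strand", "seq_errors", "damage_events", "is_duplicate"],
    )


def write_reads(reads: list, prefix: str | Path) -> list[Path]:
    """Write simulated reads to FASTQ: one file for single-end, _1/_2 pair otherwise."""
    prefix = Path(prefix)
    if reads and isinstance(reads[0], ReadPair):
        p1 = prefix.with_name(prefix.name + "_1.fastq")
        p2 = prefix.with_name(prefix.name + "_2.fastq")
        write_fastq((p.mate1 for p in reads), p1)
        write_fastq((p.mate2 for p in reads), p2)
        return [p1, p2]
    p = prefix.with_name(prefix.name + ".fastq")
    write_fastq(reads, p)
    return [p]
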