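"""Mitogenome comparison: alignment, annotation transfer, divergence tables.

An assembled mitogenome is characterized against references and against
other assemblies of the same species: globally aligned, rotated to a
canonical start (conventionally the first base of tRNA-Phe), annotated
by coordinate transfer from an annotated reference, and summarized per
region as counts of segregating sites, nonsynonymous substitutions, gap
characters, and ambiguous (N) columns.  Nonsynonymous calls use the
vertebrate mitochondrial genetic code (translation table 2), each
substitution evaluated independently against the first sequence's
codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .io import Region, SequenceRecord, revcomp
from .mapper import MapperParams, TargetIndex, map_read

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]


def translate_codon(codon: str) -> str:
    """One codon -> amino acid under the vertebrate mitochondrial code ('*' = stop)."""
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table[codon]


@dataclass
class PairwiseAlignment:
    aligned_a: str
    aligned_b: str
    score: int

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)


@dataclass
class DivergenceRow:
    region_name: str
    alignment_length: int
    segregating_sites: int
    nonsynonymous: int | None  # None = not applicable / not computable
    gaps: int
    ambiguous: int
    flags: list[str] = field(default_factory=list)

    def cell(self) -> str:
        """Table-cell format: segregating/nonsynonymous/gaps/ambiguous."""
        ns = "NA" if self.nonsynonymous is None else str(self.nonsynonymous)
        return f"{self.segregating_sites}/{ns}/{self.gaps}/{self.ambiguous}"


def global_align(
    seq_a: str, seq_b: str, match: int = 1, mismatch: int = -2, gap: int = -3
) -> PairwiseAlignment:
    """Optimal global alignment under a linear gap scheme.

    Deterministic traceback: on ties, match/mismatch is preferred over a
    gap in ``seq_a``, which is preferred over a gap in ``seq_b``.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    n, m = len(seq_a), len(seq_b)
    a = np.frombuffer(seq_a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(seq_b.encode("ascii"), dtype=np.uint8)
    N = ord("N")

    prev = (gap * np.arange(m + 1)).astype(np.int32)
    # 0 = diagonal, 1 = gap in A (consume b), 2 = gap in B (consume a)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptr[0, 1:] = 1
    ptr[1:, 0] = 2
    jj = np.arange(1, m + 1, dtype=np.int64)

    for i in range(1, n + 1):
        sub = np.where((b == a[i - 1]) & (b != N) & (a[i - 1] != N), match, mismatch).astype(np.int32)
        diag = prev[:-1] + sub
        up = prev[1:] + gap
        c0 = np.maximum(diag, up)
        cur0 = int(prev[0]) + gap
        acc = np.maximum.accumulate(
            np.concatenate(([np.int64(cur0)], c0.astype(np.int64) - gap * jj))
        )
        cur = np.empty(m + 1, dtype=np.int32)
        cur[0] = cur0
        cur[1:] = (acc[1:] + gap * jj).astype(np.int32)
        left = cur[:-1] + gap
        ptr[i, 1:] = np.where(cur[1:] == diag, 0, np.where(cur[1:] == left, 1, 2)).astype(np.int8)
        prev = cur

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        p = ptr[i, j]
        if p == 0:
            out_a.append(seq_a[i - 1])
            out_b.append(seq_b[j - 1])
            i -= 1
            j -= 1
        elif p == 1:
            out_a.append("-")
            out_b.append(seq_b[j - 1])
            j -= 1
        else:
            out_a.append(seq_a[i - 1])
            out_b.append("-")
            i -= 1
    return PairwiseAlignment("".join(reversed(out_a)), "".join(reversed(out_b)), int(prev[m]))


def _column_maps(aln: PairwiseAlignment) -> tuple[np.ndarray, np.ndarray]:
    """Per-column 0-based positions in a and b (-1 at gap columns)."""
    a = np.frombuffer(aln.aligned_a.encode(), dtype=np.uint8) != ord("-")
    b = np.frombuffer(aln.aligned_b.encode(), dtype=np.uint8) != ord("-")
    a_pos = np.where(a, np.cumsum(a) - 1, -1)
    b_pos = np.where(b, np.cumsum(b) - 1, -1)
    return a_pos, b_pos


def rotate_to_start(
    circular_seq: SequenceRecord,
    reference: SequenceRecord,
    annotation: list[Region],
    anchor_region: str = "tRNA-Phe",
    min_anchor_similarity: float = 0.7,
) -> SequenceRecord:
    """Rotate (and orient) a circular sequence so the anchor gene starts at 0.

    The anchor region's sequence is taken from the annotated reference
    and located on both orientations of the circular input; the
    orientation with the better placement wins.  Raises when the anchor
    cannot be placed at or above ``min_anchor_similarity``.
    """
    regions = [r for r in annotation if r.name == anchor_region]
    if not regions:
        raise ValueError(f"anchor region {anchor_region!r} not in annotation")
    reg = regions[0]
    anchor = reference.bases[reg.start : reg.end]
    if reg.strand == "-":
        anchor = revcomp(anchor)

    params = MapperParams(min_similarity=min_anchor_similarity, min_length_fraction=0.9)
    best = None
    for orient, seq in (("+", circular_seq.bases), ("-", revcomp(circular_seq.bases))):
        idx = TargetIndex([SequenceRecord("t", seq)], params)
        idx.mark_circular("t")
        aln = map_read(SequenceRecord("anchor", anchor), idx, params)
        if aln is None or aln.strand != "+":
            continue
        if best is None or aln.cost < best[0]:
            best = (aln.cost, orient, seq, aln.target_start)
    if best is None:
        raise ValueError(
            f"anchor {anchor_region!r} could not be located on either orientation"
        )
    _, orient, seq, start = best
    rotated = seq[start:] + seq[:start]
    return SequenceRecord(circular_seq.id, rotated)


def transfer_annotation(
    ref_annotation: list[Region], alignment: PairwiseAlignment
) -> list[Region]:
    """Project reference regions through an alignment onto the target.

    ``alignment`` aligns the reference (a) with the target (b).  Region
    endpoints landing in target gaps are snapped inward to the nearest
    aligned target base.  A region entirely deleted in the target is
    flagged ``missing``; a transferred CDS whose length is not a
    multiple of 3 is flagged ``frame_disrupted``.
    """
    a_pos, b_pos = _column_maps(alignment)
    n_ref = int(a_pos.max()) + 1
    ref_to_col = np.full(n_ref, -1, dtype=np.int64)
    mask = a_pos >= 0
    ref_to_col[a_pos[mask]] = np.flatnonzero(mask)
    # b bases consumed strictly before each column
    b_before = np.concatenate(([0], np.cumsum(b_pos >= 0)))

    out: list[Region] = []
    for reg in ref_annotation:
        if reg.end > n_ref:
            raise ValueError(f"region {reg.name!r} exceeds reference length {n_ref}")
        col_s = int(ref_to_col[reg.start])
        col_e = int(ref_to_col[reg.end - 1]) + 1
        t_start = int(b_before[col_s])
        t_end = int(b_before[col_e])
        flags = list(reg.flags)
        if t_end <= t_start:
            flags.append("missing")
            out.append(Region(reg.name, t_start, t_start, reg.strand, reg.kind, flags))
            continue
        if reg.kind == "CDS" and (t_end - t_start) % 3 != 0:
            flags.append("frame_disrupted")
        out.append(Region(reg.name, t_start, t_end, reg.strand, reg.kind, flags))
    return out


def region_divergence(
    alignment: PairwiseAlignment, annotation: list[Region]
) -> list[DivergenceRow]:
    """Per-region divergence counts between two aligned sequences.

    The annotation is in coordinates of the first (``a``) sequence.  Per
    region: alignment_length = columns spanned; segregating = columns
    where both sequences carry unambiguous, non-gap, differing bases;
    gaps = gap characters; ambiguous = columns containing N.
    Nonsynonymous calls (CDS only) substitute the b base into the a
    codon one site at a time and compare translations under the
    vertebrate mitochondrial code; a CDS whose a-length is not a
    multiple of 3 gets nonsynonymous = None.
    """
    a_pos, _ = _column_maps(alignment)
    n_ref = int(a_pos.max()) + 1
    ref_to_col = np.full(n_ref, -1, dtype=np.int64)
    mask = a_pos >= 0
    ref_to_col[a_pos[mask]] = np.flatnonzero(mask)
    A, B = alignment.aligned_a, alignment.aligned_b

    rows: list[DivergenceRow] = []
    for reg in annotation:
        col_s = int(ref_to_col[reg.start])
        col_e = int(ref_to_col[reg.end - 1]) + 1
        seg_cols: list[int] = []
        gaps = ambiguous = 0
        for col in range(col_s, col_e):
            x, y = A[col], B[col]
            if x == "-" or y == "-":
                gaps += 1
            elif x == "N" or y == "N":
                ambiguous += 1
            elif x != y:
                seg_cols.append(col)
        flags: list[str] = []
        nonsyn: int | None = None
        if reg.kind == "CDS":
            nonsyn = _count_nonsynonymous(alignment, a_pos, reg, seg_cols, flags)
        rows.append(
            DivergenceRow(
                region_name=reg.name,
                alignment_length=col_e - col_s,
                segregating_sites=len(seg_cols),
                nonsynonymous=nonsyn,
                gaps=gaps,
                ambiguous=ambiguous,
                flags=flags,
            )
        )
    return rows


def _count_nonsynonymous(
    alignment: PairwiseAlignment,
    a_pos: np.ndarray,
    reg: Region,
    seg_cols: list[int],
    flags: list[str],
) -> int | None:
    """Classify each segregating CDS site against the first sequence's codon."""
    A, B = alignment.aligned_a, alignment.aligned_b
    region_cols = [c for c in range(len(A)) if reg.start <= a_pos[c] < reg.end and A[c] != "-"]
    a_seq = "".join(A[c] for c in region_cols)
    if len(a_seq) % 3 != 0:
        flags.append("frame_disrupted")
        return None
    a_cds = revcomp(a_seq) if reg.strand == "-" else a_seq

    hits_per_codon: dict[int, int] = {}
    n_nonsyn = 0
    for col in seg_cols:
        ap = int(a_pos[col])
        off = ap - reg.start
        if reg.strand == "-":
            off = (reg.end - reg.start - 1) - off
            b_base = revcomp(B[col])
        else:
            b_base = B[col]
        codon_idx, pos = divmod(off, 3)
        codon = a_cds[codon_idx * 3 : codon_idx * 3 + 3]
        if "N" in codon or len(codon) < 3:
            continue
        mutated = codon[:pos] + b_base + codon[pos + 1 :]
        hits_per_codon[codon_idx] = hits_per_codon.get(codon_idx, 0) + 1
        if translate_codon(mutated) != translate_codon(codon):
            n_nonsyn += 1
    if any(n > 1 for n in hits_per_codon.values()):
        flags.append("multi_hit_codon")
    return n_nonsyn


def composition(sequence: str) -> tuple[dict[str, float], int]:
    """Fractions of G/A/T/C over unambiguous bases, plus the N count."""
    n_count = sequence.count("N")
    unambig = len(sequence) - n_count
    if unambig == 0:
        raise ValueError("sequence contains no unambiguous bases")
    fractions = {b: sequence.count(b) / unambig for b in "GATC"}
    return fractions, n_count


@dataclass
class MultiCompareResult:
    pairwise: dict[tuple[str, str], list[DivergenceRow]]
    segregating_sites: int
    nonsynonymous_sites: int
    segregating_positions: list[int]  # 0-based on the anchor genome


def multi_compare(
    genomes: list[SequenceRecord],
    annotation: list[Region],
    exclude_regions: tuple[str, ...] = (),
) -> MultiCompareResult:
    """All-pairs divergence plus a multi-genome segregating-site count.

    The first genome anchors the coordinate frame: every other genome
    is globally aligned to it and projected onto its positions.  A
    segregating site is an anchor position, outside the excluded
    regions, where all genomes carry an unambiguous non-gap base and at
    least two distinct bases occur.  A segregating site inside a CDS is
    counted nonsynonymous when any observed variant changes the anchor
    codon's amino acid.
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    anchor = genomes[0]
    L = len(anchor.bases)

    # per-genome base at each anchor position ('-' where deleted)
    cols = np.full((len(genomes), L), "-", dtype="U1")
    cols[0] = list(anchor.bases)
    aln_to_anchor: dict[str, PairwiseAlignment] = {}
    for gi, g in enumerate(genomes[1:], start=1):
        aln = global_align(anchor.bases, g.bases)
        aln_to_anchor[g.id] = aln
        a_pos, _ = _column_maps(aln)
        for col in range(aln.n_columns):
            ap = a_pos[col]
            if ap >= 0 and aln.aligned_b[col] != "-":
                cols[gi, ap] = aln.aligned_b[col]

    # pairwise divergence rows
    pairwise: dict[tuple[str, str], list[DivergenceRow]] = {}
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            gi, gj = genomes[i], genomes[j]
            if i == 0:
                pair_aln = aln_to_anchor[gj.id]
                pair_ann = annotation
            else:
                pair_aln = global_align(gi.bases, gj.bases)
                pair_ann = transfer_annotation(annotation, aln_to_anchor[gi.id])
            pairwise[(gi.id, gj.id)] = region_divergence(pair_aln, pair_ann)

    excluded = np.zeros(L, dtype=bool)
    cds_at: dict[int, tuple[Region, int]] = {}
    for reg in annotation:
        if reg.name in exclude_regions:
            excluded[reg.start : reg.end] = True
        if reg.kind == "CDS":
            for p in range(reg.start, reg.end):
                cds_at[p] = (reg, p - reg.start)

    seg_positions: list[int] = []
    n_nonsyn = 0
    for p in range(L):
        if excluded[p]:
            continue
        bases = cols[:, p]
        if any(b in ("-", "N") for b in bases):
            continue
        uniq = set(bases)
        if len(uniq) < 2:
            continue
        seg_positions.append(p)
        hit = cds_at.get(p)
        if hit is None:
            continue
        reg, off = hit
        if (reg.end - reg.start) % 3 != 0:
            continue
        if reg.strand == "-":
            off = (reg.end - reg.start - 1) - off
            cds_seq = revcomp(anchor.bases[reg.start : reg.end])
            variants = {revcomp(b) for b in uniq}
        else:
            cds_seq = anchor.bases[reg.start : reg.end]
            variants = uniq
        codon_idx, pos = divmod(off, 3)
        codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
        if "N" in codon:
            continue
        ref_aa = translate_codon(codon)
        for v in variants:
            if v == codon[pos]:
                continue
            if translate_codon(codon[:pos] + v + codon[pos + 1 :]) != ref_aa:
                n_nonsyn += 1
                break
    return MultiCompareResult(
        pairwise=pairwise,
        segregating_sites=len(seg_positions),
        nonsynonymous_sites=n_nonsyn,
        segregating_positions=seg_positions,
    )


def divergence_table(rows: list[DivergenceRow]):
    """Shape divergence rows as a report table (one column per region)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "region": [r.region_name for r in rows],
            "alignment_length": [r.alignment_length for r in rows],
            "seg/nonsyn/gaps/ambig": [r.cell() for r in rows],
        }
    )
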