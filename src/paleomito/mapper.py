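"""Read placement under a linear-cost edit model with identity thresholds.

Reads are placed on target sequences by exact k-mer seeding followed by
banded semiglobal dynamic programming: the read is aligned end to end
while gaps at either end of the *target* window are free.  Costs are
mismatch 2, insertion 3, deletion 3 (per base); the minimum-cost
alignment is reported.  A placement is accepted only if

* similarity = matches / alignment columns  >= ``min_similarity``, and
* aligned read fraction = aligned read bases / read length >= ``min_length_fraction``.

"Similarity" counts gap columns against identity; "overlap" is the
fraction of the read that is aligned (read bases are clipped only when a
placement runs off the end of a linear target).  N in either sequence is
costed as a mismatch and excluded from the similarity numerator.

Ties between equally good placements are broken deterministically:
lowest target id, then lowest target start, then plus strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .io import SequenceRecord, revcomp

# edit-op tags: ("match", n) | ("mismatch", read_base, target_base)
#             | ("ins", n) | ("del", n)
EditOps = list[tuple]


@dataclass
class MapperParams:
    mismatch_cost: int = 2
    insertion_cost: int = 3
    deletion_cost: int = 3
    min_similarity: float = 0.97
    min_length_fraction: float = 0.5
    band_width: int = 31
    seed_k: int = 15
    seed_stride: int = 7
    max_candidates: int = 8

    def __post_init__(self) -> None:
        if min(self.mismatch_cost, self.insertion_cost, self.deletion_cost) <= 0:
            raise ValueError("edit costs must be positive")
        for name in ("min_similarity", "min_length_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass
class AlignmentRecord:
    read_id: str
    target_id: str
    target_start: int  # 0-based on the target plus strand
    strand: str  # '+' or '-': strand of the read relative to the target
    edit_ops: EditOps
    cost: int
    matches: int
    mismatches: int  # mismatch columns with both bases in ACGT
    n_columns: int  # N-containing mismatch columns (excluded from similarity numerator)
    ins_bases: int
    del_bases: int
    aligned_read_bases: int
    read_length: int
    read_clip_left: int = 0  # oriented-read bases clipped off a linear target start

    @property
    def alignment_columns(self) -> int:
        return self.matches + self.mismatches + self.n_columns + self.ins_bases + self.del_bases

    @property
    def similarity(self) -> float:
        return self.matches / self.alignment_columns

    @property
    def aligned_read_fraction(self) -> float:
        return self.aligned_read_bases / self.read_length

    @property
    def target_end(self) -> int:
        return self.target_start + self.matches + self.mismatches + self.n_columns + self.del_bases


class BandOverflowError(RuntimeError):
    """The alignment band cannot contain any read-through path."""


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def align_semiglobal(
    read: str, target_window: str, params: MapperParams | None = None
) -> AlignmentRecord:
    """Minimum-cost alignment of the whole read within a target window.

    End gaps on the target are free; the read is aligned in full.  The
    window must be wide enough to contain the read plus any indels
    (len(window) >= len(read) - band allowance), otherwise a
    BandOverflowError is raised.
    """
    params = params or MapperParams()
    if not read or not target_window:
        raise ValueError("read and target window must be non-empty")
    m, w = len(read), len(target_window)
    if w < m - params.band_width:
        raise BandOverflowError(
            f"window of {w} bp cannot hold a {m} bp read within band {params.band_width}"
        )

    r = _encode(read)
    t = _encode(target_window)
    N = ord("N")
    mc, ic, dc = params.mismatch_cost, params.insertion_cost, params.deletion_cost

    INF = np.iinfo(np.int32).max // 2
    # D[i, j] = min cost aligning read[:i] to window[:j]; leading/trailing
    # window bases are free (semiglobal on the target).
    prev = np.zeros(w + 1, dtype=np.int32)
    ptr = np.zeros((m + 1, w + 1), dtype=np.int8)  # 0=diag, 1=up(ins), 2=left(del)
    jj = np.arange(1, w + 1, dtype=np.int64)

    for i in range(1, m + 1):
        sub = np.where((t == r[i - 1]) & (t != N) & (r[i - 1] != N), 0, mc).astype(np.int32)
        diag = prev[:-1] + sub
        up = prev[1:] + ic
        c0 = np.minimum(diag, up)
        cur0 = int(prev[0]) + ic  # D[i, 0]: read prefix inserted before the window
        # horizontal (deletion) closure:
        #   cur[j] = min(cur0 + j*dc, min_{1<=k<=j} c0[k] + (j-k)*dc)
        # computed as a running minimum of c0[k] - k*dc.
        b = np.minimum.accumulate(np.concatenate(([np.int64(cur0)], c0.astype(np.int64) - dc * jj)))
        cur = np.empty(w + 1, dtype=np.int32)
        cur[0] = cur0
        cur[1:] = (b[1:] + dc * jj).astype(np.int32)
        # pointer preference: diagonal, then insertion, then deletion
        ptr[i, 1:] = np.where(cur[1:] == diag, 0, np.where(cur[1:] == up, 1, 2)).astype(np.int8)
        ptr[i, 0] = 1
        prev = cur

    end_j = int(np.argmin(prev))  # ties -> smallest j (deterministic)
    cost = int(prev[end_j])

    # traceback
    ops_rev: list[tuple] = []
    i, j = m, end_j
    matches = mismatches = n_cols = ins_b = del_b = 0
    while i > 0:
        p = ptr[i, j]
        if p == 0:
            rb, tb = read[i - 1], target_window[j - 1]
            if rb == tb and rb != "N":
                if ops_rev and ops_rev[-1][0] == "match":
                    ops_rev[-1] = ("match", ops_rev[-1][1] + 1)
                else:
                    ops_rev.append(("match", 1))
                matches += 1
            else:
                ops_rev.append(("mismatch", rb, tb))
                if rb == "N" or tb == "N":
                    n_cols += 1
                else:
                    mismatches += 1
            i -= 1
            j -= 1
        elif p == 1:
            if ops_rev and ops_rev[-1][0] == "ins":
                ops_rev[-1] = ("ins", ops_rev[-1][1] + 1)
            else:
                ops_rev.append(("ins", 1))
            ins_b += 1
            i -= 1
        else:
            if ops_rev and ops_rev[-1][0] == "del":
                ops_rev[-1] = ("del", ops_rev[-1][1] + 1)
            else:
                ops_rev.append(("del", 1))
            del_b += 1
            j -= 1
    start_j = j
    ops_rev.reverse()

    return AlignmentRecord(
        read_id="",
        target_id="",
        target_start=start_j,
        strand="+",
        edit_ops=ops_rev,
        cost=cost,
        matches=matches,
        mismatches=mismatches,
        n_columns=n_cols,
        ins_bases=ins_b,
        del_bases=del_b,
        aligned_read_bases=m,
        read_length=m,
    )


class TargetIndex:
    """Exact k-mer index over the plus strands of a target set."""

    def __init__(self, targets: Sequence[SequenceRecord], params: MapperParams | None = None):
        self.params = params or MapperParams()
        self.targets = list(targets)
        self.circular = [False] * len(self.targets)
        k = self.params.seed_k
        self.index: dict[str, list[tuple[int, int]]] = {}
        for ti, rec in enumerate(self.targets):
            seq = rec.bases
            for pos in range(0, len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                self.index.setdefault(kmer, []).append((ti, pos))

    def mark_circular(self, target_id: str) -> None:
        for i, t in enumerate(self.targets):
            if t.id == target_id:
                self.circular[i] = True


def _candidate_diagonals(
    oriented: str, idx: TargetIndex
) -> list[tuple[int, int, int]]:
    """Vote seed hits into (target, diagonal) buckets; return by vote count."""
    p = idx.params
    k = p.seed_k
    votes: dict[tuple[int, int], int] = {}
    offsets = list(range(0, max(1, len(oriented) - k + 1), p.seed_stride))
    last = len(oriented) - k
    if last > 0 and last not in offsets:
        offsets.append(last)
    for off in offsets:
        kmer = oriented[off : off + k]
        for ti, pos in idx.index.get(kmer, ()):
            diag = pos - off
            key = (ti, diag - diag % max(1, p.band_width // 2))
            votes[key] = votes.get(key, 0) + 1
    ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(ti, diag, n) for (ti, diag), n in ranked[: p.max_candidates]]


def _align_at(
    oriented: str, idx: TargetIndex, ti: int, diag: int
) -> AlignmentRecord | None:
    """Align the oriented read near a candidate diagonal of target ti."""
    p = idx.params
    target = idx.targets[ti].bases
    L = len(target)
    pad = p.band_width
    m = len(oriented)

    if idx.circular[ti]:
        diag %= L
        ext = target + target[: m + 2 * pad]
        lo = max(0, diag - pad)
        hi = min(len(ext), diag + m + pad)
        window = ext[lo:hi]
        read_part, clip_left = oriented, 0
    else:
        lo = max(0, diag - pad)
        hi = min(L, diag + m + pad)
        # clip read bases that would run off a linear target end
        clip_left = max(0, -(diag - 0)) if diag < 0 else 0
        clip_right = max(0, (diag + m) - L) if diag + m > L else 0
        read_part = oriented[clip_left : m - clip_right]
        window = target[lo:hi]
        if not read_part or not window:
            return None
    if len(window) < len(read_part) - p.band_width:
        return None
    try:
        aln = align_semiglobal(read_part, window, p)
    except (BandOverflowError, ValueError):
        return None
    aln.target_id = idx.targets[ti].id
    start = lo + aln.target_start
    aln.target_start = start % L if idx.circular[ti] else start
    aln.aligned_read_bases = len(read_part)
    aln.read_length = m
    aln.read_clip_left = clip_left
    return aln


def map_read(
    read: SequenceRecord, idx: TargetIndex, params: MapperParams | None = None
) -> AlignmentRecord | None:
    """Best accepted placement of a read over both strands of all targets.

    Returns None when no placement meets the similarity and
    length-fraction thresholds (unmapped is a value, not an error).
    """
    if params is not None and params is not idx.params:
        # thresholds may differ from the index's seeding params
        idx = _reparam(idx, params)
    p = idx.params

    best: AlignmentRecord | None = None
    best_key = None
    for strand, oriented in (("+", read.bases), ("-", revcomp(read.bases))):
        for ti, diag, _votes in _candidate_diagonals(oriented, idx):
            aln = _align_at(oriented, idx, ti, diag)
            if aln is None:
                continue
            aln.strand = strand
            key = (aln.cost, aln.target_id, aln.target_start, 0 if strand == "+" else 1)
            if best_key is None or key < best_key:
                best, best_key = aln, key
    if best is None:
        return None
    best.read_id = read.id
    if best.similarity < p.min_similarity or best.aligned_read_fraction < p.min_length_fraction:
        return None
    return best


def _reparam(idx: TargetIndex, params: MapperParams) -> TargetIndex:
    if params.seed_k != idx.params.seed_k:
        fresh = TargetIndex(idx.targets, params)
        fresh.circular = list(idx.circular)
        return fresh
    clone = TargetIndex.__new__(TargetIndex)
    clone.params = params
    clone.targets = idx.targets
    clone.circular = idx.circular
    clone.index = idx.index
    return clone


def map_reads(
    reads: Iterable[SequenceRecord], idx: TargetIndex, params: MapperParams | None = None
) -> list[AlignmentRecord]:
    """Map many reads; unmapped reads are dropped from the result."""
    out = []
    for r in reads:
        aln = map_read(r, idx, params)
        if aln is not None:
            out.append(aln)
    return out
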