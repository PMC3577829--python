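"""De novo assembly of short reads into polished contigs.

A standard de Bruijn pipeline: canonical k-mer counting with a coverage
cutoff, tip and bubble pruning, unitig extraction, then a polish step
that maps every read back onto the contigs (under the mapper's identity
thresholds) to build a per-site pileup and call a plurality consensus.
Contigs whose ends share a (k-1)-mer overlap are flagged as circular —
the signature of a circular source such as a mitochondrial genome.

In paired-end mode, mate pairs are additionally used to join contigs
whose ends overlap and are bridged by enough pairs with a consistent
insert size.  Scaffolding with gap characters is deliberately not done.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ReadPair, SequenceRecord, revcomp
from .mapper import AlignmentRecord, MapperParams, TargetIndex, map_read

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE = "ACGT"


@dataclass
class AssemblyParams:
    kmer_size: int = 31
    min_contig_length: int = 300
    min_kmer_count: int = 2
    mapper: MapperParams = field(default_factory=MapperParams)
    min_bridge_pairs: int = 5
    insert_mean: int = 200
    insert_window: int = 50

    def __post_init__(self) -> None:
        if self.kmer_size % 2 == 0 or self.kmer_size < 15:
            raise ValueError("kmer_size must be odd and >= 15")
        if self.min_contig_length < self.kmer_size:
            raise ValueError("min_contig_length must be >= kmer_size")


@dataclass
class Contig:
    id: str
    consensus: str
    pileup: np.ndarray | None = None  # (L, 4) counts of A/C/G/T
    avg_coverage: float = 0.0
    circular_hint: bool = False

    def __len__(self) -> int:
        return len(self.consensus)


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _flatten_reads(reads) -> list[SequenceRecord]:
    flat: list[SequenceRecord] = []
    for r in reads:
        if isinstance(r, ReadPair):
            flat.append(r.mate1)
            flat.append(r.mate2)
        else:
            flat.append(r)
    return flat


class KmerGraph:
    """Canonical k-mer counts; edges are implicit single-base extensions."""

    def __init__(self, counts: dict[str, int], k: int):
        self.counts = counts
        self.k = k

    def __contains__(self, kmer: str) -> bool:
        return canonical(kmer) in self.counts

    def count(self, kmer: str) -> int:
        return self.counts.get(canonical(kmer), 0)

    def successors(self, kmer: str) -> list[str]:
        suf = kmer[1:]
        return [suf + b for b in _BASE if canonical(suf + b) in self.counts]

    def predecessors(self, kmer: str) -> list[str]:
        pre = kmer[:-1]
        return [b + pre for b in _BASE if canonical(b + pre) in self.counts]


def build_graph(reads, params: AssemblyParams | None = None) -> KmerGraph:
    """Count canonical k-mers; drop those below the coverage cutoff.

    N-containing k-mers are skipped.  Raises if no read reaches k bases.
    """
    params = params or AssemblyParams()
    k = params.kmer_size
    flat = _flatten_reads(reads)
    counts: dict[str, int] = {}
    any_long = False
    for rec in flat:
        seq = rec.bases
        if len(seq) < k:
            continue
        any_long = True
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            c = canonical(kmer)
            counts[c] = counts.get(c, 0) + 1
    if not any_long:
        raise ValueError(f"no read of length >= k ({k}); cannot build graph")
    counts = {km: c for km, c in counts.items() if c >= params.min_kmer_count}
    return KmerGraph(counts, k)


def _walk_unitig(graph: KmerGraph, start: str) -> tuple[str, list[str], bool]:
    """Extend an oriented k-mer forward while the path is unambiguous.

    Returns (sequence, oriented k-mers on the path, is_cycle).
    """
    path = [start]
    seq = list(start)
    node = start
    while True:
        succ = graph.successors(node)
        if len(succ) != 1:
            return "".join(seq), path, False
        nxt = succ[0]
        if len(graph.predecessors(nxt)) != 1:
            return "".join(seq), path, False
        if nxt == start:
            return "".join(seq), path, True
        if nxt in path and len(path) > 2 * graph.k:
            # safety against pathological loops shorter than the start anchor
            return "".join(seq), path, False
        path.append(nxt)
        seq.append(nxt[-1])
        node = nxt


def _unitigs(graph: KmerGraph) -> list[tuple[str, list[str], bool]]:
    """Partition the graph into maximal unambiguous paths (unitigs)."""
    seen: set[str] = set()
    out: list[tuple[str, list[str], bool]] = []

    def is_start(node: str) -> bool:
        preds = graph.predecessors(node)
        if len(preds) != 1:
            return True
        return len(graph.successors(preds[0])) != 1

    # deterministic order
    for c in sorted(graph.counts):
        for node in (c, revcomp(c)):
            if canonical(node) in seen or not is_start(node):
                continue
            seq, path, cyc = _walk_unitig(graph, node)
            if any(canonical(p) in seen for p in path):
                continue
            seen.update(canonical(p) for p in path)
            out.append((seq, path, cyc))
    # isolated cycles have no start node; sweep up what is left
    for c in sorted(graph.counts):
        if c in seen:
            continue
        seq, path, cyc = _walk_unitig(graph, c)
        seen.update(canonical(p) for p in path)
        out.append((seq, path, cyc))
    return out


def _prune(graph: KmerGraph, max_rounds: int = 8) -> None:
    """Iteratively remove short tips, weak branches, and simple bubbles."""
    k = graph.k
    for _ in range(max_rounds):
        removed = False

        # --- weak junction branches: where two extensions compete, an
        # extension at <= 1/8 the coverage of its strongest sibling (and
        # absolutely low) is an error chain, not a real alternative
        weak: set[str] = set()
        for c in graph.counts:
            for node in (c, revcomp(c)):
                succ = graph.successors(node)
                if len(succ) < 2:
                    continue
                cmax = max(graph.count(s) for s in succ)
                for s in succ:
                    cs = graph.count(s)
                    if cs <= cmax / 8 and cs <= 5:
                        weak.add(canonical(s))
        if weak:
            for km in weak:
                graph.counts.pop(km, None)
            removed = True

        units = _unitigs(graph)

        # --- tips: dangling unitigs shorter than 2k hanging off a junction
        for seq, path, cyc in units:
            if cyc or len(seq) >= 2 * k:
                continue
            first, last = path[0], path[-1]
            dangling_head = len(graph.predecessors(first)) == 0
            dangling_tail = len(graph.successors(last)) == 0
            if dangling_head and dangling_tail:
                continue  # an isolated short island, not a tip off a junction
            if dangling_head or dangling_tail:
                for p in path:
                    graph.counts.pop(canonical(p), None)
                removed = True
        if removed:
            continue

        # --- bubbles: two unitigs sharing both junction neighborhoods,
        # equal length, differing by <= 2 mismatches -> keep higher coverage
        by_ends: dict[tuple[str, str], list[tuple[str, list[str]]]] = {}
        for seq, path, cyc in units:
            if cyc:
                continue
            preds = graph.predecessors(path[0])
            succs = graph.successors(path[-1])
            if len(preds) == 1 and len(succs) == 1:
                key = (preds[0], succs[0])
                by_ends.setdefault(key, []).append((seq, path))
                rkey = (revcomp(succs[0]), revcomp(preds[0]))
                if rkey != key:
                    by_ends.setdefault(rkey, []).append((revcomp(seq), [revcomp(p) for p in path[::-1]]))
        for key, branches in by_ends.items():
            if len(branches) < 2:
                continue
            branches = sorted(
                branches,
                key=lambda b: -sum(graph.count(p) for p in b[1]) / len(b[1]),
            )
            keep_seq = branches[0][0]
            for seq, path in branches[1:]:
                if len(seq) != len(keep_seq):
                    continue
                diff = sum(a != b for a, b in zip(seq, keep_seq))
                if diff <= 2:
                    for p in path:
                        graph.counts.pop(canonical(p), None)
                    removed = True
        if not removed:
            break


def extract_contigs(graph: KmerGraph, params: AssemblyParams | None = None) -> list[Contig]:
    """Prune the graph and emit unitigs >= min_contig_length as raw contigs."""
    params = params or AssemblyParams()
    k = graph.k
    _prune(graph)
    contigs: list[Contig] = []
    for seq, path, cyc in _unitigs(graph):
        circular = cyc
        if cyc:
            # a cycle traversal re-appends the closing overlap; the
            # consensus is one base per k-mer on the cycle
            seq = seq[: len(path)]
        elif len(seq) >= 2 * (k - 1) and seq[: k - 1] == seq[-(k - 1) :]:
            seq = seq[: -(k - 1)]
            circular = True
        if len(seq) < params.min_contig_length:
            continue
        contigs.append(Contig(id="", consensus=_canonical_rotation(seq, circular), circular_hint=circular))
    contigs.sort(key=lambda c: (-len(c), c.consensus))
    for i, c in enumerate(contigs):
        c.id = f"contig_{i + 1}"
    return contigs


def _canonical_rotation(seq: str, circular: bool) -> str:
    """Report circular contigs from a deterministic rotation and strand."""
    if not circular:
        rc = revcomp(seq)
        return seq if seq <= rc else rc
    best = None
    for s in (seq, revcomp(seq)):
        i = _least_rotation(s)
        rot = (s + s)[i : i + len(s)]
        if best is None or rot < best:
            best = rot
    return best


def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation."""
    d = s + s
    f = [-1] * len(d)
    k = 0
    for j in range(1, len(d)):
        sj = d[j]
        i = f[j - k - 1]
        while i != -1 and sj != d[k + i + 1]:
            if sj < d[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != d[k + i + 1]:
            if sj < d[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def polish(
    contigs: list[Contig], reads, params: AssemblyParams | None = None
) -> list[Contig]:
    """Map reads back onto contigs; build pileups and call the consensus.

    Consensus per column is the plurality base; a column becomes N when
    its depth is < 2 or the plurality is tied.  Average coverage is the
    mean pileup depth.
    """
    params = params or AssemblyParams()
    if not contigs:
        raise ValueError("no contigs to polish")
    flat = _flatten_reads(reads)
    idx = TargetIndex([SequenceRecord(c.id, c.consensus) for c in contigs], params.mapper)
    for c in contigs:
        if c.circular_hint:
            idx.mark_circular(c.id)

    piles = {c.id: np.zeros((len(c), 4), dtype=np.int32) for c in contigs}
    lens = {c.id: len(c) for c in contigs}
    for read in flat:
        aln = map_read(read, idx)
        if aln is None:
            continue
        _add_to_pileup(piles[aln.target_id], aln, read.bases, lens[aln.target_id])

    out: list[Contig] = []
    for c in contigs:
        pile = piles[c.id]
        depth = pile.sum(axis=1)
        best = pile.max(axis=1)
        arg = pile.argmax(axis=1)
        tied = (pile == best[:, None]).sum(axis=1) > 1
        cons = np.frombuffer("".join(_BASE[a] for a in arg).encode(), dtype=np.uint8).copy()
        cons[(depth < 2) | tied] = ord("N")
        out.append(
            Contig(
                id=c.id,
                consensus=cons.tobytes().decode("ascii"),
                pileup=pile,
                avg_coverage=float(depth.mean()) if len(depth) else 0.0,
                circular_hint=c.circular_hint,
            )
        )
    return out


def _add_to_pileup(pile: np.ndarray, aln: AlignmentRecord, read_bases: str, L: int) -> None:
    oriented = read_bases if aln.strand == "+" else revcomp(read_bases)
    # clipped reads: the aligner clipped the oriented read's overhang
    if aln.aligned_read_bases < aln.read_length:
        oriented = oriented[aln.read_clip_left : aln.read_clip_left + aln.aligned_read_bases]
    tpos = aln.target_start
    rpos = 0
    for op in aln.edit_ops:
        if op[0] == "match":
            n = op[1]
            idx = np.arange(tpos, tpos + n) % L
            codes = np.array([_CODE[b] for b in oriented[rpos : rpos + n]])
            np.add.at(pile, (idx, codes), 1)
            tpos += n
            rpos += n
        elif op[0] == "mismatch":
            b = oriented[rpos]
            if b != "N":
                pile[tpos % L, _CODE[b]] += 1
            tpos += 1
            rpos += 1
        elif op[0] == "ins":
            rpos += op[1]
        else:  # del
            tpos += op[1]


def _join_by_pairs(
    contigs: list[Contig], pairs: list[ReadPair], params: AssemblyParams
) -> list[Contig]:
    """Merge two linear contigs whose ends overlap and are pair-bridged."""
    if len(contigs) < 2:
        return contigs
    idx = TargetIndex([SequenceRecord(c.id, c.consensus) for c in contigs], params.mapper)
    bridges: dict[tuple[str, str], int] = {}
    for pair in pairs:
        a1 = map_read(pair.mate1, idx)
        a2 = map_read(pair.mate2, idx)
        if a1 is None or a2 is None or a1.target_id == a2.target_id:
            continue
        key = tuple(sorted((a1.target_id, a2.target_id)))
        bridges[key] = bridges.get(key, 0) + 1

    by_id = {c.id: c for c in contigs}
    merged: set[str] = set()
    out: list[Contig] = []
    k = params.kmer_size
    for (ida, idb), n in sorted(bridges.items(), key=lambda kv: -kv[1]):
        if n < params.min_bridge_pairs or ida in merged or idb in merged:
            continue
        ca, cb = by_id[ida], by_id[idb]
        if ca.circular_hint or cb.circular_hint:
            continue
        joined = _try_overlap_join(ca.consensus, cb.consensus, k - 1)
        if joined is None:
            continue
        merged.update((ida, idb))
        out.append(Contig(id=f"{ida}+{idb}", consensus=joined))
    out.extend(c for c in contigs if c.id not in merged)
    out.sort(key=lambda c: (-len(c), c.consensus))
    for i, c in enumerate(out):
        c.id = f"contig_{i + 1}"
    return out


def _try_overlap_join(a: str, b: str, min_ov: int) -> str | None:
    for x, y in ((a, b), (b, a), (a, revcomp(b)), (revcomp(b), a)):
        max_ov = min(len(x), len(y)) - 1
        for ov in range(max_ov, min_ov - 1, -1):
            if x[-ov:] == y[:ov]:
                return x + y[ov:]
    return None


def assemble(reads, params: AssemblyParams | None = None, paired: bool = False) -> list[Contig]:
    """Full pipeline: k-mer graph -> contig extraction -> pair joining -> polish."""
    params = params or AssemblyParams()
    reads = list(reads)
    graph = build_graph(reads, params)
    contigs = extract_contigs(graph, params)
    if not contigs:
        return []
    if paired:
        pair_list = [r for r in reads if isinstance(r, ReadPair)]
        contigs = _join_by_pairs(contigs, pair_list, params)
    contigs = polish(contigs, reads, params)
    return [c for c in contigs if len(c) >= params.min_contig_length]
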