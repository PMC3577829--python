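"""Duplicate-read removal and read-level quality summary.

Shotgun libraries from tiny amounts of degraded template are heavily
PCR-amplified, so the same library molecule is sequenced repeatedly.
Duplicates inflate apparent coverage and must be removed before any
coverage-based inference.  Identity here is exact base-string equality
— a pair is a duplicate only if BOTH mates match an earlier pair mate
for mate — with an optional reverse-complement-aware mode for
single-end data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import ReadPair, SequenceRecord, revcomp


@dataclass
class QcSummary:
    n_reads: int
    pct_q20: float | None  # None when qualities were unavailable
    n_duplicates_removed: int
    n_reads_kept: int


def _pct_q20(records: list[SequenceRecord]) -> float | None:
    total = 0
    passing = 0
    for rec in records:
        if rec.qualities is None:
            return None
        total += len(rec.qualities)
        passing += sum(q >= 20 for q in rec.qualities)
    if total == 0:
        return 0.0
    return 100.0 * passing / total


def remove_duplicates(
    reads: list[SequenceRecord] | list[ReadPair], rc_aware: bool = False
) -> tuple[list, QcSummary]:
    """Keep the first occurrence of each distinct read (or mate-pair).

    Single-end: a read is a duplicate iff its base string equals an
    earlier-kept read's.  Paired: a pair is a duplicate iff both mate
    strings match an earlier-kept pair, mate1 against mate1 and mate2
    against mate2.  ``rc_aware`` additionally treats a single-end read
    equal to the reverse complement of a kept read as a duplicate.
    Mixed single/paired input is rejected.
    """
    reads = list(reads)
    kinds = {isinstance(r, ReadPair) for r in reads}
    if len(kinds) > 1:
        raise ValueError("mixed single-end and paired input")
    paired = kinds == {True}

    seen: set = set()
    kept: list = []
    removed = 0
    for r in reads:
        if paired:
            key = (r.mate1.bases, r.mate2.bases)
        elif rc_aware:
            key = min(r.bases, revcomp(r.bases))
        else:
            key = r.bases
        if key in seen:
            removed += 1
        else:
            seen.add(key)
            kept.append(r)

    flat = []
    for r in reads:
        if paired:
            flat.extend((r.mate1, r.mate2))
        else:
            flat.append(r)
    summary = QcSummary(
        n_reads=len(reads),
        pct_q20=_pct_q20(flat),
        n_duplicates_removed=removed,
        n_reads_kept=len(kept),
    )
    return kept, summary


def qc_summary(reads: list[SequenceRecord]) -> QcSummary:
    """Read-count and %Q20 summary; requires per-base qualities.

    %Q20 is computed per base call: 100 x (calls with Phred >= 20) /
    (total calls).  An empty input yields pct_q20 = 0 by convention.
    """
    reads = list(reads)
    for rec in reads:
        if rec.qualities is None:
            raise ValueError(f"read {rec.id!r} has no qualities")
    pct = _pct_q20(reads)
    return QcSummary(
        n_reads=len(reads),
        pct_q20=pct if pct is not None else 0.0,
        n_duplicates_removed=0,
        n_reads_kept=len(reads),
    )
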