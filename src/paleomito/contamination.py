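"""Metagenomic composition profiling against a reference panel.

Museum specimens accumulate exogenous DNA — human handling, fungal
growth, bacterial colonization — so a shotgun library is a metagenome.
Each non-duplicate read is mapped *independently* against every panel
entry (a named set of reference genomes with its own identity
threshold, e.g. 0.9 for distant proxies and 0.97 for the human genome,
where a strict threshold isolates genuine human contamination).  A read
counts toward every entry it maps to, so entry percentages need not sum
to 100; the unidentified percentage is the share mapping to no entry.
An exclusive best-hit mode is available for users who need a partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import ReadPair, SequenceRecord
from .mapper import MapperParams, TargetIndex, map_read


@dataclass
class PanelEntry:
    name: str
    genomes: list[SequenceRecord]
    min_similarity: float = 0.9
    proxy: bool = False  # e.g. chicken standing in for an unsequenced bird

    def __post_init__(self) -> None:
        if not 0.0 < self.min_similarity <= 1.0:
            raise ValueError("min_similarity must be in (0, 1]")


@dataclass
class CompositionReport:
    n_reads: int
    per_source_pct: dict[str, float]
    unidentified_pct: float
    proxy_entries: list[str] = field(default_factory=list)


def _flatten(reads) -> list[SequenceRecord]:
    out: list[SequenceRecord] = []
    for r in reads:
        if isinstance(r, ReadPair):
            out.extend((r.mate1, r.mate2))
        else:
            out.append(r)
    return out


def profile(
    reads,
    panel: list[PanelEntry],
    length_fraction: float = 0.5,
    exclusive: bool = False,
    mapper_params: MapperParams | None = None,
) -> CompositionReport:
    """Map each read against each panel entry; report percentages.

    In the default independent mode a read is tallied under every entry
    whose thresholds it meets.  In exclusive mode each mapped read is
    assigned only to the entry where it aligns at lowest cost (ties
    broken by panel order).
    """
    if not panel:
        raise ValueError("reference panel must be non-empty")
    names = [e.name for e in panel]
    if len(set(names)) != len(names):
        raise ValueError("panel entry names must be unique")
    flat = _flatten(reads)
    n = len(flat)

    base = mapper_params or MapperParams()
    indexes = []
    for entry in panel:
        params = MapperParams(
            mismatch_cost=base.mismatch_cost,
            insertion_cost=base.insertion_cost,
            deletion_cost=base.deletion_cost,
            min_similarity=entry.min_similarity,
            min_length_fraction=length_fraction,
            band_width=base.band_width,
            seed_k=base.seed_k,
            seed_stride=base.seed_stride,
            max_candidates=base.max_candidates,
        )
        indexes.append(TargetIndex(entry.genomes, params))

    hits = {e.name: 0 for e in panel}
    n_unidentified = 0
    for read in flat:
        alns = [(entry, map_read(read, idx)) for entry, idx in zip(panel, indexes)]
        mapped = [(e, a) for e, a in alns if a is not None]
        if not mapped:
            n_unidentified += 1
            continue
        if exclusive:
            best = min(mapped, key=lambda ea: ea[1].cost)
            hits[best[0].name] += 1
        else:
            for e, _ in mapped:
                hits[e.name] += 1

    pct = {name: 100.0 * c / n if n else 0.0 for name, c in hits.items()}
    return CompositionReport(
        n_reads=n,
        per_source_pct=pct,
        unidentified_pct=100.0 * n_unidentified / n if n else 0.0,
        proxy_entries=[e.name for e in panel if e.proxy],
    )
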