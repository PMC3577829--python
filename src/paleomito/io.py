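"""Sequence and report I/O.

FASTA/FASTQ (Sanger Phred+33) readers and writers over plain or gzipped
files, reverse complementation, TSV report serialization, and GenBank
feature-table extraction.  All internal coordinates are 0-based half-open;
conversion to 1-based happens only when a report is written.

The working alphabet is {A, C, G, T, N}.  Lowercase input is uppercased on
read; any other character (including IUPAC ambiguity codes and U) is
rejected, since every downstream stage assumes this five-letter alphabet.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceFormatError(ValueError):
    """Raised for malformed FASTA/FASTQ input or illegal characters."""


@dataclass
class SequenceRecord:
    """One read or reference sequence with optional per-base qualities."""

    id: str
    bases: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceFormatError("sequence record id must be non-empty")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise SequenceFormatError(
                f"record {self.id!r}: {len(self.qualities)} quality values "
                f"for {len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadPair:
    """A mate pair; mate2 is sequenced from the opposite end of the fragment."""

    mate1: SequenceRecord
    mate2: SequenceRecord
    insert_hint: int | None = None


def _validate_bases(raw: str, label: str) -> str:
    bases = raw.upper()
    bad = set(bases) - VALID_BASES
    if bad:
        raise SequenceFormatError(
            f"record {label!r}: illegal sequence character(s) {sorted(bad)}; "
            "only A/C/G/T/N accepted"
        )
    return bases


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def revcomp(bases: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(bases) - VALID_BASES
    if bad:
        raise SequenceFormatError(f"cannot reverse-complement characters {sorted(bad)}")
    return bases.translate(_COMPLEMENT)[::-1]


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a Sanger-offset (Phred+33) FASTQ file."""
    n_seen = 0
    with _open_text(path) as handle:
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                n_seen += 1
                bases = _validate_bases(str(rec.seq), rec.id)
                quals = list(rec.letter_annotations["phred_quality"])
                yield SequenceRecord(rec.id, bases, quals)
        except ValueError as exc:
            raise SequenceFormatError(
                f"malformed FASTQ near record {n_seen + 1}: {exc}"
            ) from exc


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            if rec.qualities is None:
                raise SequenceFormatError(f"record {rec.id!r} has no qualities")
            qual = "".join(chr(q + 33) for q in rec.qualities)
            handle.write(f"@{rec.id}\n{rec.bases}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records from a FASTA file; wrapped lines allowed, sequences uppercased."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield SequenceRecord(rec.id, _validate_bases(str(rec.seq), rec.id))


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.bases), width):
                handle.write(rec.bases[i : i + width] + "\n")


def read_paired_fastq(path1: str | Path, path2: str | Path) -> Iterator[ReadPair]:
    for m1, m2 in zip(read_fastq(path1), read_fastq(path2), strict=True):
        yield ReadPair(m1, m2)


def write_tsv_report(
    table: Sequence[Sequence], path: str | Path, header: Sequence[str] | None = None
) -> None:
    """Write a rectangular table as UTF-8 TSV with one header line.

    ``table`` may be a pandas DataFrame (header taken from columns) or a
    sequence of rows with ``header`` given separately.
    """
    import pandas as pd

    if isinstance(table, pd.DataFrame):
        table.to_csv(path, sep="\t", index=False)
        return
    if header is None:
        raise ValueError("header required for non-DataFrame tables")
    ncol = len(header)
    for i, row in enumerate(table):
        if len(row) != ncol:
            raise ValueError(f"ragged row {i}: {len(row)} cells, expected {ncol}")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\t".join(str(h) for h in header) + "\n")
        for row in table:
            handle.write("\t".join(repr(c) if isinstance(c, float) else str(c) for c in row) + "\n")


@dataclass
class Region:
    """An annotated feature on a reference: 0-based half-open coordinates."""

    name: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "misc_feature"
    flags: list[str] = field(default_factory=list)


def read_genbank_features(path: str | Path) -> list[Region]:
    """Extract gene name + coordinates + strand for CDS/tRNA/rRNA/misc features."""
    wanted = {"CDS", "tRNA", "rRNA", "misc_feature", "D-loop"}
    regions: list[Region] = []
    for rec in SeqIO.parse(str(path), "genbank"):
        for feat in rec.features:
            if feat.type not in wanted:
                continue
            name = (
                feat.qualifiers.get("gene", [None])[0]
                or feat.qualifiers.get("product", [None])[0]
                or feat.type
            )
            kind = {"D-loop": "control_region"}.get(feat.type, feat.type)
            regions.append(
                Region(
                    name=name,
                    start=int(feat.location.start),
                    end=int(feat.location.end),
                    strand="-" if feat.location.strand == -1 else "+",
                    kind=kind,
                )
            )
    return regions
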