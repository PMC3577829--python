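"""Postmortem damage and sequencing-error quantification.

Because the mitogenome is haploid, every disagreement between a raw
read and the assembled consensus is noise: sequencing error, library
PCR error, or postmortem deamination.  Deamination converts cytosine to
uracil, read as thymine, so genuine damage shows up as an excess of
C->T mismatches (and G->A when the sequencer reported the complementary
strand) over the other ten substitution types.

This module computes:

* the overall error rate: mismatch bases / aligned read bases,
* the 12-category directed mismatch spectrum (consensus base -> read
  base), normalized both per opportunity (count / aligned consensus-X
  columns) and per total mismatch,
* a damage flag: C->T and G->A rates each a chosen fold above the
  median of the other ten rates,
* per-site allele summaries from the polishing pileup (count of
  polymorphic sites and the distribution of major-allele frequencies).

All reads are oriented onto the consensus plus strand before counting:
a minus-strand alignment contributes the reverse complement of its
read, which is what makes the C->T / G->A asymmetry observable.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median

import numpy as np

from .mapper import AlignmentRecord

BASES = "ACGT"
SUBSTITUTIONS = [(a, b) for a in BASES for b in BASES if a != b]


@dataclass
class MismatchSpectrum:
    counts: dict[tuple[str, str], int]  # (consensus_base, read_base) -> count
    opportunities: dict[str, int]  # consensus_base -> aligned columns
    total_mismatch_bases: int
    total_aligned_bases: int

    def rate(self, cons: str, read: str) -> float:
        """Per-opportunity rate: mismatches / aligned consensus-`cons` columns."""
        opp = self.opportunities[cons]
        if opp == 0:
            raise ZeroDivisionError(f"no aligned columns with consensus base {cons}")
        return self.counts[(cons, read)] / opp

    def share(self, cons: str, read: str) -> float:
        """Per-total-mismatch share of one category."""
        if self.total_mismatch_bases == 0:
            return 0.0
        return self.counts[(cons, read)] / self.total_mismatch_bases


@dataclass
class DamageDiagnostics:
    flagged: bool
    fold_over_median: dict[tuple[str, str], float]
    ct_ga_share_of_aligned: float
    ct_ga_share_below_1pct: bool


@dataclass
class AlleleSummary:
    n_polymorphic_sites: int
    mean_major_freq: float | None
    sd_major_freq: float | None
    min_major_freq: float | None
    max_major_freq: float | None


def error_rate(alignments: list[AlignmentRecord]) -> float:
    """Mismatch bases / aligned read bases over accepted alignments.

    Inserted and deleted bases count neither in the numerator nor the
    denominator (substitution-only statistic); N-containing columns are
    excluded from the numerator.
    """
    total = sum(a.matches + a.mismatches + a.n_columns for a in alignments)
    if total == 0:
        raise ValueError("no aligned bases; cannot compute an error rate")
    return sum(a.mismatches for a in alignments) / total


def error_rate_from_counts(n_mismatch_bp: int, n_total_bp: int) -> float:
    """The same statistic from pre-tallied counts."""
    if n_total_bp <= 0:
        raise ValueError("total bases must be positive")
    return n_mismatch_bp / n_total_bp


def mismatch_spectrum(
    alignments: list[AlignmentRecord], consensus: str
) -> MismatchSpectrum:
    """Count the 12 directed substitution categories against a consensus.

    Alignments must target the given consensus.  Mismatch columns
    increment counts[consensus_base -> read_base]; N in either sequence
    excludes the column from both counts and opportunities.
    """
    counts = {s: 0 for s in SUBSTITUTIONS}
    opps = {b: 0 for b in BASES}
    total_mm = 0
    total_aligned = 0
    L = len(consensus)
    for aln in alignments:
        tpos = aln.target_start
        for op in aln.edit_ops:
            if op[0] == "match":
                n = op[1]
                for i in range(n):
                    cb = consensus[(tpos + i) % L]
                    if cb in opps:
                        opps[cb] += 1
                        total_aligned += 1
                tpos += n
            elif op[0] == "mismatch":
                rb, cb = op[1], op[2]
                if rb in opps and cb in opps:
                    opps[cb] += 1
                    counts[(cb, rb)] += 1
                    total_mm += 1
                    total_aligned += 1
                tpos += 1
            elif op[0] == "del":
                tpos += op[1]
            # ins consumes no consensus position
    return MismatchSpectrum(counts, opps, total_mm, total_aligned)


def damage_flag(spectrum: MismatchSpectrum, fold: float = 2.5) -> DamageDiagnostics:
    """Deamination signature test on the per-opportunity spectrum.

    Flags damage when the C->T and G->A rates are each at least ``fold``
    times the median of the other ten substitution rates.  When that
    median is zero, any strictly positive C->T and G->A rate flags.
    """
    for b in BASES:
        if spectrum.opportunities[b] == 0:
            raise ValueError(f"zero aligned columns for consensus base {b}")
    rates = {s: spectrum.rate(*s) for s in SUBSTITUTIONS}
    ct, ga = rates[("C", "T")], rates[("G", "A")]
    others = [r for s, r in rates.items() if s not in (("C", "T"), ("G", "A"))]
    med = median(others)
    if med == 0.0:
        flagged = ct > 0.0 and ga > 0.0
        folds = {s: float("inf") if r > 0 else 0.0 for s, r in rates.items()}
    else:
        flagged = ct >= fold * med and ga >= fold * med
        folds = {s: r / med for s, r in rates.items()}
    ct_ga_share = (
        (spectrum.counts[("C", "T")] + spectrum.counts[("G", "A")])
        / spectrum.total_aligned_bases
        if spectrum.total_aligned_bases
        else 0.0
    )
    return DamageDiagnostics(
        flagged=flagged,
        fold_over_median=folds,
        ct_ga_share_of_aligned=ct_ga_share,
        ct_ga_share_below_1pct=ct_ga_share < 0.01,
    )


def allele_summary(pileup: np.ndarray) -> AlleleSummary:
    """Summarize major-allele frequencies at polymorphic pileup columns.

    A polymorphic site is a column where at least two bases have count
    >= 1.  With a haploid source and modest error rates the major-allele
    frequency at such sites stays near 1; systematically lower values
    would suggest mixture, heteroplasmy, or a collapsed nuclear copy.
    """
    totals = pileup.sum(axis=1)
    n_alleles = (pileup > 0).sum(axis=1)
    poly = n_alleles >= 2
    n_poly = int(poly.sum())
    if n_poly == 0:
        return AlleleSummary(0, None, None, None, None)
    major = pileup[poly].max(axis=1) / totals[poly]
    return AlleleSummary(
        n_polymorphic_sites=n_poly,
        mean_major_freq=float(major.mean()),
        sd_major_freq=float(major.std(ddof=1)) if n_poly > 1 else 0.0,
        min_major_freq=float(major.min()),
        max_major_freq=float(major.max()),
    )


def major_frequency_track(pileup: np.ndarray) -> np.ndarray:
    """Per-site major-allele frequency (NaN where depth is zero)."""
    totals = pileup.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals > 0, pileup.max(axis=1) / totals, np.nan)
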