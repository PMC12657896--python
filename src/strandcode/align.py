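"""Smith-Waterman alignment and DNA-level error classification.

Errors are measured at the nucleotide level, not the bit level: under the
two-bits-per-base mapping a single base substitution corresponds to one or
two bit flips, so bit-level rates would be misleading.  A local alignment
of the query (read, or decoded strand) against the reference is classified
column by column: a gap in the reference is an insertion, a gap in the
query a deletion, and a base mismatch a substitution.  Rates divide by the
reference length, and each error's position is normalized by reference
length for positional histograms.

The alignment engine is Bio.Align.PairwiseAligner in local mode (linear
gaps); scoring defaults to match +2 / mismatch -1 / gap -2 and is pinned
by the tests.  Tie-breaking among co-optimal alignments follows the
aligner's deterministic enumeration order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

__all__ = [
    "Scoring",
    "PairwiseAlignment",
    "ErrorEvent",
    "ErrorReport",
    "smith_waterman",
    "classify_errors",
    "error_rate",
    "measure_pair",
    "dna_error_rate",
    "trimmed_error_rates",
    "positional_distribution",
]


@dataclass(frozen=True)
class Scoring:
    match: float = 2.0
    mismatch: float = -1.0
    gap: float = -2.0

    def aligner(self) -> Align.PairwiseAligner:
        a = Align.PairwiseAligner()
        a.mode = "local"
        a.match_score = self.match
        a.mismatch_score = self.mismatch
        a.open_gap_score = self.gap
        a.extend_gap_score = self.gap
        return a


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class PairwiseAlignment:
    """A local alignment; aligned strings carry ``-`` for gaps."""

    aligned_ref: str
    aligned_query: str
    score: float
    ref_start: int  # first reference base covered by the local alignment
    ref_end: int    # one past the last covered reference base
    ref_length: int
    query_length: int

    def __post_init__(self):
        if len(self.aligned_ref) != len(self.aligned_query):
            raise ValueError("aligned strings must have equal length")


@dataclass(frozen=True)
class ErrorEvent:
    kind: str       # "ins" | "del" | "sub"
    ref_pos: int    # reference index (insertions: index of the next ref base)
    norm_pos: float


@dataclass
class ErrorReport:
    """Insertion/deletion/substitution counts against a reference frame."""

    insertions: int = 0
    deletions: int = 0
    substitutions: int = 0
    reference_length: int = 0
    events: list = field(default_factory=list)

    @property
    def total_errors(self) -> int:
        return self.insertions + self.deletions + self.substitutions

    def _rate(self, count: int) -> float:
        if self.reference_length <= 0:
            raise ValueError("reference_length must be positive to compute rates")
        return count / self.reference_length

    @property
    def insertion_rate(self) -> float:
        return self._rate(self.insertions)

    @property
    def deletion_rate(self) -> float:
        return self._rate(self.deletions)

    @property
    def substitution_rate(self) -> float:
        return self._rate(self.substitutions)

    @property
    def total_rate(self) -> float:
        return self._rate(self.total_errors)

    def merged(self, other: "ErrorReport") -> "ErrorReport":
        return ErrorReport(
            self.insertions + other.insertions,
            self.deletions + other.deletions,
            self.substitutions + other.substitutions,
            self.reference_length + other.reference_length,
            self.events + other.events,
        )


def smith_waterman(ref: str, query: str, scoring: Scoring = DEFAULT_SCORING) -> PairwiseAlignment:
    """Optimal local alignment of ``query`` against ``ref``."""
    if not ref or not query:
        raise ValueError("smith_waterman requires non-empty sequences")
    aln = scoring.aligner().align(ref, query)[0]
    coords = aln.coordinates
    return PairwiseAlignment(
        aligned_ref=aln[0],
        aligned_query=aln[1],
        score=float(aln.score),
        ref_start=int(coords[0][0]),
        ref_end=int(coords[0][-1]),
        ref_length=len(ref),
        query_length=len(query),
    )


def classify_errors(aln: PairwiseAlignment) -> ErrorReport:
    """Classify alignment columns into insertions, deletions, substitutions."""
    report = ErrorReport(reference_length=aln.ref_length)
    ref_pos = aln.ref_start
    L = aln.ref_length
    for r, q in zip(aln.aligned_ref, aln.aligned_query):
        if r == "-":
            report.insertions += 1
            report.events.append(ErrorEvent("ins", ref_pos, ref_pos / L))
        elif q == "-":
            report.deletions += 1
            report.events.append(ErrorEvent("del", ref_pos, ref_pos / L))
            ref_pos += 1
        elif r != q:
            report.substitutions += 1
            report.events.append(ErrorEvent("sub", ref_pos, ref_pos / L))
            ref_pos += 1
        else:
            ref_pos += 1
    return report


def error_rate(report: ErrorReport) -> float:
    """Total DNA-level error rate, (ins + del + sub) / reference length."""
    return report.total_rate


def measure_pair(ref: str, query: str, scoring: Scoring = DEFAULT_SCORING) -> ErrorReport:
    """Align one reference/query pair and classify its errors."""
    return classify_errors(smith_waterman(ref, query, scoring))


def dna_error_rate(
    ref: str,
    query: str,
    scoring: Scoring = DEFAULT_SCORING,
    count_uncovered: bool = True,
) -> float:
    """DNA-level error rate between a reference and a read-back sequence.

    Classified errors inside the local alignment are divided by the
    reference length.  With ``count_uncovered`` (the default) reference
    bases outside the aligned region also count as errors, so a decode
    failure that destroys most of a strand is not hidden by a short
    surviving local match.
    """
    aln = smith_waterman(ref, query, scoring)
    report = classify_errors(aln)
    errors = report.total_errors
    if count_uncovered:
        errors += aln.ref_start + (aln.ref_length - aln.ref_end)
    return errors / aln.ref_length


def trimmed_error_rates(pairs, K: int, scoring: Scoring = DEFAULT_SCORING) -> ErrorReport:
    """Aggregate error rates with the first and last ``K`` reference bases removed.

    Only errors whose reference position lies in ``[K, L-K)`` are counted,
    and the denominator shrinks accordingly; ``K=0`` reproduces the
    untrimmed aggregate.
    """
    if K < 0:
        raise ValueError("K must be non-negative")
    total = ErrorReport()
    for ref, query in pairs:
        L = len(ref)
        if 2 * K >= L:
            raise ValueError(
                f"K={K} removes the whole reference (length {L})"
            )
        full = measure_pair(ref, query, scoring)
        kept = [ev for ev in full.events if K <= ev.ref_pos < L - K]
        counts = {"ins": 0, "del": 0, "sub": 0}
        for ev in kept:
            counts[ev.kind] += 1
        total = total.merged(
            ErrorReport(counts["ins"], counts["del"], counts["sub"], L - 2 * K, kept)
        )
    return total


def positional_distribution(reports, bins: int = 20):
    """Per-type histogram of normalized error positions over [0, 1].

    Returns ``(edges, {kind: counts})``; each type's bin mass sums to its
    total event count across the reports.
    """
    if bins < 1:
        raise ValueError("bins must be at least 1")
    edges = np.linspace(0.0, 1.0, bins + 1)
    hist = {}
    for kind in ("ins", "del", "sub"):
        positions = [
            ev.norm_pos for rep in reports for ev in rep.events if ev.kind == kind
        ]
        hist[kind], _ = np.histogram(positions, bins=edges)
    return edges, hist
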