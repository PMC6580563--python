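"""End-trimming and read-level filters.

Quality end-trimming uses the partial-sum rule familiar from BWA's read
trimmer, applied independently to each end: for threshold ``Q``, the 3'
cut point is the position ``x`` maximising ``sum(Q - score[i] for i in
x..L-1)`` provided that maximum is positive (ties resolved toward
trimming more), and symmetrically for the 5' end. Unlike a naive
"strip while score < Q" loop this can cut past an isolated good base
inside a low-quality tail. Interior bases are never removed.

Filters judge the read *after* all trimming and adapter removal:

* quality filter (``-q q,f``): fail when the fraction of bases with
  score >= q is below f;
* N-ratio filter (``-r r``): fail when the fraction of N calls exceeds r;
* length filter (``-m`` / ``--max-length``): fail when the read is
  shorter than the minimum or longer than the maximum.

All failing criteria are recorded (not just the first), and paired-end
verdicts are synchronised so that a read whose mate fails is itself
discarded (``mate_failed``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import FrozenSet, Optional, Set, Tuple

from .adapter_align import AdapterMatch, AdapterSpec
from .fastq_io import FastqRecord

__all__ = [
    "FilterCriterion",
    "FilterParams",
    "ReadVerdict",
    "quality_trim_ends",
    "n_trim_ends",
    "quality_filter",
    "n_ratio_filter",
    "length_filter",
    "judge_pair",
]


class FilterCriterion(enum.Enum):
    QUALITY = "quality_filter"
    N_RATIO = "n_ratio"
    TOO_SHORT = "too_short"
    TOO_LONG = "too_long"
    MATE_FAILED = "mate_failed"


@dataclass(frozen=True)
class FilterParams:
    """Trimming/filtering configuration; ``None`` disables a stage.

    quality_low:
        Phred threshold for partial-sum end-trimming (``-Q``).
    trim_n:
        Strip N runs from both ends (``-n``).
    quality_filter:
        ``(q, f)``: discard when fraction of bases with score >= q is
        below f (``-q q,f``).
    ratio_n:
        Discard when the N fraction strictly exceeds this (``-r``).
    min_length / max_length:
        Post-trim length window (``-m`` / ``--max-length``).
    """

    quality_low: Optional[int] = None
    trim_n: bool = False
    quality_filter: Optional[Tuple[int, float]] = None
    ratio_n: Optional[float] = None
    min_length: Optional[int] = None
    max_length: Optional[int] = None

    def __post_init__(self) -> None:
        if self.quality_filter is not None:
            q, f = self.quality_filter
            if not 0.0 <= f <= 1.0:
                raise ValueError("quality filter fraction must be in [0, 1]")
            if q < 0:
                raise ValueError("quality filter threshold must be >= 0")
        if self.ratio_n is not None and not 0.0 <= self.ratio_n <= 1.0:
            raise ValueError("ratio_n must be in [0, 1]")
        if self.min_length is not None and self.min_length < 0:
            raise ValueError("min_length must be >= 0")
        if (
            self.min_length is not None
            and self.max_length is not None
            and self.min_length > self.max_length
        ):
            raise ValueError("min_length must not exceed max_length")


@dataclass(frozen=True)
class ReadVerdict:
    """Per-read outcome after trimming, adapter removal and filtering."""

    record: FastqRecord
    failed_criteria: FrozenSet[FilterCriterion] = frozenset()
    adapter: Optional[AdapterSpec] = None
    adapter_match: Optional[AdapterMatch] = None

    @property
    def passed(self) -> bool:
        return not self.failed_criteria


def quality_trim_ends(record: FastqRecord, quality_low: int) -> FastqRecord:
    """Partial-sum trim of both ends against threshold ``quality_low``.

    Each end is treated independently on the original read; if the two
    cuts cross, the result is empty. A cut is only made when the maximal
    partial sum is strictly positive; ties between equal maxima trim the
    larger number of bases.
    """
    scores = record.scores
    L = len(scores)
    # 3' end: best suffix start x (L = no cut); iterate from the end so a
    # smaller x (more trimmed) wins ties via >=.
    best, running, cut3 = 0, 0, L
    for i in range(L - 1, -1, -1):
        running += quality_low - scores[i]
        if running > 0 and running >= best:
            best, cut3 = running, i
    # 5' end: best prefix stop y (0 = no cut); >= prefers larger y.
    best, running, cut5 = 0, 0, 0
    for i in range(L):
        running += quality_low - scores[i]
        if running > 0 and running >= best:
            best, cut5 = running, i + 1
    if cut5 >= cut3:
        return record.slice(0, 0)
    return record.slice(cut5, cut3)


def n_trim_ends(record: FastqRecord) -> FastqRecord:
    """Strip maximal N runs from both ends; interior Ns are kept."""
    seq = record.seq
    start = 0
    stop = len(seq)
    while start < stop and seq[start] == "N":
        start += 1
    while stop > start and seq[stop - 1] == "N":
        stop -= 1
    return record.slice(start, stop)


def quality_filter(record: FastqRecord, q: int, f: float) -> bool:
    """True iff the read passes: fraction of bases with score >= q is >= f.

    Empty reads pass vacuously (their fate is decided by the length
    filter).
    """
    L = len(record)
    if L == 0:
        return True
    good = sum(1 for s in record.scores if s >= q)
    return not (good / L < f)


def n_ratio_filter(record: FastqRecord, r: float) -> bool:
    """True iff the read passes: N fraction does not exceed ``r``."""
    L = len(record)
    if L == 0:
        return True
    return not (record.seq.count("N") / L > r)


def length_filter(
    record: FastqRecord, min_length: Optional[int], max_length: Optional[int]
) -> Set[FilterCriterion]:
    """Failing length criteria (empty set = pass)."""
    failed: Set[FilterCriterion] = set()
    if min_length is not None and len(record) < min_length:
        failed.add(FilterCriterion.TOO_SHORT)
    if max_length is not None and len(record) > max_length:
        failed.add(FilterCriterion.TOO_LONG)
    return failed


def judge_pair(v1: ReadVerdict, v2: ReadVerdict) -> Tuple[ReadVerdict, ReadVerdict]:
    """Synchronise mate verdicts: one failing mate discards both.

    A passing read whose mate failed is marked with ``MATE_FAILED``;
    reads that failed on their own keep their own criteria.
    """
    if v1.passed and not v2.passed:
        v1 = replace(v1, failed_criteria=frozenset({FilterCriterion.MATE_FAILED}))
    elif v2.passed and not v1.passed:
        v2 = replace(v2, failed_criteria=frozenset({FilterCriterion.MATE_FAILED}))
    return v1, v2
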