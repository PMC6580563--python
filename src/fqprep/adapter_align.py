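"""Adapter detection and removal by extended semiglobal alignment.

An adapter is aligned to a read with free end gaps so that it may match
internally in full or hang off a read end in part ("adapter read-through":
when the insert is shorter than the read, sequencing runs into the 3'
adapter and only a prefix of it appears at the read's 3' end). All edit
operations have unit cost; the error rate of an alignment is the number
of errors (mismatches + insertions + deletions) divided by the number of
*aligned adapter bases*, and only alignments with

    error_rate <= max_error_rate   and   aligned adapter bases >= min_overlap

are reported. Among qualifying alignments the best one maximises the
number of identically matched bases, breaking ties by fewer errors, then
by the smallest (5'-most) read start, then smallest read stop, then
smallest adapter start — a total order that makes results deterministic.

``N`` matches nothing: an ``N`` in either sequence aligned against any
base counts as a mismatch.

The dynamic programme is layered by error count and abandons rows of a
column once the running error count exceeds ``floor(e * |adapter|)``; a
full exact-substring scan short-circuits the DP entirely when the whole
adapter occurs verbatim in the read.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

from .fastq_io import FastqRecord

__all__ = [
    "AdapterKind",
    "AdapterSpec",
    "AlignParams",
    "AdapterMatch",
    "exact_search",
    "semiglobal_align",
    "find_best_match",
    "remove_adapter",
]


class AdapterKind(enum.Enum):
    """Where the adapter is expected relative to the read."""

    THREE_PRIME = "3p"
    FIVE_PRIME = "5p"
    ANYWHERE = "anywhere"


@dataclass(frozen=True)
class AdapterSpec:
    """One adapter sequence and its matching rules.

    ``anchored`` requires the full adapter to abut the respective read
    end; it is meaningless for ``ANYWHERE`` adapters and rejected there.
    """

    seq: str
    kind: AdapterKind = AdapterKind.THREE_PRIME
    anchored: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("adapter sequence must be non-empty")
        if self.anchored and self.kind is AdapterKind.ANYWHERE:
            raise ValueError("an 'anywhere' adapter cannot be anchored")
        object.__setattr__(self, "seq", self.seq.upper())


@dataclass(frozen=True)
class AlignParams:
    """Alignment thresholds: ``-e``, ``-O`` and ``--no-indels``."""

    max_error_rate: float = 0.1
    min_overlap: int = 3
    allow_indels: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_error_rate < 1.0):
            raise ValueError("max_error_rate must be in [0, 1)")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass(frozen=True)
class AdapterMatch:
    """An accepted adapter-to-read alignment (0-based, half-open)."""

    read_start: int
    read_stop: int
    adapter_start: int
    adapter_stop: int
    errors: int
    matches: int

    @property
    def aligned_length(self) -> int:
        """Number of aligned adapter bases (error-rate denominator)."""
        return self.adapter_stop - self.adapter_start

    @property
    def error_rate(self) -> float:
        return self.errors / self.aligned_length


# Candidate tuples: (matches, errors, read_start, read_stop, a_start, a_stop)
_Cand = Tuple[int, int, int, int, int, int]


def _cand_key(c: _Cand) -> Tuple[int, int, int, int, int]:
    matches, errors, rstart, rstop, astart, astop = c
    return (-matches, errors, rstart, rstop, astart)


def _eq(a: str, b: str) -> bool:
    return a == b and a != "N"


def exact_search(read_seq: str, adapter_seq: str) -> Optional[AdapterMatch]:
    """Leftmost verbatim occurrence of the full adapter, if any.

    An adapter containing ``N`` can never match exactly (``N`` matches
    nothing here), so the search is skipped for such adapters and the
    caller falls through to the dynamic programme.
    """
    read = read_seq.upper()
    adapter = adapter_seq.upper()
    if not read or not adapter or "N" in adapter:
        return None
    pos = read.find(adapter)
    while pos != -1:
        window = read[pos : pos + len(adapter)]
        if "N" not in window:
            return AdapterMatch(
                read_start=pos,
                read_stop=pos + len(adapter),
                adapter_start=0,
                adapter_stop=len(adapter),
                errors=0,
                matches=len(adapter),
            )
        pos = read.find(adapter, pos + 1)
    return None


def _back_candidates_dp(
    read: str,
    aseq: str,
    e: float,
    min_overlap: int,
    anchored: bool,
    prefer_max_start: bool,
) -> List[_Cand]:
    """Candidates for a 3'-type adapter: adapter prefix aligned, free read prefix.

    Allowed end conditions: the full adapter anywhere in the read, or an
    adapter prefix ending exactly at the read's 3' end. Layered by exact
    error count ``c`` with cap ``K = floor(e * len(adapter))``; per cell
    and layer, the maximum match count (and the preferred start among the
    maximisers) is propagated.
    """
    n, m = len(read), len(aseq)
    K = int(e * m)
    NEG = -1
    rng = range(K + 1)

    # prev/cur: per cost layer, per adapter row: match count (-1 unreachable)
    # and the alignment's read start.
    prev_m = [[NEG] * (m + 1) for _ in rng]
    prev_s = [[0] * (m + 1) for _ in rng]
    for c in rng:
        if c <= m:
            prev_m[c][c] = 0  # c leading adapter bases against gaps
    prev_last = min(K, m)

    cands: List[_Cand] = []

    def better(mat: int, start: int, cur_mat: int, cur_start: int) -> bool:
        if mat != cur_mat:
            return mat > cur_mat
        if prefer_max_start:
            return start > cur_start
        return start < cur_start

    for j in range(1, n + 1):
        cur_m = [[NEG] * (m + 1) for _ in rng]
        cur_s = [[0] * (m + 1) for _ in rng]
        for c in rng:
            if j - c >= 0:  # leading read bases against gaps
                cur_m[c][0] = 0
                cur_s[c][0] = j - c
        rchar = read[j - 1]
        row_reachable = True  # row 0 always is
        cur_last = 0
        for i in range(1, m + 1):
            if i > prev_last + 1 and not row_reachable:
                break
            achar = aseq[i - 1]
            hit = _eq(achar, rchar)
            sub_cost = 0 if hit else 1
            inc = 1 if hit else 0
            any_reach = False
            for c in rng:
                best_mat, best_start = NEG, 0
                dc = c - sub_cost
                if dc >= 0 and prev_m[dc][i - 1] >= 0:
                    mat = prev_m[dc][i - 1] + inc
                    if mat > best_mat or (
                        mat == best_mat and better(mat, prev_s[dc][i - 1], best_mat, best_start)
                    ):
                        best_mat, best_start = mat, prev_s[dc][i - 1]
                if c >= 1:
                    if cur_m[c - 1][i - 1] >= 0:  # adapter base against gap
                        mat = cur_m[c - 1][i - 1]
                        if best_mat < 0 or better(mat, cur_s[c - 1][i - 1], best_mat, best_start):
                            best_mat, best_start = mat, cur_s[c - 1][i - 1]
                    if prev_m[c - 1][i] >= 0:  # read base against gap
                        mat = prev_m[c - 1][i]
                        if best_mat < 0 or better(mat, prev_s[c - 1][i], best_mat, best_start):
                            best_mat, best_start = mat, prev_s[c - 1][i]
                if best_mat >= 0:
                    cur_m[c][i] = best_mat
                    cur_s[c][i] = best_start
                    any_reach = True
            if any_reach:
                cur_last = i
            row_reachable = any_reach

        # full adapter aligned, ending inside the read (or at its end)
        if not anchored or j == n:
            for c in rng:
                if cur_m[c][m] >= 0 and c <= e * m and m >= min_overlap:
                    cands.append((cur_m[c][m], c, cur_s[c][m], j, 0, m))
        # adapter prefix running off the read's 3' end (i == m collected above)
        if j == n and not anchored:
            for i in range(max(min_overlap, 1), m):
                for c in rng:
                    if cur_m[c][i] >= 0 and c <= e * i:
                        cands.append((cur_m[c][i], c, cur_s[c][i], n, 0, i))
        prev_m, prev_s = cur_m, cur_s
        prev_last = cur_last
    return cands


def _back_candidates_shifts(
    read: str, aseq: str, e: float, min_overlap: int, anchored: bool
) -> List[_Cand]:
    """Indel-free 3'-type candidates: per-shift Hamming comparison."""
    n, m = len(read), len(aseq)
    cands: List[_Cand] = []
    for s in range(n):
        L = min(m, n - s)
        if L < min_overlap:
            continue
        if anchored and (L != m or s + L != n):
            continue
        matches = sum(1 for k in range(L) if _eq(aseq[k], read[s + k]))
        errors = L - matches
        if errors <= e * L:
            cands.append((matches, errors, s, s + L, 0, L))
    return cands


def _reverse_cands(cands: Iterable[_Cand], n: int, m: int) -> List[_Cand]:
    """Map candidates computed on reversed strings back to original coordinates."""
    return [
        (mat, err, n - rstop, n - rstart, m - astop, m - astart)
        for (mat, err, rstart, rstop, astart, astop) in cands
    ]


def _candidates(read: str, adapter: AdapterSpec, params: AlignParams) -> List[_Cand]:
    aseq = adapter.seq
    e = params.max_error_rate
    O = params.min_overlap

    def back(r: str, a: str, anchored: bool, prefer_max_start: bool) -> List[_Cand]:
        if params.allow_indels:
            return _back_candidates_dp(r, a, e, O, anchored, prefer_max_start)
        return _back_candidates_shifts(r, a, e, O, anchored)

    if adapter.kind is AdapterKind.THREE_PRIME:
        return back(read, aseq, adapter.anchored, prefer_max_start=False)
    if adapter.kind is AdapterKind.FIVE_PRIME:
        rev = back(read[::-1], aseq[::-1], adapter.anchored, prefer_max_start=True)
        return _reverse_cands(rev, len(read), len(aseq))
    # anywhere: union of the 3'-type and 5'-type boundary conditions
    out: Set[_Cand] = set(back(read, aseq, False, prefer_max_start=False))
    rev = back(read[::-1], aseq[::-1], False, prefer_max_start=True)
    out.update(_reverse_cands(rev, len(read), len(aseq)))
    return list(out)


def semiglobal_align(
    read_seq: str, adapter: AdapterSpec, params: AlignParams
) -> Optional[AdapterMatch]:
    """Best qualifying alignment of ``adapter`` to ``read_seq``, or ``None``."""
    if not read_seq:
        return None
    read = read_seq.upper()
    cands = _candidates(read, adapter, params)
    if not cands:
        return None
    best = min(cands, key=_cand_key)
    matches, errors, rstart, rstop, astart, astop = best
    return AdapterMatch(
        read_start=rstart,
        read_stop=rstop,
        adapter_start=astart,
        adapter_stop=astop,
        errors=errors,
        matches=matches,
    )


def find_best_match(
    read_seq: str, adapters: Sequence[AdapterSpec], params: AlignParams
) -> Optional[Tuple[AdapterSpec, AdapterMatch]]:
    """Best match over several adapters.

    Per adapter, an exact full-length occurrence short-circuits the DP
    (valid only for non-anchored adapters, since an anchored adapter must
    abut a read end). Across adapters the winner maximises matched bases,
    ties going to fewer errors, then to the earlier adapter in the
    caller-supplied list.
    """
    if not adapters:
        raise ValueError("adapters must be non-empty")
    best: Optional[Tuple[int, int, int, AdapterSpec, AdapterMatch]] = None
    for idx, adapter in enumerate(adapters):
        match: Optional[AdapterMatch] = None
        if not adapter.anchored and len(adapter.seq) >= params.min_overlap:
            match = exact_search(read_seq, adapter.seq)
        if match is None:
            match = semiglobal_align(read_seq, adapter, params)
        if match is None:
            continue
        key = (-match.matches, match.errors, idx)
        if best is None or key < (best[0], best[1], best[2]):
            best = (key[0], key[1], idx, adapter, match)
    if best is None:
        return None
    return best[3], best[4]


def remove_adapter(
    record: FastqRecord, adapter: AdapterSpec, match: AdapterMatch
) -> FastqRecord:
    """Cut the matched adapter out of the read.

    3' and "anywhere" matches remove everything from the match's read
    start through the read's 3' end; 5' matches remove everything from
    the read's 5' end through the match's read stop. Quality values are
    cut identically. The result may be empty.
    """
    if not (0 <= match.read_start <= match.read_stop <= len(record)):
        raise ValueError(
            f"match interval [{match.read_start}, {match.read_stop}) out of bounds "
            f"for read of length {len(record)}"
        )
    if adapter.kind is AdapterKind.FIVE_PRIME:
        return record.slice(match.read_stop, len(record))
    return record.slice(0, match.read_start)
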