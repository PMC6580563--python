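"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results by exhaustive enumeration
over placements and bounded-error edit scripts, sharing no code with the
package's banded dynamic programme. The alignment oracle enumerates
every allowed adapter sub-interval and read start explicitly and runs a
small set-valued tabulation of all (error, match) outcomes per end cell;
it is itself cross-validated against a pure recursive edit-script
enumerator on tiny instances (see test_adapter_align).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Set, Tuple

Cand = Tuple[int, int, int, int, int, int]  # matches, errors, rs, rt, as_, ast


def _eq(a: str, b: str) -> bool:
    return a == b and a != "N"


def _cand_key(c: Cand):
    matches, errors, rstart, rstop, astart, astop = c
    return (-matches, errors, rstart, rstop, astart)


def _interval_sets(kind: str, anchored: bool, m: int, min_overlap: int):
    """Allowed (adapter_start, adapter_stop, needs_t_at_end, needs_s_at_start)."""
    out = []
    if kind in ("3p", "anywhere"):
        if anchored:
            out.append((0, m, True, False))
        else:
            for b in range(max(1, min_overlap), m + 1):
                out.append((0, b, b < m, False))
    if kind in ("5p", "anywhere"):
        if anchored:
            out.append((0, m, False, True))
        else:
            for a in range(0, m - max(1, min_overlap) + 1):
                out.append((a, m, False, a > 0))
    return out


def _pair_outcomes(
    read: str, adapter: str, a: int, b: int, s: int, budget: int
) -> Dict[int, Dict[int, int]]:
    """All global alignments of adapter[a:b] vs read[s:t] for every t.

    Returns {t: {errors: max_matches}} over alignments with at most
    ``budget`` errors. Cells outside the |diagonal| <= budget band are
    unreachable within the budget and skipped.
    """
    n = len(read)
    # state[(i, j)] = {cost: max matches} aligning adapter[a:i] to read[s:j]
    state: Dict[Tuple[int, int], Dict[int, int]] = {(a, s): {0: 0}}
    for i in range(a, b + 1):
        for j in range(s, n + 1):
            if (i, j) == (a, s):
                continue
            if abs((i - a) - (j - s)) > budget:
                continue
            cell: Dict[int, int] = {}

            def fold(src: Tuple[int, int], dcost: int, dmatch: int) -> None:
                for cost, matches in state.get(src, {}).items():
                    c2 = cost + dcost
                    if c2 > budget:
                        continue
                    m2 = matches + dmatch
                    if cell.get(c2, -1) < m2:
                        cell[c2] = m2

            if i > a and j > s:
                hit = _eq(adapter[i - 1], read[j - 1])
                fold((i - 1, j - 1), 0 if hit else 1, 1 if hit else 0)
            if i > a:
                fold((i - 1, j), 1, 0)  # adapter base against gap
            if j > s:
                fold((i, j - 1), 1, 0)  # read base against gap
            if cell:
                state[(i, j)] = cell
    return {
        j: state[(b, j)] for j in range(s, n + 1) if (b, j) in state
    }


def align_oracle(
    read: str,
    adapter: str,
    kind: str,
    anchored: bool,
    e: float,
    min_overlap: int,
    allow_indels: bool,
) -> Optional[Cand]:
    """Best qualifying alignment by exhaustive enumeration, or None.

    ``kind`` is one of '3p', '5p', 'anywhere'. The objective and
    tie-break order are: most matches, fewest errors, smallest read
    start, smallest read stop, smallest adapter start.
    """
    read = read.upper()
    adapter = adapter.upper()
    n, m = len(read), len(adapter)
    if n == 0 or m == 0:
        return None
    cands: Set[Cand] = set()
    if allow_indels:
        budget = int(e * m)
        for a, b, t_at_end, s_at_start in _interval_sets(kind, anchored, m, min_overlap):
            alen = b - a
            if alen < min_overlap:
                continue
            starts = [0] if s_at_start else range(0, n + 1)
            for s in starts:
                for t, outcomes in _pair_outcomes(read, adapter, a, b, s, budget).items():
                    if t_at_end and t != n:
                        continue
                    for errors, matches in outcomes.items():
                        if errors <= e * alen:
                            cands.add((matches, errors, s, t, a, b))
    else:
        for a, b, t_at_end, s_at_start in _interval_sets(kind, anchored, m, min_overlap):
            alen = b - a
            if alen < min_overlap:
                continue
            starts = [0] if s_at_start else range(0, n - alen + 1)
            for s in starts:
                t = s + alen
                if t > n or (t_at_end and t != n):
                    continue
                matches = sum(1 for k in range(alen) if _eq(adapter[a + k], read[s + k]))
                errors = alen - matches
                if errors <= e * alen:
                    cands.add((matches, errors, s, t, a, b))
    if not cands:
        return None
    return min(cands, key=_cand_key)


def enumerate_alignments_recursive(
    read: str, adapter: str, a: int, b: int, s: int, budget: int
) -> Set[Tuple[int, int, int]]:
    """All (t, errors, matches) via naive edit-script recursion (tiny inputs)."""
    read = read.upper()
    adapter = adapter.upper()
    out: Set[Tuple[int, int, int]] = set()

    def rec(i: int, j: int, cost: int, matches: int) -> None:
        if cost > budget:
            return
        if i == b:
            out.add((j, cost, matches))
            if j < len(read):  # trailing read base against gap
                rec(i, j + 1, cost + 1, matches)
            return
        if j < len(read):
            hit = _eq(adapter[i], read[j])
            rec(i + 1, j + 1, cost + (0 if hit else 1), matches + (1 if hit else 0))
            rec(i, j + 1, cost + 1, matches)  # read base against gap
        rec(i + 1, j, cost + 1, matches)  # adapter base against gap
    rec(a, s, 0, 0)
    return out


def quality_trim_oracle(scores, quality_low: int) -> Tuple[int, int]:
    """Best (keep_start, keep_stop) by trying every cut at each end.

    Each end is optimised independently on the full read; a cut is made
    only when its best partial sum is strictly positive, and equal maxima
    resolve toward trimming more bases. Crossing cuts give an empty keep
    interval (0, 0).
    """
    L = len(scores)
    suffix = [sum(quality_low - s for s in scores[x:]) for x in range(L + 1)]
    best3 = max(suffix)
    cut3 = min(i for i, v in enumerate(suffix) if v == best3) if best3 > 0 else L
    prefix = [sum(quality_low - s for s in scores[:y]) for y in range(L + 1)]
    best5 = max(prefix)
    cut5 = max(i for i, v in enumerate(prefix) if v == best5) if best5 > 0 else 0
    if cut5 >= cut3:
        return (0, 0)
    return (cut5, cut3)
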