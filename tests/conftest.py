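"""Shared helpers for the suite: record builders and randomized alignment cases."""

from __future__ import annotations

import random
from typing import Optional, Sequence, Tuple

import pytest

from fqprep.adapter_align import (
    AdapterKind,
    AdapterSpec,
    AlignParams,
    semiglobal_align,
)
from fqprep.fastq_io import FastqRecord, encode_quality

from oracles import align_oracle

KIND_MAP = {
    "3p": AdapterKind.THREE_PRIME,
    "5p": AdapterKind.FIVE_PRIME,
    "anywhere": AdapterKind.ANYWHERE,
}


def make_record(
    seq: str,
    scores: Optional[Sequence[int]] = None,
    rid: str = "r",
) -> FastqRecord:
    """Build a record from a sequence and optional per-base scores (default 40)."""
    if scores is None:
        scores = [40] * len(seq)
    return FastqRecord(
        id=rid,
        seq=seq.upper(),
        qual=encode_quality(scores, 33),
        scores=tuple(scores),
    )


def random_alignment_case(
    rng: random.Random,
    max_read: int = 30,
    max_adapter: int = 10,
    errs=(0.0, 0.1, 0.2),
    overlaps=(1, 3, 5),
) -> Tuple[str, str, str, bool, float, int, bool]:
    """One randomized (read, adapter, kind, anchored, e, O, indels) case.

    Reads are adapter-laced half the time (an adapter fragment, possibly
    corrupted, is spliced in) so the cases exercise hits as often as
    misses.
    """
    n = rng.randint(1, max_read)
    m = rng.randint(1, max_adapter)
    alpha = "ACGTN" if rng.random() < 0.3 else "ACGT"
    read = "".join(rng.choice(alpha) for _ in range(n))
    adapter = "".join(rng.choice(alpha) for _ in range(m))
    if rng.random() < 0.5 and n >= 2:
        frag = list(adapter[: rng.randint(1, m)])
        for k in range(len(frag)):
            if rng.random() < 0.15:
                frag[k] = rng.choice("ACGT")
        pos = rng.randint(0, max(0, n - len(frag)))
        read = (read[:pos] + "".join(frag) + read[pos + len(frag):])[:n]
    kind = rng.choice(["3p", "5p", "anywhere"])
    anchored = kind != "anywhere" and rng.random() < 0.25
    e = rng.choice(list(errs))
    O = rng.choice(list(overlaps))
    indels = rng.random() < 0.5
    return read, adapter, kind, anchored, e, O, indels


def run_case(read, adapter, kind, anchored, e, O, indels):
    """Run implementation and oracle on one case; return both as tuples."""
    spec = AdapterSpec(seq=adapter, kind=KIND_MAP[kind], anchored=anchored)
    params = AlignParams(max_error_rate=e, min_overlap=O, allow_indels=indels)
    got = semiglobal_align(read, spec, params)
    got_t = None
    if got is not None:
        got_t = (got.matches, got.errors, got.read_start, got.read_stop,
                 got.adapter_start, got.adapter_stop)
    want = align_oracle(read, adapter, kind, anchored, e, O, indels)
    return got_t, want


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240917)
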