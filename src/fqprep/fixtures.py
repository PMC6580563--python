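"""Deterministic synthetic FASTQ with known ground truth.

Reads are uniform-random over {A,C,G,T} with per-position Gaussian
quality scores clamped to [2, 40] (an Illumina-like profile declining
toward the 3' end by default). A chosen fraction of reads carries a
planted 3' adapter written over the read suffix from a recorded start
position and truncated at the read end — the read-through model, which
yields the full spread of overlap lengths for the adapter histogram —
optionally with substitution errors injected inside the visible adapter
bases. A disjoint fraction carries a planted run of Ns (disjoint so
each read's ground-truth label is unambiguous: no N ever lands inside a
planted adapter).

Everything is driven by one integer seed; the same spec produces
byte-identical files.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .fastq_io import FastqRecord, encode_quality, write_fastq

__all__ = ["FixtureSpec", "PlantedRead", "GroundTruth", "generate", "generate_records"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic FASTQ (pair)."""

    read_count: int = 1000
    read_length: int = 150
    seed: int = 0
    adapter_seq: str = "AGATCGGAAGAGC"
    adapter_fraction: float = 0.1
    adapter_error_count: int = 0
    n_block_fraction: float = 0.05
    n_block_length: int = 5
    #: (mean, sd) of the Phred score at each position; defaults to a linear
    #: decline from 38 at the 5' end to 30 at the 3' end with sd 3.
    quality_profile: Optional[Tuple[Tuple[float, ...], Tuple[float, ...]]] = None
    paired: bool = False
    encoding_offset: int = 33

    def __post_init__(self) -> None:
        for name in ("adapter_fraction", "n_block_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.adapter_fraction + self.n_block_fraction > 1.0:
            raise ValueError("adapter_fraction + n_block_fraction must not exceed 1")
        if self.n_block_fraction > 0 and self.n_block_length > self.read_length:
            raise ValueError("n_block_length exceeds read_length")
        if self.read_length < 1 or self.read_count < 0:
            raise ValueError("read_count/read_length out of range")
        if not self.adapter_seq:
            raise ValueError("adapter_seq must be non-empty")

    def profile_arrays(self) -> Tuple[np.ndarray, np.ndarray]:
        if self.quality_profile is not None:
            mean, sd = self.quality_profile
            if len(mean) != self.read_length or len(sd) != self.read_length:
                raise ValueError("quality_profile arrays must match read_length")
            return np.asarray(mean, float), np.asarray(sd, float)
        mean = np.linspace(38.0, 30.0, self.read_length)
        sd = np.full(self.read_length, 3.0)
        return mean, sd


@dataclass(frozen=True)
class PlantedRead:
    """Ground truth for one emitted read."""

    adapter_pos: Optional[int] = None      # start of the visible adapter, or None
    adapter_overlap: int = 0               # visible adapter bases (truncated)
    adapter_errors: int = 0                # substitutions injected inside them
    n_interval: Optional[Tuple[int, int]] = None  # planted N run, half-open


@dataclass
class GroundTruth:
    """Per-read truth for each mate plus convenience counts."""

    spec: FixtureSpec
    mates: List[List[PlantedRead]]  # one list per mate file

    def planted_adapter_count(self, mate: int = 0) -> int:
        return sum(1 for p in self.mates[mate] if p.adapter_pos is not None)

    def detectable_adapter_count(self, max_error_rate: float, min_overlap: int,
                                 mate: int = 0) -> int:
        """Planted adapters whose visible portion alone qualifies as a match."""
        n = 0
        for p in self.mates[mate]:
            if p.adapter_pos is None:
                continue
            if p.adapter_overlap >= min_overlap and (
                p.adapter_errors <= max_error_rate * p.adapter_overlap
            ):
                n += 1
        return n

    def n_block_count(self, mate: int = 0) -> int:
        return sum(1 for p in self.mates[mate] if p.n_interval is not None)

    def to_dict(self) -> dict:
        return {
            "spec": {k: v for k, v in asdict(self.spec).items()},
            "mates": [
                [
                    {
                        "adapter_pos": p.adapter_pos,
                        "adapter_overlap": p.adapter_overlap,
                        "adapter_errors": p.adapter_errors,
                        "n_interval": list(p.n_interval) if p.n_interval else None,
                    }
                    for p in mate
                ]
                for mate in self.mates
            ],
        }


def _simulate_mate(
    spec: FixtureSpec, rng: np.random.Generator, mate_suffix: str
) -> Tuple[List[FastqRecord], List[PlantedRead]]:
    L = spec.read_length
    m = len(spec.adapter_seq)
    adapter = np.frombuffer(spec.adapter_seq.upper().encode(), dtype=np.uint8)
    mean, sd = spec.profile_arrays()
    records: List[FastqRecord] = []
    truth: List[PlantedRead] = []

    for i in range(spec.read_count):
        seq = _BASES[rng.integers(0, 4, size=L)].copy()
        scores = np.clip(np.rint(rng.normal(mean, sd)), 2, 40).astype(int)
        planted = PlantedRead()
        u = rng.random()
        if u < spec.adapter_fraction:
            # read-through: adapter overwrites the suffix from pos, truncated
            pos = int(rng.integers(max(0, L - m - 10), L))
            vis = min(m, L - pos)
            seq[pos : pos + vis] = adapter[:vis]
            injected = 0
            if spec.adapter_error_count > 0 and vis > 0:
                k = min(spec.adapter_error_count, vis)
                err_at = rng.choice(vis, size=k, replace=False)
                for off in err_at:
                    old = seq[pos + off]
                    options = _BASES[_BASES != old]
                    seq[pos + off] = options[rng.integers(0, len(options))]
                    injected += 1
            planted = PlantedRead(adapter_pos=pos, adapter_overlap=vis,
                                  adapter_errors=injected)
        elif u < spec.adapter_fraction + spec.n_block_fraction:
            start = int(rng.integers(0, L - spec.n_block_length + 1))
            seq[start : start + spec.n_block_length] = ord("N")
            planted = PlantedRead(n_interval=(start, start + spec.n_block_length))
        rid = f"sim{i}{mate_suffix}"
        records.append(
            FastqRecord(
                id=rid,
                seq=seq.tobytes().decode(),
                qual=encode_quality(scores.tolist(), spec.encoding_offset),
                scores=tuple(int(s) for s in scores),
            )
        )
        truth.append(planted)
    return records, truth


def generate_records(
    spec: FixtureSpec,
) -> Tuple[List[List[FastqRecord]], GroundTruth]:
    """In-memory fixture: one record list per mate, plus ground truth."""
    rng = np.random.default_rng(spec.seed)
    mates: List[List[FastqRecord]] = []
    truths: List[List[PlantedRead]] = []
    suffixes = ("/1", "/2") if spec.paired else ("",)
    for sfx in suffixes:
        recs, tr = _simulate_mate(spec, rng, sfx)
        mates.append(recs)
        truths.append(tr)
    return mates, GroundTruth(spec=spec, mates=truths)


def generate(
    spec: FixtureSpec, out_dir, compress: bool = False
) -> Tuple[List[str], GroundTruth]:
    """Write the fixture FASTQ file(s) and a ground-truth JSON sidecar."""
    mates, truth = generate_records(spec)
    os.makedirs(out_dir, exist_ok=True)
    ext = ".fastq.gz" if compress else ".fastq"
    paths: List[str] = []
    if spec.paired:
        names = [f"reads_1{ext}", f"reads_2{ext}"]
    else:
        names = [f"reads{ext}"]
    for recs, name in zip(mates, names):
        path = os.path.join(str(out_dir), name)
        write_fastq(recs, path, compress=compress)
        paths.append(path)
    sidecar = os.path.join(str(out_dir), "ground_truth.json")
    with open(sidecar, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1)
    return paths, truth
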