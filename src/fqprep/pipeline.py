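"""Per-read processing pipeline and chunked-parallel run orchestration.

Stage order within one read: quality end-trim, N end-trim, adapter
removal, then the read-level filters — every stage optional, enabled by
its parameter being set. Paired reads are trimmed independently but
judged together: if one mate fails any filter, both are discarded.

The run is processed in chunks. Chunks may be handed to a thread pool,
but results are collected strictly in input order and chunk statistics
are merged associatively, so outputs and reports are byte-identical for
any thread count — parallelism is a throughput detail, never a source
of nondeterminism.
"""

from __future__ import annotations

import os
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace
from itertools import islice
from typing import Iterable, Iterator, List, Optional, Sequence, Tuple

from .adapter_align import AdapterSpec, AlignParams, find_best_match, remove_adapter
from .fastq_io import (
    FastqRecord,
    ReadPair,
    open_fastq_reader,
    open_paired_reader,
    write_fastq,
)
from .stats_report import RunStats, merge, render
from .trim_filter import (
    FilterCriterion,
    FilterParams,
    ReadVerdict,
    judge_pair,
    length_filter,
    n_ratio_filter,
    n_trim_ends,
    quality_filter,
    quality_trim_ends,
)

__all__ = ["RunConfig", "process_read", "process_pair", "run"]

_REPORT_EXT = {"text": "txt", "json": "json", "html": "html"}


@dataclass(frozen=True)
class RunConfig:
    """Everything one run needs; unset parameters disable their stage."""

    inputs: Tuple[str, ...]
    out_prefix: Optional[str] = None
    compress: bool = False
    split_count: int = 1
    encoding_offset: int = 33
    align_params: AlignParams = field(default_factory=AlignParams)
    adapters1: Tuple[AdapterSpec, ...] = ()
    adapters2: Tuple[AdapterSpec, ...] = ()
    filters: FilterParams = field(default_factory=FilterParams)
    threads: int = 1
    chunk_size: int = 1000
    report_formats: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.inputs) not in (1, 2):
            raise ValueError("inputs must hold one (single-end) or two (paired) paths")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")
        if self.chunk_size < 1:
            raise ValueError("chunk_size must be >= 1")
        for fmt in self.report_formats:
            if fmt not in _REPORT_EXT:
                raise ValueError(f"unknown report format {fmt!r}")

    @property
    def paired(self) -> bool:
        return len(self.inputs) == 2


def process_read(record: FastqRecord, cfg: RunConfig, mate: int = 1) -> ReadVerdict:
    """Trim, remove adapter, and judge one read (mate's verdict not applied)."""
    f = cfg.filters
    rec = record
    if f.quality_low is not None:
        rec = quality_trim_ends(rec, f.quality_low)
    if f.trim_n:
        rec = n_trim_ends(rec)
    adapters = cfg.adapters1 if mate == 1 else cfg.adapters2
    adapter = match = None
    if adapters and len(rec) > 0:
        found = find_best_match(rec.seq, adapters, cfg.align_params)
        if found is not None:
            adapter, match = found
            rec = remove_adapter(rec, adapter, match)
    failed = set()
    if f.quality_filter is not None and not quality_filter(rec, *f.quality_filter):
        failed.add(FilterCriterion.QUALITY)
    if f.ratio_n is not None and not n_ratio_filter(rec, f.ratio_n):
        failed.add(FilterCriterion.N_RATIO)
    failed |= length_filter(rec, f.min_length, f.max_length)
    return ReadVerdict(
        record=rec,
        failed_criteria=frozenset(failed),
        adapter=adapter,
        adapter_match=match,
    )


def process_pair(pair: ReadPair, cfg: RunConfig) -> Tuple[ReadVerdict, ReadVerdict]:
    """Process both mates independently, then synchronise their verdicts."""
    v1 = process_read(pair.r1, cfg, mate=1)
    v2 = process_read(pair.r2, cfg, mate=2)
    return judge_pair(v1, v2)


def _chunks(it: Iterator, size: int) -> Iterator[list]:
    while True:
        block = list(islice(it, size))
        if not block:
            return
        yield block


def _process_chunk_single(
    chunk: List[FastqRecord], cfg: RunConfig
) -> Tuple[List[FastqRecord], RunStats]:
    stats = RunStats()
    out: List[FastqRecord] = []
    for rec in chunk:
        verdict = process_read(rec, cfg, mate=1)
        stats.add(verdict, rec)
        if verdict.passed:
            out.append(verdict.record)
    return out, stats


def _process_chunk_paired(
    chunk: List[ReadPair], cfg: RunConfig
) -> Tuple[List[FastqRecord], List[FastqRecord], RunStats, RunStats]:
    s1, s2 = RunStats(), RunStats()
    out1: List[FastqRecord] = []
    out2: List[FastqRecord] = []
    for pair in chunk:
        v1, v2 = process_pair(pair, cfg)
        s1.add(v1, pair.r1)
        s2.add(v2, pair.r2)
        if v1.passed and v2.passed:
            out1.append(v1.record)
            out2.append(v2.record)
    return out1, out2, s1, s2


def _map_ordered(fn, chunks: Iterator, threads: int) -> Iterator:
    if threads == 1:
        return map(fn, chunks)
    pool = ThreadPoolExecutor(max_workers=threads)
    # executor.map yields results in submission order regardless of
    # completion order — exactly the determinism contract we need.
    return pool.map(fn, chunks)


def run(cfg: RunConfig) -> RunStats:
    """Execute the full pipeline; write outputs/reports; return statistics."""
    if cfg.paired:
        stats = _run_paired(cfg)
    else:
        stats = _run_single(cfg)
    if cfg.out_prefix is not None:
        for fmt in cfg.report_formats:
            render(stats, fmt, f"{cfg.out_prefix}.report.{_REPORT_EXT[fmt]}")
    return stats


def _run_single(cfg: RunConfig) -> RunStats:
    reader = open_fastq_reader(cfg.inputs[0], cfg.encoding_offset)
    total = RunStats()
    passed: List[FastqRecord] = []
    results = _map_ordered(
        lambda chunk: _process_chunk_single(chunk, cfg),
        _chunks(reader, cfg.chunk_size),
        cfg.threads,
    )
    for out, chunk_stats in results:
        passed.extend(out)
        total = merge(total, chunk_stats)
    if cfg.out_prefix is not None:
        ext = ".fastq.gz" if cfg.compress else ".fastq"
        write_fastq(passed, cfg.out_prefix + ext, cfg.compress, cfg.split_count)
    return total


def _run_paired(cfg: RunConfig) -> RunStats:
    reader = open_paired_reader(cfg.inputs[0], cfg.inputs[1], cfg.encoding_offset)
    t1, t2 = RunStats(), RunStats()
    passed1: List[FastqRecord] = []
    passed2: List[FastqRecord] = []
    results = _map_ordered(
        lambda chunk: _process_chunk_paired(chunk, cfg),
        _chunks(reader, cfg.chunk_size),
        cfg.threads,
    )
    for out1, out2, s1, s2 in results:
        passed1.extend(out1)
        passed2.extend(out2)
        t1 = merge(t1, s1)
        t2 = merge(t2, s2)
    if cfg.out_prefix is not None:
        ext = ".fastq.gz" if cfg.compress else ".fastq"
        write_fastq(passed1, f"{cfg.out_prefix}_1{ext}", cfg.compress, cfg.split_count)
        write_fastq(passed2, f"{cfg.out_prefix}_2{ext}", cfg.compress, cfg.split_count)
    combined = merge(t1, t2)
    combined.per_mate_totals = [
        dict(mate=1, **t1.totals()),
        dict(mate=2, **t2.totals()),
    ]
    return combined
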