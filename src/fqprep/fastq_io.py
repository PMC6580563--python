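"""Streaming FASTQ input/output.

Plain and gzip-compressed 4-line FASTQ, single- or paired-end, with
Phred+33 or Phred+64 quality decoding and optional block-split output.
Compression on input is detected from the gzip magic bytes (``1f 8b``),
never from the file extension. The quality encoding is an explicit caller
choice (default 33 everywhere downstream); silent auto-detection is
deliberately not offered because a misdetected offset corrupts every
score by 31.
"""

from __future__ import annotations

import gzip
import io
import math
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, List, Optional, Sequence, Tuple

__all__ = [
    "FastqRecord",
    "ReadPair",
    "FastqParseError",
    "FastqEncodingError",
    "PairingError",
    "open_fastq_reader",
    "open_paired_reader",
    "write_fastq",
]

GZIP_MAGIC = b"\x1f\x8b"

#: Highest Phred score representable in either encoding (ASCII 126 - 33).
MAX_PHRED = 93


class FastqParseError(ValueError):
    """Malformed FASTQ record (bad marker lines or length mismatch)."""


class FastqEncodingError(ValueError):
    """Quality character decodes below zero for the declared offset."""


class PairingError(ValueError):
    """Mate identifiers disagree, or one mate file is truncated."""


@dataclass(frozen=True)
class FastqRecord:
    """One sequencing read.

    Attributes
    ----------
    id:
        Header line without the leading ``@``.
    seq:
        Base string over ``{A, C, G, T, N}`` (uppercased on input).
    qual:
        Quality string, same length as ``seq``.
    scores:
        Decoded Phred scores, one per base.
    """

    id: str
    seq: str
    qual: str
    scores: Tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.seq) == len(self.qual) == len(self.scores)):
            raise FastqParseError(
                f"record {self.id!r}: sequence, quality and scores must have "
                f"equal lengths ({len(self.seq)}, {len(self.qual)}, {len(self.scores)})"
            )

    def __len__(self) -> int:
        return len(self.seq)

    @classmethod
    def from_strings(
        cls, id: str, seq: str, qual: str, encoding_offset: int = 33
    ) -> "FastqRecord":
        """Build a record, decoding ``qual`` with the given Phred offset."""
        scores = decode_quality(qual, encoding_offset, record_id=id)
        return cls(id=id, seq=seq.upper(), qual=qual, scores=scores)

    def slice(self, start: int, stop: int) -> "FastqRecord":
        """Sub-record over ``[start, stop)``; sequence and quality cut together."""
        return FastqRecord(
            id=self.id,
            seq=self.seq[start:stop],
            qual=self.qual[start:stop],
            scores=self.scores[start:stop],
        )


def decode_quality(
    qual: str, encoding_offset: int, record_id: str = ""
) -> Tuple[int, ...]:
    """Decode a quality string to Phred scores; negative scores are an error."""
    scores = tuple(ord(c) - encoding_offset for c in qual)
    for s in scores:
        if s < 0:
            raise FastqEncodingError(
                f"record {record_id!r}: quality character decodes to {s} < 0 "
                f"with offset {encoding_offset}; wrong encoding offset?"
            )
    return scores


def encode_quality(scores: Sequence[int], encoding_offset: int) -> str:
    """Inverse of :func:`decode_quality`."""
    return "".join(chr(s + encoding_offset) for s in scores)


def _mate_core_id(read_id: str) -> str:
    """Identifier used for mate comparison.

    Everything after the first whitespace is dropped (Casava 1.8+ style
    headers carry the mate number there), then a trailing ``/1`` or ``/2``
    suffix (pre-1.8 style) is stripped.
    """
    core = read_id.split(None, 1)[0]
    if core.endswith("/1") or core.endswith("/2"):
        core = core[:-2]
    return core


@dataclass(frozen=True)
class ReadPair:
    """A mate pair; identifiers must agree after mate-suffix stripping."""

    r1: FastqRecord
    r2: FastqRecord

    def __post_init__(self) -> None:
        if _mate_core_id(self.r1.id) != _mate_core_id(self.r2.id):
            raise PairingError(
                f"mate identifiers disagree: {self.r1.id!r} vs {self.r2.id!r}"
            )


def _open_maybe_gzip(path: os.PathLike | str) -> IO[str]:
    """Open text stream; gzip is recognised by magic bytes, not extension."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == GZIP_MAGIC:
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="ascii")
    return io.TextIOWrapper(raw, encoding="ascii")


def open_fastq_reader(
    path: os.PathLike | str, encoding_offset: int = 33
) -> Iterator[FastqRecord]:
    """Iterate records of a (possibly gzipped) 4-line FASTQ file.

    Raises :class:`FastqParseError` naming the 1-based record ordinal on
    malformed input and :class:`FastqEncodingError` when a quality
    character underflows the declared offset.
    """
    if encoding_offset not in (33, 64):
        raise ValueError(f"encoding_offset must be 33 or 64, got {encoding_offset}")
    with _open_maybe_gzip(path) as fh:
        ordinal = 0
        while True:
            header = fh.readline()
            if header == "":
                return
            ordinal += 1
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if qual == "" and (seq == "" or plus == ""):
                raise FastqParseError(
                    f"{path}: record {ordinal}: truncated record (fewer than 4 lines)"
                )
            header, seq, plus, qual = (
                header.rstrip("\r\n"),
                seq.rstrip("\r\n"),
                plus.rstrip("\r\n"),
                qual.rstrip("\r\n"),
            )
            if not header.startswith("@"):
                raise FastqParseError(
                    f"{path}: record {ordinal}: header does not start with '@': {header!r}"
                )
            if not plus.startswith("+"):
                raise FastqParseError(
                    f"{path}: record {ordinal}: separator line does not start with '+'"
                )
            if len(seq) != len(qual):
                raise FastqParseError(
                    f"{path}: record {ordinal}: sequence length {len(seq)} != "
                    f"quality length {len(qual)}"
                )
            rid = header[1:]
            try:
                yield FastqRecord.from_strings(rid, seq, qual, encoding_offset)
            except FastqEncodingError as exc:
                raise FastqEncodingError(f"{path}: record {ordinal}: {exc}") from None


def open_paired_reader(
    path1: os.PathLike | str,
    path2: os.PathLike | str,
    encoding_offset: int = 33,
) -> Iterator[ReadPair]:
    """Iterate mate files in lockstep.

    Raises :class:`PairingError` on an identifier mismatch or when one
    file runs out of records before the other.
    """
    it1 = open_fastq_reader(path1, encoding_offset)
    it2 = open_fastq_reader(path2, encoding_offset)
    ordinal = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        ordinal += 1
        if r1 is None or r2 is None:
            short = path1 if r1 is None else path2
            raise PairingError(
                f"{short}: truncated at pair {ordinal}: mate files have unequal "
                f"record counts"
            )
        yield ReadPair(r1, r2)


def _format_record(record: FastqRecord) -> str:
    return f"@{record.id}\n{record.seq}\n+\n{record.qual}\n"


def _open_writer(path: str, compress: bool) -> IO[str]:
    if compress:
        # mtime pinned so identical content yields identical bytes (thread
        # invariance of the pipeline is checked byte-for-byte on outputs).
        return io.TextIOWrapper(
            gzip.GzipFile(path, mode="wb", mtime=0), encoding="ascii"
        )
    return open(path, "w", encoding="ascii")


def write_fastq(
    records: Iterable[FastqRecord],
    path: os.PathLike | str,
    compress: bool = False,
    split_count: int = 1,
) -> List[str]:
    """Write records to one file, or to ``split_count`` contiguous blocks.

    With ``split_count == k > 1`` the stream is materialised and divided
    into contiguous blocks of ``ceil(n / k)`` records in input order, so
    concatenating the parts reproduces the unsplit output exactly. Part
    files are named ``<stem>.part1<suffix>`` etc. Returns the paths
    written (empty blocks produce no file, except that zero records still
    produce one valid empty file).
    """
    if split_count < 1:
        raise ValueError("split_count must be >= 1")
    path = str(path)
    if split_count == 1:
        with _open_writer(path, compress) as fh:
            for rec in records:
                fh.write(_format_record(rec))
        return [path]

    items = list(records)
    block = math.ceil(len(items) / split_count) if items else 0
    base, ext = _split_suffix(path)
    paths: List[str] = []
    if not items:
        with _open_writer(path, compress):
            pass
        return [path]
    for k in range(split_count):
        chunk = items[k * block : (k + 1) * block]
        if not chunk:
            break
        part_path = f"{base}.part{k + 1}{ext}"
        with _open_writer(part_path, compress) as fh:
            for rec in chunk:
                fh.write(_format_record(rec))
        paths.append(part_path)
    return paths


def _split_suffix(path: str) -> Tuple[str, str]:
    """Split ``x.fastq.gz`` -> (``x``, ``.fastq.gz``); tolerant of bare names."""
    suffix = ""
    base = path
    for ext in (".gz",):
        if base.endswith(ext):
            base = base[: -len(ext)]
            suffix = ext + suffix
    root, ext = os.path.splitext(base)
    if ext:
        base = root
        suffix = ext + suffix
    return base, suffix
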