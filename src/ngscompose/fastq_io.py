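"""FASTQ reading/writing with paired-end synchronization.

All pipeline stages share this layer.  Only the plain 4-line FASTQ dialect
is supported (no wrapped records, no interleaving); quality strings are
Phred+33 with scores restricted to the standard 41 bins (0-40).  Files whose
name ends in ``.gz`` are transparently (de)compressed.
"""

from __future__ import annotations

import gzip
import io
import os
from dataclasses import dataclass
from typing import IO, Iterable, Iterator

PHRED_OFFSET = 33
MAX_Q = 40  # inclusive; 41 bins 0..40


class FastqParseError(ValueError):
    """Raised when a FASTQ file violates the 4-line record contract."""


class PairingError(ValueError):
    """Raised when R1/R2 files cannot be synchronized."""


@dataclass(slots=True)
class FastqRecord:
    """One sequencing read: identifier (without '@'), bases, Phred+33 qualities."""

    id: str
    seq: str
    qual: str

    def __len__(self) -> int:
        return len(self.seq)

    def qscores(self) -> list[int]:
        """Decode the quality string to integer Phred scores."""
        return [ord(c) - PHRED_OFFSET for c in self.qual]

    def slice(self, start: int, stop: int | None = None) -> "FastqRecord":
        """Crop sequence and quality in lockstep."""
        return FastqRecord(self.id, self.seq[start:stop], self.qual[start:stop])

    def validate(self, offset: int = PHRED_OFFSET) -> None:
        if len(self.seq) != len(self.qual):
            raise FastqParseError(
                f"record {self.id!r}: seq length {len(self.seq)} != qual length {len(self.qual)}"
            )
        for c in self.qual:
            q = ord(c) - offset
            if not 0 <= q <= MAX_Q:
                raise FastqParseError(
                    f"record {self.id!r}: quality character {c!r} decodes to Q={q}, "
                    f"outside [0, {MAX_Q}]"
                )


@dataclass(slots=True)
class ReadPair:
    r1: FastqRecord
    r2: FastqRecord


def _open(path: str | os.PathLike, mode: str) -> IO[str]:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, mode.replace("t", "") + "b"))  # type: ignore[arg-type]
    return open(path, mode)


def read_fastq(path: str | os.PathLike, validate: bool = True) -> Iterator[FastqRecord]:
    """Yield records from a plain or gzipped 4-line FASTQ file.

    Raises :class:`FastqParseError` naming the (0-based) record index on a
    malformed record or a trailing partial record.
    """
    with _open(path, "rt") as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if not qual:
                raise FastqParseError(f"record {idx}: truncated record (file not 4-line)")
            header, seq, plus, qual = (s.rstrip("\n") for s in (header, seq, plus, qual))
            if not header.startswith("@"):
                raise FastqParseError(f"record {idx}: header does not start with '@'")
            if not plus.startswith("+"):
                raise FastqParseError(f"record {idx}: separator line does not start with '+'")
            rec = FastqRecord(header[1:], seq, qual)
            if validate:
                try:
                    rec.validate()
                except FastqParseError as e:
                    raise FastqParseError(f"record {idx}: {e}") from None
            yield rec
            idx += 1


def write_fastq(records: Iterable[FastqRecord], path: str | os.PathLike) -> int:
    """Write records as 4-line FASTQ (gzip iff path ends '.gz'); return count."""
    n = 0
    with _open(path, "wt") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
            n += 1
    return n


def count_records(path: str | os.PathLike) -> int:
    n = 0
    for _ in read_fastq(path, validate=False):
        n += 1
    return n


def iter_pairs(
    r1_path: str | os.PathLike, r2_path: str | os.PathLike, validate: bool = True
) -> Iterator[ReadPair]:
    """Yield synchronized read pairs; raise :class:`PairingError` on unequal counts."""
    it1 = read_fastq(r1_path, validate=validate)
    it2 = read_fastq(r2_path, validate=validate)
    n1 = n2 = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            # drain the longer file to report both totals
            for _ in it1:
                n1 += 1
            for _ in it2:
                n2 += 1
            n1 += r1 is not None
            n2 += r2 is not None
            raise PairingError(
                f"unequal record counts: {r1_path} has {n1}, {r2_path} has {n2} "
                f"(counting from the first desynchronized record)"
            )
        n1 += 1
        n2 += 1
        yield ReadPair(r1, r2)


class FastqWriter:
    """Lazy buffered writer for stages that fan out to many output files.

    Files are only created on first write unless :meth:`touch` is called.
    Buffering keeps the number of simultaneously open file handles at one,
    which matters for demultiplexing schemes with thousands of categories.
    """

    def __init__(self, flush_every: int = 20000):
        self._buffers: dict[str, list[str]] = {}
        self._counts: dict[str, int] = {}
        self._pending = 0
        self._flush_every = flush_every

    def touch(self, path: str) -> None:
        """Ensure the file exists (creates an empty category file)."""
        path = os.fspath(path)
        self._buffers.setdefault(path, [])
        self._counts.setdefault(path, 0)

    def write(self, path: str, rec: FastqRecord) -> None:
        path = os.fspath(path)
        self._buffers.setdefault(path, []).append(f"@{rec.id}\n{rec.seq}\n+\n{rec.qual}\n")
        self._counts[path] = self._counts.get(path, 0) + 1
        self._pending += 1
        if self._pending >= self._flush_every:
            self.flush()

    def flush(self) -> None:
        for path, chunks in self._buffers.items():
            if chunks or not os.path.exists(path):
                with _open(path, "at") as fh:
                    fh.write("".join(chunks))
            self._buffers[path] = []
        self._pending = 0

    def close(self) -> dict[str, int]:
        """Flush everything and return per-file record counts."""
        self.flush()
        return dict(self._counts)
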