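"""Positional nucleotide and Q-score summary statistics (crinoid).

Reads are traversed ``k`` bases at a time: each length-<=k chunk of bases (or
quality characters) is a dictionary key whose counts are kept per walk
position, then expanded into per-position count matrices — 5 x n for
nucleotides (A, C, G, T, N) and 41 x n for Q scores (0-40), where n is the
maximum read length observed.  The k-walk is purely an efficiency device:
the resulting matrices are identical for every k.
"""

from __future__ import annotations

import os
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fastq_io import MAX_Q, PHRED_OFFSET, read_fastq

NUCLEOTIDES = ("A", "C", "G", "T", "N")
_NUC_ROW = {b: i for i, b in enumerate(NUCLEOTIDES)}


@dataclass
class PositionCountMatrix:
    """Per-position category counts: 5 nucleotide rows or 41 Q-score rows."""

    kind: str  # "nucleotide" | "qscore"
    counts: np.ndarray = field(default_factory=lambda: np.zeros((5, 0), dtype=np.int64))

    @property
    def n_positions(self) -> int:
        return self.counts.shape[1]

    def row_labels(self) -> list[str]:
        if self.kind == "nucleotide":
            return list(NUCLEOTIDES)
        return [str(q) for q in range(MAX_Q + 1)]

    def column_sums(self) -> np.ndarray:
        """Number of reads covering each position."""
        return self.counts.sum(axis=0)

    def mean_q(self) -> np.ndarray:
        """Per-position mean Q score (qscore matrices only)."""
        if self.kind != "qscore":
            raise ValueError("mean_q is defined for qscore matrices only")
        qs = np.arange(MAX_Q + 1)[:, None]
        cov = self.column_sums()
        with np.errstate(invalid="ignore"):
            return (self.counts * qs).sum(axis=0) / cov

    def __add__(self, other: "PositionCountMatrix") -> "PositionCountMatrix":
        if self.kind != other.kind:
            raise ValueError("cannot add matrices of different kinds")
        n = max(self.n_positions, other.n_positions)
        rows = self.counts.shape[0]
        out = np.zeros((rows, n), dtype=np.int64)
        out[:, : self.n_positions] += self.counts
        out[:, : other.n_positions] += other.counts
        return PositionCountMatrix(self.kind, out)


def _nrows(kind: str) -> int:
    return 5 if kind == "nucleotide" else MAX_Q + 1


def summarize_records(
    records, k: int = 6
) -> tuple[PositionCountMatrix, PositionCountMatrix]:
    """Tally nucleotide and Q-score composition per read position.

    ``k`` controls the chunk size of the dictionary walk; the output is
    k-invariant.  Ambiguity codes other than N are tallied under N (with a
    warning); quality characters outside Q 0-40 are a hard error.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    # (walk position, chunk) -> count, for each stream
    nuc_chunks: dict[tuple[int, str], int] = defaultdict(int)
    q_chunks: dict[tuple[int, str], int] = defaultdict(int)
    n_max = 0
    for rec in records:
        seq, qual = rec.seq, rec.qual
        if len(seq) > n_max:
            n_max = len(seq)
        for w in range(0, len(seq), k):
            nuc_chunks[(w, seq[w : w + k])] += 1
            q_chunks[(w, qual[w : w + k])] += 1

    nuc = np.zeros((5, n_max), dtype=np.int64)
    saw_other = False
    for (w, chunk), cnt in nuc_chunks.items():
        for i, base in enumerate(chunk):
            row = _NUC_ROW.get(base)
            if row is None:
                saw_other = True
                row = _NUC_ROW["N"]
            nuc[row, w + i] += cnt
    if saw_other:
        warnings.warn("non-ACGTN characters encountered; tallied under N", stacklevel=2)

    qmat = np.zeros((MAX_Q + 1, n_max), dtype=np.int64)
    for (w, chunk), cnt in q_chunks.items():
        for i, c in enumerate(chunk):
            q = ord(c) - PHRED_OFFSET
            if not 0 <= q <= MAX_Q:
                raise ValueError(f"quality character {c!r} outside Q 0-{MAX_Q}")
            qmat[q, w + i] += cnt
    return PositionCountMatrix("nucleotide", nuc), PositionCountMatrix("qscore", qmat)


def summarize(path: str | os.PathLike, k: int = 6):
    """Summarize a FASTQ file; see :func:`summarize_records`."""
    return summarize_records(read_fastq(path), k=k)


def write_summary(matrix: PositionCountMatrix, path: str | os.PathLike) -> None:
    """Write a count matrix as CSV with category row labels and one column per position."""
    df = pd.DataFrame(
        matrix.counts,
        index=matrix.row_labels(),
        columns=[str(p) for p in range(matrix.n_positions)],
    )
    df.to_csv(path)


def read_summary(path: str | os.PathLike) -> PositionCountMatrix:
    df = pd.read_csv(path, index_col=0)
    kind = "nucleotide" if len(df.index) == 5 else "qscore"
    counts = df.to_numpy(dtype=np.int64).reshape(_nrows(kind), -1)
    return PositionCountMatrix(kind, counts)


def summarize_to_files(
    fastq_path: str | os.PathLike, outdir: str | os.PathLike, k: int = 6
) -> tuple[str, str]:
    """Run the QC summary and write ``<name>.nucleotides.csv`` / ``<name>.qscores.csv``."""
    os.makedirs(outdir, exist_ok=True)
    name = os.path.basename(os.fspath(fastq_path))
    for suffix in (".fastq.gz", ".fq.gz", ".fastq", ".fq"):
        if name.endswith(suffix):
            name = name[: -len(suffix)]
            break
    nuc, qmat = summarize(fastq_path, k=k)
    nuc_path = os.path.join(os.fspath(outdir), f"{name}.nucleotides.csv")
    q_path = os.path.join(os.fspath(outdir), f"{name}.qscores.csv")
    write_summary(nuc, nuc_path)
    write_summary(qmat, q_path)
    return nuc_path, q_path
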