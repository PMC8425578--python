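"""Empirical evaluation metrics: read compression and barcode error rates.

Two platform-independent ways of estimating base-calling accuracy without a
reference genome:

* **Read compression.**  Reduced-representation libraries contain many
  exact duplicate fragments, so collapsing identical reads shrinks the
  multiset substantially; base-call errors create novel singleton reads and
  lower the compression rate ``(1 - unique/total) * 100``.  The change in
  compression of a filtered subset, normalized against size-matched random
  subsamples of the raw file, measures whether a filter preferentially
  removed error-bearing reads.
* **Barcode error profiling.**  Sample barcodes are the only read bases
  whose true sequence is known.  Demultiplexing at increasing Hamming
  mismatch levels and comparing assigned reads base-by-base to their
  barcode yields an empirical per-position error probability, reported
  alongside its Phred equivalent Q = -10*log10(p) and the per-position
  distribution of instrument-reported Q scores.
"""

from __future__ import annotations

import math
import os
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .anemone import BarcodeScheme, check_tolerance, staged_match
from .fastq_io import PHRED_OFFSET, read_fastq

PHRED_INF = float("inf")  # sentinel: zero observed errors


@dataclass(slots=True)
class CompressionReport:
    total_reads: int
    unique_reads: int
    compression_rate: float  # (1 - unique/total) * 100
    unique_ratio: float  # raw unique/total, for transparency
    delta_compression: float | None = None
    delta_sd: float | None = None


def phred(probability: float) -> float:
    """Phred equivalent Q = -10 log10(p); infinity sentinel at p == 0."""
    if not 0 <= probability <= 1:
        raise ValueError("probability must be in [0, 1]")
    if probability == 0:
        return PHRED_INF
    return -10.0 * math.log10(probability)


def collapse_reads(
    source: str | os.PathLike | list[str], allow_unequal: bool = False
) -> Counter:
    """Collapse identical read sequences to a frequency map.

    Reads should be end-trimmed to identical length first; mixed lengths
    bias the comparison and are refused unless ``allow_unequal`` (reads
    containing N are kept as distinct literal strings).
    """
    if isinstance(source, (str, os.PathLike)):
        seqs = (rec.seq for rec in read_fastq(source))
    else:
        seqs = iter(source)
    counts: Counter = Counter()
    lengths: set[int] = set()
    for s in seqs:
        lengths.add(len(s))
        counts[s] += 1
    if len(lengths) > 1:
        msg = f"reads have {len(lengths)} distinct lengths {sorted(lengths)[:5]}..."
        if not allow_unequal:
            raise ValueError(msg + " (end-trim to identical length, or pass allow_unequal)")
        warnings.warn(msg, stacklevel=2)
    return counts


def compression_rate(counts: Counter) -> CompressionReport:
    """Compression rate of a collapsed read multiset."""
    total = sum(counts.values())
    if total == 0:
        raise ValueError("empty read set")
    unique = len(counts)
    return CompressionReport(
        total_reads=total,
        unique_reads=unique,
        compression_rate=(1 - unique / total) * 100.0,
        unique_ratio=unique / total,
    )


def delta_compression(
    filtered: str | os.PathLike | list[str],
    raw: str | os.PathLike | list[str],
    seed: int,
    n_replicates: int = 10,
    allow_unequal: bool = False,
) -> CompressionReport:
    """Delta compression of a filtered subset vs size-matched raw subsamples.

    Subsamples the raw reads (without replacement) to the filtered size over
    ``n_replicates`` seeded draws; delta = rate(filtered) - mean(rate(subsample)),
    in percentage points, with the subsampling SD reported.
    """
    if isinstance(raw, (str, os.PathLike)):
        raw_seqs = [rec.seq for rec in read_fastq(raw)]
    else:
        raw_seqs = list(raw)
    filt_counts = collapse_reads(filtered, allow_unequal=allow_unequal)
    report = compression_rate(filt_counts)
    n = report.total_reads
    if n > len(raw_seqs):
        raise ValueError(f"filtered set ({n}) larger than raw set ({len(raw_seqs)})")
    rng = np.random.default_rng(seed)
    rates = []
    raw_arr = np.asarray(raw_seqs, dtype=object)
    for _ in range(n_replicates):
        sub = rng.choice(raw_arr, size=n, replace=False)
        rates.append(compression_rate(Counter(sub.tolist())).compression_rate)
    report.delta_compression = report.compression_rate - float(np.mean(rates))
    report.delta_sd = float(np.std(rates))
    return report


def strip_motif(seqs: list[str], motifs: list[str]) -> list[str]:
    """Remove the matching motif-length prefix (for non-motif-portion comparisons)."""
    out = []
    for s in seqs:
        for m in motifs:
            if s.startswith(m):
                s = s[len(m):]
                break
        out.append(s)
    return out


@dataclass
class BarcodeErrorProfile:
    """Per-barcode-position empirical error rates, grouped by mismatch level.

    For each maximum mismatch level M, statistics pool all reads assigned at
    level M *and fewer*.  ``error[M]`` is the per-position error
    probability, ``assessed[M]`` the per-position read count (variable
    barcode lengths mean distal positions are covered by fewer reads), and
    ``q_counts[M]`` the 41 x n tally of instrument-reported Q scores.
    """

    max_m: int
    n_positions: int
    error: dict[int, np.ndarray] = field(default_factory=dict)
    assessed: dict[int, np.ndarray] = field(default_factory=dict)
    mismatches: dict[int, np.ndarray] = field(default_factory=dict)
    q_counts: dict[int, np.ndarray] = field(default_factory=dict)

    def phred_equivalent(self, level: int) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(
                self.error[level] > 0, -10.0 * np.log10(self.error[level]), PHRED_INF
            )

    def mean_reported_q(self, level: int) -> np.ndarray:
        qc = self.q_counts[level]
        qs = np.arange(qc.shape[0])[:, None]
        cov = qc.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return (qc * qs).sum(axis=0) / cov


def barcode_error_profile(
    r1_path: str | os.PathLike,
    scheme: BarcodeScheme,
    max_m: int = 1,
    override: bool = False,
) -> BarcodeErrorProfile:
    """Empirical per-position barcode error rates at staged mismatch levels.

    Reads are assigned by the same staged, ambiguity-refusing matcher the
    demultiplexer uses; per position j and level M,
    ``error(j) = mismatching bases at j / reads assessed at level <= M``.
    ``max_m`` beyond the identifiability bound of the barcode set requires
    ``override`` (profiling deliberately stretches the tolerance).
    """
    check_tolerance(scheme, max_m, override=override)
    barcodes = scheme.forward
    n_pos = max(len(b) for b in barcodes)
    mism = np.zeros((max_m + 1, n_pos), dtype=np.int64)
    cover = np.zeros((max_m + 1, n_pos), dtype=np.int64)
    qcnt = np.zeros((max_m + 1, 41, n_pos), dtype=np.int64)
    n_assigned = 0
    for rec in read_fastq(r1_path):
        bc, level = staged_match(rec.seq, barcodes, max_m)
        if bc is None:
            continue
        n_assigned += 1
        L = len(bc)
        cover[level, :L] += 1
        for j in range(L):
            if rec.seq[j] != bc[j]:
                mism[level, j] += 1
            q = ord(rec.qual[j]) - PHRED_OFFSET
            qcnt[level, q, j] += 1
    if n_assigned == 0:
        raise ValueError("no reads could be assigned to any barcode")
    profile = BarcodeErrorProfile(max_m=max_m, n_positions=n_pos)
    for M in range(max_m + 1):
        pooled_m = mism[: M + 1].sum(axis=0)
        pooled_c = cover[: M + 1].sum(axis=0)
        with np.errstate(invalid="ignore"):
            err = np.where(pooled_c > 0, pooled_m / np.maximum(pooled_c, 1), np.nan)
        profile.error[M] = err
        profile.assessed[M] = pooled_c
        profile.mismatches[M] = pooled_m
        profile.q_counts[M] = qcnt[: M + 1].sum(axis=0)
    return profile
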