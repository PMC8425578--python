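"""Whole-read Q-score composition threshold filtering (krill).

A read passes when at least ``p`` percent of its bases have Phred quality at
or above ``q``.  Equivalently, the failing allowance is
``(100 - p)/100 * read_length`` (kept as an exact rational, not floored) and
a read is rejected only when its count of sub-``q`` bases *exceeds* that
allowance — a count exactly at the allowance passes.  Qualities are scanned
3' to 5' with early rejection, mirroring where errors concentrate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from ._routing import route_filter
from .fastq_io import FastqRecord, MAX_Q, PHRED_OFFSET


@dataclass(slots=True)
class ThresholdSpec:
    q: int  # minimum passing Q score, 0-40
    p: int  # required percent of bases at or above q, 0-100

    def __post_init__(self):
        if not 0 <= self.q <= MAX_Q:
            raise ValueError(f"q must be in [0, {MAX_Q}]")
        if not 0 <= self.p <= 100:
            raise ValueError("p must be in [0, 100]")


def passes_threshold(rec: FastqRecord, spec: ThresholdSpec) -> bool:
    """Exact-rational threshold test with 3'->5' early exit.

    Pass iff ``count(Q < q) <= (100 - p)/100 * len``; comparison is done as
    ``100 * count <= (100 - p) * len`` to avoid floating point.
    """
    n = len(rec)
    if n == 0:
        return True
    limit = (100 - spec.p) * n  # 100 * failing allowance
    threshold = chr(spec.q + PHRED_OFFSET)
    failing = 0
    for c in reversed(rec.qual):
        if c < threshold:
            failing += 1
            if 100 * failing > limit:
                return False
    return True


def filter_file(
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike | None,
    spec: ThresholdSpec,
    outdir: str | os.PathLike,
    prefix: str = "krill",
) -> dict:
    """Route reads by the Q/p threshold; same pairing semantics as motif filtering."""
    test = lambda rec: passes_threshold(rec, spec)  # noqa: E731
    return route_filter(r1_path, r2_path, test, test, outdir, prefix)
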