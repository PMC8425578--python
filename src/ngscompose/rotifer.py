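"""Expected-motif presence filtering (rotifer).

Library construction with restriction enzymes (or A-tailing) guarantees that
every correctly sequenced read begins with a known motif — e.g. TGCAT on
forward reads and CATG on reverse reads of an NsiI/NlaIII double digest.  A
read that fails to begin with any expected motif is assumed to begin with
sequencing error and is filtered out.  Matching is exact and anchored at
position 0: an erroneous motif base *is* the error signal, so no mismatch
tolerance is applied.  Multiple motifs are OR-ed (A-tailed whole-genome
designs expect e.g. TCC or TCT).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from ._routing import route_filter
from .fastq_io import FastqRecord


@dataclass(slots=True)
class MotifSet:
    r1_motifs: list[str] = field(default_factory=list)
    r2_motifs: list[str] = field(default_factory=list)


def has_motif(rec: FastqRecord, motifs: list[str]) -> bool:
    """True iff the read begins (position 0, exact) with any of the motifs."""
    if not motifs:
        raise ValueError("motif list must be non-empty")
    return any(rec.seq.startswith(m) for m in motifs)


def filter_motif(
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike | None,
    motifs: MotifSet,
    outdir: str | os.PathLike,
    prefix: str = "motif",
) -> dict:
    """Route reads by motif presence; reads are never modified.

    Paired reads that both pass stay paired; a passing mate whose partner
    fails is written with an ``se.`` prefix and the failing mate to a fail
    file, so the failing population stays available for comparison.
    """
    r1m = motifs.r1_motifs
    r2m = motifs.r2_motifs if r2_path is not None else None
    if not r1m:
        raise ValueError("r1 motifs required")
    if r2_path is not None and not r2m:
        raise ValueError("r2 motifs required for paired input")
    return route_filter(
        r1_path,
        r2_path,
        lambda rec: has_motif(rec, r1m),
        (lambda rec: has_motif(rec, r2m)) if r2m else None,
        outdir,
        prefix,
    )
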