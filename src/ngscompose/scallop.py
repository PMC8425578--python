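"""Fixed-position and quality-window end trimming (scallop).

Two modes, composable:

* fixed trimming removes a set number of bases from the front (``-f``) and/or
  back (``-b``) of every read — used to strip the 6 bp buffer region before
  demultiplexing;
* quality end-trimming slides a window of size ``-w`` base-by-base from the
  3' end towards the 5' end until the window contains only bases at or above
  the end-trimming Q score ``-e``; the read is cut at the 3' edge of that
  window (the qualifying window itself is kept).

Reads trimmed to length zero are routed to a discard file; mates of
discarded reads drop to single-end outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from .fastq_io import (
    FastqRecord,
    FastqWriter,
    PHRED_OFFSET,
    iter_pairs,
    read_fastq,
)


@dataclass(slots=True)
class TrimSpec:
    front: int = 0
    back: int = 0  # bases removed from the 3' end ("cut at position" via back_is_position)
    back_is_position: bool = False
    window: int = 0  # 0 disables quality end-trimming
    end_q: int = 0


def trim_fixed(rec: FastqRecord, front: int = 0, back: int = 0,
               back_is_position: bool = False) -> FastqRecord:
    """Crop ``front`` bases from the 5' end and ``back`` from the 3' end.

    With ``back_is_position`` the read is instead cut at absolute position
    ``back`` (0-based, exclusive) before the front trim is applied.
    """
    if front < 0 or back < 0:
        raise ValueError("front and back must be non-negative")
    if back_is_position:
        rec = rec.slice(0, back)
        return rec.slice(front) if front else rec
    stop = len(rec) - back if back else None
    return rec.slice(front, stop)


def trim_quality_end(rec: FastqRecord, window: int, end_q: int) -> FastqRecord:
    """Quality end-trim: keep the prefix through the most 3' all-passing window.

    Scans windows of size ``window`` from the 3' end towards the 5' end and
    returns the read cut at the 3' edge of the first window whose every base
    has Q >= ``end_q``; an empty read if no window qualifies.  A window larger
    than the read treats the whole read as the single window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(rec)
    if n == 0:
        return rec
    w = min(window, n)
    threshold = chr(end_q + PHRED_OFFSET)
    qual = rec.qual
    for end in range(n, w - 1, -1):
        if all(c >= threshold for c in qual[end - w : end]):
            return rec.slice(0, end)
    return rec.slice(0, 0)


def apply_spec(rec: FastqRecord, spec: TrimSpec) -> FastqRecord:
    rec = trim_fixed(rec, spec.front, spec.back, spec.back_is_position)
    if spec.window:
        rec = trim_quality_end(rec, spec.window, spec.end_q)
    return rec


def trim_file(
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike | None,
    spec: TrimSpec,
    outdir: str | os.PathLike,
    prefix: str = "trimmed",
) -> dict:
    """Trim a single- or paired-end library; empty results are discarded.

    For paired input, a pair whose single mate becomes empty is broken: the
    surviving mate is written to an ``se.``-prefixed single-end file.
    Returns a manifest with file paths and conservation counts
    (reads in == reads out + discards).
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    writer = FastqWriter()
    paths = {
        "r1": os.path.join(outdir, f"{prefix}.R1.fastq"),
        "discard_r1": os.path.join(outdir, f"discard.{prefix}.R1.fastq"),
    }
    n_in = n_out = n_discard = 0
    if r2_path is None:
        writer.touch(paths["r1"])
        for rec in read_fastq(r1_path):
            n_in += 1
            t = apply_spec(rec, spec)
            if len(t):
                writer.write(paths["r1"], t)
                n_out += 1
            else:
                writer.write(paths["discard_r1"], rec)
                n_discard += 1
    else:
        paths.update(
            r2=os.path.join(outdir, f"{prefix}.R2.fastq"),
            se_r1=os.path.join(outdir, f"se.{prefix}.R1.fastq"),
            se_r2=os.path.join(outdir, f"se.{prefix}.R2.fastq"),
            discard_r2=os.path.join(outdir, f"discard.{prefix}.R2.fastq"),
        )
        writer.touch(paths["r1"])
        writer.touch(paths["r2"])
        for pair in iter_pairs(r1_path, r2_path):
            n_in += 2
            t1 = apply_spec(pair.r1, spec)
            t2 = apply_spec(pair.r2, spec)
            if len(t1) and len(t2):
                writer.write(paths["r1"], t1)
                writer.write(paths["r2"], t2)
                n_out += 2
            elif len(t1):
                writer.write(paths["se_r1"], t1)
                writer.write(paths["discard_r2"], pair.r2)
                n_out += 1
                n_discard += 1
            elif len(t2):
                writer.write(paths["se_r2"], t2)
                writer.write(paths["discard_r1"], pair.r1)
                n_out += 1
                n_discard += 1
            else:
                writer.write(paths["discard_r1"], pair.r1)
                writer.write(paths["discard_r2"], pair.r2)
                n_discard += 2
    counts = writer.close()
    return {
        "paths": paths,
        "file_counts": counts,
        "reads_in": n_in,
        "reads_out": n_out,
        "reads_discarded": n_discard,
    }
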