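"""Shared pass/fail routing for read-level filters (motif and Q-threshold).

Paired reads that both pass stay paired; a lone passing mate is written with
an ``se.`` prefix while its failing mate goes to a fail file; reads are never
modified, only routed.
"""

from __future__ import annotations

import os
from typing import Callable

from .fastq_io import FastqRecord, FastqWriter, iter_pairs, read_fastq


def route_filter(
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike | None,
    passes_r1: Callable[[FastqRecord], bool],
    passes_r2: Callable[[FastqRecord], bool] | None,
    outdir: str | os.PathLike,
    prefix: str,
) -> dict:
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    writer = FastqWriter()

    def p(name: str) -> str:
        return os.path.join(outdir, name)

    counts = {"pairs_pass": 0, "se_pass": 0, "fail": 0}
    n_in = 0
    if r2_path is None:
        paths = {"pass_r1": p(f"{prefix}.R1.fastq"), "fail_r1": p(f"fail.{prefix}.R1.fastq")}
        for path in paths.values():
            writer.touch(path)
        for rec in read_fastq(r1_path):
            n_in += 1
            if passes_r1(rec):
                writer.write(paths["pass_r1"], rec)
                counts["se_pass"] += 1
            else:
                writer.write(paths["fail_r1"], rec)
                counts["fail"] += 1
    else:
        if passes_r2 is None:
            passes_r2 = passes_r1
        paths = {
            "pass_r1": p(f"{prefix}.R1.fastq"),
            "pass_r2": p(f"{prefix}.R2.fastq"),
            "se_r1": p(f"se.{prefix}.R1.fastq"),
            "se_r2": p(f"se.{prefix}.R2.fastq"),
            "fail_r1": p(f"fail.{prefix}.R1.fastq"),
            "fail_r2": p(f"fail.{prefix}.R2.fastq"),
        }
        for path in paths.values():
            writer.touch(path)
        for pair in iter_pairs(r1_path, r2_path):
            n_in += 2
            ok1, ok2 = passes_r1(pair.r1), passes_r2(pair.r2)
            if ok1 and ok2:
                writer.write(paths["pass_r1"], pair.r1)
                writer.write(paths["pass_r2"], pair.r2)
                counts["pairs_pass"] += 2
            elif ok1:
                writer.write(paths["se_r1"], pair.r1)
                writer.write(paths["fail_r2"], pair.r2)
                counts["se_pass"] += 1
                counts["fail"] += 1
            elif ok2:
                writer.write(paths["se_r2"], pair.r2)
                writer.write(paths["fail_r1"], pair.r1)
                counts["se_pass"] += 1
                counts["fail"] += 1
            else:
                writer.write(paths["fail_r1"], pair.r1)
                writer.write(paths["fail_r2"], pair.r2)
                counts["fail"] += 2
    file_counts = writer.close()
    return {
        "paths": paths,
        "file_counts": file_counts,
        "reads_in": n_in,
        "reads_pass": counts["pairs_pass"] + counts["se_pass"],
        "reads_fail": counts["fail"],
        **counts,
    }
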