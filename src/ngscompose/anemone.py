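"""Ambiguity-safe dual-barcode demultiplexing with staged Hamming passes (anemone).

Inline barcodes of variable length (typically 7-10 bp) sit at the 5' end of
each read.  Reads are first assigned by exact prefix match (Hamming distance
0); reads left unknown are optionally re-examined in further passes with
increasing mismatch tolerance ``-m``.  Whenever a read prefix is within the
current tolerance of more than one barcode — including exact prefix nesting
of a shorter barcode inside a longer one — the read is kept as unknown: no
read is ever assigned preferentially, so assignment is independent of
barcode file order.

Demultiplexing at a mismatch tolerance m with 2m >= the barcode set's
minimum pairwise Levenshtein distance can no longer guarantee unique
identifiability and is refused unless explicitly overridden (the override
exists for empirical barcode-error profiling, which deliberately stretches
the tolerance).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import edlib

from .fastq_io import FastqRecord, FastqWriter, iter_pairs, read_fastq

UNKNOWN = "unknown"


class DemuxRefusalError(ValueError):
    """Mismatch tolerance incompatible with the barcode set's edit-distance margin."""


def hamming_leq(a: str, b: str, m: int) -> int:
    """Hamming distance of equal-length strings, capped at m+1 (early exit)."""
    d = 0
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > m:
                return d
    return d


def min_levenshtein(barcodes: list[str]) -> int:
    """Minimum pairwise Levenshtein distance within a barcode set."""
    best = None
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
            if best is None or d < best:
                best = d
                if best == 0:
                    return 0
    return best if best is not None else 0


@dataclass
class BarcodeScheme:
    """Forward/reverse barcode sets mapped to sample names.

    ``sample_matrix`` maps ``(forward barcode, reverse barcode)`` to a sample
    name for dual-index schemes; single-index schemes map
    ``(forward barcode, None)``.
    """

    forward: list[str]
    reverse: list[str] = field(default_factory=list)
    sample_matrix: dict[tuple[str, str | None], str] = field(default_factory=dict)

    def __post_init__(self):
        for name, bcs in (("forward", self.forward), ("reverse", self.reverse)):
            if len(set(bcs)) != len(bcs):
                raise ValueError(f"duplicate {name} barcodes")

    @property
    def dual(self) -> bool:
        return bool(self.reverse)

    def min_distance(self) -> int:
        """Smallest pairwise Levenshtein distance across both directions."""
        dists = [min_levenshtein(self.forward)]
        if self.reverse:
            dists.append(min_levenshtein(self.reverse))
        return min(d for d in dists if d is not None)

    def sample(self, fwd: str | None, rev: str | None) -> str | None:
        if fwd is None:
            return None
        if not self.dual:
            return self.sample_matrix.get((fwd, None))
        if rev is None:
            return None
        return self.sample_matrix.get((fwd, rev))

    def samples(self) -> list[str]:
        return sorted(set(self.sample_matrix.values()))


def load_barcode_scheme(path: str | os.PathLike) -> BarcodeScheme:
    """Load a TSV barcode/sample matrix.

    Dual-index layout: forward barcodes as column labels on the first row
    (first field empty), reverse barcodes as row labels, sample names as
    cells (empty cell = unused combination).  Single-index layout: two
    columns, ``barcode<TAB>sample`` per line, no header.
    """
    with open(path) as fh:
        rows = [line.rstrip("\n").split("\t") for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"empty barcode file: {path}")
    if rows[0][0] == "" and len(rows[0]) > 1:  # dual-index matrix
        forward = rows[0][1:]
        reverse = []
        matrix: dict[tuple[str, str | None], str] = {}
        for row in rows[1:]:
            rev = row[0]
            reverse.append(rev)
            for fwd, cell in zip(forward, row[1:]):
                if cell:
                    matrix[(fwd, rev)] = cell
        return BarcodeScheme(forward, reverse, matrix)
    if any(len(r) != 2 for r in rows):
        raise ValueError(f"barcode file {path} is neither a dual matrix nor 2-column TSV")
    forward = [r[0] for r in rows]
    matrix = {(r[0], None): r[1] for r in rows}
    return BarcodeScheme(forward, [], matrix)


def match_barcode(rec: FastqRecord, barcodes: list[str], m: int) -> str | None:
    """Unique barcode within Hamming distance m of the read prefix, else None.

    Each barcode is compared against the read prefix of its own length;
    prefixes shorter than a barcode cannot match it.  Zero or multiple
    qualifying barcodes both yield None (ambiguity is never resolved by
    preference).
    """
    hits = []
    seq = rec.seq
    for bc in barcodes:
        if len(seq) < len(bc):
            continue
        if hamming_leq(seq[: len(bc)], bc, m) <= m:
            hits.append(bc)
            if len(hits) > 1:
                return None
    return hits[0] if len(hits) == 1 else None


def staged_match(seq: str, barcodes: list[str], max_m: int) -> tuple[str | None, int]:
    """Assign by staged passes m = 0, 1, ..., max_m.

    Each pass considers only reads left unknown by the previous pass; a pass
    in which several barcodes qualify leaves the read unknown permanently
    (later, more lenient passes can only re-encounter the same ambiguity).
    Returns ``(barcode, mismatch_used)`` or ``(None, -1)``.
    """
    for m in range(max_m + 1):
        hits = []
        for bc in barcodes:
            if len(seq) < len(bc):
                continue
            if hamming_leq(seq[: len(bc)], bc, m) <= m:
                hits.append(bc)
                if len(hits) > 1:
                    return None, -1
        if len(hits) == 1:
            return hits[0], m
    return None, -1


def check_tolerance(scheme: BarcodeScheme, max_m: int, override: bool = False) -> int:
    min_d = scheme.min_distance()
    if not override and max_m > 0 and 2 * max_m >= min_d:
        raise DemuxRefusalError(
            f"mismatch tolerance m={max_m} unsafe: barcode set has minimum pairwise "
            f"Levenshtein distance {min_d}, and 2m >= {min_d} permits misassignment "
            f"(pass override to proceed anyway)"
        )
    return min_d


def demultiplex(
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike | None,
    scheme: BarcodeScheme,
    max_m: int = 0,
    outdir: str | os.PathLike = ".",
    override: bool = False,
    create_all_files: bool = True,
) -> dict:
    """Demultiplex a single- or paired-end library into per-sample files.

    Forward barcodes are matched against R1 prefixes and reverse barcodes
    against R2 prefixes in independent staged passes; assignments are then
    reconciled through the sample matrix.  Matched barcodes are trimmed from
    the 5' end; unknown reads keep their original sequence.  One output file
    exists per (forward, reverse) sample cell for each of the four
    categories — paired R1/R2 and unpaired (``se.``) R1/R2 — plus the two
    unknown files, so a full 96x96 dual scheme fans out to 9216 files per
    category.

    A read pair in a dual scheme with exactly one matched mate cannot be
    resolved to a sample cell; the matched mate is written to the
    corresponding unknown file untrimmed (no guessing), unless the matched
    direction alone uniquely determines a sample, in which case the mate
    goes to that sample's ``se.`` file.
    """
    check_tolerance(scheme, max_m, override=override)
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    writer = FastqWriter()

    def p(name: str) -> str:
        return os.path.join(outdir, name)

    paired = r2_path is not None
    if create_all_files:
        for s in scheme.samples():
            writer.touch(p(f"{s}.R1.fastq"))
            writer.touch(p(f"se.{s}.R1.fastq"))
            if paired:
                writer.touch(p(f"{s}.R2.fastq"))
                writer.touch(p(f"se.{s}.R2.fastq"))
    writer.touch(p(f"{UNKNOWN}.R1.fastq"))
    if paired:
        writer.touch(p(f"{UNKNOWN}.R2.fastq"))

    # forward-barcode -> sample when that single direction is decisive
    fwd_unique: dict[str, str] = {}
    rev_unique: dict[str, str] = {}
    if scheme.dual:
        for (f, r), s in scheme.sample_matrix.items():
            fwd_unique.setdefault(f, s)
            rev_unique.setdefault(r, s)  # type: ignore[arg-type]
        fwd_counts: dict[str, int] = {}
        rev_counts: dict[str, int] = {}
        for (f, r) in scheme.sample_matrix:
            fwd_counts[f] = fwd_counts.get(f, 0) + 1
            rev_counts[r] = rev_counts.get(r, 0) + 1  # type: ignore[index]
        fwd_unique = {f: s for f, s in fwd_unique.items() if fwd_counts[f] == 1}
        rev_unique = {r: s for r, s in rev_unique.items() if rev_counts[r] == 1}

    n_in = n_assigned = n_unknown = 0
    sample_counts: dict[str, int] = {}
    mismatch_counts: dict[int, int] = {}

    def bump(sample: str, level: int) -> None:
        nonlocal n_assigned
        n_assigned += 1
        sample_counts[sample] = sample_counts.get(sample, 0) + 1
        mismatch_counts[level] = mismatch_counts.get(level, 0) + 1

    if not paired:
        for rec in read_fastq(r1_path):
            n_in += 1
            bc, level = staged_match(rec.seq, scheme.forward, max_m)
            sample = scheme.sample(bc, None) if not scheme.dual else (
                fwd_unique.get(bc) if bc is not None else None
            )
            if sample is not None:
                writer.write(p(f"{sample}.R1.fastq"), rec.slice(len(bc)))
                bump(sample, level)
            else:
                writer.write(p(f"{UNKNOWN}.R1.fastq"), rec)
                n_unknown += 1
    else:
        for pair in iter_pairs(r1_path, r2_path):
            n_in += 2
            fbc, flevel = staged_match(pair.r1.seq, scheme.forward, max_m)
            rbc, rlevel = staged_match(
                pair.r2.seq, scheme.reverse if scheme.dual else scheme.forward, max_m
            )
            sample = scheme.sample(fbc, rbc)
            if sample is not None:
                writer.write(p(f"{sample}.R1.fastq"), pair.r1.slice(len(fbc)))
                writer.write(p(f"{sample}.R2.fastq"), pair.r2.slice(len(rbc)))
                bump(sample, max(flevel, rlevel))
                n_assigned += 1  # both mates assigned
            else:
                s1 = fwd_unique.get(fbc) if fbc is not None else None
                s2 = rev_unique.get(rbc) if rbc is not None else None
                if s1 is not None:
                    writer.write(p(f"se.{s1}.R1.fastq"), pair.r1.slice(len(fbc)))
                    bump(s1, flevel)
                else:
                    writer.write(p(f"{UNKNOWN}.R1.fastq"), pair.r1)
                    n_unknown += 1
                if s2 is not None:
                    writer.write(p(f"se.{s2}.R2.fastq"), pair.r2.slice(len(rbc)))
                    bump(s2, rlevel)
                else:
                    writer.write(p(f"{UNKNOWN}.R2.fastq"), pair.r2)
                    n_unknown += 1
    counts = writer.close()
    return {
        "outdir": outdir,
        "file_counts": counts,
        "reads_in": n_in,
        "reads_assigned": n_assigned,
        "reads_unknown": n_unknown,
        "sample_counts": sample_counts,
        "mismatch_counts": mismatch_counts,
    }
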