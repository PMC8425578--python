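"""3' adapter read-through detection and trimming via k-mer offset voting (porifera).

Each expected adapter (optionally a composite of adapter + buffer + barcode +
restriction motif, which places the searchable sequence upstream of the
characteristic 3' quality drop) is split into k-mers stored with their
offset from the adapter start.  Scanning a read proceeds in rounds: round 1
examines adapter offsets {0, k, 2k, ...}, round 2 offsets {1, k+1, 2k+1, ...},
and so on for ``-r`` rounds or until the k-mers are exhausted.  Every
occurrence of an indexed k-mer at read position p with adapter offset o
votes for adapter start index p - o; the first start index supported by
``-m`` distinct offsets is the hit (ties within a round resolve to the
5'-most start — maximal removal is the conservative choice for
contamination).  Seed voting is robust to the poly-A/poly-G artifacts and
base-call errors that derail local alignment of deeply embedded adapters;
an optional modified Smith-Waterman mode (``-t``) covers short terminal
overlaps instead.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from .fastq_io import FastqRecord, FastqWriter, iter_pairs, read_fastq

DEFAULT_K = 8
DEFAULT_ROUNDS = 3
DEFAULT_VOTES = 2
DEFAULT_MIN_OVERLAP = 12
DEFAULT_MIN_LEN = 50


@dataclass(slots=True)
class AdapterHit:
    adapter: str  # adapter id
    start_index: int  # 0-based read position where the adapter begins (may be < 0)
    votes: int


@dataclass
class AdapterIndex:
    """k-mer -> (adapter id, offset-from-adapter-start) lookup.

    ``rounds[j]`` lists the (adapter id, offset, k-mer) triples whose offset
    is congruent to j modulo k, sorted by offset — the search schedule.
    """

    k: int
    adapters: dict[str, str]  # id -> sequence
    entries: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    rounds: list[list[tuple[str, int, str]]] = field(default_factory=list)


def build_index(adapters: list[str] | dict[str, str], k: int = DEFAULT_K) -> AdapterIndex:
    """Index every k-mer of every adapter at every offset."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not isinstance(adapters, dict):
        adapters = {f"adapter{i}": a for i, a in enumerate(adapters)}
    entries: dict[str, list[tuple[str, int]]] = {}
    for aid, seq in adapters.items():
        if len(seq) < k:
            raise ValueError(f"adapter {aid!r} is shorter than k={k}")
        for o in range(len(seq) - k + 1):
            entries.setdefault(seq[o : o + k], []).append((aid, o))
    rounds: list[list[tuple[str, int, str]]] = [[] for _ in range(k)]
    for aid, seq in adapters.items():
        for o in range(len(seq) - k + 1):
            rounds[o % k].append((aid, o, seq[o : o + k]))
    for rnd in rounds:
        rnd.sort(key=lambda t: t[1])
    return AdapterIndex(k=k, adapters=dict(adapters), entries=entries, rounds=rounds)


def _read_kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    pos: dict[str, list[int]] = {}
    for p in range(len(seq) - k + 1):
        pos.setdefault(seq[p : p + k], []).append(p)
    return pos


def scan_read(
    rec: FastqRecord,
    index: AdapterIndex,
    m: int = DEFAULT_VOTES,
    r: int = DEFAULT_ROUNDS,
) -> AdapterHit | None:
    """Vote for adapter start indices over the round schedule.

    Votes are counted as *distinct* supporting offsets per (adapter, start)
    candidate, so a repeated k-mer cannot double-vote.  Candidates are
    evaluated at the end of each round; among candidates reaching m votes in
    the same round the smallest start index wins.
    """
    if m < 1 or r < 1:
        raise ValueError("m and r must be >= 1")
    candidates = _scan_candidates(rec, index, m, r)
    if not candidates:
        return None
    start, aid, n = candidates[0]
    return AdapterHit(adapter=aid, start_index=start, votes=n)


def _scan_candidates(
    rec: FastqRecord, index: AdapterIndex, m: int, r: int
) -> list[tuple[int, str, int]]:
    """(start, adapter id, votes) candidates from the first qualifying round."""
    kmers = _read_kmer_positions(rec.seq, index.k)
    if not kmers:
        return []
    votes: dict[tuple[str, int], set[int]] = {}
    for rnd in index.rounds[:r]:
        for aid, o, kmer in rnd:
            hits = kmers.get(kmer)
            if hits is None:
                continue
            for p in hits:
                votes.setdefault((aid, p - o), set()).add(o)
        qualified = sorted(
            (start, aid, len(offs))
            for (aid, start), offs in votes.items()
            if len(offs) >= m
        )
        if qualified:
            return qualified
    return []


def smith_waterman(
    read: str, adapter: str, match: int = 1, mismatch: int = -1, gap: int = -2
) -> tuple[int, int, int, int, int]:
    """Plain Smith-Waterman; returns (score, read_start, read_end, ad_start, ad_end).

    End coordinates are exclusive.  On ties the highest-scoring cell first
    encountered row-major wins (deterministic).
    """
    n, mlen = len(read), len(adapter)
    prev = [0] * (mlen + 1)
    best = (0, 0, 0)  # score, i, j
    cells = {}
    for i in range(1, n + 1):
        cur = [0] * (mlen + 1)
        ri = read[i - 1]
        for j in range(1, mlen + 1):
            diag = prev[j - 1] + (match if ri == adapter[j - 1] else mismatch)
            score = max(0, diag, prev[j] + gap, cur[j - 1] + gap)
            cur[j] = score
            if score > 0:
                if score == diag and diag > 0:
                    src = (i - 1, j - 1)
                elif score == prev[j] + gap:
                    src = (i - 1, j)
                else:
                    src = (i, j - 1)
                cells[(i, j)] = src
                if score > best[0]:
                    best = (score, i, j)
        prev = cur
    score, i, j = best
    if score == 0:
        return 0, 0, 0, 0, 0
    end_i, end_j = i, j
    while (i, j) in cells:
        i, j = cells[(i, j)]
    return score, i, end_i, j, end_j


def align_fallback(rec: FastqRecord, adapter: str, t: int) -> AdapterHit | None:
    """Modified Smith-Waterman adapter search requiring >= t aligned adapter bases.

    The inferred adapter start is the aligned block's read start projected
    back to adapter position 0.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    score, rs, re, as_, ae = smith_waterman(rec.seq, adapter)
    if score <= 0 or (ae - as_) < t:
        return None
    return AdapterHit(adapter="sw", start_index=rs - as_, votes=score)


MAX_MISMATCH_FRAC = 0.1  # verification tolerance over the overlap region


def mismatch_allowance(overlap: int, max_frac: float = MAX_MISMATCH_FRAC) -> int:
    """Mismatches tolerated when verifying a voted hit over ``overlap`` bases."""
    return max(1, int(max_frac * overlap))


def _verify(rec: FastqRecord, template: str, start: int,
            max_frac: float = MAX_MISMATCH_FRAC) -> bool:
    """Hamming-check a voted hit against its template over the overlap.

    Chance collinear k-mer matches (e.g. a 9-base overlap voting at two
    adjacent offsets) can reach the vote threshold; a genuine read-through
    agrees with the template across the whole overlap up to base-call error.
    """
    s = max(start, 0)
    tpl = template[s - start :]
    region = rec.seq[s:]
    n = min(len(region), len(tpl))
    if n == 0:
        return False
    mm = sum(a != b for a, b in zip(region[:n], tpl[:n]))
    return mm <= mismatch_allowance(n, max_frac)


def find_adapter(
    rec: FastqRecord,
    index: AdapterIndex,
    m: int = DEFAULT_VOTES,
    r: int = DEFAULT_ROUNDS,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    t: int | None = None,
) -> AdapterHit | None:
    """k-mer scan with overlap and template-agreement rules, plus optional fallback.

    A voted candidate is accepted only if (a) its start leaves at least
    ``min_overlap`` adapter bases inside the read — shorter overlaps must be
    confirmed by the Smith-Waterman mode when enabled — and (b) the read
    agrees with the adapter template across the overlap up to a mismatch
    tolerance, which rejects chance k-mer collisions.
    """
    for start, aid, votes in _scan_candidates(rec, index, m, r):
        overlap = len(rec) - start
        if overlap >= min_overlap:
            if _verify(rec, index.adapters[aid], start):
                return AdapterHit(adapter=aid, start_index=start, votes=votes)
            continue
        if t is not None:
            confirmed = align_fallback(rec, index.adapters[aid], t)
            if confirmed is not None and confirmed.start_index == start:
                return AdapterHit(adapter=aid, start_index=start, votes=votes)
    if t is not None:
        best: AdapterHit | None = None
        for aid, seq in index.adapters.items():
            sw = align_fallback(rec, seq, t)
            if sw is not None and (best is None or sw.start_index < best.start_index):
                best = AdapterHit(adapter=aid, start_index=sw.start_index, votes=sw.votes)
        return best
    return None


def trim_read(rec: FastqRecord, hit: AdapterHit | None) -> FastqRecord:
    """Truncate sequence and quality at the adapter start (negative start -> empty)."""
    if hit is None:
        return rec
    return rec.slice(0, max(0, hit.start_index))


def trim_adapters(
    r1_path: str | os.PathLike,
    r2_path: str | os.PathLike | None,
    index_r1: AdapterIndex,
    index_r2: AdapterIndex | None = None,
    m: int = DEFAULT_VOTES,
    r: int = DEFAULT_ROUNDS,
    t: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_len: int = DEFAULT_MIN_LEN,
    outdir: str | os.PathLike = ".",
    prefix: str = "porifera",
) -> dict:
    """Trim adapter read-through from a library; conservation is tracked.

    Reads with a detected adapter are truncated at the inferred start; reads
    shorter than ``min_len`` after trimming are dropped to a discard file
    (their mate survives in an ``se.`` file); adapter-free reads pass
    unchanged.  Returns a manifest with counts and the post-trim read-length
    distribution.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    writer = FastqWriter()

    def p(name: str) -> str:
        return os.path.join(outdir, name)

    lengths: dict[int, int] = {}
    n_in = n_out = n_discard = n_trimmed = 0

    def process(rec: FastqRecord, index: AdapterIndex) -> FastqRecord:
        nonlocal n_trimmed
        hit = find_adapter(rec, index, m=m, r=r, min_overlap=min_overlap, t=t)
        if hit is not None:
            n_trimmed += 1
            rec = trim_read(rec, hit)
        return rec

    if r2_path is None:
        paths = {"r1": p(f"{prefix}.R1.fastq"), "discard_r1": p(f"discard.{prefix}.R1.fastq")}
        writer.touch(paths["r1"])
        for rec in read_fastq(r1_path):
            n_in += 1
            out = process(rec, index_r1)
            if len(out) >= min_len:
                writer.write(paths["r1"], out)
                lengths[len(out)] = lengths.get(len(out), 0) + 1
                n_out += 1
            else:
                writer.write(paths["discard_r1"], out)
                n_discard += 1
    else:
        idx2 = index_r2 if index_r2 is not None else index_r1
        paths = {
            "r1": p(f"{prefix}.R1.fastq"),
            "r2": p(f"{prefix}.R2.fastq"),
            "se_r1": p(f"se.{prefix}.R1.fastq"),
            "se_r2": p(f"se.{prefix}.R2.fastq"),
            "discard_r1": p(f"discard.{prefix}.R1.fastq"),
            "discard_r2": p(f"discard.{prefix}.R2.fastq"),
        }
        writer.touch(paths["r1"])
        writer.touch(paths["r2"])
        for pair in iter_pairs(r1_path, r2_path):
            n_in += 2
            o1 = process(pair.r1, index_r1)
            o2 = process(pair.r2, idx2)
            ok1, ok2 = len(o1) >= min_len, len(o2) >= min_len
            if ok1 and ok2:
                writer.write(paths["r1"], o1)
                writer.write(paths["r2"], o2)
                n_out += 2
            elif ok1:
                writer.write(paths["se_r1"], o1)
                writer.write(paths["discard_r2"], o2)
                n_out += 1
                n_discard += 1
            elif ok2:
                writer.write(paths["se_r2"], o2)
                writer.write(paths["discard_r1"], o1)
                n_out += 1
                n_discard += 1
            else:
                writer.write(paths["discard_r1"], o1)
                writer.write(paths["discard_r2"], o2)
                n_discard += 2
            for out, ok in ((o1, ok1), (o2, ok2)):
                if ok:
                    lengths[len(out)] = lengths.get(len(out), 0) + 1
    file_counts = writer.close()
    return {
        "paths": paths,
        "file_counts": file_counts,
        "reads_in": n_in,
        "reads_out": n_out,
        "reads_discarded": n_discard,
        "reads_trimmed": n_trimmed,
        "length_distribution": dict(sorted(lengths.items())),
    }


def load_adapters(path: str | os.PathLike) -> list[str]:
    """Read a newline-separated adapter list (blank lines ignored)."""
    with open(path) as fh:
        adapters = [line.strip().upper() for line in fh if line.strip()]
    if not adapters:
        raise ValueError(f"no adapters in {path}")
    return adapters
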