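"""Reduced-representation paired-end read simulator with full ground truth.

Emulates an enzyme-fragmented dual-barcoded library: a (synthetic or
user-supplied) genome is digested in silico, double-digest fragments flanked
by the two different enzymes are retained, sampled with weights from a
Normal(400, 100) fragment-length law, and dressed with the library
construct — 6 bp buffer + variable-length (7-10 bp) barcode on each side
plus outer sequencing adapters.  Reads of fixed length are taken from both
ends; when the construct is shorter than the read, sequencing runs through
into the opposite adapter and the read-through start index is recorded in
the per-read truth table alongside sample identity, genome coordinates and
the unmutated sequences.

Default enzymes are NsiI (ATGCA^T, 3' overhang TGCA: retained forward ends
begin with TGCAT) and NlaIII (CATG^, 3' overhang CATG: retained reverse
ends begin with CATG).  Base-call errors are applied as independent
substitutions by a separate, seeded mutation step so the same library can
be emitted at several error rates; indels are not modeled (downstream
matching is Hamming-based).
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .anemone import BarcodeScheme, min_levenshtein
from .fastq_io import FastqRecord, PHRED_OFFSET, read_fastq, write_fastq

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Enzyme:
    """Restriction enzyme with 0-based effective cut offsets.

    ``down_start``: offset from the recognition-site start at which the
    downstream fragment's sequenced end begins (the 3' overhang, if any, is
    regenerated on both products, so neighbouring fragments overlap over it).
    ``up_end``: offset at which the upstream fragment's sequenced end stops
    (exclusive).
    """

    name: str
    site: str
    down_start: int
    up_end: int


ENZYMES = {
    "NsiI": Enzyme("NsiI", "ATGCAT", 1, 5),  # ATGCA^T; both ends carry TGCA(T)
    "NlaIII": Enzyme("NlaIII", "CATG", 0, 4),  # CATG^; both ends carry CATG
    "AluI": Enzyme("AluI", "AGCT", 2, 2),  # AG^CT, blunt
    "HaeIII": Enzyme("HaeIII", "GGCC", 2, 2),  # GG^CC, blunt
}

# outer sequencing adapters flanking the barcoded construct (synthetic
# Illumina-style stand-ins; any fixed strings work for validation)
ADAPTER_P1 = "AATGATACGGCGACCACCGAGATCTACAC"
ADAPTER_P2 = "CAAGCAGAAGACGGCATACGAGATCGGTC"

DEFAULT_BUFFER_F = "TCAGCT"
DEFAULT_BUFFER_R = "GATCGA"


@dataclass(frozen=True)
class Fragment:
    contig: str
    start: int  # 0-based, inclusive, in genome coordinates
    end: int  # exclusive
    left: str  # enzyme name at the 5' boundary
    right: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimConfig:
    read_length: int = 150
    frag_mean: float = 400.0
    frag_sd: float = 100.0
    frag_min: int = 30
    frag_max: int = 800
    n_pairs: int = 10000
    mutation_rate: float | np.ndarray = 0.0
    buffer_f: str = DEFAULT_BUFFER_F
    buffer_r: str = DEFAULT_BUFFER_R
    adapter_p1: str = ADAPTER_P1
    adapter_p2: str = ADAPTER_P2
    enzymes: tuple[str, str] = ("NsiI", "NlaIII")
    a_tail: bool = False  # blunt-digest WGS preset: A-tailing adds a T motif
    q_plateau: int = 38
    q_end: int = 31
    q_start: int = 33
    q_noise: float = 1.5
    seed: int = 0


def wgs_preset(**kwargs) -> SimConfig:
    """Partial blunt digest (AluI/HaeIII) + A-tailing; reads begin with 'T'."""
    kwargs.setdefault("enzymes", ("AluI", "HaeIII"))
    kwargs.setdefault("a_tail", True)
    return SimConfig(**kwargs)


@dataclass(slots=True)
class TruthRecord:
    read_id: str
    sample: str
    contig: str
    start: int
    end: int
    strand: str
    r1_adapter: int | None  # adapter start index in R1, None if absent
    r2_adapter: int | None
    r1_seq: str  # unmutated
    r2_seq: str


def make_genome(length: int, gc: float = 0.4, seed: int = 0, name: str = "chr1") -> str:
    """Random i.i.d. genome with the given GC fraction; deterministic per seed."""
    if length < 10_000:
        raise ValueError("genome length must be >= 10 kb for a useful digest")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return bases.tobytes().decode()


def write_genome(seq: str, path: str | os.PathLike, name: str = "chr1") -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="synthetic")], os.fspath(path), "fasta")


def read_genome(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(os.fspath(path), "fasta")]


def digest(
    contigs: list[tuple[str, str]] | str, enzymes: tuple[str, str] = ("NsiI", "NlaIII")
) -> list[Fragment]:
    """In-silico double digest; fragments between consecutive cut sites.

    Terminal (chromosome-end) pieces have only one enzymatic end and are
    dropped.  Retained-class fragments (one end per enzyme) are the ones a
    double-digest library amplifies; use :func:`retained` to select them.
    """
    if isinstance(contigs, str):
        contigs = [("chr1", contigs)]
    enz = [ENZYMES[e] if isinstance(e, str) else e for e in enzymes]
    frags: list[Fragment] = []
    for name, seq in contigs:
        cuts: list[tuple[int, Enzyme]] = []
        for e in enz:
            for m in re.finditer(f"(?={e.site})", seq):
                cuts.append((m.start(), e))
        cuts.sort(key=lambda c: c[0])
        for (s1, e1), (s2, e2) in zip(cuts, cuts[1:]):
            start = s1 + e1.down_start
            end = s2 + e2.up_end
            if end > start:
                frags.append(Fragment(name, start, end, e1.name, e2.name))
    return frags


def retained(frags: list[Fragment], enzymes: tuple[str, str]) -> list[Fragment]:
    """Double-digest retained class: one end from each enzyme."""
    a, b = enzymes
    return [f for f in frags if {f.left, f.right} == {a, b}]


def make_barcode_scheme(
    n_forward: int,
    n_reverse: int = 0,
    lengths: tuple[int, ...] = (7, 8, 9, 10),
    min_dist: int = 3,
    seed: int = 0,
) -> BarcodeScheme:
    """Random variable-length barcode sets with minimum Levenshtein distance.

    Greedy rejection sampling; deterministic per seed.  Sample names are
    ``s<F>`` for single-index schemes and ``s<F>.<R>`` for dual.
    """
    rng = np.random.default_rng(seed)
    bases = "ACGT"

    def grow(n: int) -> list[str]:
        out: list[str] = []
        attempts = 0
        while len(out) < n:
            attempts += 1
            if attempts > 200 * n:
                raise RuntimeError("could not grow barcode set; relax constraints")
            L = lengths[len(out) % len(lengths)]
            cand = "".join(bases[i] for i in rng.integers(0, 4, size=L))
            # exact prefix nesting is rejected outright: a nested pair keeps
            # Levenshtein distance >= 3 yet collides during prefix matching
            if all(
                _lev(cand, b) >= min_dist
                and not cand.startswith(b)
                and not b.startswith(cand)
                for b in out
            ):
                out.append(cand)
        return out

    forward = grow(n_forward)
    if n_reverse:
        reverse = grow(n_reverse)
        matrix = {
            (f, r): f"s{i}.{j}"
            for i, f in enumerate(forward)
            for j, r in enumerate(reverse)
        }
        return BarcodeScheme(forward, reverse, matrix)
    return BarcodeScheme(forward, [], {(f, None): f"s{i}" for i, f in enumerate(forward)})


def _lev(a: str, b: str) -> int:
    import edlib

    return edlib.align(a, b, mode="NW", task="distance")["editDistance"]


def _quality_means(config: SimConfig) -> np.ndarray:
    """Per-position mean Q: 5' ramp-up, high plateau, 3' decay."""
    L = config.read_length
    means = np.full(L, float(config.q_plateau))
    ramp = min(6, L)
    means[:ramp] = np.linspace(config.q_start, config.q_plateau, ramp)
    tail = max(L - int(0.75 * L), 2)
    means[-tail:] = np.linspace(config.q_plateau, config.q_end, tail)
    return means


def _qualities(rng: np.random.Generator, config: SimConfig, n: int) -> list[str]:
    means = _quality_means(config)
    q = rng.normal(means, config.q_noise, size=(n, len(means)))
    q = np.clip(np.rint(q), 2, 40).astype(np.uint8) + PHRED_OFFSET
    return [row.tobytes().decode() for row in q]


def build_reads(
    frags: list[Fragment],
    contigs: list[tuple[str, str]] | str,
    scheme: BarcodeScheme,
    config: SimConfig,
    round_robin: bool = True,
) -> tuple[list[FastqRecord], list[FastqRecord], list[TruthRecord]]:
    """Sample fragments under the length law and emit unmutated read pairs.

    Fragments are drawn with replacement, weighted by the Normal(frag_mean,
    frag_sd) density truncated to [frag_min, frag_max] (a reduced-representation library
    sequences each retained locus many times over).  Sample identities cycle
    round-robin through every (forward, reverse) cell so a run with
    ``n_pairs`` >= number of cells exercises the full combinatorial space.
    """
    if isinstance(contigs, str):
        contigs = [("chr1", contigs)]
    seqs = dict(contigs)
    keep = retained(frags, config.enzymes) if config.enzymes else list(frags)
    if not keep:
        raise ValueError("no retained fragments to sample from")
    lens = np.array([f.length for f in keep], dtype=float)
    w = np.exp(-0.5 * ((lens - config.frag_mean) / config.frag_sd) ** 2)
    w[(lens < config.frag_min) | (lens > config.frag_max)] = 0.0
    if w.sum() == 0:
        raise ValueError("no fragments within the length-law truncation window")
    w /= w.sum()

    rng = np.random.default_rng(config.seed)
    picks = rng.choice(len(keep), size=config.n_pairs, p=w)
    cells = sorted(scheme.sample_matrix.items(), key=lambda kv: kv[1])
    if round_robin:
        cell_idx = np.arange(config.n_pairs) % len(cells)
    else:
        cell_idx = rng.integers(0, len(cells), size=config.n_pairs)

    fwd_enz = ENZYMES[config.enzymes[0]] if config.enzymes else None
    L = config.read_length
    quals1 = _qualities(rng, config, config.n_pairs)
    quals2 = _qualities(rng, config, config.n_pairs)
    r1_out: list[FastqRecord] = []
    r2_out: list[FastqRecord] = []
    truth: list[TruthRecord] = []
    for i in range(config.n_pairs):
        frag = keep[picks[i]]
        (bf, br), sample = cells[cell_idx[i]]
        insert = seqs[frag.contig][frag.start : frag.end]
        strand = "+"
        if fwd_enz is not None and frag.left != fwd_enz.name:
            insert = revcomp(insert)  # orient so the forward enzyme's motif leads
            strand = "-"
        if config.a_tail:
            insert = "T" + insert + "A"
        rc_br = revcomp(br or "")
        r1_tpl = config.buffer_f + bf + insert + rc_br + revcomp(
            config.buffer_r
        ) + revcomp(config.adapter_p2)
        r2_tpl = config.buffer_r + (br or "") + revcomp(insert) + revcomp(
            bf
        ) + revcomp(config.buffer_f) + revcomp(config.adapter_p1)
        a1 = len(config.buffer_f) + len(bf) + len(insert)
        a2 = len(config.buffer_r) + len(br or "") + len(insert)
        r1_seq = (r1_tpl + "A" * L)[:L]
        r2_seq = (r2_tpl + "A" * L)[:L]
        rid = f"sim{i}"
        r1_out.append(FastqRecord(rid, r1_seq, quals1[i]))
        r2_out.append(FastqRecord(rid, r2_seq, quals2[i]))
        truth.append(
            TruthRecord(
                read_id=rid,
                sample=sample,
                contig=frag.contig,
                start=frag.start,
                end=frag.end,
                strand=strand,
                r1_adapter=a1 if a1 < L else None,
                r2_adapter=a2 if a2 < L else None,
                r1_seq=r1_seq,
                r2_seq=r2_seq,
            )
        )
    return r1_out, r2_out, truth


def mutate_records(
    records: list[FastqRecord],
    rate: float | np.ndarray,
    seed: int,
    degrade_q: bool = False,
) -> list[FastqRecord]:
    """Independent per-base substitutions (uniform over the 3 alternatives).

    ``rate`` may be a scalar or a per-position array (padded/truncated to
    each read's length), so error can be concentrated in chosen regions.
    Optionally drops the quality of mutated bases to Q 12.
    """
    rng = np.random.default_rng(seed)
    per_pos = np.asarray(rate, dtype=float)
    out: list[FastqRecord] = []
    alt = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}
    low_q = chr(12 + PHRED_OFFSET)
    for rec in records:
        n = len(rec)
        if per_pos.ndim == 0:
            hit = rng.random(n) < float(per_pos)
        else:
            r = np.zeros(n)
            r[: min(n, per_pos.size)] = per_pos[:n]
            hit = rng.random(n) < r
        if not hit.any():
            out.append(rec)
            continue
        seq = list(rec.seq)
        qual = list(rec.qual)
        for j in np.nonzero(hit)[0]:
            base = seq[j]
            choices = alt.get(base, list("ACGT"))
            seq[j] = choices[rng.integers(0, len(choices))]
            if degrade_q:
                qual[j] = low_q
        out.append(FastqRecord(rec.id, "".join(seq), "".join(qual)))
    return out


def write_truth(truth: list[TruthRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(
            "read_id\tsample\tcontig\tstart\tend\tstrand\tr1_adapter\tr2_adapter\tr1_seq\tr2_seq\n"
        )
        for t in truth:
            a1 = "NA" if t.r1_adapter is None else str(t.r1_adapter)
            a2 = "NA" if t.r2_adapter is None else str(t.r2_adapter)
            fh.write(
                f"{t.read_id}\t{t.sample}\t{t.contig}\t{t.start}\t{t.end}\t{t.strand}"
                f"\t{a1}\t{a2}\t{t.r1_seq}\t{t.r2_seq}\n"
            )


def read_truth(path: str | os.PathLike) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            f = line.rstrip("\n").split("\t")
            out.append(
                TruthRecord(
                    f[0], f[1], f[2], int(f[3]), int(f[4]), f[5],
                    None if f[6] == "NA" else int(f[6]),
                    None if f[7] == "NA" else int(f[7]),
                    f[8], f[9],
                )
            )
    return out


def adapter_templates(
    bf: str, br: str, config: SimConfig, tier: str = "barcode"
) -> tuple[str, str]:
    """Per-sample adapter search templates for the read-through trimmer.

    Tiers mirror increasing template specificity: ``adapter`` (outer adapter
    only), ``barcode`` (barcode + buffer + adapter — starts exactly at the
    contamination boundary), ``motif`` (restriction-site motif prepended;
    detected starts sit motif-length bases 5' of the boundary).
    """
    ad1 = revcomp(config.adapter_p2)
    ad2 = revcomp(config.adapter_p1)
    if tier == "adapter":
        return ad1, ad2
    r1 = revcomp(br) + revcomp(config.buffer_r) + ad1
    r2 = revcomp(bf) + revcomp(config.buffer_f) + ad2
    if tier == "barcode":
        return r1, r2
    if tier == "motif":
        e1, e2 = (ENZYMES[e] for e in config.enzymes)
        # sequence immediately 5' of the contamination boundary in each read:
        # the insert's trailing restriction-site piece (or the A-tail base)
        m1 = e2.site[: e2.up_end] if not config.a_tail else "A"
        m2 = revcomp(e1.site[e1.down_start :]) if not config.a_tail else "A"
        return m1 + r1, m2 + r2
    raise ValueError(f"unknown tier {tier!r}")


def expected_motifs(config: SimConfig) -> tuple[list[str], list[str]]:
    """Read-start motifs implied by the enzyme pair (e.g. TGCAT / CATG)."""
    if config.a_tail:
        return ["T"], ["T"]
    e1, e2 = (ENZYMES[e] for e in config.enzymes)
    return [e1.site[e1.down_start :]], [revcomp(e2.site[: e2.up_end])]


def simulate_library(
    scheme: BarcodeScheme,
    config: SimConfig,
    outdir: str | os.PathLike,
    genome: str | list[tuple[str, str]] | None = None,
    genome_length: int = 1_000_000,
    genome_gc: float = 0.4,
    prefix: str = "sim",
) -> dict:
    """End-to-end simulation: genome -> digest -> reads (+ optional mutation).

    Writes ``<prefix>.R1.fastq``, ``<prefix>.R2.fastq`` and
    ``<prefix>.truth.tsv`` under ``outdir``; byte-deterministic for a fixed
    config and seed.
    """
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    if genome is None:
        genome = make_genome(genome_length, genome_gc, seed=config.seed)
    contigs = [("chr1", genome)] if isinstance(genome, str) else genome
    frags = digest(contigs, config.enzymes)
    r1, r2, truth = build_reads(frags, contigs, scheme, config)
    rate = config.mutation_rate
    mutated = (np.asarray(rate).max() if np.asarray(rate).size else 0) > 0
    if mutated:
        r1 = mutate_records(r1, rate, seed=config.seed + 1)
        r2 = mutate_records(r2, rate, seed=config.seed + 2)
    paths = {
        "r1": os.path.join(outdir, f"{prefix}.R1.fastq"),
        "r2": os.path.join(outdir, f"{prefix}.R2.fastq"),
        "truth": os.path.join(outdir, f"{prefix}.truth.tsv"),
    }
    write_fastq(r1, paths["r1"])
    write_fastq(r2, paths["r2"])
    write_truth(truth, paths["truth"])
    return {
        "paths": paths,
        "n_pairs": len(truth),
        "n_fragments": len(frags),
        "n_retained": len(retained(frags, config.enzymes)),
        "truth": truth,
    }
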