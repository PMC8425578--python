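import math
import re

import numpy as np
import pytest

from ngscompose import simulate as sim
from ngscompose.anemone import min_levenshtein
from ngscompose.fastq_io import read_fastq
from ngscompose.rotifer import has_motif
from ngscompose.simulate import (
    ENZYMES,
    Fragment,
    SimConfig,
    digest,
    expected_motifs,
    make_genome,
    mutate_records,
    retained,
    revcomp,
)


# ---------------------------------------------------------------- genome


def test_genome_deterministic_per_seed():
    assert make_genome(20_000, seed=4) == make_genome(20_000, seed=4)
    assert make_genome(20_000, seed=4) != make_genome(20_000, seed=5)


def test_site_density_matches_iid_expectation():
    length, gc = 2_000_000, 0.4
    genome = make_genome(length, gc, seed=1)
    p_at, p_gc = (1 - gc) / 2, gc / 2
    # NsiI site ATGCAT: A,T,G,C,A,T
    p_site = p_at**4 * p_gc**2
    expected = (length - 5) * p_site
    observed = len(re.findall("(?=ATGCAT)", genome))
    sd = math.sqrt(expected)
    assert abs(observed - expected) < 3 * sd


def test_pure_gc_genome_has_no_nsii_sites():
    genome = make_genome(50_000, gc=1.0, seed=2)
    assert "ATGCAT" not in genome


def test_gc_fraction():
    genome = make_genome(100_000, gc=0.6, seed=3)
    frac = (genome.count("G") + genome.count("C")) / len(genome)
    assert abs(frac - 0.6) < 0.01


# ---------------------------------------------------------------- digestion


def test_hand_computed_double_digest_fragment():
    genome = "AAAA" + "ATGCAT" + "AAAA" + "CATG" + "AAAA"
    frags = digest(genome)
    keep = retained(frags, ("NsiI", "NlaIII"))
    assert len(keep) == 1
    (f,) = keep
    # NsiI cut keeps TGCAT at the fragment start; NlaIII keeps CATG at its end
    assert (f.start, f.end) == (5, 18)
    assert genome[f.start : f.end] == "TGCATAAAACATG"


def test_siteless_genome_yields_no_fragments():
    assert digest("AC" * 5000) == []


def test_digest_matches_regex_oracle():
    genome = make_genome(200_000, seed=6)
    frags = digest(genome)
    cuts = []
    for name in ("NsiI", "NlaIII"):
        e = ENZYMES[name]
        for m in re.finditer(f"(?={e.site})", genome):
            cuts.append((m.start(), e))
    cuts.sort()
    expected = []
    for (s1, e1), (s2, e2) in zip(cuts, cuts[1:]):
        start, end = s1 + e1.down_start, s2 + e2.up_end
        if end > start:
            expected.append(Fragment("chr1", start, end, e1.name, e2.name))
    assert frags == expected
    # retained-class fragments carry the expected terminal motifs
    for f in retained(frags, ("NsiI", "NlaIII"))[:50]:
        insert = genome[f.start : f.end]
        if f.left == "NsiI":
            assert insert.startswith("TGCAT") and insert.endswith("CATG")
        else:
            assert insert.startswith("CATG") and insert.endswith("ATGCA")


# ---------------------------------------------------------------- barcodes


def test_barcode_scheme_distance_and_lengths():
    scheme = sim.make_barcode_scheme(24, 24, seed=2)
    for bcs in (scheme.forward, scheme.reverse):
        assert min_levenshtein(bcs) >= 3
        assert {len(b) for b in bcs} <= {7, 8, 9, 10}
    assert len(scheme.sample_matrix) == 576


# ---------------------------------------------------------------- reads


def test_simulation_deterministic(tmp_path, small_scheme):
    cfg = SimConfig(n_pairs=300, seed=12)
    a = sim.simulate_library(small_scheme, cfg, tmp_path / "a", genome_length=100_000)
    b = sim.simulate_library(small_scheme, cfg, tmp_path / "b", genome_length=100_000)
    assert (tmp_path / "a/sim.R1.fastq").read_bytes() == (tmp_path / "b/sim.R1.fastq").read_bytes()
    assert (tmp_path / "a/sim.truth.tsv").read_bytes() == (tmp_path / "b/sim.truth.tsv").read_bytes()


def test_truth_and_reads_correspond(sim_library):
    truth = {t.read_id: t for t in sim_library["truth"]}
    n = 0
    for rec in read_fastq(sim_library["paths"]["r1"]):
        n += 1
        t = truth[rec.id]
        assert rec.seq == t.r1_seq  # zero mutation: emitted == unmutated
        if t.r1_adapter is not None:
            assert t.r1_adapter < len(rec)
    assert n == len(truth)


def test_construct_layout_and_motifs(sim_library):
    scheme, cfg = sim_library["scheme"], sim_library["config"]
    cells = {s: (f, r) for (f, r), s in scheme.sample_matrix.items()}
    m1, m2 = expected_motifs(cfg)
    truth = {t.read_id: t for t in sim_library["truth"]}
    r2 = {rec.id: rec for rec in read_fastq(sim_library["paths"]["r2"])}
    for rec in read_fastq(sim_library["paths"]["r1"]):
        t = truth[rec.id]
        bf, br = cells[t.sample]
        assert rec.seq.startswith(cfg.buffer_f + bf + m1[0])
        assert r2[rec.id].seq.startswith(cfg.buffer_r + br + m2[0])
        # read-through arithmetic: construct boundary == recorded index
        insert_len = t.end - t.start
        a1 = len(cfg.buffer_f) + len(bf) + insert_len
        assert t.r1_adapter == (a1 if a1 < cfg.read_length else None)


def test_adapter_position_in_both_mates(tmp_path, small_scheme):
    cfg = SimConfig(n_pairs=400, frag_mean=90.0, frag_sd=30.0, frag_min=30, seed=8)
    res = sim.simulate_library(small_scheme, cfg, tmp_path, genome_length=200_000)
    cells = {s: (f, r) for (f, r), s in small_scheme.sample_matrix.items()}
    for t in res["truth"]:
        bf, br = cells[t.sample]
        if t.r1_adapter is not None and t.r2_adapter is not None:
            # same insert, frame differs only by barcode length
            assert t.r1_adapter - t.r2_adapter == len(bf) - len(br)
            avail = min(len(br), len(t.r1_seq) - t.r1_adapter)
            assert t.r1_seq[t.r1_adapter : t.r1_adapter + avail] == revcomp(br)[:avail]


def test_motif_guarantee_zero_mutation(sim_library):
    scheme, cfg = sim_library["scheme"], sim_library["config"]
    m1, m2 = expected_motifs(cfg)
    cells = {s: (f, r) for (f, r), s in scheme.sample_matrix.items()}
    truth = {t.read_id: t for t in sim_library["truth"]}
    for rec in read_fastq(sim_library["paths"]["r1"]):
        bf, _ = cells[truth[rec.id].sample]
        demuxed = rec.slice(len(cfg.buffer_f) + len(bf))
        assert has_motif(demuxed, m1)


# ---------------------------------------------------------------- mutation


def test_mutate_rate_zero_and_one(sim_library):
    recs = list(read_fastq(sim_library["paths"]["r1"]))[:50]
    same = mutate_records(recs, 0.0, seed=1)
    assert all(a.seq == b.seq for a, b in zip(recs, same))
    flipped = mutate_records(recs, 1.0, seed=1)
    for a, b in zip(recs, flipped):
        assert all(x != y for x, y in zip(a.seq, b.seq))


def test_mutate_observed_rate(sim_library):
    recs = list(read_fastq(sim_library["paths"]["r1"]))
    rate = 0.02
    mutated = mutate_records(recs, rate, seed=2)
    n_bases = sum(len(r) for r in recs)
    n_sub = sum(
        sum(x != y for x, y in zip(a.seq, b.seq)) for a, b in zip(recs, mutated)
    )
    sd = math.sqrt(rate * (1 - rate) * n_bases)
    assert abs(n_sub - rate * n_bases) < 3 * sd


def test_per_position_mutation_schedule(sim_library):
    recs = list(read_fastq(sim_library["paths"]["r1"]))[:400]
    L = len(recs[0])
    schedule = np.zeros(L)
    schedule[:10] = 0.5  # error concentrated at the 5' end
    mutated = mutate_records(recs, schedule, seed=3)
    head = sum(
        sum(x != y for x, y in zip(a.seq[:10], b.seq[:10]))
        for a, b in zip(recs, mutated)
    )
    tail = sum(
        sum(x != y for x, y in zip(a.seq[10:], b.seq[10:]))
        for a, b in zip(recs, mutated)
    )
    assert tail == 0 and head > 0.3 * 10 * len(recs)


def test_wgs_preset_reads_start_with_t(tmp_path, small_scheme):
    cfg = sim.wgs_preset(n_pairs=200, seed=13)
    res = sim.simulate_library(small_scheme, cfg, tmp_path, genome_length=150_000)
    cells = {s: (f, r) for (f, r), s in small_scheme.sample_matrix.items()}
    truth = {t.read_id: t for t in res["truth"]}
    for rec in read_fastq(res["paths"]["r1"]):
        bf, _ = cells[truth[rec.id].sample]
        assert rec.seq[len(cfg.buffer_f) + len(bf)] == "T"
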