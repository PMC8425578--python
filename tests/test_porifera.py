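import numpy as np
import pytest

from ngscompose import simulate as sim
from ngscompose.fastq_io import FastqRecord, read_fastq
from ngscompose.porifera import (
    AdapterHit,
    align_fallback,
    build_index,
    find_adapter,
    scan_read,
    smith_waterman,
    trim_adapters,
    trim_read,
)


def fq(seq, rid="r"):
    return FastqRecord(rid, seq, "I" * len(seq))


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


# ---------------------------------------------------------------- index


def test_index_offsets_and_size():
    idx = build_index(["ACGTACGT"], k=4)
    n_entries = sum(len(v) for v in idx.entries.values())
    assert n_entries == 5  # len - k + 1
    for kmer, hits in idx.entries.items():
        assert len(kmer) == 4
        for aid, o in hits:
            assert 0 <= o <= 4


def test_shared_kmer_listed_under_both_adapters():
    idx = build_index({"a": "AACCGGTTAA", "b": "TTAACCGGTT"}, k=6)
    shared = idx.entries.get("AACCGG")
    assert {aid for aid, _ in shared} == {"a", "b"}


def test_index_size_equals_enumeration(rng):
    adapters = [rand_seq(rng, int(rng.integers(10, 40))) for _ in range(5)]
    idx = build_index(adapters, k=8)
    expected = sum(len(a) - 8 + 1 for a in adapters)
    assert sum(len(v) for v in idx.entries.values()) == expected


def test_adapter_shorter_than_k_rejected():
    with pytest.raises(ValueError, match="shorter than k"):
        build_index({"tiny": "ACGT"}, k=8)


# ---------------------------------------------------------------- scanning


def test_exact_adapter_found_at_truth_index(rng):
    adapter = rand_seq(rng, 30)
    read = fq(rand_seq(rng, 40) + adapter)
    hit = scan_read(read, build_index({"a": adapter}, k=8), m=2)
    assert hit == AdapterHit("a", 40, hit.votes) and hit.votes >= 2


def test_adapter_free_read_yields_none(rng):
    adapter = "A" * 15 + "C" * 15
    read = fq("GT" * 75)
    assert scan_read(read, build_index({"a": adapter}, k=8)) is None


def test_round_schedule_rescues_shifted_match():
    # only offsets {1, 9, ...} (round 2) match: round 1 alone must fail
    rng = np.random.default_rng(7)
    adapter = rand_seq(rng, 24)
    # embed a version whose round-1 k-mers (offsets 0,8,16) are each broken
    broken = list(adapter)
    for o in (0, 8 + 7, 16 + 7):  # disrupt k-mers starting at 0, 8, 16
        broken[o] = "A" if broken[o] != "A" else "C"
    read = fq(rand_seq(rng, 50) + "".join(broken))
    idx = build_index({"a": adapter}, k=8)
    assert scan_read(read, idx, m=2, r=1) is None
    hit = scan_read(read, idx, m=2, r=3)
    assert hit is not None and hit.start_index == 50


def test_tiebreak_prefers_smaller_start():
    # adapter repeated back-to-back: both starts accumulate votes in round 1
    adapter = "ACGGTTCAACGGATCCGGAA"
    read = fq(adapter + adapter)
    hit = scan_read(read, build_index({"a": adapter}, k=8), m=2, r=1)
    assert hit.start_index == 0


def test_vote_threshold_monotonicity(rng):
    adapter = rand_seq(rng, 30)
    idx = build_index({"a": adapter}, k=8)
    reads = []
    for _ in range(300):
        pos = int(rng.integers(20, 120))
        seq = list(rand_seq(rng, 150))
        for i, c in enumerate(adapter[: 150 - pos]):
            seq[pos + i] = c
        for _ in range(rng.integers(0, 3)):
            j = int(rng.integers(0, 150))
            seq[j] = "ACGT"[rng.integers(0, 4)]
        reads.append(fq("".join(seq)))
    hits_by_m = [sum(scan_read(r, idx, m=m) is not None for r in reads) for m in (1, 2, 3, 4)]
    assert hits_by_m == sorted(hits_by_m, reverse=True)


def schedule_support(read, adapter, start, k=8, r=3):
    """Distinct schedule offsets exactly matching at a candidate start."""
    n = 0
    for o in range(len(adapter) - k + 1):
        if o % k >= r:
            continue
        p = start + o
        if 0 <= p <= len(read) - k and read[p : p + k] == adapter[o : o + k]:
            n += 1
    return n


def oracle_starts(read, adapter, max_mm=2, min_overlap=12):
    """Slide the full adapter; accept Hamming <= max_mm over >= min_overlap bases."""
    out = []
    for s in range(0, len(read) - min_overlap + 1):
        ov = min(len(adapter), len(read) - s)
        if ov < min_overlap:
            continue
        mm = sum(a != b for a, b in zip(read[s : s + ov], adapter[:ov]))
        if mm <= max_mm:
            out.append(s)
    return out


def overlap_mismatches(read, adapter, start):
    ov = min(len(adapter), len(read) - start)
    return sum(a != b for a, b in zip(read[start : start + ov], adapter[:ov]))


def explained_miss(read, adapter, start):
    """A missed oracle start is legitimate if votes or verification fall short."""
    from ngscompose.porifera import mismatch_allowance

    ov = min(len(adapter), len(read) - start)
    return (
        schedule_support(read, adapter, start) < 2
        or overlap_mismatches(read, adapter, start) > mismatch_allowance(ov)
    )


def test_scan_matches_sliding_oracle_on_simulated_reads():
    """10,000 reads with embedded adapters carrying 0-2 substitutions.

    Every disagreement with the sliding-Hamming oracle must be explained by
    insufficient k-mer vote support at the oracle position.
    """
    rng = np.random.default_rng(2024)
    adapter = rand_seq(rng, 35)
    idx = build_index({"a": adapter}, k=8)
    n_checked = n_hits = 0
    for _ in range(10_000):
        embed = int(rng.integers(60, 143))
        seq = list(rand_seq(rng, 150))
        region = adapter[: 150 - embed]
        for i, c in enumerate(region):
            seq[embed + i] = c
        n_sub = int(rng.integers(0, 3))
        for _ in range(n_sub):
            j = int(rng.integers(0, len(region)))
            seq[embed + j] = "ACGT"[rng.integers(0, 4)]
        read = "".join(seq)
        hit = find_adapter(fq(read), idx, m=2, r=3, min_overlap=12)
        accepted = oracle_starts(read, adapter)
        n_checked += 1
        if hit is None:
            # a miss is legitimate only where votes or verification fall short
            for s in accepted:
                assert explained_miss(read, adapter, s)
        else:
            n_hits += 1
            assert schedule_support(read, adapter, hit.start_index) >= 2
            assert len(read) - hit.start_index >= 12
            if accepted:
                assert hit.start_index <= min(accepted) or hit.start_index in accepted
    assert n_hits > 0.7 * n_checked  # the schedule detects the bulk of embeds


# ---------------------------------------------------------------- alignment


def test_sw_exact_terminal_overlap():
    adapter = "ACGGTTCAACGG"
    read = fq("T" * 30 + adapter[:8])  # 8 adapter bases at the 3' end
    hit = align_fallback(read, adapter, t=8)
    assert hit is not None and hit.start_index == 30


def test_sw_no_shared_block():
    assert align_fallback(fq("A" * 40), "C" * 20, t=10) is None


def test_sw_score_matches_biotite_oracle(rng):
    import biotite.sequence as bseq
    import biotite.sequence.align as bali

    alph = bseq.NucleotideSequence.alphabet_unamb
    mat = np.full((4, 4), -1, dtype=np.int32)
    np.fill_diagonal(mat, 1)
    matrix = bali.SubstitutionMatrix(alph, alph, mat)
    for _ in range(20):
        a = rand_seq(rng, int(rng.integers(10, 60)))
        b = rand_seq(rng, int(rng.integers(10, 40)))
        score, *_ = smith_waterman(a, b)
        ref = bali.align_optimal(
            bseq.NucleotideSequence(a), bseq.NucleotideSequence(b),
            matrix, gap_penalty=-2, local=True, max_number=1,
        )[0].score
        assert score == ref


# ---------------------------------------------------------------- trimming


def cells_of(scheme):
    return {s: (f, r) for (f, r), s in scheme.sample_matrix.items()}


def test_truth_guided_trimming_zero_mutation(sim_library):
    scheme, cfg = sim_library["scheme"], sim_library["config"]
    truth = {t.read_id: t for t in sim_library["truth"]}
    cells = cells_of(scheme)
    by_sample = {}
    for rec in read_fastq(sim_library["paths"]["r1"]):
        by_sample.setdefault(truth[rec.id].sample, []).append(rec)
    n_exact = n_with_adapter = 0
    for sample, recs in by_sample.items():
        bf, br = cells[sample]
        tpl1, _ = sim.adapter_templates(bf, br, cfg, tier="barcode")
        idx = build_index({sample: tpl1}, k=8)
        for rec in recs:
            t = truth[rec.id]
            hit = find_adapter(rec, idx, m=2, r=3, min_overlap=12)
            if t.r1_adapter is None:
                assert hit is None  # zero false positives
            elif len(rec) - t.r1_adapter >= 12:
                n_with_adapter += 1
                assert hit is not None and hit.start_index == t.r1_adapter
                n_exact += 1
            else:
                assert hit is None or hit.start_index == t.r1_adapter
    assert n_with_adapter > 100 and n_exact == n_with_adapter


def test_no_readthrough_means_no_trim(rng):
    adapter = rand_seq(rng, 30)
    idx = build_index({"a": adapter}, k=8)
    kmers = set(idx.entries)
    clean, n_random, n_fp = [], 0, 0
    while len(clean) < 300:
        seq = rand_seq(rng, 150)
        n_random += 1
        if find_adapter(fq(seq), idx) is not None:
            n_fp += 1
        if not any(seq[p : p + 8] in kmers for p in range(143)):
            clean.append(fq(seq))
    # no shared indexed k-mer -> provably no hit
    assert all(find_adapter(r, idx) is None for r in clean)
    # chance 9-base overlaps can vote at adjacent offsets, but only rarely
    assert n_fp / n_random < 0.01


def test_template_specificity_ordering(tmp_path, small_scheme):
    """Detection count: adapter-only <= +barcode <= +restriction-site templates."""
    cfg = sim.SimConfig(n_pairs=800, frag_mean=100.0, frag_sd=50.0, frag_min=30,
                        mutation_rate=0.01, seed=9)
    res = sim.simulate_library(small_scheme, cfg, tmp_path, genome_length=200_000)
    truth = {t.read_id: t for t in res["truth"]}
    cells = cells_of(small_scheme)
    counts = {}
    for tier in ("adapter", "barcode", "motif"):
        n = 0
        for rec in read_fastq(res["paths"]["r1"]):
            sample = truth[rec.id].sample
            bf, br = cells[sample]
            tpl1, _ = sim.adapter_templates(bf, br, cfg, tier=tier)
            idx = build_index({sample: tpl1}, k=8)
            if find_adapter(rec, idx, m=2, r=3, min_overlap=12) is not None:
                n += 1
        counts[tier] = n
    assert counts["adapter"] <= counts["barcode"] <= counts["motif"]
    assert counts["motif"] > 0


def test_trim_file_conservation_and_min_len(sim_library):
    scheme, cfg = sim_library["scheme"], sim_library["config"]
    cells = cells_of(scheme)
    bf, br = next(iter(cells.values()))
    tpl1, tpl2 = sim.adapter_templates(bf, br, cfg, tier="barcode")
    outdir = str(sim_library["paths"]["r1"]).rsplit("/", 1)[0] + "/trimout"
    res = trim_adapters(
        sim_library["paths"]["r1"], sim_library["paths"]["r2"],
        build_index({"s": tpl1}), build_index({"s": tpl2}),
        outdir=outdir, min_len=50,
    )
    assert res["reads_in"] == res["reads_out"] + res["reads_discarded"]
    for L in res["length_distribution"]:
        assert L >= 50


def test_negative_start_trims_whole_read():
    rec = fq("ACGTACGTAC")
    assert len(trim_read(rec, AdapterHit("a", -3, 2))) == 0
    assert trim_read(rec, None).seq == rec.seq
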