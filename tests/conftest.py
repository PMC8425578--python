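import numpy as np
import pytest

from ngscompose.fastq_io import FastqRecord, PHRED_OFFSET
from ngscompose import simulate as sim


def random_record(rng: np.random.Generator, length: int, rid: str = "r") -> FastqRecord:
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
    qual = "".join(chr(int(q) + PHRED_OFFSET) for q in rng.integers(0, 41, size=length))
    return FastqRecord(rid, seq, qual)


def random_records(seed: int, n: int, lengths=(80, 100, 120)) -> list[FastqRecord]:
    rng = np.random.default_rng(seed)
    return [
        random_record(rng, int(rng.choice(lengths)), rid=f"r{i}") for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_scheme():
    """4x4 dual-index scheme with minimum Levenshtein distance 3."""
    return sim.make_barcode_scheme(4, 4, seed=11)


@pytest.fixture(scope="session")
def sim_library(tmp_path_factory, small_scheme):
    """Zero-mutation simulated library with heavy adapter read-through."""
    cfg = sim.SimConfig(
        n_pairs=1500, frag_mean=120.0, frag_sd=60.0, frag_min=30, seed=5
    )
    outdir = tmp_path_factory.mktemp("simlib")
    res = sim.simulate_library(small_scheme, cfg, outdir, genome_length=300_000)
    res["config"] = cfg
    res["scheme"] = small_scheme
    return res
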