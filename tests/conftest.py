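"""Shared fixtures: small deterministic genomes and one mid-size library."""

import numpy as np
import pytest

from bsmira import bsalign, methcall, simseq
from bsmira.refdata import ReferenceGenome


def random_genome(length: int, seed: int, gc: float = 0.4, n_chroms: int = 1):
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    at = (1 - gc) / 2
    p = [at, gc / 2, gc / 2, at]
    return ReferenceGenome(
        {
            f"chr{i+1}": bases[rng.choice(4, size=length // n_chroms, p=p)]
            .tobytes()
            .decode()
            for i in range(n_chroms)
        }
    )


@pytest.fixture(scope="session")
def small_genome():
    return random_genome(5_000, seed=42)


@pytest.fixture(scope="session")
def mini_library():
    """A small but complete error-free simulated library (fast to map)."""
    cfg = simseq.SimulationConfig(
        genome_length=60_000,
        n_chroms=2,
        cgi_count=8,
        cgi_length_range=(400, 900),
        gene_count=8,
        n_reads=2_000,
        error_rate=0.0,
        seed=5,
    )
    return simseq.simulate(cfg)


@pytest.fixture(scope="session")
def mini_mapped(mini_library):
    """Trimmed + mapped mini library with per-CpG calls."""
    lib = mini_library
    trimmed = [
        (rid, t)
        for rid, seq in lib.reads
        if (t := bsalign.trim_adapters(seq)) is not None
    ]
    mapper = bsalign.Mapper(lib.genome)
    alignments, counts = mapper.map_reads(trimmed)
    site_table, cph = methcall.call_sample(alignments, dict(trimmed), lib.genome)
    return {
        "library": lib,
        "trimmed": trimmed,
        "alignments": alignments,
        "counts": counts,
        "site_table": site_table,
        "cph": cph,
    }
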