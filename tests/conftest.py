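import numpy as np
import pytest

from mdstab.benchmark import build_benchmark
from mdstab.ensemble import Mutation
from mdstab.synthetic import (
    FixtureSpec,
    build_benchmark_samples,
    build_ideal_peptide,
    jitter_trajectory,
)


@pytest.fixture(scope="session")
def helix15():
    """Ideal 15-mer polyalanine helix, single frame."""
    return build_ideal_peptide("A" * 15)


@pytest.fixture(scope="session")
def strand15():
    return build_ideal_peptide(FixtureSpec("A" * 15, conformation="strand"))


@pytest.fixture(scope="session")
def mixed_helix():
    """A 16-residue mixed-sequence helix used across metric tests."""
    return build_ideal_peptide("ADKLSNQERTVYFAMW")


@pytest.fixture
def make_trajectory():
    def _make(structure, n_frames=10, jitter=0.1, seed=0):
        spec = FixtureSpec(
            structure.variant_id.split(":")[1] if ":" in structure.variant_id else "X",
            n_frames=n_frames,
            jitter=jitter,
            seed=seed,
        )
        return jitter_trajectory(structure, spec)

    return _make


@pytest.fixture(scope="session")
def benchmark_sets():
    """Synthetic 60-RMSF/20-SASA curve sets."""
    samples = build_benchmark_samples(n_per_category=40, seed=3)
    rmsf_set, sasa_set, manifest = build_benchmark(samples)
    return rmsf_set, sasa_set, manifest


@pytest.fixture(scope="session")
def scored_variant_pair():
    """Wild type + three mutant jitter ensembles sharing the same backbone
    statistics, for scoring-pipeline tests."""
    seq_wt = "ADKLSNQERTVYFAMW"
    def ens_for(seq, seed):
        base = build_ideal_peptide(seq)
        return jitter_trajectory(base, FixtureSpec(seq, n_frames=6, jitter=0.12, seed=seed))

    wt = ens_for(seq_wt, 0)
    mutants = {}
    for pos, newaa in [(5, "R"), (7, "K"), (12, "A")]:
        seq = seq_wt[: pos - 1] + newaa + seq_wt[pos:]
        mutants[Mutation("A", pos, seq_wt[pos - 1], newaa)] = ens_for(seq, 10 + pos)
    return wt, mutants
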