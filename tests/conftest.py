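import numpy as np
import pytest

from readscrub.minimizers import MinimizerConfig
from readscrub.overlap import find_overlaps
from readscrub.pipeline import build_segments
from readscrub.simulate import (SimConfig, simulate_genome, simulate_reads,
                                truth_labels)


@pytest.fixture(scope="session")
def sim_small():
    """A small noisy dataset: one 20 kb genome at 14x, no chimeras (~100 reads)."""
    cfg = SimConfig(genome_lengths=(20_000,), coverage=14, chimera_rate=0.0,
                    rng_seed=7)
    genomes = simulate_genome(cfg)
    reads, truths = simulate_reads(genomes, cfg)
    return cfg, genomes, reads, truths


@pytest.fixture(scope="session")
def piles_small(sim_small):
    _, _, reads, _ = sim_small
    return find_overlaps(reads)


@pytest.fixture(scope="session")
def segments_small(sim_small, piles_small):
    _, _, reads, truths = sim_small
    segments = build_segments(reads, piles_small)
    labels = truth_labels(truths, segments)
    return segments, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)


def random_seq(rng, n, alphabet="ACGT", n_prob=0.0):
    letters = list(alphabet) + (["N"] if n_prob else [])
    p = None
    if n_prob:
        p = [(1 - n_prob) / len(alphabet)] * len(alphabet) + [n_prob]
    return "".join(rng.choice(letters, p=p, size=n))
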