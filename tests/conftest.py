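import numpy as np
import pytest

from paircraft import (
    InteractionDataset, KmerToyEmbedder, PairKey, SequenceRecord, generate,
)
from paircraft.synthetic import SyntheticConfig, TypeSpec


@pytest.fixture(scope="session")
def small_synthetic():
    """A fast three-class dataset with a planted signal, for pipeline tests."""
    cfg = SyntheticConfig(
        type_specs=[
            TypeSpec("miRNA", 80, 18, 25),
            TypeSpec("lncRNA", 40, 200, 800),
            TypeSpec("snoRNA", 40, 60, 120),
        ],
        pair_counts={
            ("miRNA", "lncRNA"): 120,
            ("lncRNA", "snoRNA"): 60,
        },
        label_noise=0.0,
    )
    return generate(cfg, seed=11)


@pytest.fixture(scope="session")
def default_synthetic():
    """The default study conditions (600 sequences, ~1,500 positives)."""
    return generate(seed=5)


@pytest.fixture
def toy_embedder():
    return KmerToyEmbedder(k=3, stride=3, H=8, seed=42)


def random_typed_pool(rng, n_per_type=50, types=("miRNA", "lncRNA", "snoRNA", "snRNA")):
    """Random sequences spread over several ncRNA classes."""
    seqs = {}
    for t in types:
        for i in range(n_per_type):
            sid = f"{t}_{i:03d}"
            length = int(rng.integers(20, 60))
            seq = "".join(rng.choice(list("ACGU"), size=length))
            seqs[sid] = SequenceRecord(id=sid, sequence=seq, rna_type=t)
    return seqs


def random_positives(rng, seqs, n_pairs):
    """Random distinct positive pairs over a typed sequence pool."""
    ids = sorted(seqs)
    positives = set()
    while len(positives) < n_pairs:
        a, b = rng.choice(ids, size=2, replace=False)
        positives.add(PairKey(str(a), str(b)))
    return positives
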