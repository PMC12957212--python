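"""Sequence featurization: token embeddings, pooling, and pair features.

A token embedder turns a nucleotide sequence into an L x H matrix (one
H-dimensional vector per token). Pooling collapses that matrix into a
fixed-length molecule embedding — column mean (``avg``), column maximum
(``max``), or their concatenation (``concat``) — and a candidate pair is
represented by concatenating the two molecule embeddings in presentation
order (order matters: the symmetry augmentation supplies both orders).

The embedder is pluggable. Production use plugs in a pre-trained RNA
language model through the :class:`TokenEmbedder` contract; the package
ships :class:`KmerToyEmbedder`, a deterministic k-mer lookup embedder, so
the full pipeline is testable without any external model. Adapters for
external models must strip special/delimiter tokens before handoff, so that
pooling semantics stay uniform, and should record the extracted layer in
their fingerprint.
"""

from __future__ import annotations

import json
import zlib
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .augment import OrientedInstance, flip_sequence
from .dataset import SequenceRecord

POOLING_MODES = ("avg", "max", "concat")


@dataclass(frozen=True)
class TokenEmbeddingMatrix:
    """Per-token embedding matrix of shape L x H for one sequence."""

    values: np.ndarray
    sequence_id: str = ""

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError(f"expected L x H matrix with L,H >= 1, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("token embeddings contain non-finite entries")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def H(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MoleculeEmbedding:
    """Fixed-length pooled embedding of one molecule."""

    values: np.ndarray
    pooling_mode: str

    def __post_init__(self) -> None:
        if self.pooling_mode not in POOLING_MODES:
            raise ValueError(f"unknown pooling mode {self.pooling_mode!r}")
        if self.values.ndim != 1:
            raise ValueError("molecule embedding must be a 1-D vector")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("molecule embedding contains non-finite entries")

    @property
    def dim(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class PairFeature:
    """Concatenated [left; right] molecule embeddings for one oriented pair."""

    values: np.ndarray
    left_id: str = ""
    right_id: str = ""
    variant: str = "original"

    @property
    def dim(self) -> int:
        return self.values.shape[0]


class TokenEmbedder(ABC):
    """Contract every token embedder must satisfy.

    Implementations must be deterministic (same instance, same input ->
    bitwise-identical output), must reject sequences exceeding their context
    limit, and must expose a ``fingerprint`` that changes whenever the
    embedding function changes.
    """

    #: hidden dimension H of the emitted matrices
    H: int
    #: maximum accepted sequence length in nucleotides
    max_length: int

    @abstractmethod
    def embed_tokens(self, sequence: str, sequence_id: str = "") -> TokenEmbeddingMatrix:
        ...

    @property
    @abstractmethod
    def fingerprint(self) -> str:
        ...


class KmerToyEmbedder(TokenEmbedder):
    """Deterministic k-mer lookup embedder.

    Tokenizes a sequence into k-mers at a fixed stride (the final partial
    k-mer is kept) and maps each distinct k-mer to a fixed H-dimensional
    standard-normal vector drawn once from a PRNG keyed by (seed, k-mer).
    Reversing a sequence changes its token multiset, so flipped orientations
    get distinct but fully deterministic embeddings — the property the
    symmetry augmentation relies on.
    """

    def __init__(self, k: int = 3, stride: int = 3, H: int = 64,
                 seed: int = 0, max_length: int = 4096) -> None:
        if k < 1 or stride < 1 or H < 1:
            raise ValueError("k, stride and H must be >= 1")
        self.k = k
        self.stride = stride
        self.H = H
        self.seed = seed
        self.max_length = max_length
        self._table: Dict[str, np.ndarray] = {}

    def _vector(self, kmer: str) -> np.ndarray:
        vec = self._table.get(kmer)
        if vec is None:
            # crc32 is stable across processes, unlike hash()
            key = zlib.crc32(kmer.encode("ascii"))
            vec = np.random.default_rng([self.seed, key]).standard_normal(self.H)
            self._table[kmer] = vec
        return vec

    def tokenize(self, sequence: str) -> List[str]:
        return [sequence[i:i + self.k] for i in range(0, len(sequence), self.stride)]

    def embed_tokens(self, sequence: str, sequence_id: str = "") -> TokenEmbeddingMatrix:
        if not sequence:
            raise ValueError("cannot embed an empty sequence")
        if len(sequence) > self.max_length:
            raise ValueError(
                f"sequence of {len(sequence)} nt exceeds embedder context limit "
                f"of {self.max_length} nt"
            )
        rows = [self._vector(t) for t in self.tokenize(sequence)]
        return TokenEmbeddingMatrix(values=np.vstack(rows), sequence_id=sequence_id)

    @property
    def fingerprint(self) -> str:
        return f"kmer-toy:k={self.k}:stride={self.stride}:H={self.H}:seed={self.seed}"


def pool(X: TokenEmbeddingMatrix, mode: str) -> MoleculeEmbedding:
    """Collapse an L x H token matrix into a fixed-length molecule embedding."""
    if mode == "avg":
        v = X.values.mean(axis=0)
    elif mode == "max":
        v = X.values.max(axis=0)
    elif mode == "concat":
        v = np.concatenate([X.values.mean(axis=0), X.values.max(axis=0)])
    else:
        raise ValueError(f"unknown pooling mode {mode!r}")
    return MoleculeEmbedding(values=v, pooling_mode=mode)


def pair_features(left: MoleculeEmbedding, right: MoleculeEmbedding,
                  left_id: str = "", right_id: str = "",
                  variant: str = "original") -> PairFeature:
    """Concatenate two molecule embeddings, left first. Order is significant."""
    if left.pooling_mode != right.pooling_mode:
        raise ValueError(
            f"pooling mode mismatch: {left.pooling_mode!r} vs {right.pooling_mode!r}"
        )
    if left.dim != right.dim:
        raise ValueError(f"dimension mismatch: {left.dim} vs {right.dim}")
    return PairFeature(
        values=np.concatenate([left.values, right.values]),
        left_id=left_id, right_id=right_id, variant=variant,
    )


class EmbeddingCache:
    """Persistent store of pooled molecule embeddings.

    One ``.npy`` file per (sequence, orientation) under ``store_path``, with
    a JSON index keyed by (sequence_id, flipped, embedder fingerprint,
    pooling mode). Hits are bitwise-identical to recomputation; a
    fingerprint or mode mismatch is simply a miss, forcing recompute.
    """

    def __init__(self, store_path: str | Path) -> None:
        self.store_path = Path(store_path)
        self.store_path.mkdir(parents=True, exist_ok=True)
        self._index_path = self.store_path / "index.json"
        if self._index_path.exists():
            self._index: Dict[str, str] = json.loads(self._index_path.read_text())
        else:
            self._index = {}

    @staticmethod
    def _key(sequence_id: str, flipped: bool, fingerprint: str, mode: str) -> str:
        return json.dumps([sequence_id, flipped, fingerprint, mode])

    def get(self, sequence_id: str, flipped: bool, fingerprint: str,
            mode: str) -> Optional[np.ndarray]:
        fname = self._index.get(self._key(sequence_id, flipped, fingerprint, mode))
        if fname is None:
            return None
        return np.load(self.store_path / fname)

    def put(self, sequence_id: str, flipped: bool, fingerprint: str, mode: str,
            values: np.ndarray) -> None:
        fname = f"emb_{len(self._index):06d}.npy"
        np.save(self.store_path / fname, values)
        self._index[self._key(sequence_id, flipped, fingerprint, mode)] = fname
        self._index_path.write_text(json.dumps(self._index))


class MoleculeEmbedder:
    """Memoizing wrapper: sequence id + orientation -> pooled embedding."""

    def __init__(self, embedder: TokenEmbedder, mode: str,
                 cache: Optional[EmbeddingCache] = None) -> None:
        if mode not in POOLING_MODES:
            raise ValueError(f"unknown pooling mode {mode!r}")
        self.embedder = embedder
        self.mode = mode
        self.cache = cache
        self._memo: Dict[Tuple[str, bool], np.ndarray] = {}

    @property
    def d_mol(self) -> int:
        return 2 * self.embedder.H if self.mode == "concat" else self.embedder.H

    def __call__(self, record: SequenceRecord, flipped: bool) -> np.ndarray:
        key = (record.id, flipped)
        vec = self._memo.get(key)
        if vec is not None:
            return vec
        if self.cache is not None:
            vec = self.cache.get(record.id, flipped, self.embedder.fingerprint, self.mode)
        if vec is None:
            seq = flip_sequence(record.sequence) if flipped else record.sequence
            vec = pool(self.embedder.embed_tokens(seq, record.id), self.mode).values
            if self.cache is not None:
                self.cache.put(record.id, flipped, self.embedder.fingerprint,
                               self.mode, vec)
        self._memo[key] = vec
        return vec


def featurize_instances(
    instances: Sequence[OrientedInstance],
    sequences: Mapping[str, SequenceRecord],
    molecule_embedder: MoleculeEmbedder,
) -> Tuple[np.ndarray, np.ndarray]:
    """Build the (n, 2*d_mol) feature matrix and label vector for instances."""
    feats = np.empty((len(instances), 2 * molecule_embedder.d_mol))
    labels = np.empty(len(instances), dtype=np.int64)
    for i, inst in enumerate(instances):
        left = molecule_embedder(sequences[inst.left_id], inst.left_flipped)
        right = molecule_embedder(sequences[inst.right_id], inst.right_flipped)
        feats[i, :molecule_embedder.d_mol] = left
        feats[i, molecule_embedder.d_mol:] = right
        labels[i] = inst.label
    return feats, labels
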