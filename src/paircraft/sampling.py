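"""Type-constrained negative sampling, stratified splitting, balanced batches.

Only positive interactions are observed; any unobserved pair of distinct
molecules is a potential negative. Negatives are generated per positive pair
by *corruption*: keep one member fixed and replace the other with a
same-type molecule not known to interact with the kept one. Because the
replacement has the same ncRNA class, the negative set preserves the
positives' type-pair distribution in expectation — negatives between classes
that never interact (e.g. scaRNA-lncRNA) are never fabricated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Set, Tuple

import numpy as np

from .dataset import PairKey, SequenceRecord, TypePair

logger = logging.getLogger(__name__)

LabeledPair = Tuple[PairKey, int]

# Rejection sampling gives up after this many draws per positive and falls
# back to exhaustive enumeration of the eligible pool, guaranteeing
# termination on near-exhausted pools.
_REJECTION_CAP_FACTOR = 100


def _types_of(sequences) -> Dict[str, str]:
    if isinstance(sequences, Mapping):
        return {sid: rec.rna_type for sid, rec in sequences.items()}
    return {rec.id: rec.rna_type for rec in sequences}


def sample_negatives(
    positives: Set[PairKey],
    sequences: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
    n: int = 20,
    seed: int = 0,
) -> Set[PairKey]:
    """Sample up to ``n`` type-constrained negatives per positive pair.

    For each positive (s_i, s_j), s_i is held fixed and candidates s' are
    drawn uniformly subject to: s' != s_i, the class of s' equals the class
    of s_j, (s_i, s') is not a positive, and the canonical pair was not
    already sampled as a negative anywhere in the run. When the eligible
    pool has fewer than n members, all of it is emitted and the shortfall is
    logged; an empty pool yields zero negatives with a warning, never an
    error.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    types = _types_of(sequences)
    by_type: Dict[str, List[str]] = {}
    for sid, t in types.items():
        by_type.setdefault(t, []).append(sid)
    for ids in by_type.values():
        ids.sort()

    rng = np.random.default_rng(seed)
    negatives: Set[PairKey] = set()
    n_short = 0
    n_empty = 0
    # Iterate in sorted order so the result is a pure function of (inputs, seed).
    for pos in sorted(positives):
        anchor, corrupt = pos.first_id, pos.second_id
        pool = by_type.get(types[corrupt], [])
        got = 0
        cap = _REJECTION_CAP_FACTOR * n
        draws = 0
        while got < n and draws < cap and len(pool) > 1:
            draws += 1
            cand = pool[int(rng.integers(len(pool)))]
            if cand == anchor:
                continue
            key = PairKey(anchor, cand)
            if key in positives or key in negatives:
                continue
            negatives.add(key)
            got += 1
        if got < n:
            # Exhaustive fallback: enumerate every still-eligible candidate.
            eligible = []
            for cand in pool:
                if cand == anchor:
                    continue
                key = PairKey(anchor, cand)
                if key in positives or key in negatives:
                    continue
                eligible.append(key)
            take = min(n - got, len(eligible))
            if take:
                idx = rng.permutation(len(eligible))[:take]
                for i in idx:
                    negatives.add(eligible[int(i)])
                got += take
            if got == 0:
                n_empty += 1
            elif got < n:
                n_short += 1
    if n_short:
        logger.info("negative sampling: %d positives had an exhausted pool (<%d)", n_short, n)
    if n_empty:
        logger.warning("negative sampling: %d positives yielded zero negatives", n_empty)
    return negatives


def check_type_distribution(
    positives: Set[PairKey],
    negatives: Set[PairKey],
    sequences: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
) -> Tuple[Dict[TypePair, float], Dict[TypePair, float], float]:
    """Compare the empirical TypePair distributions of positives vs negatives.

    Returns (positive distribution, negative distribution, max absolute
    proportion difference). A diagnostic, not a hard gate: pool exhaustion
    skews the negative distribution away from exact preservation.
    """
    if not positives or not negatives:
        raise ValueError("both sets must be non-empty")
    types = _types_of(sequences)

    def dist(pairs: Set[PairKey]) -> Dict[TypePair, float]:
        counts: Dict[TypePair, int] = {}
        for p in pairs:
            tp = TypePair(types[p.first_id], types[p.second_id])
            counts[tp] = counts.get(tp, 0) + 1
        total = len(pairs)
        return {tp: c / total for tp, c in counts.items()}

    dp, dn = dist(positives), dist(negatives)
    keys = set(dp) | set(dn)
    max_diff = max(abs(dp.get(k, 0.0) - dn.get(k, 0.0)) for k in keys)
    return dp, dn, max_diff


@dataclass
class SplitBundle:
    """Disjoint train/validation/test partitions of labeled pairs."""

    train: List[LabeledPair]
    validation: List[LabeledPair]
    test: List[LabeledPair]

    def __post_init__(self) -> None:
        seen: Set[PairKey] = set()
        for part in (self.train, self.validation, self.test):
            for pair, _ in part:
                if pair in seen:
                    raise ValueError(f"pair {pair.ids} appears in more than one split")
                seen.add(pair)

    @property
    def all_pairs(self) -> List[LabeledPair]:
        return self.train + self.validation + self.test


def _largest_remainder(sizes: Sequence[int], fraction: float) -> List[int]:
    """Apportion round(sum(sizes)*fraction) across strata by largest remainder."""
    total = int(round(sum(sizes) * fraction))
    quotas = [s * fraction for s in sizes]
    base = [min(int(math.floor(q)), s) for q, s in zip(quotas, sizes)]
    rem = total - sum(base)
    order = sorted(
        range(len(sizes)),
        key=lambda i: (-(quotas[i] - math.floor(quotas[i])), i),
    )
    alloc = list(base)
    for i in order:
        if rem <= 0:
            break
        if alloc[i] < sizes[i]:
            alloc[i] += 1
            rem -= 1
    return alloc


def stratified_split(
    labeled_pairs: Sequence[LabeledPair],
    sequences: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
    outer_test_fraction: float = 0.10,
    inner_validation_fraction: float = 0.20,
    seed: int = 0,
) -> SplitBundle:
    """Split labeled pairs into train/validation/test, stratified by (TypePair, label).

    The outer split holds out ``outer_test_fraction`` for test; the inner
    split carves ``inner_validation_fraction`` of the remainder for
    validation (defaults 90:10 then 80:20, i.e. 72/18/10 overall).
    Per-stratum counts use largest-remainder rounding; single-member strata
    go entirely to train (logged) so no class disappears from training.
    Deterministic under a fixed seed.
    """
    for f in (outer_test_fraction, inner_validation_fraction):
        if not 0.0 < f < 1.0:
            raise ValueError("fractions must be in (0, 1)")
    types = _types_of(sequences)

    strata: Dict[Tuple[TypePair, int], List[LabeledPair]] = {}
    for pair, label in labeled_pairs:
        tp = TypePair(types[pair.first_id], types[pair.second_id])
        strata.setdefault((tp, label), []).append((pair, label))

    rng = np.random.default_rng(seed)
    train: List[LabeledPair] = []
    validation: List[LabeledPair] = []
    test: List[LabeledPair] = []

    keys = sorted(strata.keys(), key=lambda k: (str(k[0]), k[1]))
    singles = [k for k in keys if len(strata[k]) == 1]
    for k in singles:
        train.extend(strata[k])
        logger.info("stratum %s/%d has a single member; assigned to train", k[0], k[1])
    keys = [k for k in keys if len(strata[k]) > 1]

    shuffled: Dict[Tuple[TypePair, int], List[LabeledPair]] = {}
    for k in keys:
        members = sorted(strata[k], key=lambda lp: lp[0])
        perm = rng.permutation(len(members))
        shuffled[k] = [members[int(i)] for i in perm]

    sizes = [len(shuffled[k]) for k in keys]
    test_alloc = _largest_remainder(sizes, outer_test_fraction)
    remaining_sizes = [s - a for s, a in zip(sizes, test_alloc)]
    val_alloc = _largest_remainder(remaining_sizes, inner_validation_fraction)

    for k, n_test, n_val in zip(keys, test_alloc, val_alloc):
        members = shuffled[k]
        test.extend(members[:n_test])
        validation.extend(members[n_test:n_test + n_val])
        train.extend(members[n_test + n_val:])

    return SplitBundle(train=train, validation=validation, test=test)


@dataclass(frozen=True)
class BatchPlan:
    """Composition of one balanced mini-batch of size m with negative fraction r."""

    m: int
    r: float

    @property
    def m_n(self) -> int:
        # round half away from zero; r*m >= 0 so floor(x + 0.5) suffices
        return int(math.floor(self.r * self.m + 0.5))

    @property
    def m_p(self) -> int:
        return self.m - self.m_n

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("batch size must be >= 1")
        if not 0.0 < self.r < 1.0:
            raise ValueError("r must be in (0, 1)")
        if self.m_n == 0 or self.m_n == self.m:
            raise ValueError(f"degenerate batch mix: m={self.m}, r={self.r} -> m_n={self.m_n}")


def make_batches(
    train_positives: Sequence,
    train_negatives: Sequence,
    m: int = 512,
    r: float = 0.7,
    seed: int = 0,
) -> Iterator[List]:
    """Yield one epoch of balanced mini-batches of labeled instances.

    Each full batch holds exactly m_n = round(r*m) negatives and m_p = m - m_n
    positives. Positives are drawn uniformly *with* replacement (they are
    scarce; every batch must see enough of them); negatives are drawn
    *without* replacement within the epoch, for broad coverage of the
    abundant class. The epoch ends when fewer than m_n negatives remain;
    the negative order is reshuffled by the caller's seed.
    """
    if not train_positives or not train_negatives:
        raise ValueError("both pools must be non-empty")
    plan = BatchPlan(m=m, r=r)
    rng = np.random.default_rng(seed)
    neg_order = rng.permutation(len(train_negatives))
    n_batches = len(train_negatives) // plan.m_n
    for b in range(n_batches):
        neg_idx = neg_order[b * plan.m_n:(b + 1) * plan.m_n]
        pos_idx = rng.integers(len(train_positives), size=plan.m_p)
        batch = [train_negatives[int(i)] for i in neg_idx]
        batch.extend(train_positives[int(i)] for i in pos_idx)
        yield batch
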