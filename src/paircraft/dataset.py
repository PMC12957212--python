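"""Loading, validation and filtering of ncRNA sequences and interaction pairs.

An interaction is an *unordered* pair of distinct molecules: (s_i, s_j) and
(s_j, s_i) denote the same edge, and its type is the unordered pair of the
two molecules' ncRNA classes. Both identities are realized here by storing
ids (and types) in canonical lexicographic order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: ncRNA classes recognized in type maps. "ncRNA" is the catch-all class for
#: molecules without a finer annotation; "pseudo" marks pseudogene-derived RNA.
NCRNA_TYPES = (
    "lncRNA", "circRNA", "miRNA", "snRNA", "snoRNA",
    "scaRNA", "scRNA", "ncRNA", "pseudo",
)

_VALID_CHARS = frozenset("ACGU")


@dataclass(frozen=True)
class SequenceRecord:
    """A single ncRNA molecule: unique id, RNA-alphabet sequence, class label."""

    id: str
    sequence: str
    rna_type: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.sequence:
            raise ValueError(f"sequence {self.id!r} is empty")
        for pos, ch in enumerate(self.sequence, start=1):
            if ch not in _VALID_CHARS:
                raise ValueError(
                    f"sequence {self.id!r}: invalid character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class PairKey:
    """Canonical identity of an unordered pair of distinct sequence ids.

    Ids are stored lexicographically sorted, so ``PairKey(a, b) == PairKey(b, a)``.
    Self-pairs are rejected: self-interactions are outside the problem.
    """

    first_id: str
    second_id: str

    def __init__(self, id_a: str, id_b: str) -> None:
        if id_a == id_b:
            raise ValueError(f"self-pair not allowed: {id_a!r}")
        a, b = sorted((id_a, id_b))
        object.__setattr__(self, "first_id", a)
        object.__setattr__(self, "second_id", b)

    @property
    def ids(self) -> Tuple[str, str]:
        return (self.first_id, self.second_id)

    def other(self, one_id: str) -> str:
        if one_id == self.first_id:
            return self.second_id
        if one_id == self.second_id:
            return self.first_id
        raise KeyError(f"{one_id!r} not in pair {self.ids}")


@dataclass(frozen=True, order=True)
class TypePair:
    """Unordered pair of ncRNA classes, stored in canonical order."""

    type_a: str
    type_b: str

    def __init__(self, t1: str, t2: str) -> None:
        a, b = sorted((t1, t2))
        object.__setattr__(self, "type_a", a)
        object.__setattr__(self, "type_b", b)

    def __str__(self) -> str:
        return f"{self.type_a}-{self.type_b}"

    @classmethod
    def parse(cls, text: str) -> "TypePair":
        a, b = text.split("-", 1)
        return cls(a, b)


@dataclass
class InteractionDataset:
    """Sequences plus disjoint positive and (sampled) negative pair sets."""

    sequences: Dict[str, SequenceRecord]
    positives: Set[PairKey]
    negatives: Set[PairKey] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"{len(overlap)} pairs labeled both positive and negative")
        for pair in list(self.positives) + list(self.negatives):
            for sid in pair.ids:
                if sid not in self.sequences:
                    raise ValueError(f"pair references unknown sequence id {sid!r}")

    def type_of(self, seq_id: str) -> str:
        return self.sequences[seq_id].rna_type

    def type_pair(self, pair: PairKey) -> TypePair:
        return TypePair(self.type_of(pair.first_id), self.type_of(pair.second_id))

    def type_pair_counts(self, pairs: Iterable[PairKey]) -> Dict[TypePair, int]:
        counts: Dict[TypePair, int] = {}
        for p in pairs:
            tp = self.type_pair(p)
            counts[tp] = counts.get(tp, 0) + 1
        return counts


def _normalize(seq: str, seq_id: str) -> str:
    """Uppercase and map T->U; reject anything outside {A,C,G,U,T}."""
    out = seq.upper().replace("T", "U")
    for pos, ch in enumerate(out, start=1):
        if ch not in _VALID_CHARS:
            raise ValueError(
                f"sequence {seq_id!r}: invalid character {seq[pos - 1]!r} at position {pos}"
            )
    return out


def load_sequences(fasta_path: str | Path, type_map_path: str | Path) -> List[SequenceRecord]:
    """Load sequences from FASTA and attach ncRNA types from a 2-column TSV.

    The type map is header-free with columns (id, type). DNA-style input (T,
    lowercase) is normalized to the uppercase RNA alphabet. Duplicate FASTA
    ids, ids missing from the type map, and characters outside {A,C,G,U,T}
    are hard errors.
    """
    type_map: Dict[str, str] = {}
    with open(type_map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{type_map_path}:{lineno}: expected 2 columns, got {len(parts)}")
            type_map[parts[0]] = parts[1]

    records: List[SequenceRecord] = []
    seen: Set[str] = set()
    missing: List[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {fasta_path}")
        seen.add(rec.id)
        if rec.id not in type_map:
            missing.append(rec.id)
            continue
        records.append(
            SequenceRecord(
                id=rec.id,
                sequence=_normalize(str(rec.seq), rec.id),
                rna_type=type_map[rec.id],
            )
        )
    if missing:
        raise ValueError(
            f"{len(missing)} FASTA ids missing from type map: {', '.join(sorted(missing)[:10])}"
        )
    return records


def load_positive_edges(
    tsv_path: str | Path, sequences: Iterable[SequenceRecord] | Mapping[str, SequenceRecord]
) -> Set[PairKey]:
    """Read a 2-column edge list into a set of canonical PairKeys.

    Self-loops are dropped (with a logged count); duplicate rows in either
    order collapse to a single key; an id that does not resolve against the
    sequence collection is a hard error.
    """
    if isinstance(sequences, Mapping):
        known = set(sequences.keys())
    else:
        known = {r.id for r in sequences}

    pairs: Set[PairKey] = set()
    n_self = 0
    n_dup = 0
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{tsv_path}:{lineno}: expected 2 columns")
            a, b = parts[0], parts[1]
            for sid in (a, b):
                if sid not in known:
                    raise ValueError(f"{tsv_path}:{lineno}: unknown sequence id {sid!r}")
            if a == b:
                n_self += 1
                continue
            key = PairKey(a, b)
            if key in pairs:
                n_dup += 1
            else:
                pairs.add(key)
    if n_self:
        logger.info("dropped %d self-loop rows from %s", n_self, tsv_path)
    if n_dup:
        logger.info("collapsed %d duplicate rows from %s", n_dup, tsv_path)
    return pairs


def filter_by_length(
    records: Sequence[SequenceRecord], max_nt: int = 4096
) -> Tuple[List[SequenceRecord], int]:
    """Keep sequences of length <= max_nt (inclusive); return (kept, n_removed).

    The cutoff is a nucleotide-count proxy for a downstream embedder's
    context limit; 4,096 nt is the default budget for long-context RNA
    language models whose BPE tokenizers compress ~4 nt per token.
    """
    if max_nt < 1:
        raise ValueError("max_nt must be >= 1")
    kept = [r for r in records if len(r) <= max_nt]
    removed = len(records) - len(kept)
    if removed:
        logger.info("length filter removed %d/%d sequences (> %d nt)", removed, len(records), max_nt)
    return kept, removed


def filter_rare_type_pairs(
    positives: Set[PairKey],
    sequences: Mapping[str, SequenceRecord] | Sequence[SequenceRecord],
    min_count: int = 100,
) -> Tuple[Set[PairKey], Set[TypePair], Dict[str, SequenceRecord]]:
    """Drop positive pairs whose type pair has fewer than min_count examples.

    Interaction classes with negligible sample sizes add noise rather than
    signal, so whole type pairs below the threshold (strictly fewer than
    min_count) are removed. Sequences no longer referenced by any retained
    pair are dropped from the working set.

    Returns (retained positives, retained TypePair set, retained sequences).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not isinstance(sequences, Mapping):
        sequences = {r.id: r for r in sequences}

    def tp_of(pair: PairKey) -> TypePair:
        return TypePair(sequences[pair.first_id].rna_type, sequences[pair.second_id].rna_type)

    counts: Dict[TypePair, int] = {}
    for p in positives:
        tp = tp_of(p)
        counts[tp] = counts.get(tp, 0) + 1
    retained_types = {tp for tp, c in counts.items() if c >= min_count}
    retained = {p for p in positives if tp_of(p) in retained_types}

    referenced = {sid for p in retained for sid in p.ids}
    retained_seqs = {sid: rec for sid, rec in sequences.items() if sid in referenced}
    logger.info(
        "type-pair filter: kept %d/%d pairs over %d/%d type pairs, %d sequences",
        len(retained), len(positives), len(retained_types), len(counts), len(retained_seqs),
    )
    return retained, retained_types, retained_seqs
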