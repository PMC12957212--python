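"""Factor-4 symmetry augmentation of labeled pair instances.

An interaction has two presentation symmetries a classifier should be
invariant to: the order in which the two molecules are given, and the
reading orientation of their sequences. Each original instance (s_i, s_j)
therefore expands into exactly four oriented instances:

    original        (s_i,   s_j)
    order_reversed  (s_j,   s_i)
    flipped         (s_i^F, s_j^F)   with ^F = character reversal
    both            (s_j^F, s_i^F)

Flipping is plain string reversal, not reverse complement: it changes the
reading orientation of the same strand rather than switching strands. Flips
always apply to both molecules together.

Augmentation is applied strictly *after* splitting — otherwise orientations
of one pair could land in both train and test and leak label information.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, List, Sequence

from .dataset import PairKey

VARIANTS = ("original", "order_reversed", "flipped", "both")


def flip_sequence(sequence: str) -> str:
    """Reverse the nucleotide order of a sequence (involutive)."""
    return sequence[::-1]


@dataclass(frozen=True)
class OrientedInstance:
    """An ordered, possibly flipped presentation of an unordered labeled pair."""

    left_id: str
    right_id: str
    left_flipped: bool
    right_flipped: bool
    label: int  # 1 positive, 0 negative
    origin: PairKey
    variant: str = "original"
    split: str = "train"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.left_flipped != self.right_flipped:
            raise ValueError("flips must apply to both molecules together")
        if PairKey(self.left_id, self.right_id) != self.origin:
            raise ValueError("(left_id, right_id) does not resolve to origin PairKey")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")

    @classmethod
    def from_pair(cls, pair: PairKey, label: int, split: str = "train") -> "OrientedInstance":
        return cls(
            left_id=pair.first_id, right_id=pair.second_id,
            left_flipped=False, right_flipped=False,
            label=label, origin=pair, variant="original", split=split,
        )


def expand(instance: OrientedInstance) -> List[OrientedInstance]:
    """The four symmetry variants of one original instance."""
    if instance.variant != "original":
        raise ValueError("can only expand variant='original' instances")
    swapped = dict(left_id=instance.right_id, right_id=instance.left_id)
    return [
        instance,
        replace(instance, variant="order_reversed", **swapped),
        replace(instance, variant="flipped", left_flipped=True, right_flipped=True),
        replace(instance, variant="both", left_flipped=True, right_flipped=True, **swapped),
    ]


def augment_split(
    instances: Sequence[OrientedInstance] | Iterable[OrientedInstance],
    positives_only: bool = False,
) -> List[OrientedInstance]:
    """Expand every original instance of a single split by the factor-4 scheme.

    Output size is exactly 4x the number of augmented inputs; duplicates
    arising from palindromic sequences are retained so the 4x count is exact.
    With ``positives_only=True`` (an ablation switch) negatives pass through
    unexpanded.

    Raises if instances span more than one split: augmentation must happen
    after splitting, and expanding a mixed collection would hide a leak.
    """
    instances = list(instances)
    if not instances:
        return []
    splits = {i.split for i in instances}
    if len(splits) > 1:
        raise ValueError(f"instances span multiple splits {sorted(splits)}; augment per split")
    for inst in instances:
        if inst.variant != "original":
            raise ValueError("augment_split expects only variant='original' inputs")

    out: List[OrientedInstance] = []
    for inst in instances:
        if positives_only and inst.label == 0:
            out.append(inst)
        else:
            out.extend(expand(inst))
    return out
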