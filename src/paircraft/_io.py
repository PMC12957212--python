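"""TSV/JSON plumbing shared by the CLI stages: split tables, instance tables,
and the provenance manifest each stage writes next to its outputs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import pandas as pd

from .augment import OrientedInstance
from .dataset import PairKey, SequenceRecord, TypePair
from .sampling import LabeledPair, SplitBundle


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record one pipeline stage writes next to its outputs."""

    stage: str
    tool_version: str
    parameters: Dict = field(default_factory=dict)
    inputs: Dict[str, str] = field(default_factory=dict)   # path -> sha256
    outputs: Dict[str, str] = field(default_factory=dict)  # path -> sha256

    def write(self, out_dir: str | Path) -> Path:
        path = Path(out_dir) / f"manifest_{self.stage}.json"
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def make_manifest(stage: str, parameters: Mapping, inputs: Sequence[Path],
                  outputs: Sequence[Path]) -> RunManifest:
    from . import __version__
    return RunManifest(
        stage=stage,
        tool_version=__version__,
        parameters=dict(parameters),
        inputs={str(p): sha256_of(p) for p in inputs},
        outputs={str(p): sha256_of(p) for p in outputs},
    )


def write_pairs_tsv(path: str | Path, pairs: Sequence[PairKey]) -> None:
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\n")
        for p in sorted(pairs):
            fh.write(f"{p.first_id}\t{p.second_id}\n")


def read_pairs_tsv(path: str | Path) -> List[PairKey]:
    df = pd.read_csv(path, sep="\t")
    return [PairKey(a, b) for a, b in zip(df["id_a"], df["id_b"])]


def write_splits_tsv(path: str | Path, bundle: SplitBundle,
                     sequences: Mapping[str, SequenceRecord]) -> None:
    rows = []
    for split_name, part in (("train", bundle.train),
                             ("validation", bundle.validation),
                             ("test", bundle.test)):
        for pair, label in part:
            tp = TypePair(sequences[pair.first_id].rna_type,
                          sequences[pair.second_id].rna_type)
            rows.append((pair.first_id, pair.second_id, label, split_name, str(tp)))
    df = pd.DataFrame(rows, columns=["id_a", "id_b", "label", "split", "type_pair"])
    df.sort_values(["split", "id_a", "id_b"]).to_csv(path, sep="\t", index=False)


def read_splits_tsv(path: str | Path) -> Dict[str, List[LabeledPair]]:
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, List[LabeledPair]] = {"train": [], "validation": [], "test": []}
    for row in df.itertuples(index=False):
        out[row.split].append((PairKey(row.id_a, row.id_b), int(row.label)))
    return out


_INSTANCE_COLS = ["left_id", "right_id", "left_flipped", "right_flipped",
                  "label", "variant", "split"]


def write_instances_tsv(path: str | Path, instances: Sequence[OrientedInstance]) -> None:
    rows = [(i.left_id, i.right_id, int(i.left_flipped), int(i.right_flipped),
             i.label, i.variant, i.split) for i in instances]
    pd.DataFrame(rows, columns=_INSTANCE_COLS).to_csv(path, sep="\t", index=False)


def read_instances_tsv(path: str | Path) -> List[OrientedInstance]:
    df = pd.read_csv(path, sep="\t")
    return [
        OrientedInstance(
            left_id=row.left_id, right_id=row.right_id,
            left_flipped=bool(row.left_flipped), right_flipped=bool(row.right_flipped),
            label=int(row.label), origin=PairKey(row.left_id, row.right_id),
            variant=row.variant, split=row.split,
        )
        for row in df.itertuples(index=False)
    ]


def write_fasta_and_types(out_dir: str | Path,
                          sequences: Mapping[str, SequenceRecord]) -> Tuple[Path, Path]:
    out = Path(out_dir)
    fasta = out / "sequences.fasta"
    with open(fasta, "w") as fh:
        for sid in sorted(sequences):
            fh.write(f">{sid}\n{sequences[sid].sequence}\n")
    tmap = out / "types.tsv"
    with open(tmap, "w") as fh:
        for sid in sorted(sequences):
            fh.write(f"{sid}\t{sequences[sid].rna_type}\n")
    return fasta, tmap
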