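"""File formats: FASTA, TSV tables, embedding caches, configs.

Sequences travel as FASTA (via Biopython); labels, pair categories,
interaction tables and k-mer bags as TSV; embedding caches as one
whitespace-free TSV matrix per sequence id plus a manifest
(``manifest.tsv``: id, length, d, provider tag); configuration as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pooling import KmerBag
from .providers import SequenceRecord, TokenEmbeddingMatrix

__all__ = [
    "read_fasta",
    "write_fasta",
    "filter_by_length",
    "read_label_table",
    "write_label_table",
    "read_pair_table",
    "save_embedding_cache",
    "load_embedding_cache",
    "bag_to_frame",
    "load_config",
    "dump_json",
]


def read_fasta(path) -> list[SequenceRecord]:
    return [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(records: Iterable[SequenceRecord], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.residues), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def filter_by_length(
    records: Iterable[SequenceRecord],
    min_len: int | None = None,
    max_len: int | None = None,
) -> list[SequenceRecord]:
    """Length-window filter (e.g. 150-1022 residues for PLM pipelines)."""
    out = []
    for r in records:
        if min_len is not None and len(r) < min_len:
            continue
        if max_len is not None and len(r) > max_len:
            continue
        out.append(r)
    return out


def read_label_table(path, value_col: str = "label") -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["id"], df[value_col].astype(float)))


def write_label_table(labels: Mapping[str, float], path, value_col: str = "label"):
    pd.DataFrame({"id": list(labels), value_col: list(labels.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_pair_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"id_a", "id_b", "category"}
    if not need <= set(df.columns):
        raise ValueError(f"pair table must have columns {sorted(need)}")
    return df


def save_embedding_cache(
    directory, matrices: Iterable[TokenEmbeddingMatrix], provider_tag: str = ""
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for mat in matrices:
        np.savetxt(directory / f"{mat.source_id}.tsv", mat.values, delimiter="\t")
        manifest.append(
            {
                "id": mat.source_id,
                "length": mat.l,
                "d": mat.d,
                "provider": provider_tag,
                "has_cls": int(mat.has_cls),
                "has_eos": int(mat.has_eos),
            }
        )
    pd.DataFrame(manifest).to_csv(directory / "manifest.tsv", sep="\t", index=False)


def load_embedding_cache(directory) -> dict[str, TokenEmbeddingMatrix]:
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.tsv", sep="\t")
    out = {}
    for _, row in manifest.iterrows():
        values = np.loadtxt(directory / f"{row['id']}.tsv", delimiter="\t", ndmin=2)
        out[row["id"]] = TokenEmbeddingMatrix(
            values,
            has_cls=bool(row["has_cls"]),
            has_eos=bool(row["has_eos"]),
            source_id=row["id"],
        )
    return out


def bag_to_frame(bag: KmerBag, seq_id: str) -> pd.DataFrame:
    """K-mer bag as a flat table: one row per window, mean values spread
    over ``v0..v{d-1}`` columns."""
    base = pd.DataFrame(
        {
            "id": seq_id,
            "window_index": np.arange(1, bag.n + 1),
            "start": bag.starts,
            "end": bag.ends,
        }
    )
    vals = pd.DataFrame(bag.omegas, columns=[f"v{i}" for i in range(bag.omegas.shape[1])])
    return pd.concat([base, vals], axis=1)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must hold a mapping")
    return cfg


def dump_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
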