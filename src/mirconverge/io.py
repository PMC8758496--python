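"""Readers and writers for the pipeline's plain-text formats.

Tables are TSV with headers, gene lists are one id per line, sequences
are FASTA (via Biopython).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO

from .consensus import PredictionCallSet
from .puncta import PunctaSet
from .seeds import MiRNASeq


def read_screen_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    df["entity_id"] = df["entity_id"].astype(str)
    return df


def read_id_list(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def write_id_list(path: str | Path, ids: Iterable[str]) -> None:
    Path(path).write_text("\n".join(ids) + "\n")


def read_prediction_calls(
    path: str | Path, algorithms: Iterable[str] | None = None
) -> PredictionCallSet:
    """Long-format TSV (mirna_id, gene_id, algorithm_id); the algorithm
    universe defaults to the distinct ids present in the file."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    algs = tuple(algorithms) if algorithms is not None else tuple(
        sorted(df["algorithm_id"].unique())
    )
    return PredictionCallSet(calls=df, algorithms=algs)


def read_puncta(path: str | Path, channel: str) -> PunctaSet:
    return PunctaSet.from_frame(pd.read_csv(path, sep=None, engine="python"), channel)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_mirna_fasta(path: str | Path) -> list[MiRNASeq]:
    return [
        MiRNASeq(id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def read_single_fasta(path: str | Path) -> dict[str, str]:
    """All records of a FASTA as {id: sequence}."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
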