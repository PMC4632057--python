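"""File formats: FASTA via Biopython, tab-separated tables via pandas."""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .proteins import PEPTIDE_COLUMNS
from .types import StandardSpec, ToxinRecord, TranscriptRecord, VenomSystemTruth

__all__ = [
    "write_fasta",
    "read_fasta",
    "read_transcript_records",
    "write_counts",
    "read_counts",
    "write_coverage",
    "read_coverage",
    "write_peptide_table",
    "read_peptide_table",
    "write_abundance",
    "read_abundance",
    "write_truth",
    "read_truth",
    "read_ortholog_tsv",
]


def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=i, description="") for i, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_transcript_records(path: str | Path) -> list[TranscriptRecord]:
    return [TranscriptRecord(id=i, cds=s) for i, s in read_fasta(path).items()]


def write_counts(counts: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(
        {"id": list(counts), "count": list(counts.values())}
    ).to_csv(path, sep="\t", index=False)


def read_counts(path: str | Path) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["id"].astype(str), df["count"].astype(int)))


def write_coverage(profiles: Mapping[str, np.ndarray], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {"id": tid, "site": np.arange(1, len(depth) + 1), "depth": depth}
        )
        for tid, depth in profiles.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_coverage(path: str | Path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, np.ndarray] = {}
    for tid, sub in df.groupby("id", sort=False):
        out[str(tid)] = sub.sort_values("site")["depth"].to_numpy()
    return out


def write_peptide_table(table: pd.DataFrame, path: str | Path) -> None:
    table[PEPTIDE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEPTIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: peptide table missing columns {missing}")
    return df


def write_abundance(values: Mapping[str, float], path: str | Path, col: str = "tpm") -> None:
    pd.DataFrame({"id": list(values), col: list(values.values())}).to_csv(
        path, sep="\t", index=False
    )


def read_abundance(path: str | Path, col: str | None = None) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t")
    if col is None:
        col = df.columns[1]
    return dict(zip(df["id"].astype(str), df[col].astype(float)))


def write_truth(truth: VenomSystemTruth, path: str | Path) -> None:
    payload = {
        "toxins": [
            {"id": t.id, "protein": t.protein, "cds": t.cds, "family": t.family}
            for t in truth.toxins
        ],
        "true_transcript_comp": truth.true_transcript_comp,
        "true_protein_fmol": truth.true_protein_fmol,
        "standard": {
            "protein_id": truth.standard.protein_id,
            "sequence": truth.standard.sequence,
            "load_fmol": truth.standard.load_fmol,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> VenomSystemTruth:
    payload = json.loads(Path(path).read_text())
    return VenomSystemTruth(
        toxins=[ToxinRecord(**t) for t in payload["toxins"]],
        true_transcript_comp=payload["true_transcript_comp"],
        true_protein_fmol=payload["true_protein_fmol"],
        standard=StandardSpec(**payload["standard"]),
    )


def read_ortholog_tsv(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: ortholog table needs two columns (id_a, id_b)")
    return list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
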