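"""Readers and writers for the plain-text interchange formats.

Expression matrices travel as TSV with genes as rows and samples as
columns (first column ``gene``); traits as two-column TSV (sample id,
0/1); protein sequences as 60-column wrapped FASTA; pair lists,
localization tables and annotations as simple TSVs; distance matrices in
square PHYLIP format; trees as Newick.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_expression(path: str | Path, values: pd.DataFrame) -> None:
    """Write a samples x genes DataFrame as a genes-as-rows TSV."""
    out = values.T
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read an expression TSV back into a samples x genes DataFrame."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.T


def write_trait(path: str | Path, trait: pd.Series) -> None:
    df = pd.DataFrame({"sample": trait.index, "trait": trait.to_numpy().astype(int)})
    df.to_csv(path, sep="\t", index=False)


def read_trait(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df["trait"].to_numpy(), index=df["sample"], name="trait")


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_pairs(path: str | Path, pairs, columns=("protein_a", "protein_b")) -> None:
    pd.DataFrame(list(pairs), columns=list(columns)).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return [tuple(row[:2]) for row in df.itertuples(index=False)]


def write_localizations(path: str | Path, loc: dict[str, frozenset[str] | set[str]]) -> None:
    rows = [
        {"protein": pid, "compartments": ";".join(sorted(comps))}
        for pid, comps in sorted(loc.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_localizations(path: str | Path) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, frozenset[str]] = {}
    for row in df.itertuples(index=False):
        comps = row.compartments
        out[row.protein] = frozenset(
            c for c in (comps.split(";") if isinstance(comps, str) else []) if c
        )
    return out


def write_annotations(path: str | Path, annotations: dict[str, set[str]]) -> None:
    """Write term -> gene-set annotations as (gene, term) rows."""
    rows = [
        {"gene": g, "term": t}
        for t in sorted(annotations)
        for g in sorted(annotations[t])
    ]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.term, set()).add(row.gene)
    return out


def write_phylip_distances(path: str | Path, taxa: list[str], matrix: np.ndarray) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(taxa)}\n")
        for i, name in enumerate(taxa):
            row = " ".join(f"{x:.6f}" for x in matrix[i])
            fh.write(f"{name} {row}\n")


def read_phylip_distances(path: str | Path) -> tuple[list[str], np.ndarray]:
    lines = Path(path).read_text().strip().splitlines()
    n = int(lines[0])
    taxa, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        taxa.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    return taxa, np.array(rows)
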