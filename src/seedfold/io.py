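"""File I/O and small sequence utilities shared across the package.

FASTA is read and written through Biopython; tables (seed lists, site files,
score reports, expression matrices) are plain TSV via pandas.  DNA input is
accepted everywhere and normalized to RNA (T -> U) on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from .sequence_sites import MirnaFamily, SeedSite, TargetWindow, UTRRecord

_COMPLEMENT = str.maketrans("ACGUN", "UGCAN")


def normalize_rna(sequence: str) -> str:
    """Uppercase and convert T to U."""
    return sequence.upper().replace("T", "U")


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an RNA string (N maps to N)."""
    return normalize_rna(sequence).translate(_COMPLEMENT)[::-1]


def read_utr_fasta(path: str | Path) -> list["UTRRecord"]:
    """Read 3'-UTR sequences from FASTA, normalizing T to U."""
    from .sequence_sites import UTRRecord

    records = [
        UTRRecord(gene_id=rec.id, sequence=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(
    sequences: Iterable[tuple[str, str]], path: str | Path, as_dna: bool = False
) -> None:
    """Write (id, sequence) pairs as 80-column-wrapped FASTA."""
    recs = []
    for name, seq in sequences:
        if as_dna:
            seq = seq.replace("U", "T")
        recs.append(SeqRecord(Seq(seq), id=name, description=""))
    SeqIO.write(recs, str(path), "fasta")


def read_seed_table(path: str | Path) -> list["MirnaFamily"]:
    """Read a seed table TSV with columns family_name, seed_7nt."""
    from .sequence_sites import MirnaFamily

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"family_name", "seed_7nt"}
    if not required.issubset(df.columns):
        raise ValueError(f"seed table {path} must have columns {sorted(required)}")
    return [
        MirnaFamily(family_name=row.family_name, seed=row.seed_7nt)
        for row in df.itertuples()
    ]


def read_site_table(path: str | Path) -> list["SeedSite"]:
    """Read precomputed sites (gene_id, start, end, site_type; 0-based half-open)."""
    from .sequence_sites import SeedSite

    df = pd.read_csv(path, sep="\t")
    return [
        SeedSite(str(r.gene_id), int(r.start), int(r.end), str(r.site_type))
        for r in df.itertuples()
    ]


def write_site_table(sites: Iterable["SeedSite"], path: str | Path) -> None:
    pd.DataFrame(
        [(s.gene_id, s.start, s.end, s.site_type) for s in sites],
        columns=["gene_id", "start", "end", "site_type"],
    ).to_csv(path, sep="\t", index=False)


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample expression matrix (first column = row id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"expression matrix {path} contains missing values")
    if df.shape[1] < 4:
        raise ValueError("expression matrix needs at least 4 samples")
    return df


def read_gene_list(path: str | Path) -> set[str]:
    """Read a one-column (or first-column) gene list TSV."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return set(df.iloc[:, 0])
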