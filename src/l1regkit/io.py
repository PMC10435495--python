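"""Readers and writers for the plain-text formats used across the package.

FASTA via Biopython, BED6 via :mod:`l1regkit.g4`, tables as tab-separated
text with a header row, '.' decimal and UTF-8.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .g4 import Interval, SequenceRecord, load_intervals, write_intervals  # noqa: F401
from .setstats import DETable, GeneSet, GeneUniverse

__all__ = [
    "read_fasta",
    "write_fasta",
    "load_intervals",
    "write_intervals",
    "read_table",
    "write_table",
    "read_gene_set",
    "write_gene_set",
    "read_universe",
    "read_de_table",
]


def read_fasta(path) -> list[SequenceRecord]:
    """Read sequences; a subfamily label may ride in the description
    (``>id subfamily``)."""
    out = []
    with open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            parts = rec.description.split(maxsplit=1)
            subfamily = parts[1].strip() if len(parts) > 1 else ""
            out.append(SequenceRecord(id=rec.id, sequence=str(rec.seq), subfamily=subfamily))
    return out


def write_fasta(path, seqs: Sequence[SequenceRecord], width: int = 80) -> None:
    records = [
        BioSeqRecord(Seq(s.sequence), id=s.id, description=s.subfamily)
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_gene_set(path, label: str | None = None) -> GeneSet:
    """One identifier per line, or a two-column TSV (set_label, gene)."""
    path = Path(path)
    first = path.read_text().splitlines()
    genes: list[str] = []
    lab = label
    for line in first:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) >= 2:
            if lab is None:
                lab = fields[0]
            genes.append(fields[1])
        else:
            genes.append(fields[0])
    return GeneSet.from_iterable(lab or path.stem, genes)


def write_gene_set(path, gene_set: GeneSet) -> None:
    with open(path, "w") as fh:
        for g in sorted(gene_set.members):
            fh.write(f"{g}\n")


def read_universe(path) -> GeneUniverse:
    """Read a universe as an ordered line list (file order is preserved)."""
    lines = Path(path).read_text().splitlines()
    genes = [ln.split("\t")[-1].strip() for ln in lines if ln.strip() and not ln.startswith("#")]
    return GeneUniverse(genes)


def read_de_table(path, threshold: float = 0.05, label: str = "") -> DETable:
    return DETable(read_table(path), threshold=threshold, label=label or Path(path).stem)
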