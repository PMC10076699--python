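"""Format readers/writers shared by all stages.

FASTA/FASTQ go through Biopython's SeqIO.  Tables are tab-separated with a
header line and ``.`` for missing values; result tables carry ``#``-prefixed
provenance header lines (inputs, parameters, seed, version) that readers
skip.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from . import __version__

MISSING = "."


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Mapping[str, str]) -> None:
    recs = [
        BioSeqRecord(Seq(seq), id=name, description="")
        for name, seq in records.items()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path: str | Path) -> list[tuple[str, str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(
            chr(q + 33) for q in rec.letter_annotations["phred_quality"]
        )
        out.append((rec.id, str(rec.seq), qual))
    return out


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def provenance_lines(**params) -> str:
    parts = "; ".join(f"{k}={v}" for k, v in params.items())
    return f"# isoswitch v{__version__}" + (f"; {parts}" if parts else "") + "\n"


def write_tsv(path: str | Path, frame: pd.DataFrame, index: bool = True, **params) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_lines(**params))
        frame.to_csv(fh, sep="\t", na_rep=MISSING, index=index)


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(
        str(path), sep="\t", comment="#", na_values=[MISSING], index_col=index_col
    )


def write_bed(path: str | Path, features: Iterable[tuple]) -> None:
    """Write (chrom, start, end, name, strand) features as 6-column BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name, strand in features:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")
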