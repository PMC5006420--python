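"""File formats: FASTA in/out, TSV with config-stamped headers, GFF3 out.

Internal coordinates are 0-based half-open everywhere; conversion to GFF3's
1-based inclusive convention happens only in :func:`gff3_line`.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from urllib.parse import quote

import pandas as pd
from Bio import SeqIO

from dgrhunt.core import Contig, Interval


def read_fasta(path) -> list[Contig]:
    """Read contigs from FASTA (wrapped lines and CRLF tolerated).

    Duplicate sequence identifiers are rejected.
    """
    contigs: list[Contig] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        contigs.append(Contig(rec.id, str(rec.seq).upper(), source=str(path)))
    return contigs


def write_fasta(contigs: list[Contig], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.seq), width):
                fh.write(c.seq[i:i + width] + "\n")


def write_tsv(df: pd.DataFrame, path, header_comments: list[str] | None = None) -> None:
    """TSV with '#'-prefixed comment lines (config hash etc.) above the header."""
    with open(path, "w") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def _attr(value) -> str:
    return quote(str(value), safe=" :/|().,-_")


def gff3_line(seqid: str, source: str, ftype: str, interval: Interval, strand: str,
              attributes: dict, score: str = ".") -> str:
    """One GFF3 feature line; *interval* is 0-based half-open."""
    start, end = interval
    attrs = ";".join(f"{k}={_attr(v)}" for k, v in attributes.items())
    return "\t".join(
        [seqid, source, ftype, str(start + 1), str(end), score, strand, ".", attrs]
    )


def write_gff3(lines: list[str], path, header_comments: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        for line in lines:
            fh.write(line + "\n")
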