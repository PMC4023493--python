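"""FASTA/FASTQ reading and writing.

Format is sniffed from the first byte ('>' FASTA, '@' FASTQ), with
transparent gzip support.  Parsing is delegated to Biopython; qualities
travel as Phred+33 strings alongside the sequence.  FASTA output wraps at
70 columns (the documented dialect of this tool).
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

from .corrector import Read

FASTA_WRAP = 70


def _open_text(path):
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return gzip.open(raw, "rt")
    return open(path, "rt")


def sniff_format(path) -> str:
    with _open_text(path) as fh:
        first = fh.read(1)
    if first in (">", ""):  # an empty file parses as an empty FASTA
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"{path}: cannot sniff format from first byte {first!r}")


def read_sequences(path) -> list[Read]:
    """All reads of a FASTA/FASTQ(.gz) file, order and ids preserved."""
    fmt = sniff_format(path)
    out = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, fmt):
            qual = None
            if fmt == "fastq":
                qual = "".join(
                    chr(q + 33) for q in rec.letter_annotations["phred_quality"]
                )
            out.append(Read(rec.id, str(rec.seq), qual))
    return out


def write_sequences(reads: Iterable[Read], path, format: Optional[str] = None) -> None:
    """Write reads as FASTA (70-column wrap) or FASTQ.

    When ``format`` is omitted it is inferred from the file suffix.
    FASTQ requires every read to carry a quality string.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower().lstrip(".")
        format = {"fa": "fasta", "fasta": "fasta", "fq": "fastq", "fastq": "fastq"}.get(
            suffix
        )
        if format is None:
            raise ValueError(f"cannot infer format from suffix of {path}")
    with open(path, "w") as fh:
        if format == "fasta":
            for r in reads:
                fh.write(f">{r.id}\n")
                for i in range(0, len(r.sequence), FASTA_WRAP):
                    fh.write(r.sequence[i : i + FASTA_WRAP] + "\n")
        elif format == "fastq":
            for r in reads:
                if r.quality is None:
                    raise ValueError(f"read {r.id} has no quality; cannot write FASTQ")
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")
        else:
            raise ValueError(f"unknown format {format!r}")
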