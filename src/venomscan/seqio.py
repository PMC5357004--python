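"""File-format plumbing: FASTA / FASTQ / MGF / TSV readers and writers.

Thin wrappers over Biopython and pyteomics.  Reference-database FASTA records
carry their family label and ICK flag in the description line as
``family=<id> ick=<0|1>``; MGF spectra are identified by their TITLE field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

PathLike = Union[str, Path]

__all__ = [
    "FastaRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_mgf",
    "write_mgf",
    "parse_label",
]


@dataclass
class FastaRecord:
    id: str
    seq: str
    description: str = ""

    @property
    def family(self) -> Optional[str]:
        return parse_label(self.description).get("family")

    @property
    def ick(self) -> Optional[bool]:
        v = parse_label(self.description).get("ick")
        return None if v is None else v == "1"


_LABEL_RE = re.compile(r"(\w+)=(\S+)")


def parse_label(description: str) -> Dict[str, str]:
    """Parse ``key=value`` tokens out of a FASTA description line."""
    return dict(_LABEL_RE.findall(description or ""))


def read_fasta(path: PathLike) -> List[FastaRecord]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(FastaRecord(rec.id, str(rec.seq), desc))
    return out


def write_fasta(records: Iterable[FastaRecord], path: PathLike) -> None:
    seqs = [
        SeqRecord(Seq(r.seq), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_fastq(path: PathLike) -> List[Tuple[str, str, str]]:
    """Return (id, sequence, Sanger-quality string) triples."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((rec.id, str(rec.seq), qual))
    return out


def write_fastq(reads: Iterable[Tuple[str, str, str]], path: PathLike) -> None:
    records = []
    for rid, seq, qual in reads:
        rec = SeqRecord(Seq(seq), id=rid, description="")
        rec.letter_annotations["phred_quality"] = [ord(c) - 33 for c in qual]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_mgf(path: PathLike) -> List[dict]:
    """Read an MGF file into pyteomics spectrum dictionaries."""
    with _mgf.read(str(path)) as reader:
        return list(reader)


def write_mgf(spectra: Sequence[dict], path: PathLike) -> None:
    _mgf.write(spectra, str(path), file_mode="w")
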