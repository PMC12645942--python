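"""Small shared helpers: sequence ops and FASTA/FASTQ I/O wrappers."""

from __future__ import annotations

import io
from typing import Dict, Iterable, List, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def comp_base(base: str) -> str:
    return base.translate(_COMP)


def read_fasta(path) -> Dict[str, str]:
    """Reference set as an ordered {name: sequence} dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(refs: Dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in refs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fasta_bytes(refs: Dict[str, str], width: int = 60) -> bytes:
    buf = io.StringIO()
    for name, seq in refs.items():
        buf.write(f">{name}\n")
        for i in range(0, len(seq), width):
            buf.write(seq[i : i + width] + "\n")
    return buf.getvalue().encode()


def read_fastq(path) -> List[Tuple[str, str, List[int]]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq).upper(), rec.letter_annotations["phred_quality"]))
    return out


def write_fastq(records: Iterable[Tuple[str, str, List[int]]], path) -> None:
    with open(path, "w") as fh:
        fh.write(fastq_str(records))


def fastq_str(records: Iterable[Tuple[str, str, List[int]]]) -> str:
    buf = io.StringIO()
    for read_id, seq, quals in records:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = list(quals)
        SeqIO.write(rec, buf, "fastq")
    return buf.getvalue()
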