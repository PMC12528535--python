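"""FASTA alignment I/O (thin wrappers around Biopython)."""

from __future__ import annotations

from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """Read an aligned FASTA file into an ordered {name: sequence} dict."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"duplicate FASTA record {rec.id!r}")
        out[rec.id] = str(rec.seq)
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(alignment: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in alignment.items()]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")
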