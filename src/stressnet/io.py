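"""FASTA and TSV helpers shared by the pipeline stages."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an id -> sequence mapping (insertion order)."""
    return {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: Mapping[str, str], path, sort: bool = True) -> None:
    """Write sequences as FASTA; sorted by id for byte-stable output."""
    ids = sorted(seqs) if sort else list(seqs)
    records = (SeqRecord(Seq(seqs[i]), id=i, description="") for i in ids)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def sequence_lengths(path) -> dict[str, int]:
    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
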