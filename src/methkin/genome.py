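"""Genome sequence I/O (FASTA, via Biopython)."""
from __future__ import annotations

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def load_fasta(path: str) -> dict[str, str]:
    """Load a genome as a dict of uppercase chromosome sequences."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(genome: dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, path, "fasta")
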