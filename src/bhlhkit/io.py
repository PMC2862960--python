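"""FASTA and tabular I/O helpers shared across the pipeline."""

from __future__ import annotations

from typing import Iterable, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered ``{seq_id: sequence}`` dict.

    The sequence id is the first whitespace-delimited token of the header.
    """
    seqs: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(path, seqs: Iterable[Tuple[str, str]], width: int = 60) -> None:
    """Write ``(id, sequence)`` pairs as FASTA wrapped at ``width`` columns."""
    records = [SeqRecord(Seq(s), id=sid, description="") for sid, s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def match_report_rows(matches) -> list:
    """TSV-ready rows for a list of :class:`~bhlhkit.motif.MotifMatch`."""
    return [
        {
            "seq_id": m.seq_id,
            "start": m.start,
            "end": m.end,
            "n_mismatch": m.n_mismatch,
            "n_conserved": m.n_conserved,
            "is_candidate": m.is_candidate,
            "domain_seq": m.domain_seq,
        }
        for m in matches
    ]
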