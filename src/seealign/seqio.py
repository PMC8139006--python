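"""FASTA/FASTQ input and SAM output.

Coordinates are 0-based half-open internally and 1-based in SAM output.
The SAM body is written deterministically: identical inputs, configuration
and seed produce byte-identical files.
"""

from __future__ import annotations

import gzip
import sys
from typing import Iterator

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import __version__
from .extension import AlignmentResult
from .pipeline import Read


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


class SequenceFileError(ValueError):
    """Malformed FASTA/FASTQ input."""


def read_fasta(path) -> list[tuple[str, str]]:
    """All records of a (possibly gzipped, line-wrapped) FASTA file as
    (name, uppercased sequence), in file order."""
    records = []
    with _open_text(path) as fh:
        try:
            for rec in SeqIO.parse(fh, "fasta"):
                records.append((rec.id, str(rec.seq).upper()))
        except ValueError as exc:
            raise SequenceFileError(f"{path}: {exc}") from exc
    if not records:
        raise SequenceFileError(f"{path}: no FASTA records found")
    return records


def read_fastq(path, mate: int = 0) -> Iterator[Read]:
    """Stream reads from a (possibly gzipped) FASTQ file.

    Raises :class:`SequenceFileError` naming the offending record when the
    quality string length does not match the sequence length.
    """
    with _open_text(path) as fh:
        try:
            for title, seq, qual in FastqGeneralIterator(fh):
                yield Read(id=title.split()[0], seq=seq.upper(), qual=qual, mate=mate)
        except ValueError as exc:
            raise SequenceFileError(f"{path}: {exc}") from exc


def _flag(r: AlignmentResult) -> int:
    flag = 0
    if r.is_paired:
        flag |= 0x1
        if r.proper_pair:
            flag |= 0x2
        if not r.mate_mapped:
            flag |= 0x8
        elif r.mate_strand == "-":
            flag |= 0x20
        flag |= 0x40 if r.mate == 1 else 0x80
    if not r.mapped:
        flag |= 0x4
    elif r.strand == "-":
        flag |= 0x10
    return flag


def sam_record(r: AlignmentResult) -> str:
    """One SAM body line for an alignment result."""
    flag = _flag(r)
    rname = r.ref_name if r.ref_name is not None else "*"
    pos = (r.pos + 1) if r.pos is not None else 0
    mapq = r.mapq if r.mapped else 0
    cigar = r.cigar if (r.mapped and r.cigar) else "*"
    if r.is_paired and r.mate_ref_name is not None:
        rnext = "=" if r.mate_ref_name == rname else r.mate_ref_name
        pnext = (r.mate_pos + 1) if r.mate_pos is not None else 0
    else:
        rnext, pnext = "*", 0
    qual = r.qual if r.qual is not None else "*"
    fields = [
        r.read_id,
        str(flag),
        rname,
        str(pos),
        str(mapq),
        cigar,
        rnext,
        str(pnext),
        str(r.tlen),
        r.seq,
        qual,
    ]
    if r.mapped and r.nm is not None:
        fields.append(f"NM:i:{r.nm}")
    if r.embed_dist is not None:
        fields.append(f"XE:i:{r.embed_dist}")
    return "\t".join(fields)


def write_sam(results, reference, path, command: str | None = None) -> None:
    """Write a SAM file: @HD/@SQ/@PG header then one line per result.

    ``reference`` supplies the @SQ table; ``results`` is an iterable of
    :class:`AlignmentResult` in output order (mates adjacent).
    """
    out = sys.stdout if path in (None, "-") else open(path, "w")
    try:
        out.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, _start, length in reference.seq_table:
            out.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        pg = f"@PG\tID:seealign\tPN:seealign\tVN:{__version__}"
        if command:
            pg += f"\tCL:{command}"
        out.write(pg + "\n")
        for r in results:
            out.write(sam_record(r) + "\n")
    finally:
        if out is not sys.stdout:
            out.close()
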