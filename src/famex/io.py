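"""Sequence file handling: streaming FASTA/FASTQ readers and writers."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO


class SequenceFileError(ValueError):
    """Malformed sequence file; message names the failing record ordinal."""


def _open_text(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(handle) -> str:
    pos = handle.tell()
    first = handle.read(1)
    handle.seek(pos)
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise SequenceFileError("cannot detect format: file does not start with '>' or '@'")


def read_sequences(path: str | Path) -> Iterator[tuple[str, str, str | None]]:
    """Stream (id, sequence, qualities) records from FASTA/FASTQ.

    Plain or gzip-compressed input is auto-detected; ids are preserved
    verbatim (full description up to first whitespace, as the format
    defines). Malformed records raise :class:`SequenceFileError` naming the
    record ordinal.
    """
    path = Path(path)
    handle = _open_text(path)
    try:
        fmt = _sniff_format(handle)
        ordinal = 0
        iterator = SeqIO.parse(handle, fmt)
        while True:
            try:
                record = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise SequenceFileError(
                    f"{path}: malformed record {ordinal + 1}: {exc}"
                ) from exc
            ordinal += 1
            quals = None
            if fmt == "fastq":
                phred = record.letter_annotations.get("phred_quality")
                if phred is not None:
                    quals = "".join(chr(q + 33) for q in phred)
            yield record.id, str(record.seq).upper(), quals
    finally:
        handle.close()


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write (id, sequence) pairs as FASTQ with uniform placeholder quality."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
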