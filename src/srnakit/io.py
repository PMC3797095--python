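"""Sequence and table I/O helpers.

FASTA/FASTQ parsing is delegated to Biopython; all sequences are
normalized to the DNA alphabet (U -> T, uppercase) on the way in.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator

from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")


def normalize_seq(seq: str) -> str:
    """Uppercase and map U -> T. Raises on symbols outside {A,C,G,T,U,N}."""
    s = seq.upper().replace("U", "T")
    if not set(s) <= VALID_BASES:
        bad = sorted(set(s) - VALID_BASES)
        raise ValueError(f"unknown nucleotide symbols {bad!r} in sequence")
    return s


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Read a FASTA file into [(id, T-normalized sequence), ...]."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, normalize_seq(str(rec.seq))))
    return records


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]],
                rna: bool = False) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{to_rna(seq) if rna else seq}\n")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, T-normalized sequence, phred qualities) from a FASTQ file.

    Malformed records (sequence/quality length mismatch, truncated entries)
    raise ``ValueError`` with the record index.
    """
    for idx, rec in enumerate(SeqIO.parse(str(path), "fastq")):
        quals = rec.letter_annotations["phred_quality"]
        seq = str(rec.seq)
        if len(quals) != len(seq):
            raise ValueError(f"FASTQ record {idx}: quality/sequence length mismatch")
        try:
            yield rec.id, normalize_seq(seq), list(quals)
        except ValueError as exc:
            raise ValueError(f"FASTQ record {idx}: {exc}") from exc


def write_fastq(path: str | os.PathLike,
                records: Iterable[tuple[str, str, str]]) -> None:
    """Write (id, sequence, quality-string) triples as 4-line FASTQ."""
    with open(path, "w") as fh:
        for name, seq, qual in records:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")
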