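"""Raw read cleaning, tag collapsing and length distributions.

Cleaning applies a fixed cascade of filters so that every discarded read
is counted under exactly one reason:

    low_quality -> contains_N -> adapter5_pollution -> no_adapter3
    -> (trim) -> no_insert -> polyA -> too_short -> too_long

The 3' adapter is located by the leftmost exact match of its first
``adapter3_seed`` bases; everything 5' of the match is the insert.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

from .io import normalize_seq, read_fasta, read_fastq

#: discard reasons, in the order the filters are applied
REASONS = (
    "low_quality",
    "contains_N",
    "adapter5_pollution",
    "no_adapter3",
    "no_insert",
    "polyA",
    "too_short",
    "too_long",
)


@dataclass
class RawRead:
    id: str
    sequence: str
    quality: list[int] | None = None

    def __post_init__(self) -> None:
        self.sequence = normalize_seq(self.sequence)
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id}: quality/sequence length mismatch")


@dataclass
class FilterParams:
    adapter3: str
    adapter5: str = ""
    min_len: int = 18
    max_len: int = 30
    min_phred: int = 20
    max_low_quality_frac: float = 0.10
    polya_frac: float = 0.80
    polya_run: int = 10
    adapter_seed: int = 8

    def __post_init__(self) -> None:
        if not self.adapter3:
            raise ValueError("adapter3 must be non-empty")
        self.adapter3 = normalize_seq(self.adapter3)
        if self.adapter5:
            self.adapter5 = normalize_seq(self.adapter5)


@dataclass
class CleanStats:
    input_reads: int = 0
    removed_by_reason: dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in REASONS})
    clean_reads: int = 0

    def check(self) -> None:
        total = self.clean_reads + sum(self.removed_by_reason.values())
        if total != self.input_reads:
            raise AssertionError(
                f"stats do not reconcile: {self.input_reads} in, "
                f"{self.clean_reads} clean + {total - self.clean_reads} removed")


@dataclass(frozen=True)
class CountedTag:
    """A unique insert sequence with per-library read counts."""
    sequence: str
    count_na: int = 0
    count_da: int = 0

    @property
    def total(self) -> int:
        return self.count_na + self.count_da


def _is_polya(insert: str, frac: float, run: int) -> bool:
    if not insert:
        return False
    if insert.count("A") / len(insert) >= frac:
        return True
    return "A" * run in insert


def clean_read(read: RawRead, params: FilterParams) -> tuple[str | None, str | None]:
    """Clean one read. Returns (insert, None) or (None, discard reason)."""
    seq = read.sequence
    if read.quality is not None:
        n_low = sum(1 for q in read.quality if q < params.min_phred)
        if n_low / len(seq) > params.max_low_quality_frac:
            return None, "low_quality"
    if "N" in seq:
        return None, "contains_N"
    if params.adapter5:
        seed5 = params.adapter5[: params.adapter_seed]
        if seed5 in seq:
            return None, "adapter5_pollution"
    seed3 = params.adapter3[: params.adapter_seed]
    pos = seq.find(seed3)
    if pos < 0:
        return None, "no_adapter3"
    insert = seq[:pos]
    if not insert:
        return None, "no_insert"
    if _is_polya(insert, params.polya_frac, params.polya_run):
        return None, "polyA"
    if len(insert) < params.min_len:
        return None, "too_short"
    if len(insert) > params.max_len:
        return None, "too_long"
    return insert, None


def clean_reads(reads: Iterable[RawRead],
                params: FilterParams) -> tuple[list[str], CleanStats]:
    """Run the filter cascade over a read stream.

    Returns the clean insert sequences (T-normalized, adapter-trimmed)
    and reconciled :class:`CleanStats`.
    """
    stats = CleanStats()
    inserts: list[str] = []
    for read in reads:
        stats.input_reads += 1
        insert, reason = clean_read(read, params)
        if insert is None:
            stats.removed_by_reason[reason] += 1
        else:
            stats.clean_reads += 1
            inserts.append(insert)
    stats.check()
    return inserts, stats


def iter_reads(path: str, fmt: str | None = None) -> Iterator[RawRead]:
    """Stream RawReads from a FASTQ or FASTA file (format sniffed by suffix)."""
    if fmt is None:
        low = str(path).lower()
        fmt = "fasta" if low.endswith((".fa", ".fasta", ".fna")) else "fastq"
    if fmt == "fasta":
        for name, seq in read_fasta(path):
            yield RawRead(name, seq)
    else:
        for name, seq, quals in read_fastq(path):
            yield RawRead(name, seq, quals)


def collapse_unique(inserts_na: Iterable[str],
                    inserts_da: Iterable[str]) -> list[CountedTag]:
    """Collapse cleaned inserts from both libraries into unique tags.

    Tags are sorted by total count descending, ties broken by sequence.
    """
    counts: dict[str, list[int]] = {}
    for seq in inserts_na:
        counts.setdefault(seq, [0, 0])[0] += 1
    for seq in inserts_da:
        counts.setdefault(seq, [0, 0])[1] += 1
    tags = [CountedTag(s, x, y) for s, (x, y) in counts.items()]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def expand_tags(tags: Iterable[CountedTag], library: str) -> list[str]:
    """Inverse of collapse for one library (round-trip testing helper)."""
    out: list[str] = []
    for tag in tags:
        n = tag.count_na if library == "NA" else tag.count_da
        out.extend([tag.sequence] * n)
    return out


def length_distribution(tags: Iterable[CountedTag], library: str) -> dict[int, float]:
    """Percentage of reads (not unique tags) at each insert length."""
    hist: dict[int, int] = {}
    total = 0
    for tag in tags:
        n = tag.count_na if library == "NA" else tag.count_da
        if n:
            hist[len(tag.sequence)] = hist.get(len(tag.sequence), 0) + n
            total += n
    if total == 0:
        raise ValueError(f"no reads in library {library}")
    return {length: 100.0 * n / total for length, n in sorted(hist.items())}


def write_tags_fasta(path: str, tags: Iterable[CountedTag]) -> None:
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{tag.total}\n{tag.sequence}\n")


def write_tags_tsv(path: str, tags: Iterable[CountedTag]) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount_na\tcount_da\n")
        for tag in tags:
            fh.write(f"{tag.sequence}\t{tag.count_na}\t{tag.count_da}\n")


def read_tags_tsv(path: str) -> list[CountedTag]:
    tags = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("sequence"):
            raise ValueError("tag TSV must have a 'sequence\\tcount_na\\tcount_da' header")
        for line in fh:
            seq, x, y = line.rstrip("\n").split("\t")
            tags.append(CountedTag(normalize_seq(seq), int(x), int(y)))
    return tags
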