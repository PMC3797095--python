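"""Novel miRNA candidate calling from unannotated tags.

Pipeline: anchor a tag in genome/transcriptome contigs, cut candidate
precursor windows around each occurrence, fold each window into its
minimum-energy single stem-loop, and accept a hairpin when the mature
tag sits entirely on one arm, the fold energy is at or below the
threshold (default -18 kcal/mol) and read support is sufficient.

The folding model is deliberately restricted to one helix (with bulges
and internal loops up to a configurable size) closed by one terminal
loop — the geometry of an animal pre-miRNA — so the dynamic program is
exact, fast and trivially re-scorable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .io import normalize_seq, reverse_complement

_PAIR_TYPE = {
    ("G", "C"): "GC", ("C", "G"): "GC",
    ("A", "T"): "AU", ("T", "A"): "AU",
    ("G", "T"): "GU", ("T", "G"): "GU",
}


@dataclass
class EnergyModel:
    """Additive stack/loop energies for the single-stem-loop fold."""
    pair_energies: dict[str, float] = field(
        default_factory=lambda: {"GC": -3.3, "AU": -1.1, "GU": -0.5})
    loop_a: float = 5.5
    loop_b: float = 2.0
    min_loop: int = 3
    max_interior: int = 3

    def __post_init__(self) -> None:
        if self.min_loop < 3:
            raise ValueError("minimum loop size must be >= 3")
        if any(e > 0 for e in self.pair_energies.values()):
            raise ValueError("stack energies must be <= 0")

    @classmethod
    def default(cls) -> "EnergyModel":
        with resources.files("srnakit.data").joinpath("energy.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, d: dict) -> "EnergyModel":
        return cls(pair_energies=dict(d["pair_energies"]),
                   loop_a=float(d["loop_a"]), loop_b=float(d["loop_b"]),
                   min_loop=int(d["min_loop"]), max_interior=int(d["max_interior"]))

    @classmethod
    def from_yaml(cls, path: str) -> "EnergyModel":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def pairable(self, a: str, b: str) -> bool:
        return (a, b) in _PAIR_TYPE

    def stack(self, pair_outer: str, pair_inner: str) -> float:
        return 0.5 * (self.pair_energies[pair_outer] + self.pair_energies[pair_inner])

    def loop_penalty(self, length: int) -> float:
        if length <= 0:
            raise ValueError("loop length must be positive")
        return max(0.0, self.loop_a + self.loop_b * math.log(length / 4.0))


def fold_hairpin(sequence: str,
                 model: EnergyModel | None = None) -> tuple[str, float]:
    """Fold a sequence into its minimum-energy single stem-loop.

    Returns (dot-bracket pairing, mfe in kcal/mol). If no structure has
    negative energy the sequence is returned unpaired with mfe 0.0. The
    returned mfe always equals :func:`score_structure` of the returned
    pairing.
    """
    model = model or EnergyModel.default()
    seq = normalize_seq(sequence)
    n = len(seq)
    NEG = float("inf")

    def ptype(i: int, j: int) -> str | None:
        return _PAIR_TYPE.get((seq[i], seq[j]))

    # C[(i, j)] = best energy of a stem-loop closed by pair (i, j)
    C: dict[tuple[int, int], float] = {}
    back: dict[tuple[int, int], tuple[int, int] | None] = {}
    max_span = model.max_interior
    for span in range(model.min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            pt = ptype(i, j)
            if pt is None:
                continue
            best = NEG
            choice: tuple[int, int] | None = None
            loop_len = j - i - 1
            if loop_len >= model.min_loop:
                best = model.loop_penalty(loop_len)
                choice = None
            for i2 in range(i + 1, min(i + 2 + max_span, j)):
                l1 = i2 - i - 1
                for j2 in range(max(i2 + 1, j - 1 - (max_span - l1)), j):
                    l2 = j - j2 - 1
                    if l1 + l2 > max_span:
                        continue
                    inner = C.get((i2, j2))
                    if inner is None:
                        continue
                    if l1 == 0 and l2 == 0:
                        e = inner + model.stack(pt, ptype(i2, j2))
                    else:
                        e = inner + model.loop_penalty(l1 + l2)
                    if e < best:
                        best = e
                        choice = (i2, j2)
            if best < NEG:
                C[(i, j)] = best
                back[(i, j)] = choice

    if not C:
        return "." * n, 0.0
    (i0, j0), mfe = min(C.items(), key=lambda kv: (kv[1], kv[0]))
    if mfe >= 0.0:
        return "." * n, 0.0

    pairing = ["."] * n
    node: tuple[int, int] | None = (i0, j0)
    while node is not None:
        i, j = node
        pairing[i], pairing[j] = "(", ")"
        node = back[node]
    dotbracket = "".join(pairing)
    # report the energy re-scored from the structure so that mfe is
    # exactly reproducible from the returned pairing
    return dotbracket, score_structure(seq, dotbracket, model)


def parse_pairs(dotbracket: str) -> list[tuple[int, int]]:
    """Dot-bracket -> sorted (i, j) pairs (0-based). Must be nested."""
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for idx, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket")
            pairs.append((stack.pop(), idx))
    if stack:
        raise ValueError("unbalanced dot-bracket")
    return sorted(pairs)


def score_structure(sequence: str, dotbracket: str,
                    model: EnergyModel | None = None) -> float:
    """Recompute the energy of a single-stem-loop pairing from scratch.

    Independent of the folding DP: walks the helix from the outermost
    pair inward summing stack energies and loop penalties, then adds the
    terminal loop penalty.
    """
    model = model or EnergyModel.default()
    seq = normalize_seq(sequence)
    pairs = parse_pairs(dotbracket)
    if not pairs:
        return 0.0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        if not (i1 < i2 < j2 < j1):
            raise ValueError("pairing is not a single nested stem")
    energy = 0.0
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        l1, l2 = i2 - i1 - 1, j1 - j2 - 1
        pt1, pt2 = _PAIR_TYPE[(seq[i1], seq[j1])], _PAIR_TYPE[(seq[i2], seq[j2])]
        if l1 == 0 and l2 == 0:
            energy += model.stack(pt1, pt2)
        else:
            energy += model.loop_penalty(l1 + l2)
    i_in, j_in = pairs[-1]
    energy += model.loop_penalty(j_in - i_in - 1)
    return energy


@dataclass(frozen=True)
class CandidateWindow:
    """A precursor window around a genomic tag occurrence, in folding orientation."""
    contig: str
    start: int            # 1-based inclusive, forward strand
    end: int
    strand: str           # '+' or '-'
    sequence: str         # folding orientation (revcomp for '-' windows)
    mature_start: int     # 0-based offset of the tag within `sequence`
    mature_end: int       # exclusive


@dataclass
class HairpinCandidate:
    tag: str
    contig: str
    start: int
    end: int
    strand: str
    precursor: str
    pairing: str
    mfe: float
    mature_start: int
    mature_end: int
    arm: str              # 5p | 3p | loop-overlap
    supporting_reads: int


def extract_candidate_precursors(tag: str,
                                 references: list[tuple[str, str]],
                                 flank_long: int = 70,
                                 flank_short: int = 20) -> list[CandidateWindow]:
    """Windows around every exact occurrence of the tag (either strand).

    Each occurrence yields two asymmetric windows (long flank upstream or
    downstream of the mature) so the mature can land on either hairpin arm.
    """
    tag = normalize_seq(tag)
    rc = reverse_complement(tag)
    windows: list[CandidateWindow] = []
    for contig_id, contig_seq in references:
        for strand, query in (("+", tag), ("-", rc)):
            pos = contig_seq.find(query)
            while pos >= 0:
                occ_start, occ_end = pos + 1, pos + len(query)  # 1-based
                for up, down in ((flank_long, flank_short), (flank_short, flank_long)):
                    w_start = max(1, occ_start - up)
                    w_end = min(len(contig_seq), occ_end + down)
                    w_seq = contig_seq[w_start - 1:w_end]
                    if strand == "+":
                        m0 = occ_start - w_start
                    else:
                        w_seq = reverse_complement(w_seq)
                        m0 = w_end - occ_end
                    windows.append(CandidateWindow(
                        contig_id, w_start, w_end, strand, w_seq,
                        m0, m0 + len(tag)))
                pos = contig_seq.find(query, pos + 1)
    return windows


def mature_arm(dotbracket: str, mature_start: int, mature_end: int) -> str:
    """Which hairpin arm holds the mature interval (0-based, end exclusive)."""
    pairs = parse_pairs(dotbracket)
    if not pairs:
        return "loop-overlap"
    i_in, j_in = pairs[-1]           # innermost pair flanks the terminal loop
    if mature_end - 1 <= i_in:
        return "5p"
    if mature_start >= j_in:
        return "3p"
    return "loop-overlap"


def call_novel_mirna(windows: list[CandidateWindow],
                     tag: str,
                     supporting_reads: int,
                     model: EnergyModel | None = None,
                     mfe_max: float = -18.0,
                     min_reads: int = 5) -> tuple[HairpinCandidate | None, str | None]:
    """Apply the acceptance cascade to a tag's candidate windows.

    Criteria, in order: (1) a genomic match exists; (2) the fold is a
    single stem-loop with the mature entirely on one arm; (3) mfe <=
    ``mfe_max``; (4) supporting reads >= ``min_reads``. Returns the
    accepted candidate (best mfe, ties to smallest coordinate) or
    (None, first-failed-criterion).
    """
    model = model or EnergyModel.default()
    if not windows:
        return None, "no_genomic_match"

    folded: list[tuple[float, CandidateWindow, str, str]] = []
    for w in windows:
        pairing, mfe = fold_hairpin(w.sequence, model)
        arm = mature_arm(pairing, w.mature_start, w.mature_end)
        folded.append((mfe, w, pairing, arm))
    folded.sort(key=lambda t: (t[0], t[1].contig, t[1].start))

    accepted = [f for f in folded
                if f[3] in ("5p", "3p") and f[0] <= mfe_max]
    if accepted and supporting_reads >= min_reads:
        mfe, w, pairing, arm = accepted[0]
        return HairpinCandidate(
            tag=normalize_seq(tag), contig=w.contig, start=w.start, end=w.end,
            strand=w.strand, precursor=w.sequence, pairing=pairing, mfe=mfe,
            mature_start=w.mature_start, mature_end=w.mature_end, arm=arm,
            supporting_reads=supporting_reads), None

    best = folded[0]
    if best[3] not in ("5p", "3p") and not any(f[3] in ("5p", "3p") for f in folded):
        return None, "loop-overlap"
    if not accepted:
        return None, "mfe_above_threshold"
    return None, "insufficient_reads"
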