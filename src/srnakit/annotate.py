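"""Tag classification against ncRNA references and known-miRNA quantification.

A tag is first tested against contaminant classes in the fixed priority
order rRNA > tRNA > snRNA > snoRNA (exact substring of any reference
record). Surviving tags are matched to known mature/precursor miRNAs
(perfect matches only), one representative per family is chosen as the
quantification reference ("temporary database"), and expression is the
sum of counts of tags matching a representative without mismatches.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from .io import normalize_seq
from .preprocess import CountedTag

CONTAMINANT_PRIORITY = ("rRNA", "tRNA", "snRNA", "snoRNA")
CATEGORIES = ("miRNA",) + CONTAMINANT_PRIORITY + ("unannotated",)


@dataclass
class ReferenceSet:
    name: str
    records: list[tuple[str, str]]
    family_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r[0] for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate ids in reference set {self.name}")
        self.records = [(i, normalize_seq(s)) for i, s in self.records]


_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-")
_ARM_SUFFIX = re.compile(r"-(5p|3p)$")


def family_root(mature_id: str) -> str:
    """Fallback family name: strip species prefix and -5p/-3p arm suffix."""
    return _ARM_SUFFIX.sub("", _SPECIES_PREFIX.sub("", mature_id))


def classify_ncrna(tags: list[CountedTag],
                   refsets: dict[str, ReferenceSet]) -> dict[str, tuple[str, str]]:
    """Assign tags to contaminant classes by exact substring matching.

    Returns {tag sequence: (class, reference id)} for assigned tags only;
    unassigned tags stay available for miRNA matching.
    """
    assignment: dict[str, tuple[str, str]] = {}
    for cls in CONTAMINANT_PRIORITY:
        refset = refsets.get(cls)
        if refset is None:
            continue
        if not refset.records:
            warnings.warn(f"empty reference set for class {cls}")
            continue
        for tag in tags:
            if tag.sequence in assignment:
                continue
            for ref_id, ref_seq in refset.records:
                if tag.sequence in ref_seq:
                    assignment[tag.sequence] = (cls, ref_id)
                    break
    return assignment


@dataclass(frozen=True)
class MirnaHit:
    tag: str
    mature_id: str
    family: str


def _precursor_mature_starts(precursor_seq: str,
                             matures: list[tuple[str, str]]) -> list[tuple[str, int]]:
    """All (mature_id, 0-based start) placements of mature refs inside a precursor."""
    placements = []
    for mid, mseq in matures:
        start = precursor_seq.find(mseq)
        while start >= 0:
            placements.append((mid, start))
            start = precursor_seq.find(mseq, start + 1)
    return placements


def match_known_mirnas(tags: list[CountedTag],
                       mature: ReferenceSet,
                       precursor: ReferenceSet | None = None,
                       offset_tol: int = 2) -> dict[str, list[MirnaHit]]:
    """Match tags against known miRNAs, grouped by family.

    A tag hits a mature reference if it is identical to it, or if it is an
    exact substring of a precursor starting within ``offset_tol`` nt of
    that mature's annotated start in the precursor (isomiR 5' wobble).
    """
    def family(mid: str) -> str:
        fam = mature.family_of.get(mid)
        if fam is None:
            fam = family_root(mid)
            warnings.warn(f"mature id {mid} missing from family map; using root {fam}")
        return fam

    by_seq: dict[str, list[tuple[str, str]]] = {}
    for mid, mseq in mature.records:
        by_seq.setdefault(mseq, []).append((mid, mseq))

    placements: list[tuple[str, str, list[tuple[str, int]]]] = []
    if precursor is not None:
        for pid, pseq in precursor.records:
            placements.append((pid, pseq, _precursor_mature_starts(pseq, mature.records)))

    hits: dict[str, list[MirnaHit]] = {}
    for tag in tags:
        seen: set[str] = set()
        for mid, _ in by_seq.get(tag.sequence, []):
            if mid not in seen:
                seen.add(mid)
                hits.setdefault(family(mid), []).append(MirnaHit(tag.sequence, mid, family(mid)))
        for pid, pseq, mstarts in placements:
            pos = pseq.find(tag.sequence)
            while pos >= 0:
                for mid, mstart in mstarts:
                    if abs(pos - mstart) <= offset_tol and mid not in seen:
                        seen.add(mid)
                        hits.setdefault(family(mid), []).append(
                            MirnaHit(tag.sequence, mid, family(mid)))
                pos = pseq.find(tag.sequence, pos + 1)
    return hits


@dataclass
class TemporaryMirnaDB:
    """One representative mature miRNA per family, chosen by expression."""
    representatives: dict[str, tuple[str, str]]  # family -> (mature_id, sequence)

    def items(self):
        return self.representatives.items()


def build_temporary_db(hits: dict[str, list[MirnaHit]],
                       tags: list[CountedTag],
                       mature: ReferenceSet) -> TemporaryMirnaDB:
    """Pick the highest-expressed mature reference per family.

    Expression of a mature reference = summed NA+DA counts of all tags
    hitting it; ties broken by lexicographically smallest reference id.
    """
    if not any(hits.values()):
        raise ValueError("no miRNA families with hits")
    count_of = {t.sequence: t.total for t in tags}
    seq_of = dict(mature.records)
    reps: dict[str, tuple[str, str]] = {}
    for fam, fam_hits in hits.items():
        expr: dict[str, int] = {}
        for hit in fam_hits:
            expr[hit.mature_id] = expr.get(hit.mature_id, 0) + count_of.get(hit.tag, 0)
        best = min(expr, key=lambda mid: (-expr[mid], mid))
        reps[fam] = (best, seq_of[best])
    return TemporaryMirnaDB(reps)


def quantify_mirnas(tags: list[CountedTag],
                    db: TemporaryMirnaDB) -> dict[str, tuple[int, int]]:
    """Sum tag counts per representative (exact substring, 0 mismatches).

    A tag matching several representatives is assigned once, to the one
    with the longest matched span (always the full tag here), ties going
    to the lexicographically smallest representative id.
    """
    counts = {mid: [0, 0] for mid, _ in db.representatives.values()}
    reps = sorted(db.representatives.values())  # (mid, seq) sorted by id
    for tag in tags:
        matches = [(len(tag.sequence), mid) for mid, seq in reps if tag.sequence in seq]
        if not matches:
            continue
        _, mid = min(matches, key=lambda m: (-m[0], m[1]))
        counts[mid][0] += tag.count_na
        counts[mid][1] += tag.count_da
    return {mid: (x, y) for mid, (x, y) in counts.items()}


@dataclass
class AnnotationTable:
    """Exclusive, exhaustive per-tag categories with per-library tallies."""
    category_of: dict[str, str]                  # tag sequence -> category
    ref_of: dict[str, str]                       # tag sequence -> reference id
    unique: dict[str, tuple[int, int]]           # category -> (NA unique, DA unique)
    reads: dict[str, tuple[int, int]]            # category -> (NA reads, DA reads)
    totals_unique: tuple[int, int]
    totals_reads: tuple[int, int]


def annotate_tags(tags: list[CountedTag],
                  refsets: dict[str, ReferenceSet],
                  mature: ReferenceSet,
                  precursor: ReferenceSet | None = None,
                  offset_tol: int = 2) -> tuple[AnnotationTable,
                                                dict[str, list[MirnaHit]]]:
    """Full classification: contaminants, then known miRNAs, rest unannotated."""
    contaminant = classify_ncrna(tags, refsets)
    remaining = [t for t in tags if t.sequence not in contaminant]
    hits = match_known_mirnas(remaining, mature, precursor, offset_tol)
    mirna_tags = {h.tag for fam_hits in hits.values() for h in fam_hits}

    category_of: dict[str, str] = {}
    ref_of: dict[str, str] = {}
    for seq, (cls, rid) in contaminant.items():
        category_of[seq] = cls
        ref_of[seq] = rid
    for fam_hits in hits.values():
        for h in fam_hits:
            category_of.setdefault(h.tag, "miRNA")
            ref_of.setdefault(h.tag, h.mature_id)
    for tag in tags:
        category_of.setdefault(tag.sequence, "unannotated")

    unique = {c: [0, 0] for c in CATEGORIES}
    reads = {c: [0, 0] for c in CATEGORIES}
    tot_u, tot_r = [0, 0], [0, 0]
    for tag in tags:
        cat = category_of[tag.sequence]
        for lib, n in ((0, tag.count_na), (1, tag.count_da)):
            if n > 0:
                unique[cat][lib] += 1
                reads[cat][lib] += n
                tot_u[lib] += 1
                tot_r[lib] += n
    table = AnnotationTable(
        category_of=category_of,
        ref_of=ref_of,
        unique={c: tuple(v) for c, v in unique.items()},
        reads={c: tuple(v) for c, v in reads.items()},
        totals_unique=tuple(tot_u),
        totals_reads=tuple(tot_r),
    )
    return table, hits


def percentage(part: int, whole: int) -> float:
    """Category share as a percentage rounded to 2 decimals (0 if whole is 0)."""
    if whole == 0:
        return 0.0
    return round(100.0 * part / whole, 2)


def mapping_stats(table: AnnotationTable) -> dict[str, dict[str, float | int]]:
    """Summary rows mirroring a mapping-statistics table.

    For each category: unique tag counts, read counts and their
    percentages of the library totals, per library.
    """
    out: dict[str, dict[str, float | int]] = {}
    for cat in CATEGORIES:
        u_na, u_da = table.unique[cat]
        r_na, r_da = table.reads[cat]
        out[cat] = {
            "unique_na": u_na,
            "unique_da": u_da,
            "unique_pct_na": percentage(u_na, table.totals_unique[0]),
            "unique_pct_da": percentage(u_da, table.totals_unique[1]),
            "reads_na": r_na,
            "reads_da": r_da,
            "reads_pct_na": percentage(r_na, table.totals_reads[0]),
            "reads_pct_da": percentage(r_da, table.totals_reads[1]),
        }
    return out


def read_family_map(path: str) -> dict[str, str]:
    fam: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("mature_id\t"):
                continue
            mid, f = line.split("\t")[:2]
            fam[mid] = f
    return fam
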