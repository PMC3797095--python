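"""Seed-based miRNA target site prediction on 3'UTRs.

The seed is miRNA positions 2-8 (5' end). An 8-nt UTR window (read
5'->3') is classified by perfect complementarity to the seed:

    8mer     window[1..7] == revcomp(miRNA 2-8) and window[8] == 'A'
    7mer-m8  window[1..7] == revcomp(miRNA 2-8)
    7mer-1a  window[2..7] == revcomp(miRNA 2-7) and window[8] == 'A'

with precedence 8mer > 7mer-m8 > 7mer-1a; the position-8 'A' is required
as a literal A in the UTR. No context scoring or conservation filters.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io import normalize_seq, reverse_complement

SITE_TYPES = ("8mer", "7mer-m8", "7mer-1a")


def seed_of(mirna_sequence: str) -> str:
    """Positions 2-8 (1-based) of a mature miRNA; error if shorter than 8 nt."""
    seq = normalize_seq(mirna_sequence)
    if len(seq) < 8:
        raise ValueError(f"mature miRNA must be >= 8 nt, got {len(seq)}")
    return seq[1:8]


@dataclass(frozen=True)
class SeedMatch:
    mirna_id: str
    utr_id: str
    start: int        # 1-based inclusive on the UTR
    end: int
    site_type: str


def classify_site(mirna_sequence: str, window: str) -> str | None:
    """Classify one 8-nt UTR window against a miRNA seed (or None)."""
    w = normalize_seq(window)
    if len(w) != 8:
        raise ValueError("window must be 8 nt")
    seed7 = seed_of(mirna_sequence)
    rc7 = reverse_complement(seed7)          # complements positions 2-8
    rc6 = reverse_complement(seed7[:6])      # complements positions 2-7
    if w[:7] == rc7:
        return "8mer" if w[7] == "A" else "7mer-m8"
    if w[1:7] == rc6 and w[7] == "A":
        return "7mer-1a"
    return None


def _site_coords(window_start: int, site_type: str) -> tuple[int, int]:
    """1-based inclusive site coordinates from the window's 1-based start."""
    if site_type == "8mer":
        return window_start, window_start + 7
    if site_type == "7mer-m8":
        return window_start, window_start + 6
    return window_start + 1, window_start + 8   # 7mer-1a


def scan_utr(mirnas: list[tuple[str, str]],
             utrs: list[tuple[str, str]]) -> list[SeedMatch]:
    """All seed sites for every (miRNA, UTR) pair.

    Every 8-nt window is tested independently (overlapping sites are all
    reported, each at its strongest class). Output sorted by
    (utr id, start, mirna id).
    """
    matches: list[SeedMatch] = []
    prepared = []
    for mid, mseq in mirnas:
        seed7 = seed_of(mseq)
        rc7 = reverse_complement(seed7)
        rc6 = reverse_complement(seed7[:6])
        prepared.append((mid, rc7, rc6))
    for uid, useq in utrs:
        useq = normalize_seq(useq)
        for s in range(len(useq) - 7):
            w = useq[s:s + 8]
            for mid, rc7, rc6 in prepared:
                if w[:7] == rc7:
                    st = "8mer" if w[7] == "A" else "7mer-m8"
                elif w[1:7] == rc6 and w[7] == "A":
                    st = "7mer-1a"
                else:
                    continue
                start, end = _site_coords(s + 1, st)
                matches.append(SeedMatch(mid, uid, start, end, st))
    matches.sort(key=lambda m: (m.utr_id, m.start, m.mirna_id))
    return matches


def target_genes(matches: list[SeedMatch]) -> dict[str, set[str]]:
    """Predicted target UTR/gene ids per miRNA (>= 1 site of any class)."""
    out: dict[str, set[str]] = {}
    for m in matches:
        out.setdefault(m.mirna_id, set()).add(m.utr_id)
    return out


def write_sites_tsv(path: str, matches: list[SeedMatch]) -> None:
    with open(path, "w") as fh:
        fh.write("mirna\tutr\tstart\tend\ttype\n")
        for m in matches:
            fh.write(f"{m.mirna_id}\t{m.utr_id}\t{m.start}\t{m.end}\t{m.site_type}\n")
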