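"""Synthetic two-library small-RNA datasets with ground truth.

Generates everything the pipeline consumes — reference sets, two FASTQ
libraries, UTRs, a GO map — with planted structure (a dominant miRNA
family, per-family fold changes, genomic hairpin precursors, seed sites,
one enriched GO term) and truth tables recording every planted item.
All randomness flows from a single seeded generator, so a fixed seed
gives byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .io import reverse_complement, write_fasta, write_fastq
from .novel import EnergyModel, fold_hairpin
from .targets import seed_of, scan_utr

_BASES = np.array(list("ACGT"))

#: insert length model: mode 22, support 18-30
_LEN_VALUES = np.arange(18, 31)
_LEN_WEIGHTS = np.array([1, 2, 4, 10, 30, 10, 4, 2, 1, 1, 1, 1, 1], dtype=float)
_LEN_WEIGHTS /= _LEN_WEIGHTS.sum()


@dataclass
class SimulationConfig:
    seed: int = 0
    # miRNA complement
    n_families: int = 30
    members_per_family: int = 2
    dominant_factor: float = 50.0
    abundance_mu: float = 4.0          # ln-scale log-normal parameters
    abundance_sigma: float = 1.2
    planted_fcs: list = field(
        default_factory=lambda: [0.0, 1.0, -1.0, 1.5, -1.5, 2.0, -2.0])
    # libraries
    library_size: int = 1_000_000
    read_length: int = 50
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    frac_rrna: float = 0.05
    frac_trna: float = 0.02
    frac_snrna: float = 0.005
    frac_snorna: float = 0.005
    frac_polya: float = 0.01
    frac_adapter5: float = 0.005
    frac_low_quality: float = 0.005
    # novel hairpins
    n_novel_hairpins: int = 5
    novel_read_mean: float = 40.0
    n_decoy_contigs: int = 3
    contig_length: int = 300
    # targets / GO
    n_utrs: int = 30
    utr_length: int = 200
    n_target_mirnas: int = 3
    sites_per_class: int = 3
    n_genes: int = 400
    n_go_terms: int = 30
    planted_term_rate: float = 0.8
    planted_term_factor: float = 5.0

    def __post_init__(self) -> None:
        fracs = (self.frac_rrna + self.frac_trna + self.frac_snrna
                 + self.frac_snorna + self.frac_polya + self.frac_adapter5
                 + self.frac_low_quality)
        if fracs > 1.0:
            raise ValueError("contamination fractions must sum to <= 1")

    @property
    def mirna_fraction(self) -> float:
        return 1.0 - (self.frac_rrna + self.frac_trna + self.frac_snrna
                      + self.frac_snorna + self.frac_polya
                      + self.frac_adapter5 + self.frac_low_quality)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class References:
    mature: list[tuple[str, str]]
    precursor: list[tuple[str, str]]
    family_of: dict[str, str]
    rrna: list[tuple[str, str]]
    trna: list[tuple[str, str]]
    snrna: list[tuple[str, str]]
    snorna: list[tuple[str, str]]
    genome: list[tuple[str, str]]
    utrs: list[tuple[str, str]]
    go_map: list[tuple[str, str]]      # (gene, term)


@dataclass
class Truth:
    mirna_table: "np.recarray | list"  # list of dicts: id, family, fc, lam_na, lam_da
    novel_loci: list[dict]
    seed_sites: list[dict]
    planted_go_term: str
    target_genes: list[str]
    category_reads: dict[str, dict[str, int]] | None = None
    counts: dict[str, tuple[int, int]] | None = None


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _clean_rand_seq(rng: np.random.Generator, length: int,
                    forbidden: list[str]) -> str:
    """Random sequence avoiding forbidden substrings (adapter seeds)."""
    for _ in range(200):
        s = _rand_seq(rng, length)
        if not any(f in s for f in forbidden):
            return s
    raise RuntimeError("could not generate sequence avoiding forbidden motifs")


def _hairpin_precursor(mature: str, loop: str) -> str:
    return mature + loop + reverse_complement(mature)


def gen_references(config: SimulationConfig,
                   rng: np.random.Generator | None = None) -> tuple[References, Truth]:
    """Generate all reference sets plus the truth tables for planted items."""
    rng = rng or np.random.default_rng(config.seed)
    seeds = [config.adapter3[:8], config.adapter5[:8]]
    model = EnergyModel.default()

    # known miRNA families: each member gets its own mature + hairpin precursor
    mature: list[tuple[str, str]] = []
    precursor: list[tuple[str, str]] = []
    family_of: dict[str, str] = {}
    fcs = config.planted_fcs
    mirna_rows: list[dict] = []
    for fam_idx in range(config.n_families):
        fam = f"fam{fam_idx:03d}"
        fc = 0.0 if fam_idx == 0 else fcs[fam_idx % len(fcs)]
        for m_idx in range(config.members_per_family):
            # the dominant family stays at 22 nt so it anchors the length mode
            if fam_idx == 0:
                length = 22
            else:
                length = int(rng.choice([21, 22, 23], p=[0.2, 0.6, 0.2]))
            mid = f"sim-miR-{fam_idx:03d}{chr(ord('a') + m_idx)}"
            mseq = _clean_rand_seq(rng, length, seeds)
            loop = _clean_rand_seq(rng, 8, seeds)
            mature.append((mid, mseq))
            precursor.append((f"{mid}-pre", _hairpin_precursor(mseq, loop)))
            family_of[mid] = fam
            mirna_rows.append({"id": mid, "family": fam, "fc": fc})

    # contaminant sets
    def _refset(prefix: str, n: int, length: int) -> list[tuple[str, str]]:
        return [(f"{prefix}{i + 1}", _clean_rand_seq(rng, length, seeds))
                for i in range(n)]

    rrna = _refset("rRNA_", 2, 500)
    trna = _refset("tRNA_", 5, 75)
    snrna = _refset("snRNA_", 3, 150)
    snorna = _refset("snoRNA_", 3, 120)

    # genome contigs with planted hairpin precursors
    genome: list[tuple[str, str]] = []
    novel_loci: list[dict] = []
    for h in range(config.n_novel_hairpins):
        for _ in range(100):
            nm = _clean_rand_seq(rng, 22, seeds)
            loop = _clean_rand_seq(rng, 8, seeds)
            pre = _hairpin_precursor(nm, loop)
            _, mfe = fold_hairpin(pre, model)
            if mfe <= -25.0:
                break
        else:
            raise RuntimeError("failed to design a stable hairpin")
        contig_id = f"contig{h + 1}"
        offset = int(rng.integers(60, config.contig_length - len(pre) - 60))
        left = _clean_rand_seq(rng, offset, seeds)
        right = _clean_rand_seq(rng, config.contig_length - offset - len(pre), seeds)
        strand = "+" if rng.random() < 0.5 else "-"
        planted = pre if strand == "+" else reverse_complement(pre)
        genome.append((contig_id, left + planted + right))
        novel_loci.append({
            "tag": nm, "contig": contig_id, "strand": strand,
            "pre_start": offset + 1, "pre_end": offset + len(pre),
            "designed_mfe": float(mfe),
        })
    for d in range(config.n_decoy_contigs):
        genome.append((f"decoy{d + 1}", _clean_rand_seq(rng, config.contig_length, seeds)))

    # UTRs with planted seed sites for the first n_target_mirnas families
    target_mirnas = [mature[i * config.members_per_family]
                     for i in range(1, config.n_target_mirnas + 1)]
    utrs, seed_sites = _gen_utrs(config, rng, target_mirnas)

    # GO map with one planted enriched term among target genes
    site_genes = sorted({s["utr"] for s in seed_sites})
    genes = [f"g{i + 1:04d}" for i in range(config.n_genes)]
    # UTR ids double as gene ids; ensure they are in the universe
    genes = sorted(set(genes) | {u for u, _ in utrs})
    planted_term = "GO:PLANTED"
    terms = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    go_map: list[tuple[str, str]] = []
    base_rate = config.planted_term_rate / config.planted_term_factor
    for gene in genes:
        rate = config.planted_term_rate if gene in site_genes else base_rate
        if rng.random() < rate:
            go_map.append((gene, planted_term))
        for term in terms:
            if rng.random() < 0.08:
                go_map.append((gene, term))

    refs = References(mature, precursor, family_of, rrna, trna, snrna, snorna,
                      genome, utrs, go_map)
    truth = Truth(mirna_table=mirna_rows, novel_loci=novel_loci,
                  seed_sites=seed_sites, planted_go_term=planted_term,
                  target_genes=site_genes)
    return refs, truth


def _plant_site_window(rng: np.random.Generator, mirna_seq: str,
                       site_type: str) -> str:
    """8-nt UTR window realizing exactly the requested site class."""
    seed7 = seed_of(mirna_seq)
    rc7 = reverse_complement(seed7)
    rc6 = reverse_complement(seed7[:6])
    if site_type == "8mer":
        return rc7 + "A"
    if site_type == "7mer-m8":
        return rc7 + str(rng.choice(["C", "G", "T"]))
    # 7mer-1a: first base must break the position-8 pairing
    choices = [b for b in "ACGT" if b != rc7[0]]
    return str(rng.choice(choices)) + rc6 + "A"


def _gen_utrs(config: SimulationConfig, rng: np.random.Generator,
              target_mirnas: list[tuple[str, str]]) -> tuple[list[tuple[str, str]],
                                                             list[dict]]:
    """UTRs containing exactly the planted sites for the target miRNAs."""
    from .targets import SITE_TYPES

    n_slots = config.utr_length // 20
    if n_slots < 1:
        raise ValueError("UTR too short to place seed sites")
    # schedule: (utr_index, mirna, site_type) round-robin over UTRs
    schedule: dict[int, list[tuple[str, str, str]]] = {i: [] for i in range(config.n_utrs)}
    u = 0
    for mid, mseq in target_mirnas:
        for st in SITE_TYPES:
            for _ in range(config.sites_per_class):
                schedule[u % config.n_utrs].append((mid, mseq, st))
                u += 1

    utrs: list[tuple[str, str]] = []
    truth_sites: list[dict] = []
    for i in range(config.n_utrs):
        uid = f"utr{i + 1:04d}"
        plan = schedule[i]
        if len(plan) > n_slots:
            raise ValueError("UTR too short for the requested number of sites")
        for _ in range(100):
            seq = _rand_seq(rng, config.utr_length)
            placed: list[dict] = []
            # non-overlapping 20-nt slots, window planted at slot start + 6
            slots = rng.permutation(n_slots)[:len(plan)]
            chars = list(seq)
            for (mid, mseq, st), slot in zip(plan, slots):
                w = _plant_site_window(rng, mseq, st)
                start0 = int(slot) * 20 + 6
                chars[start0:start0 + 8] = list(w)
                if st == "8mer":
                    s, e = start0 + 1, start0 + 8
                elif st == "7mer-m8":
                    s, e = start0 + 1, start0 + 7
                else:
                    s, e = start0 + 2, start0 + 9
                placed.append({"utr": uid, "mirna": mid, "start": s, "end": e,
                               "type": st})
            candidate = "".join(chars)
            found = scan_utr(target_mirnas, [(uid, candidate)])
            want = sorted((p["mirna"], p["start"], p["end"], p["type"])
                          for p in placed)
            got = sorted((m.mirna_id, m.start, m.end, m.site_type) for m in found)
            if want == got:
                utrs.append((uid, candidate))
                truth_sites.extend(placed)
                break
        else:
            raise RuntimeError(f"failed to build UTR {uid} with exact planted sites")
    return utrs, truth_sites


def gen_libraries(config: SimulationConfig, refs: References, truth: Truth,
                  rng: np.random.Generator | None = None
                  ) -> tuple[list[tuple[str, str, str]], list[tuple[str, str, str]]]:
    """Draw Poisson read counts and emit two FASTQ-ready read lists.

    Returns (reads_na, reads_da) as (id, sequence, quality) triples and
    fills ``truth.counts`` (realized clean counts per mature id) and
    ``truth.category_reads`` (realized clean reads per category/library).
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    lam_total = config.library_size

    # per-mature expected counts
    abundances = {}
    for row in truth.mirna_table:
        a = float(rng.lognormal(config.abundance_mu, config.abundance_sigma))
        if row["family"] == "fam000":
            a *= config.dominant_factor
        abundances[row["id"]] = a
    scale = config.mirna_fraction * lam_total / sum(abundances.values())
    for row in truth.mirna_table:
        a = abundances[row["id"]] * scale
        row["lam_na"] = a * 2.0 ** (-row["fc"] / 2.0)
        row["lam_da"] = a * 2.0 ** (row["fc"] / 2.0)

    # expected clean-library totals and the RPM-scale fold change each
    # miRNA will show after normalization (library-composition shift)
    contaminant_frac = (config.frac_rrna + config.frac_trna
                        + config.frac_snrna + config.frac_snorna)
    base = contaminant_frac * lam_total + len(truth.novel_loci) * config.novel_read_mean
    exp_n1 = base + sum(r["lam_na"] for r in truth.mirna_table)
    exp_n2 = base + sum(r["lam_da"] for r in truth.mirna_table)
    for row in truth.mirna_table:
        row["fc_expected"] = float(
            np.log2((row["lam_da"] / exp_n2) / (row["lam_na"] / exp_n1)))

    seq_of = dict(refs.mature)
    counts: dict[str, tuple[int, int]] = {}
    category_reads = {"miRNA": {"NA": 0, "DA": 0}, "rRNA": {"NA": 0, "DA": 0},
                      "tRNA": {"NA": 0, "DA": 0}, "snRNA": {"NA": 0, "DA": 0},
                      "snoRNA": {"NA": 0, "DA": 0}}

    hi_q = "I" * config.read_length

    def make_read(insert: str) -> str:
        return (insert + config.adapter3 + "A" * config.read_length)[:config.read_length]

    reads = {"NA": [], "DA": []}

    def emit(lib: str, insert: str, qual: str | None = None) -> None:
        i = len(reads[lib])
        reads[lib].append((f"{lib}_{i + 1}", make_read(insert), qual or hi_q))

    # known miRNAs
    for row in truth.mirna_table:
        c_na = int(rng.poisson(row["lam_na"]))
        c_da = int(rng.poisson(row["lam_da"]))
        counts[row["id"]] = (c_na, c_da)
        mseq = seq_of[row["id"]]
        for _ in range(c_na):
            emit("NA", mseq)
        for _ in range(c_da):
            emit("DA", mseq)
        category_reads["miRNA"]["NA"] += c_na
        category_reads["miRNA"]["DA"] += c_da

    # novel hairpin matures (unannotated, genome-anchored)
    for locus in truth.novel_loci:
        c_na = int(rng.poisson(config.novel_read_mean))
        c_da = int(rng.poisson(config.novel_read_mean))
        locus["count_na"], locus["count_da"] = c_na, c_da
        for _ in range(c_na):
            emit("NA", locus["tag"])
        for _ in range(c_da):
            emit("DA", locus["tag"])

    # contaminant fragments
    contaminants = (("rRNA", refs.rrna, config.frac_rrna),
                    ("tRNA", refs.trna, config.frac_trna),
                    ("snRNA", refs.snrna, config.frac_snrna),
                    ("snoRNA", refs.snorna, config.frac_snorna))
    for lib in ("NA", "DA"):
        for cls, records, frac in contaminants:
            n = int(rng.poisson(frac * lam_total))
            for _ in range(n):
                rid = int(rng.integers(0, len(records)))
                ref_seq = records[rid][1]
                length = int(rng.choice(_LEN_VALUES, p=_LEN_WEIGHTS))
                start = int(rng.integers(0, len(ref_seq) - length + 1))
                emit(lib, ref_seq[start:start + length])
            category_reads[cls][lib] += n
        # junk: poly(A) artifacts, 5' adapter pollution, low-quality reads
        for _ in range(int(rng.poisson(config.frac_polya * lam_total))):
            emit(lib, "A" * int(rng.integers(20, 28)))
        for _ in range(int(rng.poisson(config.frac_adapter5 * lam_total))):
            tail = _rand_seq(rng, config.read_length)
            seq = (config.adapter5[:8] + tail)[:config.read_length]
            i = len(reads[lib])
            reads[lib].append((f"{lib}_{i + 1}", seq, hi_q))
        for _ in range(int(rng.poisson(config.frac_low_quality * lam_total))):
            insert = _rand_seq(rng, 22)
            qual = list(hi_q)
            n_bad = max(1, int(0.3 * config.read_length))
            for pos in rng.choice(config.read_length, size=n_bad, replace=False):
                qual[pos] = "#"
            emit(lib, insert, "".join(qual))

    truth.counts = counts
    truth.category_reads = category_reads
    return reads["NA"], reads["DA"]


def write_all(config: SimulationConfig, out_dir: str) -> tuple[References, Truth]:
    """Generate the full dataset and write it under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    refs, truth = gen_references(config, rng)
    reads_na, reads_da = gen_libraries(config, refs, truth, rng)

    j = os.path.join
    write_fastq(j(out_dir, "reads_na.fastq"), reads_na)
    write_fastq(j(out_dir, "reads_da.fastq"), reads_da)
    write_fasta(j(out_dir, "mirna_mature.fasta"), refs.mature)
    write_fasta(j(out_dir, "mirna_precursor.fasta"), refs.precursor)
    write_fasta(j(out_dir, "rrna.fasta"), refs.rrna)
    write_fasta(j(out_dir, "trna.fasta"), refs.trna)
    write_fasta(j(out_dir, "snrna.fasta"), refs.snrna)
    write_fasta(j(out_dir, "snorna.fasta"), refs.snorna)
    write_fasta(j(out_dir, "genome.fasta"), refs.genome)
    write_fasta(j(out_dir, "utrs.fasta"), refs.utrs)
    with open(j(out_dir, "family_map.tsv"), "w") as fh:
        fh.write("mature_id\tfamily\n")
        for mid, fam in sorted(refs.family_of.items()):
            fh.write(f"{mid}\t{fam}\n")
    with open(j(out_dir, "go_map.tsv"), "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for gene, term in refs.go_map:
            fh.write(f"{gene}\t{term}\n")
    with open(j(out_dir, "truth_mirnas.tsv"), "w") as fh:
        fh.write("id\tfamily\tfc\tlam_na\tlam_da\tcount_na\tcount_da\n")
        for row in truth.mirna_table:
            c_na, c_da = truth.counts[row["id"]]
            fh.write(f"{row['id']}\t{row['family']}\t{row['fc']}\t"
                     f"{row['lam_na']:.3f}\t{row['lam_da']:.3f}\t{c_na}\t{c_da}\n")
    with open(j(out_dir, "truth_novel.tsv"), "w") as fh:
        fh.write("tag\tcontig\tstrand\tpre_start\tpre_end\tdesigned_mfe\t"
                 "count_na\tcount_da\n")
        for locus in truth.novel_loci:
            fh.write(f"{locus['tag']}\t{locus['contig']}\t{locus['strand']}\t"
                     f"{locus['pre_start']}\t{locus['pre_end']}\t"
                     f"{locus['designed_mfe']:.2f}\t{locus['count_na']}\t"
                     f"{locus['count_da']}\n")
    with open(j(out_dir, "truth_sites.tsv"), "w") as fh:
        fh.write("utr\tmirna\tstart\tend\ttype\n")
        for s in truth.seed_sites:
            fh.write(f"{s['utr']}\t{s['mirna']}\t{s['start']}\t{s['end']}\t{s['type']}\n")
    with open(j(out_dir, "truth_go.tsv"), "w") as fh:
        fh.write("planted_term\n")
        fh.write(truth.planted_go_term + "\n")
    config.to_yaml(j(out_dir, "sim_config.yaml"))
    return refs, truth
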