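# srnakit

Two-library small RNA-seq analysis toolkit: read cleaning, miRNA
annotation and quantification, novel-miRNA hairpin discovery,
digital differential expression, seed-based target prediction, GO
over-representation and qPCR relative quantification — plus a synthetic
data generator so the whole pipeline is testable without downloads.

## Modules

| module | what it does |
| --- | --- |
| `srnakit.preprocess` | FASTQ/FASTA cleaning cascade (quality, adapters, poly(A), 18–30 nt window), tag collapsing, length distributions |
| `srnakit.annotate` | contaminant classification (rRNA > tRNA > snRNA > snoRNA, exact substring), known-miRNA matching, per-family representative ("temporary database"), expression quantification, mapping statistics |
| `srnakit.novel` | genomic anchoring of unannotated tags, exact single-stem-loop folding DP with a configurable energy model, hairpin candidate calling (arm placement, MFE ≤ −18 kcal/mol, read support) |
| `srnakit.diffexpr` | RPM normalization, log2 fold change with 0.01 zero-substitution, exact conditional two-library count test, Benjamini–Hochberg FDR, threshold calling, dual-platform intersection |
| `srnakit.targets` | seed (positions 2–8) site scanning of 3'UTRs: 8mer / 7mer-m8 / 7mer-1a |
| `srnakit.enrichment` | one-sided hypergeometric GO over-representation with BH control |
| `srnakit.qpcr` | 2^−ΔΔCt relative expression with reference-gene normalization and one-way ANOVA |
| `srnakit.simulate` | seeded synthetic libraries/references with planted fold changes, hairpins, seed sites and an enriched GO term, plus truth tables |
| `srnakit.datasets` | bundled published dual-platform differential table and mapping totals used as regression fixtures |
| `srnakit.cli` | `srnakit` command with one subcommand per stage and a pipeline runner |

## CLI

```bash
# generate a synthetic dataset with ground truth
srnakit simulate --seed 7 --library-size 100000 --out-dir data/

# individual stages
srnakit clean --na data/reads_na.fastq --da data/reads_da.fastq \
    --adapter3 TGGAATTCTCGGGTGCCAAGG --min-len 18 --max-len 30 --out-dir out/
srnakit annotate --tags out/tags.tsv --mirna-mature data/mirna_mature.fasta \
    --mirna-precursor data/mirna_precursor.fasta --family-map data/family_map.tsv \
    --rrna data/rrna.fasta --trna data/trna.fasta \
    --snrna data/snrna.fasta --snorna data/snorna.fasta --out out/
srnakit novel --tags out/tags.tsv --genome data/genome.fasta \
    --min-reads 5 --mfe-max -18 --out out/novel.tsv
srnakit diffexp --counts out/mirna_counts.tsv --n1 10876248 --n2 11194928 \
    --rpm-min 10 --fc-min 1 --fdr-max 0.01 --out out/diffexpr.tsv
srnakit targets --mirnas data/mirna_mature.fasta --utrs data/utrs.fasta \
    --out out/sites.tsv
srnakit enrich --targets targets.txt --go-map data/go_map.tsv \
    --fdr 0.05 --out out/enrichment.tsv
srnakit qpcr --ct ct.tsv --calibrator NA --out out/qpcr.tsv

# or everything at once from a YAML config (paths + thresholds)
srnakit all --config pipeline.yaml
```

All intermediate results are plain TSV/FASTA/JSON so stages can be
inspected and resumed individually.

## Notes on conventions

- U and T are equivalent everywhere; sequences are normalized to DNA
  internally and FASTA writers can re-emit RNA.
- The two-library count test reports a two-sided P-value: twice the
  inclusive lower tail of the count on the side with the smaller
  normalized rate, conditioning on the other count (clamped to (0, 1]).
  This is the convention that reproduces the bundled table's printed
  P-values.
- The folding energy model (`srnakit/data/energy.yaml`) is a small
  additive stack/loop table chosen for exactness and testability, not a
  full thermodynamic parameter set; substitute your own via
  `EnergyModel.from_yaml`.
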