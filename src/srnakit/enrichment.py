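"""GO term over-representation among predicted target genes.

One-sided hypergeometric test per term against a gene background, with
Benjamini-Hochberg control across tested terms. Flat term map — no
ontology-DAG ancestor propagation unless the caller pre-propagates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_fdr


@dataclass
class GoAnnotation:
    gene_terms: dict[str, set[str]]              # gene -> term ids
    term_names: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_tsv(cls, path: str, names_path: str | None = None) -> "GoAnnotation":
        gene_terms: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "gene_id\t")):
                    continue
                gene, term = line.split("\t")[:2]
                gene_terms.setdefault(gene, set()).add(term)
        names: dict[str, str] = {}
        if names_path:
            with open(names_path) as fh:
                for line in fh:
                    line = line.rstrip("\n")
                    if not line or line.startswith(("#", "term_id\t")):
                        continue
                    term, name = line.split("\t")[:2]
                    names[term] = name
        return cls(gene_terms, names)

    def genes_with(self, term: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term in ts}


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): over-representation tail."""
    if not (0 <= k <= n <= N) or not (0 <= K <= N) or k > K:
        raise ValueError(f"impossible configuration k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, N, K, n)))


def enrich(targets: set[str],
           background: set[str],
           annotation: GoAnnotation,
           fdr_max: float = 0.05,
           min_background_genes: int = 2) -> pd.DataFrame:
    """Over-represented terms among ``targets`` at q < ``fdr_max``.

    One test per term annotated to at least ``min_background_genes``
    background genes; BH across tested terms; sorted by (q, p, term).
    """
    if not targets <= background:
        raise ValueError("target set must be a subset of the background")
    if not targets:
        return _empty_results()
    N = len(background)
    n = len(targets)
    term_bg: dict[str, int] = {}
    term_fg: dict[str, int] = {}
    for gene, terms in annotation.gene_terms.items():
        if gene not in background:
            continue
        in_fg = gene in targets
        for t in terms:
            term_bg[t] = term_bg.get(t, 0) + 1
            if in_fg:
                term_fg[t] = term_fg.get(t, 0) + 1
    rows = []
    for term, K in sorted(term_bg.items()):
        if K < min_background_genes:
            continue
        k = term_fg.get(term, 0)
        rows.append({"term": term, "name": annotation.term_names.get(term, ""),
                     "k": k, "n": n, "K": K, "N": N,
                     "p": hypergeom_p(k, n, K, N)})
    if not rows:
        return _empty_results()
    df = pd.DataFrame(rows)
    df["q"] = bh_fdr(df["p"].to_numpy())
    df = df[df["q"] < fdr_max]
    return df.sort_values(["q", "p", "term"]).reset_index(drop=True)


def _empty_results() -> pd.DataFrame:
    return pd.DataFrame(columns=["term", "name", "k", "n", "K", "N", "p", "q"])
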