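"""Two-library digital differential expression.

Counts from a pair of pooled sequencing libraries (totals n1, n2) are
RPM-normalized, given a log2 fold change (zero RPM substituted by 0.01),
and tested with the exact conditional count test: given a tag with x
reads out of n1 and y out of n2, the distribution of y' conditional on x
under equal underlying rates is

    p(y' | x) = r^y' * (x + y')! / ( x! * y'! * (1 + r)^(x + y' + 1) ),
    r = n2 / n1.

The reported P-value is two-sided: twice the inclusive lower tail of the
count on the side with the smaller normalized rate (conditioning on the
other side's count), clamped to (0, 1]. This convention reproduces the
printed values of the reference digital-expression protocol.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma, log

import numpy as np
import pandas as pd

ZERO_RPM_SUBSTITUTE = 0.01


@dataclass(frozen=True)
class LibraryPair:
    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library totals must be positive")


def rpm(count: float, total: int) -> float:
    """Reads-per-million normalization."""
    if total <= 0:
        raise ValueError("library total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total * 1e6


def log2_fold_change(x: int, y: int, pair: LibraryPair) -> float:
    """log2(RPM_da / RPM_na); a zero RPM is replaced by 0.01 first."""
    if x == 0 and y == 0:
        raise ValueError("fold change undefined for x = y = 0")
    rpm_na = rpm(x, pair.n1) or ZERO_RPM_SUBSTITUTE
    rpm_da = rpm(y, pair.n2) or ZERO_RPM_SUBSTITUTE
    return float(np.log2(rpm_da / rpm_na))


def _lower_tail(c: int, n_other: int, r: float, rel_tol: float = 1e-16) -> float:
    """Sum_{k=0..c} p(k | n_other) with p(k) = r^k (k+n)!/(k! n! (1+r)^(k+n+1)).

    Summed from k = c downward by term-wise recurrence in linear space
    after factoring out the largest term; truncated when a term falls
    below ``rel_tol`` of the partial sum.
    """
    n = n_other
    log_top = c * log(r) + lgamma(c + n + 1) - lgamma(c + 1) - lgamma(n + 1) \
        - (c + n + 1) * log(1.0 + r)
    # terms decrease away from the mode; walk down from k=c
    total = 1.0
    term = 1.0
    k = c
    while k > 0:
        # p(k-1)/p(k) = k (1+r) / (r (k+n))
        term *= k * (1.0 + r) / (r * (k + n))
        total += term
        k -= 1
        if term < rel_tol * total:
            break
    return exp(log_top) * total


def ac_pvalue(x: int, y: int, pair: LibraryPair) -> float:
    """Two-sided exact conditional P-value for counts (x, y).

    Twice the inclusive lower tail of the deficient side's count; by a
    tail identity this equals twice the strict upper tail of the
    enriched side's count. Symmetric: ac_pvalue(x, y, n1, n2) ==
    ac_pvalue(y, x, n2, n1).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    n1, n2 = pair.n1, pair.n2
    # the two directions' tails are exact complements:
    # P(X <= x | y, n1/n2) = 1 - P(Y <= y | x, n2/n1),
    # so only the deficient side's (small) tail is ever summed
    if y / n2 > x / n1:
        t = _lower_tail(x, y, n1 / n2)
    else:
        t = _lower_tail(y, x, n2 / n1)
    p = 2.0 * min(t, 1.0 - t)
    return min(max(p, 5e-324), 1.0)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def score_table(counts: pd.DataFrame, pair: LibraryPair) -> pd.DataFrame:
    """Score an (id, x, y) count table: RPM, fold change, P, q.

    Rows with x = y = 0 are dropped (no evidence either way).
    """
    df = counts.copy()
    df = df[(df["x"] > 0) | (df["y"] > 0)].reset_index(drop=True)
    df["rpm_na"] = [rpm(x, pair.n1) for x in df["x"]]
    df["rpm_da"] = [rpm(y, pair.n2) for y in df["y"]]
    df["fc"] = [log2_fold_change(x, y, pair) for x, y in zip(df["x"], df["y"])]
    df["p"] = [ac_pvalue(x, y, pair) for x, y in zip(df["x"], df["y"])]
    df["q"] = bh_fdr(df["p"].to_numpy())
    return df


def call_differential(scored: pd.DataFrame,
                      rpm_min: float = 10.0,
                      fc_min: float = 1.0,
                      fdr_max: float = 0.01,
                      exclude_rpm_below: float = 1.0,
                      rpm_rule: str = "any") -> pd.DataFrame:
    """Attach up/down/ns/excluded calls under the three-part criterion.

    Rows with RPM below ``exclude_rpm_below`` in BOTH libraries are
    excluded from the analysis. A row is called up when RPM exceeds
    ``rpm_min`` (in at least one library by default), fc >= fc_min and
    q < fdr_max; down symmetrically.
    """
    df = scored.copy()
    if rpm_rule == "any":
        expressed = (df["rpm_na"] > rpm_min) | (df["rpm_da"] > rpm_min)
    elif rpm_rule == "both":
        expressed = (df["rpm_na"] > rpm_min) & (df["rpm_da"] > rpm_min)
    else:
        raise ValueError("rpm_rule must be 'any' or 'both'")
    excluded = (df["rpm_na"] < exclude_rpm_below) & (df["rpm_da"] < exclude_rpm_below)
    sig = expressed & (df["q"] < fdr_max) & ~excluded
    call = np.where(excluded, "excluded",
                    np.where(sig & (df["fc"] >= fc_min), "up",
                             np.where(sig & (df["fc"] <= -fc_min), "down", "ns")))
    df["call"] = call
    return df


def summarize_calls(called: pd.DataFrame) -> dict[str, int]:
    vc = called["call"].value_counts()
    return {k: int(vc.get(k, 0)) for k in ("up", "down", "ns", "excluded")}


def array_significant(array_rows: pd.DataFrame,
                      signal_min: float = 500.0,
                      fc_min: float = 1.0,
                      fdr_max: float = 0.01) -> pd.Series:
    """Microarray significance: signal above threshold in at least one
    condition, |fc| >= fc_min and q < fdr_max (array values are consumed
    pre-normalized)."""
    return ((array_rows[["signal_na", "signal_da"]].max(axis=1) > signal_min)
            & (array_rows["fc"].abs() >= fc_min)
            & (array_rows["q"] < fdr_max))


def intersect_platforms(seq_rows: pd.DataFrame,
                        array_rows: pd.DataFrame,
                        signal_min: float = 500.0,
                        fc_min: float = 1.0,
                        fdr_max: float = 0.01) -> list[str]:
    """Ids significant on both platforms with concordant fold-change sign.

    ``seq_rows`` must carry a 'call' column (up/down from
    :func:`call_differential`); ``array_rows`` columns: id, signal_na,
    signal_da, fc, q. Ids present on only one platform are treated as
    not significant there.
    """
    seq_sig = seq_rows[seq_rows["call"].isin(["up", "down"])]
    seq_dir = dict(zip(seq_sig["id"], np.sign(seq_sig["fc"])))
    if len(array_rows) == 0:
        return []
    arr = array_rows[array_significant(array_rows, signal_min, fc_min, fdr_max)]
    common = []
    for _, row in arr.iterrows():
        d = seq_dir.get(row["id"])
        if d is not None and d == np.sign(row["fc"]):
            common.append(row["id"])
    return sorted(set(common))
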