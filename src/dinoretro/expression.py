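"""Expression-level comparison of retrogenes and ordinary genes.

TPM normalization of per-gene count tables, expression filtering, the
Wilcoxon rank-sum comparison of retrogene vs normal-gene expression, and the
shared-enrichment correlation between two pruned enrichment tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, pearsonr, rankdata

__all__ = [
    "RankSumResult",
    "SharedEnrichment",
    "tpm_normalize",
    "expression_filter",
    "rank_sum_test",
    "compare_enrichment_profiles",
]


def tpm_normalize(counts, lengths) -> np.ndarray:
    """Transcripts-per-million: per-kilobase count rates rescaled to 1e6.

    rate_g = count_g / (length_g / 1000); tpm_g = 1e6 * rate_g / sum(rates).
    Invariant to rescaling all counts by a positive constant; the TPMs of one
    sample sum to 1e6.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must have the same shape")
    if np.any(lengths <= 0):
        raise ValueError("gene lengths must be positive")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    rates = counts / (lengths / 1000.0)
    total = rates.sum()
    if total == 0:
        raise ValueError("all counts are zero; TPM undefined")
    return 1e6 * rates / total


def expression_filter(table: pd.DataFrame, min_tpm: float = 1.0) -> pd.DataFrame:
    """Retain rows with tpm strictly greater than ``min_tpm``."""
    if min_tpm < 0:
        raise ValueError("min_tpm must be >= 0")
    return table[table["tpm"] > min_tpm].copy()


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample, mid-ranks for ties
    pvalue: float
    method: str  # "exact" or "asymptotic"
    n_x: int
    n_y: int


def _exact_ranksum_p(ranks: np.ndarray, n: int, w_obs: float) -> float:
    """Two-sided exact p by enumeration of all n-subsets of the pooled ranks."""
    total = len(ranks)
    mu = n * (total + 1) / 2
    d = abs(w_obs - mu) - 1e-12
    hit = tot = 0
    for comb in itertools.combinations(range(total), n):
        tot += 1
        if abs(ranks[list(comb)].sum() - mu) >= d:
            hit += 1
    return hit / tot


def rank_sum_test(x, y, exact_max: int = 8) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Ties receive mid-ranks.  When both samples have at most ``exact_max``
    observations the null is enumerated exactly over all rank assignments;
    otherwise a normal approximation with tie correction and continuity
    correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    ranks = rankdata(np.concatenate([x, y]))
    w = float(ranks[:n].sum())
    if n <= exact_max and m <= exact_max:
        p = _exact_ranksum_p(ranks, n, w)
        return RankSumResult(w, min(p, 1.0), "exact", n, m)
    total = n + m
    mu = n * (total + 1) / 2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (total * (total - 1))
    var = n * m / 12.0 * (total + 1 - tie_term)
    if var == 0:
        return RankSumResult(w, 1.0, "asymptotic", n, m)
    z = (abs(w - mu) - 0.5) / np.sqrt(var)
    p = 2 * norm.sf(max(z, 0.0))
    return RankSumResult(w, float(min(p, 1.0)), "asymptotic", n, m)


@dataclass(frozen=True)
class SharedEnrichment:
    """Overlap between two pruned enrichment tables."""

    shared_fraction: float
    correlation: Optional[float]  # Pearson on -log10 p_adj; None if < 3 shared
    n_shared: int
    shared_terms: tuple[str, ...]


def compare_enrichment_profiles(
    rows_a: pd.DataFrame, rows_b: pd.DataFrame
) -> SharedEnrichment:
    """Shared-term fraction and enrichment-magnitude correlation.

    Operates on retained rows (tables with a ``retained`` column are
    subset to it).  The shared fraction is relative to the smaller table;
    the correlation is Pearson's r on paired -log10 adjusted p over shared
    terms, undefined (None) with fewer than 3 shared terms.
    """
    def _retained(df: pd.DataFrame) -> pd.DataFrame:
        if "retained" in df.columns:
            return df[df["retained"]]
        return df

    a = _retained(rows_a).set_index("term_id")
    b = _retained(rows_b).set_index("term_id")
    if len(a) == 0 or len(b) == 0:
        return SharedEnrichment(0.0, None, 0, ())
    shared = sorted(set(a.index) & set(b.index))
    frac = len(shared) / min(len(a), len(b))
    corr: Optional[float] = None
    if len(shared) >= 3:
        la = -np.log10(a.loc[shared, "p_adj"].to_numpy(dtype=float))
        lb = -np.log10(b.loc[shared, "p_adj"].to_numpy(dtype=float))
        if np.std(la) > 0 and np.std(lb) > 0:
            corr = float(pearsonr(la, lb)[0])
        else:
            corr = 1.0 if np.allclose(la, lb) else None
    return SharedEnrichment(frac, corr, len(shared), tuple(shared))
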