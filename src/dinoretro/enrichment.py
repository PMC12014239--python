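"""Term over-representation of a retrogene set against its transcriptome.

One-sided Fisher/hypergeometric testing of each annotation term carried by
the foreground (retrogene) set against the background (all annotated genes of
the same transcriptome), Benjamini-Hochberg correction, redundancy pruning by
foreground gene-set overlap, and the rich factor (foreground genes with a
term / background genes with that term) used for dot-plot displays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnnotationTable",
    "EnrichmentRow",
    "fisher_enrich",
    "bh_adjust",
    "enrich_set",
]


@dataclass
class AnnotationTable:
    """gene_id -> set of term_ids, with optional term labels."""

    gene_terms: dict[str, set[str]] = field(default_factory=dict)
    term_labels: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AnnotationTable":
        """Build from a table with columns gene_id, term_id[, label]."""
        tab = cls()
        has_label = "label" in df.columns
        for row in df.itertuples(index=False):
            tab.add(str(row.gene_id), str(row.term_id))
            if has_label and isinstance(row.label, str):
                tab.term_labels[str(row.term_id)] = row.label
        return tab

    @classmethod
    def from_tsv(cls, path) -> "AnnotationTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_frame(df)

    def add(self, gene_id: str, term_id: str) -> None:
        if not gene_id:
            raise ValueError("gene id must be non-empty")
        self.gene_terms.setdefault(gene_id, set()).add(term_id)

    def terms(self) -> set[str]:
        out: set[str] = set()
        for ts in self.gene_terms.values():
            out |= ts
        return out

    def genes_with(self, term_id: str) -> set[str]:
        return {g for g, ts in self.gene_terms.items() if term_id in ts}


@dataclass(frozen=True)
class EnrichmentRow:
    """One term's 2x2 counts and test results.

    k of K foreground genes and n of N background genes carry the term;
    rich_factor = k/n.
    """

    term_id: str
    k: int
    K: int
    n: int
    N: int
    odds_ratio: float
    p: float
    p_adj: float = float("nan")
    rich_factor: float = float("nan")
    retained: bool = False


def fisher_enrich(
    term_id: str,
    foreground: Iterable[str],
    background: Iterable[str],
    annot: AnnotationTable,
) -> EnrichmentRow:
    """One-sided over-representation test for one term.

    p = P(X >= k) for X ~ Hypergeom(N, n, K); the odds ratio comes from the
    2x2 table (k, K-k; n-k, N-n-K+k), infinite when an off-diagonal cell is
    zero.  A term absent from the annotation gives k = n = 0 and p = 1.
    """
    fg = set(foreground)
    bg = set(background)
    if not fg or not bg:
        raise ValueError("foreground and background must be non-empty")
    if not fg <= bg:
        raise ValueError("foreground must be a subset of background")
    with_term = annot.genes_with(term_id)
    K, N = len(fg), len(bg)
    k = len(fg & with_term)
    n = len(bg & with_term)
    p = float(hypergeom.sf(k - 1, N, n, K))
    a, b, c, d = k, K - k, n - k, N - n - K + k
    if b * c == 0:
        odds = math.inf if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    rich = k / n if n > 0 else float("nan")
    return EnrichmentRow(
        term_id=term_id, k=k, K=K, n=n, N=N,
        odds_ratio=odds, p=min(p, 1.0), rich_factor=rich,
    )


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    pvals = list(pvalues)
    if not pvals:
        return []
    if any(not (0 < p <= 1) for p in pvals):
        raise ValueError("p-values must be in (0, 1]")
    return list(multipletests(pvals, method="fdr_bh")[1])


def enrich_set(
    foreground: Iterable[str],
    background: Iterable[str],
    annot: AnnotationTable,
    p_cut: float = 0.01,
    overlap_cut: float = 0.6,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Test every term carried by the foreground; threshold and prune.

    Terms with at least one foreground gene are tested; rows pass the
    threshold when raw p (or adjusted p with ``use_adjusted``) < ``p_cut``.
    Redundant terms are then pruned: processing by ascending p (term id as
    tie-break), a term is dropped when the Jaccard overlap of its foreground
    gene set with an already retained term exceeds ``overlap_cut`` — a
    gene-overlap stand-in for ontology-graph term simplification.

    Returns all tested rows sorted by p with a ``retained`` flag.
    """
    if not (0 < p_cut < 1):
        raise ValueError("p_cut must be in (0, 1)")
    if not (0 < overlap_cut <= 1):
        raise ValueError("overlap_cut must be in (0, 1]")
    fg = sorted(set(foreground))
    if not fg:
        return pd.DataFrame(
            columns=["term_id", "k", "K", "n", "N", "odds_ratio", "p", "p_adj",
                     "rich_factor", "retained"]
        )
    fg_set = set(fg)
    terms = sorted(
        {t for g in fg for t in annot.gene_terms.get(g, ())}
    )
    rows = [fisher_enrich(t, fg, background, annot) for t in terms]
    padj = bh_adjust([r.p for r in rows])

    order = sorted(range(len(rows)), key=lambda i: (rows[i].p, rows[i].term_id))
    kept_sets: list[set[str]] = []
    retained = [False] * len(rows)
    for i in order:
        r = rows[i]
        p_gate = padj[i] if use_adjusted else r.p
        if p_gate >= p_cut:
            continue
        genes = annot.genes_with(r.term_id) & fg_set
        redundant = any(
            len(genes & kept) / len(genes | kept) > overlap_cut
            for kept in kept_sets
            if genes | kept
        )
        if redundant:
            continue
        retained[i] = True
        kept_sets.append(genes)

    df = pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "k": [r.k for r in rows],
            "K": [r.K for r in rows],
            "n": [r.n for r in rows],
            "N": [r.N for r in rows],
            "odds_ratio": [r.odds_ratio for r in rows],
            "p": [r.p for r in rows],
            "p_adj": padj,
            "rich_factor": [r.rich_factor for r in rows],
            "retained": retained,
        }
    )
    return df.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
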