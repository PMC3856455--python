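"""Hypergeometric GO-term over-representation with BH FDR control.

Only genes carrying at least one GO annotation enter the study (n) and
background (N) totals, so every reported p-value is recomputable from
the four printed counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._util import round_half_up


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    k: int  # annotated study genes carrying the term
    n: int  # annotated study genes
    K: int  # annotated background genes carrying the term
    N: int  # annotated background genes
    p_value: float
    fdr_q: float = float("nan")


def hypergeom_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_fdr(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, capped at 1, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def enrich_genes(
    study_genes: list[str],
    background_genes: list[str],
    go_map: dict[str, set[str]] | pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """One-sided over-representation test per GO term.

    ``go_map`` maps gene -> set of GO terms (or a two-column DataFrame
    gene/term). Returns a result table (one row per term with >=1 study
    hit, sorted by q then p) and a metadata dict with the annotated-set
    bookkeeping percentages.
    """
    if isinstance(go_map, pd.DataFrame):
        mapping: dict[str, set[str]] = {}
        for gene, term in go_map.itertuples(index=False):
            mapping.setdefault(str(gene), set()).add(str(term))
        go_map = mapping
    study = set(study_genes)
    background = set(background_genes)
    if not study <= background:
        raise ValueError("study genes must be a subset of the background")
    study_annot = {g for g in study if go_map.get(g)}
    bg_annot = {g for g in background if go_map.get(g)}
    meta = {
        "n_study": len(study),
        "n_study_annotated": len(study_annot),
        "n_background": len(background),
        "n_background_annotated": len(bg_annot),
        "pct_study_annotated": round_half_up(
            100.0 * len(study_annot) / len(study), 2
        )
        if study
        else 0.0,
        "pct_background_annotated": round_half_up(
            100.0 * len(bg_annot) / len(background), 2
        )
        if background
        else 0.0,
        "fdr_method": "benjamini-hochberg",
    }
    if not study_annot:
        warnings.warn("no annotated genes in study set; empty enrichment result")
        return (
            pd.DataFrame(columns=["term", "k", "n", "K", "N", "p_value", "fdr_q"]),
            meta,
        )
    n, N = len(study_annot), len(bg_annot)
    term_background: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in bg_annot:
        for term in go_map[gene]:
            term_background[term] = term_background.get(term, 0) + 1
            if gene in study_annot:
                term_study[term] = term_study.get(term, 0) + 1
    rows = []
    for term, k in term_study.items():
        K = term_background[term]
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p_value": hypergeom_pvalue(k, n, K, N),
            }
        )
    df = pd.DataFrame(rows)
    df["fdr_q"] = bh_fdr(df["p_value"].to_numpy())
    df = df.sort_values(["fdr_q", "p_value", "term"], kind="stable").reset_index(drop=True)
    return df, meta
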