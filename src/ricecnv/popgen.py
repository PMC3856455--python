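"""Population-genetic summaries over the CNVR genotype matrix.

CNV states {normal, loss, gain} are treated as alleles of a triallelic
locus. Gene diversity is Nei's He = 1 - sum(p_i^2) without small-sample
correction. Differentiation is Fst = 1 - Hs/Ht with Hs the unweighted
mean within-subspecies He and Ht the He of the pooled (size-weighted)
frequency vector; both choices are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .cnvr import GenotypeMatrix, NORMAL

CATEGORIES = ("N", "L", "G")

SUBSPECIES = ("indica", "japonica")
GROUPS_BY_SUBSPECIES = {
    "indica": ("indica", "aus"),
    "japonica": ("rayada", "aromatic", "tropical_japonica", "temperate_japonica"),
}


@dataclass(frozen=True)
class PanelMetadata:
    """sample -> (subspecies, group) assignments."""

    table: pd.DataFrame  # index: sample; columns: subspecies, group

    def __post_init__(self) -> None:
        for sample, row in self.table.iterrows():
            if row["subspecies"] not in GROUPS_BY_SUBSPECIES:
                raise ValueError(f"unknown subspecies {row['subspecies']!r} for {sample}")
            if row["group"] not in GROUPS_BY_SUBSPECIES[row["subspecies"]]:
                raise ValueError(
                    f"group {row['group']!r} does not nest in {row['subspecies']!r}"
                )

    def samples_of_subspecies(self, subspecies: str) -> list[str]:
        t = self.table
        return list(t.index[t["subspecies"] == subspecies])

    def samples_of_group(self, group: str) -> list[str]:
        t = self.table
        return list(t.index[t["group"] == group])

    @property
    def groups(self) -> list[str]:
        return sorted(self.table["group"].unique())

    def subspecies_of(self, sample: str) -> str:
        return str(self.table.loc[sample, "subspecies"])


def category_frequencies(column: pd.Series, subset: list[str] | None = None) -> np.ndarray:
    """(p_normal, p_loss, p_gain) over the given samples."""
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("sample subset is empty")
        column = column.loc[subset]
    if len(column) == 0:
        raise ValueError("sample subset is empty")
    counts = np.array([(column == c).sum() for c in CATEGORIES], dtype=float)
    return counts / counts.sum()


def heterozygosity(p: np.ndarray) -> float:
    """Nei gene diversity 1 - sum(p_i^2)."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("frequencies must be non-negative")
    if not np.isclose(p.sum(), 1.0):
        raise ValueError("frequencies must sum to 1")
    return float(1.0 - np.sum(p**2))


def fst(
    freqs: dict[str, np.ndarray],
    sizes: dict[str, int],
    weighted_hs: bool = False,
    ht_from_pool: bool = True,
) -> tuple[float, float, float]:
    """(Hs, Ht, Fst) from per-subpopulation frequency vectors.

    Hs is the (un)weighted mean within-subpopulation He; Ht by default is
    the He of the size-weighted pooled frequencies. Fst = 1 - Hs/Ht, with
    Fst = 0 by convention when Ht = 0 (monomorphic everywhere).
    """
    if len(freqs) < 2:
        raise ValueError("need >= 2 subpopulations")
    names = sorted(freqs)
    hes = np.array([heterozygosity(freqs[g]) for g in names])
    n = np.array([sizes[g] for g in names], dtype=float)
    hs = float(np.average(hes, weights=n)) if weighted_hs else float(hes.mean())
    stacked = np.vstack([freqs[g] for g in names])
    pooled = np.average(stacked, axis=0, weights=n)
    ht = heterozygosity(pooled) if ht_from_pool else float(
        np.mean([heterozygosity(f) for f in stacked])
    )
    # with unweighted Hs and unequal sizes the raw ratio can dip slightly
    # below zero; clamp to the definitional [0, 1] range
    fst_val = 0.0 if ht == 0 else max(1.0 - hs / ht, 0.0)
    return hs, ht, fst_val


def diversity_table(matrix: GenotypeMatrix, metadata: PanelMetadata) -> pd.DataFrame:
    """Per-CNVR frequencies, He per subspecies, Hs, Ht and Fst.

    Complex CNVRs are excluded; monomorphic columns get He = Fst = 0.
    """
    rows = []
    subs = {s: metadata.samples_of_subspecies(s) for s in SUBSPECIES}
    sizes = {s: len(v) for s, v in subs.items()}
    for cid in matrix.analysis_columns():
        col = matrix.states[cid]
        freqs = {s: category_frequencies(col, subs[s]) for s in SUBSPECIES}
        hs, ht, f_val = fst(freqs, sizes)
        row = {"cnvr": cid, "Hs": hs, "Ht": ht, "Fst": f_val}
        for s in SUBSPECIES:
            row[f"He_{s}"] = heterozygosity(freqs[s])
            for cat, p in zip(CATEGORIES, freqs[s]):
                row[f"p{cat}_{s}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def subspecies_specific(matrix: GenotypeMatrix, metadata: PanelMetadata) -> pd.DataFrame:
    """Classify each CNVR as indica-only / japonica-only / shared.

    A CNVR is X-only iff every carrier belongs to subspecies X; the
    ``unique`` flag marks single-carrier CNVRs.
    """
    rows = []
    for cid in matrix.cnvr_ids:
        carriers = matrix.carriers(cid)
        if not carriers:
            cls = "none"
        else:
            carrier_subs = {metadata.subspecies_of(s) for s in carriers}
            cls = f"{next(iter(carrier_subs))}-only" if len(carrier_subs) == 1 else "shared"
        rows.append({"cnvr": cid, "classification": cls, "n_carriers": len(carriers),
                     "unique": len(carriers) == 1})
    return pd.DataFrame(rows).set_index("cnvr")


def group_event_frequencies(matrix: GenotypeMatrix, metadata: PanelMetadata) -> pd.DataFrame:
    """Per-CNVR, per-group frequency of non-normal states."""
    data = {}
    for group in metadata.groups:
        samples = metadata.samples_of_group(group)
        sub = matrix.states.loc[samples]
        data[group] = (sub != NORMAL).sum(axis=0) / len(samples)
    return pd.DataFrame(data)


def group_frequency_screen(
    matrix: GenotypeMatrix, metadata: PanelMetadata, min_diff: float = 0.8
) -> pd.DataFrame:
    """CNVRs whose max pairwise group-frequency difference >= min_diff,
    sorted by decreasing difference."""
    freqs = group_event_frequencies(matrix, metadata)
    diff = freqs.max(axis=1) - freqs.min(axis=1)
    out = freqs.copy()
    out["max_diff"] = diff
    out = out[out["max_diff"] >= min_diff]
    return out.sort_values("max_diff", ascending=False, kind="stable")


def uncentered_correlation_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - sum(u v) / (||u|| ||v||); scale-invariant, no mean-centering."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-norm row")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def hierarchical_cluster(
    data: pd.DataFrame | np.ndarray, labels: list[str] | None = None
) -> np.ndarray:
    """Average-linkage (UPGMA) clustering under uncentered correlation.

    Returns a scipy-style linkage matrix Z (n-1) x 4: merged indices,
    merge height (mean pairwise distance), new cluster size. Ties are
    broken toward the lexicographically smallest (i, j) cluster-index
    pair, making the tree deterministic.
    """
    if isinstance(data, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in data.index]
        X = data.to_numpy(dtype=float)
    else:
        X = np.asarray(data, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 items to cluster")
    norms = np.linalg.norm(X, axis=1)
    for i in np.nonzero(norms == 0)[0]:
        name = labels[int(i)] if labels else str(int(i))
        raise ValueError(f"zero-norm row: {name}")

    # average-linkage distance between clusters = mean over member pairs
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = uncentered_correlation_distance(X[i], X[j])
    active = {i: [i] for i in range(n)}  # cluster id -> leaf members
    cluster_idx = {i: i for i in range(n)}  # cluster id -> linkage index
    Z = np.zeros((n - 1, 4))
    next_idx = n
    for step in range(n - 1):
        best = None
        ids = sorted(active)
        for ai, i in enumerate(ids):
            for j in ids[ai + 1 :]:
                d = _avg_dist(D, active[i], active[j])
                key = (d, cluster_idx[i], cluster_idx[j])
                if best is None or key < best[0]:
                    best = (key, i, j)
        (d, _, _), i, j = best
        Z[step] = [cluster_idx[i], cluster_idx[j], d, len(active[i]) + len(active[j])]
        active[i] = active[i] + active[j]
        del active[j]
        cluster_idx[i] = next_idx
        next_idx += 1
    return Z


def _avg_dist(D: np.ndarray, members_a: list[int], members_b: list[int]) -> float:
    return float(D[np.ix_(members_a, members_b)].mean())


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a linkage matrix as a Newick string with branch lengths
    height/2 (ultrametric)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: labels[i] for i in range(n)}
    for step, (a, b, h, _size) in enumerate(Z):
        a, b = int(a), int(b)
        idx = n + step
        # ultrametric: a node sits at half its merge height above the leaves
        nodes[idx] = (
            f"({nodes[a]}:{h / 2 - heights[a] / 2:.6g},"
            f"{nodes[b]}:{h / 2 - heights[b] / 2:.6g})"
        )
        heights[idx] = h
    return nodes[n + len(Z) - 1] + ";"


def anova_cnv_length(groups: dict[str, list[float]] | list[list[float]]) -> tuple[float, float]:
    """One-way fixed-effects ANOVA (F, p) on CNV lengths grouped by sample.

    Degenerate inputs (zero between-group or zero within-group sum of
    squares) return F = 0 / F = inf with the matching p rather than NaN.
    """
    if isinstance(groups, dict):
        data = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        data = [np.asarray(v, dtype=float) for v in groups]
    k = len(data)
    if k < 2:
        raise ValueError("need >= 2 groups")
    n_total = sum(len(g) for g in data)
    if n_total - k < 1:
        raise ValueError("need >= 2 total degrees of freedom")
    grand = np.concatenate(data).mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in data)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in data)
    df_b, df_w = k - 1, n_total - k
    if ssb == 0:
        return 0.0, 1.0
    if ssw == 0:
        return float("inf"), 0.0
    F = (ssb / df_b) / (ssw / df_w)
    p = float(f_dist.sf(F, df_b, df_w))
    return float(F), p
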