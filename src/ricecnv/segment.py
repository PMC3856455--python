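"""Least-squares change-point segmentation of ordered probe log2 ratios.

Each chromosome's probe ratios are partitioned into contiguous
constant-mean segments by exact dynamic programming on the objective

    sum over segments of within-segment SSE  +  penalty * n_segments.

The DP attains the global optimum; ties are broken toward fewer
segments, then toward the smaller split index at each step. The default
penalty follows a BIC-like rule, penalty = 2 * sigma^2 * log(n), with
sigma estimated from the median absolute successive difference (robust
to the planted events themselves).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ArrayScan, ProbeLayout

_TIE_EPS = 1e-9


@dataclass(frozen=True)
class Segment:
    """A maximal constant-mean probe run within one chromosome."""

    sample: str
    chrom: str
    first_probe: int  # within-chromosome probe index, inclusive
    last_probe: int  # inclusive
    start: int  # bp, 1-based inclusive
    end: int
    n_probes: int
    mean_log2: float
    sse: float


def estimate_noise_sd(ratios: np.ndarray) -> float:
    """Robust sigma from successive differences: median|diff| scaled for
    Gaussian data (diff of two independents has sd sigma*sqrt(2))."""
    diffs = np.abs(np.diff(ratios))
    if diffs.size == 0:
        return 0.0
    return float(np.median(diffs) / (0.6744897501960817 * math.sqrt(2.0)))


def auto_penalty(ratios: np.ndarray) -> float:
    sigma = estimate_noise_sd(np.asarray(ratios, dtype=float))
    n = len(ratios)
    return 2.0 * sigma**2 * math.log(max(n, 2))


def _dp_breakpoints(x: np.ndarray, penalty: float) -> list[int]:
    """Optimal segment end indices (exclusive) for the penalized objective."""
    n = len(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    best = np.empty(n + 1)
    nseg = np.zeros(n + 1, dtype=int)
    back = np.zeros(n + 1, dtype=int)
    best[0] = 0.0
    idx = np.arange(n)
    for j in range(1, n + 1):
        i = idx[:j]
        lengths = j - i
        sums = s1[j] - s1[i]
        sse = (s2[j] - s2[i]) - sums * sums / lengths
        costs = best[:j] + sse + penalty
        lo = costs.min()
        cand = np.nonzero(costs <= lo + _TIE_EPS)[0]
        if len(cand) > 1:
            # fewest segments, then leftmost split
            segs = nseg[cand]
            cand = cand[segs == segs.min()]
        pick = int(cand[0])
        best[j] = costs[pick]
        nseg[j] = nseg[pick] + 1
        back[j] = pick
    bounds = []
    j = n
    while j > 0:
        bounds.append(j)
        j = int(back[j])
    return bounds[::-1]


def _dp_breakpoints_capped(x: np.ndarray, penalty: float, max_segments: int) -> list[int]:
    """Constrained DP: at most ``max_segments`` segments."""
    n = len(x)
    s1 = np.concatenate([[0.0], np.cumsum(x)])
    s2 = np.concatenate([[0.0], np.cumsum(x * x)])
    inf = math.inf
    kmax = min(max_segments, n)
    best = np.full((kmax + 1, n + 1), inf)
    back = np.zeros((kmax + 1, n + 1), dtype=int)
    best[0, 0] = 0.0
    for k in range(1, kmax + 1):
        for j in range(k, n + 1):
            i = np.arange(k - 1, j)
            lengths = j - i
            sums = s1[j] - s1[i]
            sse = (s2[j] - s2[i]) - sums * sums / lengths
            costs = best[k - 1, k - 1 : j] + sse + penalty
            pick = int(np.argmin(costs))
            best[k, j] = costs[pick]
            back[k, j] = pick + k - 1
    totals = best[1 : kmax + 1, n]
    k = int(np.argmin(totals)) + 1
    # prefer fewest segments on ties
    for kk in range(1, k):
        if totals[kk - 1] <= totals[k - 1] + _TIE_EPS:
            k = kk
            break
    bounds = []
    j = n
    while k > 0:
        bounds.append(j)
        j = int(back[k, j])
        k -= 1
    return bounds[::-1]


def segment_values(
    ratios: np.ndarray, penalty: float, max_segments: int | None = None
) -> list[tuple[int, int, float, float]]:
    """Segment a plain value vector.

    Returns (first_index, last_index, mean, sse) per segment, indices
    0-based inclusive.
    """
    x = np.asarray(ratios, dtype=float)
    if x.size == 0:
        raise ValueError("need at least one probe to segment")
    nan = np.nonzero(~np.isfinite(x))[0]
    if nan.size:
        raise ValueError(f"non-finite ratio at probe index {int(nan[0])}")
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    if max_segments is not None:
        bounds = _dp_breakpoints_capped(x, penalty, max_segments)
    else:
        bounds = _dp_breakpoints(x, penalty)
    out = []
    prev = 0
    for b in bounds:
        seg = x[prev:b]
        mean = float(seg.mean())
        out.append((prev, b - 1, mean, float(((seg - mean) ** 2).sum())))
        prev = b
    return out


def segment_chromosome(
    ratios: np.ndarray,
    penalty: float,
    max_segments: int | None = None,
    sample: str = "",
    chrom: str = "",
    starts: np.ndarray | None = None,
    ends: np.ndarray | None = None,
) -> list[Segment]:
    """Optimal penalized least-squares segmentation of one chromosome."""
    parts = segment_values(ratios, penalty, max_segments)
    x = np.asarray(ratios, dtype=float)
    if starts is None:
        starts = np.arange(1, len(x) + 1)
    if ends is None:
        ends = starts
    return [
        Segment(
            sample=sample,
            chrom=chrom,
            first_probe=a,
            last_probe=b,
            start=int(starts[a]),
            end=int(ends[b]),
            n_probes=b - a + 1,
            mean_log2=mean,
            sse=sse,
        )
        for a, b, mean, sse in parts
    ]


def segment_scan(
    scan: ArrayScan,
    layout: ProbeLayout,
    penalty: float | str = "auto",
) -> list[Segment]:
    """Per-chromosome segmentation of a normalized scan.

    Chromosomes are processed independently; segments never span
    chromosome boundaries. ``penalty="auto"`` applies the BIC-like rule
    to the whole scan's ratio vector.
    """
    if len(scan.probes) != layout.n_probes or not (
        scan.probes["probe_id"].to_numpy() == layout.probes["probe_id"].to_numpy()
    ).all():
        raise ValueError("scan probes do not match layout")
    ratios = scan.ratios
    pen = auto_penalty(ratios) if penalty == "auto" else float(penalty)
    segments: list[Segment] = []
    chrom_arr = layout.probes["chrom"].to_numpy()
    for chrom in layout.genome.names:
        mask = chrom_arr == chrom
        if not mask.any():
            continue
        sub = layout.probes[mask]
        segments.extend(
            segment_chromosome(
                ratios[mask],
                pen,
                sample=scan.sample,
                chrom=chrom,
                starts=sub["start"].to_numpy(),
                ends=sub["end"].to_numpy(),
            )
        )
    return segments


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": s.sample,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "n_probes": s.n_probes,
                "mean_log2": s.mean_log2,
                "sse": s.sse,
            }
            for s in segments
        ],
        columns=["sample", "chrom", "start", "end", "n_probes", "mean_log2", "sse"],
    )
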