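"""Spatial correction and between-channel q-spline normalization.

Order of operations follows standard two-channel practice: the spatial
artifact is removed first (a LOESS surface fitted to the log2 ratio over
array grid coordinates), then the dye bias is removed by mapping the
reference-channel intensity distribution onto the test channel through a
monotone spline fitted between matched quantiles.

Both corrections are applied to log-intensities and the ratio is
recomputed, so both channels stay available for QC after every stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator, RegularGridInterpolator

from .synthetic import ArrayScan, ProbeLayout


@dataclass
class NormalizationReport:
    """Per-stage correction magnitudes (all >= 0)."""

    spatial_surface_rms: float | None = None
    spatial_span: float | None = None
    qspline_max_quantile_shift: float | None = None
    qspline_knots: int | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _loess_surface(
    gx: np.ndarray, gy: np.ndarray, z: np.ndarray, span: float, n_nodes: int = 10
) -> np.ndarray:
    """Local-linear (degree 1, tricube) surface fitted on a node grid and
    interpolated back to the probes.

    Evaluating the local fit at ``n_nodes``^2 grid nodes instead of every
    probe keeps the cost linear in array size; a plane is reproduced
    exactly (local linear fit + bilinear interpolation are both exact on
    planes).
    """
    n = len(z)
    k = max(int(math.ceil(span * n)), 3)
    if k > n:
        raise ValueError(
            f"local fit needs {k} probes but only {n} available; increase span "
            "or supply more probes"
        )
    xs = np.linspace(gx.min(), gx.max(), n_nodes)
    ys = np.linspace(gy.min(), gy.max(), n_nodes)
    node_vals = np.empty((n_nodes, n_nodes))
    pts = np.column_stack([gx, gy])
    for i, x0 in enumerate(xs):
        for j, y0 in enumerate(ys):
            d = np.hypot(gx - x0, gy - y0)
            idx = np.argpartition(d, k - 1)[:k]
            dk = d[idx]
            dmax = dk.max()
            if dmax == 0:
                node_vals[i, j] = z[idx].mean()
                continue
            w = (1.0 - (dk / dmax) ** 3) ** 3
            A = np.column_stack(
                [np.ones(k), pts[idx, 0] - x0, pts[idx, 1] - y0]
            )
            sw = np.sqrt(np.maximum(w, 0.0))
            coef, *_ = np.linalg.lstsq(A * sw[:, None], z[idx] * sw, rcond=None)
            node_vals[i, j] = coef[0]
    interp = RegularGridInterpolator(
        (xs, ys), node_vals, method="linear", bounds_error=False, fill_value=None
    )
    return interp(pts)


def spatial_correct(
    scan: ArrayScan, layout: ProbeLayout, span: float = 0.3
) -> tuple[ArrayScan, NormalizationReport]:
    """Subtract a LOESS surface in (grid_x, grid_y) from the log2 ratios.

    The fitted surface is mean-centred over the probes before
    subtraction, so the global signal level is preserved. The correction
    is applied to the test-channel log-intensity and the ratio recomputed.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    gx = layout.probes["grid_x"].to_numpy(dtype=float)
    gy = layout.probes["grid_y"].to_numpy(dtype=float)
    z = scan.ratios.astype(float)
    surface = _loess_surface(gx, gy, z, span)
    surface = surface - surface.mean()
    test_log2 = np.log2(scan.probes["test"].to_numpy()) - surface
    out = scan.with_channels(
        np.exp2(test_log2), scan.probes["ref"].to_numpy(), stage="spatial"
    )
    report = NormalizationReport(
        spatial_surface_rms=float(np.sqrt(np.mean(surface**2))), spatial_span=span
    )
    return out, report


def qspline_fit_knots(
    test_log2: np.ndarray,
    ref_log2: np.ndarray,
    n_quantile_knots: int,
    tail_trim: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Matched quantile knots (x = reference, y = test) for the channel map.

    Knots are placed on interior quantile levels only
    (``[tail_trim, 1 - tail_trim]``): the extreme quantiles of the test
    channel are dominated by genuine copy-number probes, and a map fitted
    through them would absorb real signal. Outside the knot range the map
    is continued linearly (see :func:`_monotone_map`).

    Each knot is the mean of an equal-count bin of the sorted channel
    values rather than a raw sample quantile — bin means are strictly
    increasing and far less noisy on small arrays. The effective knot
    count is capped so every bin keeps >= 50 probes.
    """
    ts = np.sort(test_log2)
    rs = np.sort(ref_log2)
    n = len(ts)
    cut = int(round(tail_trim * n))
    if cut > 0:
        ts, rs = ts[cut : n - cut], rs[cut : n - cut]
    m = len(ts)
    k = int(min(n_quantile_knots, max(3, m // 50)))
    edges = np.linspace(0, m, k + 1).astype(int)
    qx = np.array([rs[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
    qy = np.array([ts[a:b].mean() for a, b in zip(edges[:-1], edges[1:]) if b > a])
    # PCHIP needs strictly increasing x; collapse duplicated bins.
    keep = np.concatenate([[True], np.diff(qx) > 1e-12])
    return qx[keep], qy[keep]


def _monotone_map(qx: np.ndarray, qy: np.ndarray):
    """PCHIP through the knots, linear beyond the knot range.

    Tail slopes come from a least-squares line through the outer fifth of
    the knots (clipped non-negative): single end-knot derivatives are too
    noisy on small arrays and would amplify into the extrapolated tails.
    """
    spline = PchipInterpolator(qx, qy, extrapolate=False)

    def _edge_slope(xs: np.ndarray, ys: np.ndarray) -> float:
        if len(xs) < 2 or xs[-1] == xs[0]:
            return 1.0
        return max(float(np.polyfit(xs, ys, 1)[0]), 0.0)

    edge = max(2, len(qx) // 5)
    lo_slope = _edge_slope(qx[:edge], qy[:edge])
    hi_slope = _edge_slope(qx[-edge:], qy[-edge:])

    def apply(x: np.ndarray) -> np.ndarray:
        y = spline(x)
        below = x < qx[0]
        above = x > qx[-1]
        y[below] = qy[0] + lo_slope * (x[below] - qx[0])
        y[above] = qy[-1] + hi_slope * (x[above] - qx[-1])
        return y

    return apply


def qspline_normalize(
    scan: ArrayScan, n_quantile_knots: int = 100, tail_trim: float = 0.05
) -> tuple[ArrayScan, NormalizationReport]:
    """Map the reference channel onto the test channel's intensity scale.

    A monotone cubic (PCHIP) interpolant through matched quantiles of the
    two log-intensity distributions is applied to the reference channel;
    log2 ratios are recomputed from the adjusted channels. The map is
    non-decreasing by construction, so within-channel ranks are preserved.
    """
    if n_quantile_knots < 3:
        raise ValueError("n_quantile_knots must be >= 3")
    test = scan.probes["test"].to_numpy(dtype=float)
    ref = scan.probes["ref"].to_numpy(dtype=float)
    for name, channel in (("test", test), ("ref", ref)):
        bad = np.nonzero(channel <= 0)[0]
        if bad.size:
            pid = scan.probes["probe_id"].iloc[int(bad[0])]
            raise ValueError(f"non-positive {name} intensity at probe {pid}")
    test_log2 = np.log2(test)
    ref_log2 = np.log2(ref)
    qx, qy = qspline_fit_knots(test_log2, ref_log2, n_quantile_knots, tail_trim)
    if len(qx) < 2:
        raise ValueError("reference channel is degenerate; cannot fit quantile map")
    ref_adj_log2 = _monotone_map(qx, qy)(ref_log2)
    out = scan.with_channels(test, np.exp2(ref_adj_log2), stage="normalized")
    report = NormalizationReport(
        qspline_max_quantile_shift=float(np.max(np.abs(qy - qx))),
        qspline_knots=n_quantile_knots,
    )
    return out, report


def normalize_scan(
    scan: ArrayScan,
    layout: ProbeLayout,
    span: float = 0.3,
    n_quantile_knots: int = 100,
) -> tuple[ArrayScan, NormalizationReport]:
    """spatial_correct followed by qspline_normalize; merged report."""
    corrected, rep1 = spatial_correct(scan, layout, span=span)
    normalized, rep2 = qspline_normalize(corrected, n_quantile_knots=n_quantile_knots)
    report = NormalizationReport(
        spatial_surface_rms=rep1.spatial_surface_rms,
        spatial_span=rep1.spatial_span,
        qspline_max_quantile_shift=rep2.qspline_max_quantile_shift,
        qspline_knots=rep2.qspline_knots,
    )
    return normalized, report
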