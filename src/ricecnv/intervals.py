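"""1-based inclusive interval arithmetic on (start, end) pairs.

Small, dependency-free helpers shared by the CNVR, annotation and
coverage code. All functions treat intervals as closed: ``(100, 100)``
has length 1.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np

Interval = tuple[int, int]


def interval_length(iv: Interval) -> int:
    return iv[1] - iv[0] + 1


def overlaps(a: Interval, b: Interval) -> bool:
    """>=1 bp overlap between two closed intervals."""
    return a[0] <= b[1] and b[0] <= a[1]


def contains(outer: Interval, inner: Interval) -> bool:
    """Non-strict containment: coterminous intervals count."""
    return outer[0] <= inner[0] and inner[1] <= outer[1]


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of closed intervals; adjacent-but-disjoint stay separate."""
    ivs = sorted(intervals)
    merged: list[Interval] = []
    for start, end in ivs:
        if end < start:
            raise ValueError(f"invalid interval ({start}, {end})")
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def union_length(intervals: Iterable[Interval]) -> int:
    return sum(interval_length(iv) for iv in merge_intervals(intervals))


def intersect_length(iv: Interval, others: Sequence[Interval]) -> int:
    """Bp of ``iv`` covered by the union of ``others``."""
    total = 0
    for start, end in merge_intervals(others):
        lo, hi = max(iv[0], start), min(iv[1], end)
        if lo <= hi:
            total += hi - lo + 1
    return total


def any_overlap(iv: Interval, others: Sequence[Interval]) -> bool:
    return any(overlaps(iv, other) for other in others)


def probes_in_interval(starts: np.ndarray, ends: np.ndarray, iv: Interval) -> np.ndarray:
    """Boolean mask of probes fully contained in the closed interval."""
    return (starts >= iv[0]) & (ends <= iv[1])
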