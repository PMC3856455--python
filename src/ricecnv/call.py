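"""Stringent filter cascade turning segments into per-sample CNV calls.

A segment survives iff:

1. its mean log2 ratio is aberrant (<= loss threshold or >= gain
   threshold; the neutral band in between is discarded),
2. 100% of its member probes individually clear the same directional
   cut-off (single outlier probes cannot carry a call),
3. it spans at least ``min_probes`` probes and ``min_length_bp``.

Rejected candidates are logged with a reason so the cascade is fully
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segment import Segment
from .synthetic import ArrayScan, ProbeLayout

CALL_COLUMNS = ["sample", "chrom", "start", "end", "type", "mean_log2", "n_probes", "length"]


@dataclass(frozen=True)
class CallingConfig:
    loss_threshold: float = -2.0
    gain_threshold: float = 1.0
    min_probes: int = 5
    require_all_probes: bool = True
    min_length_bp: int = 1000

    def __post_init__(self) -> None:
        if not self.loss_threshold < 0 < self.gain_threshold:
            raise ValueError("need loss_threshold < 0 < gain_threshold")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")


@dataclass(frozen=True)
class CnvCall:
    sample: str
    chrom: str
    start: int
    end: int
    type: str  # "loss" | "gain"
    mean_log2: float
    n_probes: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def candidate_type(segment: Segment, config: CallingConfig) -> str | None:
    """loss / gain / None for the neutral band (thresholds inclusive)."""
    if segment.mean_log2 <= config.loss_threshold:
        return "loss"
    if segment.mean_log2 >= config.gain_threshold:
        return "gain"
    return None


def filter_segments(
    segments: list[Segment], config: CallingConfig | None = None
) -> list[Segment]:
    """Keep only segments whose mean is aberrant; drop the neutral band."""
    config = config or CallingConfig()
    return [s for s in segments if candidate_type(s, config) is not None]


def apply_probe_level_filter(
    segment: Segment, probe_ratios: np.ndarray, config: CallingConfig | None = None
) -> tuple[bool, str]:
    """Secondary filter: every member probe must clear the directional
    cut-off; single-probe segments are rejected outright when
    ``min_probes`` > 1.
    """
    config = config or CallingConfig()
    ctype = candidate_type(segment, config)
    if ctype is None:
        return False, "neutral segment"
    ratios = np.asarray(probe_ratios, dtype=float)
    if ratios.size != segment.n_probes:
        raise ValueError("probe ratio vector does not match segment size")
    if segment.n_probes == 1 and config.min_probes > 1:
        return False, "single outlier probe"
    if config.require_all_probes:
        if ctype == "loss":
            bad = ratios[ratios > config.loss_threshold]
            if bad.size:
                return False, f"probe {bad[0]:.4g} above cut-off"
        else:
            bad = ratios[ratios < config.gain_threshold]
            if bad.size:
                return False, f"probe {bad[0]:.4g} below cut-off"
    if segment.n_probes < config.min_probes:
        return False, f"fewer than {config.min_probes} probes"
    return True, "accepted"


def call_cnvs(
    segments: list[Segment],
    scans: dict[str, ArrayScan] | list[ArrayScan],
    layout: ProbeLayout,
    config: CallingConfig | None = None,
    rejects: list[dict] | None = None,
) -> list[CnvCall]:
    """Full cascade over all samples' segments.

    ``scans`` supplies the per-probe ratios backing each segment;
    ``rejects``, if given, collects one dict per discarded candidate.
    """
    config = config or CallingConfig()
    if isinstance(scans, list):
        scans = {s.sample: s for s in scans}
    chrom_arr = layout.probes["chrom"].to_numpy()
    chrom_masks = {c: chrom_arr == c for c in layout.genome.names}
    calls: list[CnvCall] = []
    for seg in filter_segments(segments, config):
        scan = scans.get(seg.sample)
        if scan is None:
            raise ValueError(f"no scan supplied for sample {seg.sample!r}")
        ratios = scan.ratios[chrom_masks[seg.chrom]][seg.first_probe : seg.last_probe + 1]
        ok, reason = apply_probe_level_filter(seg, ratios, config)
        length = seg.end - seg.start + 1
        if ok and length < config.min_length_bp:
            ok, reason = False, f"shorter than {config.min_length_bp} bp"
        if not ok:
            if rejects is not None:
                rejects.append(
                    {
                        "sample": seg.sample,
                        "chrom": seg.chrom,
                        "start": seg.start,
                        "end": seg.end,
                        "mean_log2": seg.mean_log2,
                        "reason": reason,
                    }
                )
            continue
        calls.append(
            CnvCall(
                sample=seg.sample,
                chrom=seg.chrom,
                start=seg.start,
                end=seg.end,
                type=candidate_type(seg, config),  # type: ignore[arg-type]
                mean_log2=seg.mean_log2,
                n_probes=seg.n_probes,
            )
        )
    calls.sort(key=lambda c: (c.sample, c.chrom, c.start))
    return calls


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample": c.sample,
                "chrom": c.chrom,
                "start": c.start,
                "end": c.end,
                "type": c.type,
                "mean_log2": c.mean_log2,
                "n_probes": c.n_probes,
                "length": c.length,
            }
            for c in calls
        ],
        columns=CALL_COLUMNS,
    )


def frame_to_calls(df: pd.DataFrame) -> list[CnvCall]:
    return [
        CnvCall(
            sample=str(r.sample),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            type=str(r.type),
            mean_log2=float(r.mean_log2),
            n_probes=int(r.n_probes),
        )
        for r in df.itertuples(index=False)
    ]
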