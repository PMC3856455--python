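"""Cross-sample consolidation of CNV calls into CNVRs.

CNVRs are the connected components of the >=1 bp interval-overlap graph
over all samples' calls (transitive chaining); an optional reciprocal
overlap fraction tightens the criterion. Probe re-validation then drops
probes without a unique perfect genome match, discards CNVRs left with
fewer than five probes, and discards CNVRs overlapping declared assembly
gaps. Finally calls are simplified to a samples x CNVRs matrix over
{normal, loss, gain}; complex regions (loss and gain observed in the
same region) are genotyped but excluded from population statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .call import CnvCall
from .intervals import any_overlap, probes_in_interval
from .synthetic import ProbeLayout

NORMAL, LOSS, GAIN = "N", "L", "G"


@dataclass
class Cnvr:
    id: str
    chrom: str
    start: int
    end: int
    type: str  # "loss" | "gain" | "both"
    carrier_samples: frozenset[str]
    n_probes: int = 0
    frequency: float = 0.0
    calls: tuple[CnvCall, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProbeValidationTable:
    """Per-probe count of perfect genome matches against the current build."""

    matches: pd.DataFrame  # columns: probe_id, n_perfect_matches

    def __post_init__(self) -> None:
        if (self.matches["n_perfect_matches"] < 0).any():
            raise ValueError("match counts must be >= 0")

    def unique_probe_ids(self) -> set[str]:
        m = self.matches
        return set(m.loc[m["n_perfect_matches"] == 1, "probe_id"])

    def summary(self) -> dict:
        n = len(self.matches)
        n_single = int((self.matches["n_perfect_matches"] == 1).sum())
        return {"n_probes": n, "n_single_match": n_single}


@dataclass
class GenotypeMatrix:
    """samples x CNVRs over {N, L, G} plus the complex-CNVR exclusion set."""

    states: pd.DataFrame  # index: samples, columns: CNVR ids, values N/L/G
    excluded_complex: frozenset[str]

    @property
    def samples(self) -> list[str]:
        return list(self.states.index)

    @property
    def cnvr_ids(self) -> list[str]:
        return list(self.states.columns)

    def carriers(self, cnvr_id: str) -> set[str]:
        col = self.states[cnvr_id]
        return set(col.index[col != NORMAL])

    def analysis_columns(self) -> list[str]:
        """CNVR ids entering population statistics (complex excluded)."""
        return [c for c in self.states.columns if c not in self.excluded_complex]


def _fraction_ok(a: CnvCall, start: int, end: int, min_reciprocal: float) -> bool:
    if min_reciprocal <= 0:
        return True
    ov = min(a.end, end) - max(a.start, start) + 1
    if ov <= 0:
        return False
    return ov >= min_reciprocal * a.length and ov >= min_reciprocal * (end - start + 1)


def merge_calls(calls: list[CnvCall], min_reciprocal: float = 0.0) -> list[Cnvr]:
    """Chain overlapping calls across samples into CNVRs.

    With the default ``min_reciprocal=0`` any >=1 bp overlap chains;
    a positive fraction requires reciprocal overlap with the growing
    region. Result is independent of input order (calls are sorted
    internally).
    """
    by_chrom: dict[str, list[CnvCall]] = {}
    for c in sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.sample)):
        by_chrom.setdefault(c.chrom, []).append(c)
    cnvrs: list[Cnvr] = []
    for chrom in sorted(by_chrom):
        cluster: list[CnvCall] = []
        cur_end = -1
        for call in by_chrom[chrom]:
            if cluster and call.start <= cur_end and _fraction_ok(
                call, cluster[0].start, cur_end, min_reciprocal
            ):
                cluster.append(call)
                cur_end = max(cur_end, call.end)
            else:
                if cluster:
                    cnvrs.append(_make_cnvr(chrom, cluster))
                cluster = [call]
                cur_end = call.end
        if cluster:
            cnvrs.append(_make_cnvr(chrom, cluster))
    for i, r in enumerate(cnvrs):
        r.id = f"CNVR{i + 1:05d}"
    return cnvrs


def _make_cnvr(chrom: str, cluster: list[CnvCall]) -> Cnvr:
    types = {c.type for c in cluster}
    rtype = "both" if len(types) > 1 else next(iter(types))
    return Cnvr(
        id="",
        chrom=chrom,
        start=min(c.start for c in cluster),
        end=max(c.end for c in cluster),
        type=rtype,
        carrier_samples=frozenset(c.sample for c in cluster),
        calls=tuple(cluster),
    )


def count_probes(cnvr: Cnvr, layout: ProbeLayout, valid_ids: set[str] | None = None) -> int:
    sub = layout.chromosome_probes(cnvr.chrom)
    mask = probes_in_interval(
        sub["start"].to_numpy(), sub["end"].to_numpy(), (cnvr.start, cnvr.end)
    )
    ids = sub.loc[mask, "probe_id"]
    if valid_ids is not None:
        return int(ids.isin(list(valid_ids)).sum())
    return len(ids)


def validate_cnvrs(
    cnvrs: list[Cnvr],
    layout: ProbeLayout,
    validation: ProbeValidationTable | None = None,
    gaps: dict[str, list[tuple[int, int]]] | None = None,
    min_probes: int = 5,
    rejects: list[dict] | None = None,
) -> list[Cnvr]:
    """Probe re-validation and gap screening.

    Probes without exactly one perfect match are removed from each
    CNVR's probe count; CNVRs left with fewer than ``min_probes`` are
    discarded, as are CNVRs overlapping any supplied gap interval.
    """
    valid_ids = validation.unique_probe_ids() if validation is not None else None
    gaps = gaps or {}
    kept: list[Cnvr] = []
    for cnvr in cnvrs:
        n = count_probes(cnvr, layout, valid_ids)
        if n < min_probes:
            if rejects is not None:
                rejects.append({"id": cnvr.id, "reason": f"fewer than {min_probes} probes"})
            continue
        if any_overlap((cnvr.start, cnvr.end), gaps.get(cnvr.chrom, [])):
            if rejects is not None:
                rejects.append({"id": cnvr.id, "reason": "gap overlap"})
            continue
        cnvr.n_probes = n
        kept.append(cnvr)
    return kept


def genotype(cnvrs: list[Cnvr], calls: list[CnvCall], panel: list[str]) -> GenotypeMatrix:
    """Simplify calls into per-sample {normal, loss, gain} states.

    A sample is loss/gain at a CNVR iff it carries an overlapping call of
    that type; a sample with both call types inside one region is
    recorded as loss and the region lands in ``excluded_complex``
    (as does every region of type "both").
    """
    panel_set = set(panel)
    for c in calls:
        if c.sample not in panel_set:
            raise ValueError(f"sample {c.sample!r} has calls but no panel metadata")
    ids = [r.id for r in cnvrs]
    states = pd.DataFrame(NORMAL, index=list(panel), columns=ids, dtype=object)
    excluded: set[str] = set()
    for cnvr in cnvrs:
        per_sample: dict[str, set[str]] = {}
        for call in cnvr.calls:
            per_sample.setdefault(call.sample, set()).add(call.type)
        for sample, types in per_sample.items():
            if sample not in panel_set:
                continue
            states.loc[sample, cnvr.id] = LOSS if "loss" in types else GAIN
        if cnvr.type == "both":
            excluded.add(cnvr.id)
        cnvr.frequency = len(cnvr.carrier_samples & panel_set) / len(panel)
    return GenotypeMatrix(states=states, excluded_complex=frozenset(excluded))


def unique_cnvrs(matrix: GenotypeMatrix) -> list[str]:
    """CNVR ids carried by exactly one sample."""
    counts = (matrix.states != NORMAL).sum(axis=0)
    return list(counts.index[counts == 1])


def cnvrs_to_frame(cnvrs: list[Cnvr]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "type": r.type,
                "n_probes": r.n_probes,
                "frequency": r.frequency,
                "carriers": ",".join(sorted(r.carrier_samples)),
            }
            for r in cnvrs
        ],
        columns=["id", "chrom", "start", "end", "type", "n_probes", "frequency", "carriers"],
    )
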