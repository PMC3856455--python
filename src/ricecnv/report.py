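"""Summary tables and pipeline orchestration.

The summary operations are pure arithmetic on their inputs: per-panel
CNV counts, per-chromosome CNVR coverage with fold enrichment, and the
half-up percentage bookkeeping used throughout the output tables.
``run_pipeline`` chains simulate -> preprocess -> segment -> call ->
merge -> genotype -> popgen on a YAML/dict config and writes TSV/BED
artifacts plus a JSON manifest; a rerun with the same config reproduces
the outputs byte for byte.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._util import round_half_up
from .call import CallingConfig, CnvCall, call_cnvs
from .cnvr import Cnvr, genotype as genotype_op, merge_calls, validate_cnvrs
from .genome import GenomeModel, default_genome
from .intervals import union_length
from .popgen import (
    GROUPS_BY_SUBSPECIES,
    PanelMetadata,
    diversity_table,
    group_frequency_screen,
    subspecies_specific,
)
from .preprocess import normalize_scan
from .segment import segment_scan
from .synthetic import make_probe_layout, plant_cnvs, simulate_scan


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * num / den with half-up rounding at ``decimals``."""
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    return round_half_up(100.0 * numerator / denominator, decimals)


def summarize_panel(
    calls: list[CnvCall], metadata: PanelMetadata, by: str = "subspecies"
) -> pd.DataFrame:
    """Per-subspecies (or per-group) CNV counts: n samples, total, mean
    per cultivar (1 decimal), min-max range, gains, losses."""
    if len(metadata.table) == 0:
        raise ValueError("empty panel")
    known = set(metadata.table.index)
    for c in calls:
        if c.sample not in known:
            raise ValueError(f"call sample {c.sample!r} not in panel metadata")
    df = pd.DataFrame(
        [{"sample": c.sample, "type": c.type} for c in calls],
        columns=["sample", "type"],
    )
    rows = []
    for level in sorted(metadata.table[by].unique()):
        samples = list(metadata.table.index[metadata.table[by] == level])
        sub = df[df["sample"].isin(samples)]
        per_sample = sub.groupby("sample").size().reindex(samples, fill_value=0)
        total = int(per_sample.sum())
        rows.append(
            {
                by: level,
                "n_samples": len(samples),
                "total_cnvs": total,
                "mean_per_cultivar": round_half_up(total / len(samples), 1),
                "min_per_cultivar": int(per_sample.min()),
                "max_per_cultivar": int(per_sample.max()),
                "gains": int((sub["type"] == "gain").sum()),
                "losses": int((sub["type"] == "loss").sum()),
            }
        )
    return pd.DataFrame(rows).set_index(by)


def coverage_stats(cnvrs: list[Cnvr], genome: GenomeModel) -> pd.DataFrame:
    """Per-chromosome CNVR coverage and fold enrichment vs genome-wide.

    CNVR intervals are unioned per chromosome before counting, so
    overlapping regions are not double counted. Percentages carry 2
    decimals; fold = chromosome percent / genome percent, computed on
    the rounded percentages to match printed-table conventions.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.names}
    for r in cnvrs:
        if r.chrom not in per_chrom:
            raise ValueError(f"CNVR {r.id} on unknown chromosome {r.chrom!r}")
        per_chrom[r.chrom].append((r.start, r.end))
    total_bp = genome.total_length
    total_cnvr_bp = 0
    rows = []
    for chrom, length in genome.chromosomes:
        ivs = per_chrom[chrom]
        cov = union_length(ivs) if ivs else 0
        total_cnvr_bp += cov
        rows.append(
            {
                "chrom": chrom,
                "n_cnvrs": len(ivs),
                "cnvr_bp": cov,
                "chrom_bp": length,
                "pct_covered": percentage(cov, length, 2),
            }
        )
    genome_pct = percentage(total_cnvr_bp, total_bp, 2)
    df = pd.DataFrame(rows).set_index("chrom")
    df["genome_pct"] = genome_pct
    df["fold_enrichment"] = [
        round_half_up(p / genome_pct, 2) if genome_pct > 0 else 0.0
        for p in df["pct_covered"]
    ]
    return df


# ------------------------------------------------------------- pipeline

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "genome": {"n_chromosomes": 12, "chrom_length": 300_000},
    "layout": {"median_spacing_bp": 500},
    "panel": {
        "n_indica": 9,
        "n_japonica": 11,
        "n_self_self": 2,
    },
    "truth": {
        "n_events_per_sample": 10,
        "length_range": [2600, 3500],
        "loss_fraction": 0.93,
        "min_probes": 5,
    },
    "scan": {"noise_sd": 0.15, "spatial_amp": 0.2, "dye_bias_strength": 0.2},
    "preprocess": {"span": 0.3, "n_quantile_knots": 100},
    "segment": {"penalty": "auto"},
    "call": {
        "loss_threshold": -2.0,
        "gain_threshold": 1.0,
        "min_probes": 5,
        "min_length_bp": 1000,
    },
    "cnvr": {"min_probes": 5},
    "popgen": {"min_group_diff": 0.8},
}


def default_panel_metadata(n_indica: int = 9, n_japonica: int = 11) -> PanelMetadata:
    """Synthetic panel: samples cycled through the groups of each subspecies."""
    rows = {}
    for i in range(n_indica):
        group = GROUPS_BY_SUBSPECIES["indica"][i % 2]
        rows[f"IND{i + 1:02d}"] = {"subspecies": "indica", "group": group}
    for i in range(n_japonica):
        group = GROUPS_BY_SUBSPECIES["japonica"][i % 4]
        rows[f"JAP{i + 1:02d}"] = {"subspecies": "japonica", "group": group}
    return PanelMetadata(pd.DataFrame.from_dict(rows, orient="index"))


def _merge_config(user: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in (user or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def run_pipeline(config: dict | None = None, out_dir: str | Path = "ricecnv_out") -> dict:
    """Execute the full synthetic pipeline and write artifacts.

    Returns the run manifest (also written to ``manifest.json``). All
    randomness derives from ``config['seed']``, so a rerun with the same
    config reproduces every output file exactly.
    """
    from . import io as rio

    cfg = _merge_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    genome = default_genome(**cfg["genome"])
    layout = make_probe_layout(genome, seed=seed, **cfg["layout"])
    metadata = default_panel_metadata(
        cfg["panel"]["n_indica"], cfg["panel"]["n_japonica"]
    )
    samples = list(metadata.table.index)
    truth = plant_cnvs(
        layout,
        n_events_per_sample=cfg["truth"]["n_events_per_sample"],
        length_range=tuple(cfg["truth"]["length_range"]),
        loss_fraction=cfg["truth"]["loss_fraction"],
        samples=samples,
        seed=seed + 1,
        min_probes=cfg["truth"]["min_probes"],
    )
    rio.write_genome(genome, out / "genome.tsv")
    rio.write_layout(layout, out / "layout.tsv")
    rio.write_truth(truth, out / "truth.tsv")
    rio.write_metadata(metadata, out / "metadata.tsv")

    scan_params = cfg["scan"]
    calls = []
    counts = {"segments": 0}
    for i, sample in enumerate(samples):
        scan = simulate_scan(layout, truth, sample, seed=seed + 100 + i, **scan_params)
        normalized, _rep = normalize_scan(scan, layout, span=cfg["preprocess"]["span"],
                                          n_quantile_knots=cfg["preprocess"]["n_quantile_knots"])
        segments = segment_scan(normalized, layout, penalty=cfg["segment"]["penalty"])
        counts["segments"] += len(segments)
        calls.extend(
            call_cnvs(segments, {sample: normalized}, layout, CallingConfig(**cfg["call"]))
        )
    null_calls = 0
    for i in range(cfg["panel"]["n_self_self"]):
        scan = simulate_scan(
            layout, truth, f"SELF{i + 1}", seed=seed + 900 + i, **scan_params
        )
        normalized, _ = normalize_scan(scan, layout, span=cfg["preprocess"]["span"],
                                       n_quantile_knots=cfg["preprocess"]["n_quantile_knots"])
        segments = segment_scan(normalized, layout, penalty=cfg["segment"]["penalty"])
        null_calls += len(
            call_cnvs(segments, {f"SELF{i + 1}": normalized}, layout,
                      CallingConfig(**cfg["call"]))
        )
    rio.write_calls(calls, out / "calls.tsv")
    rio.write_calls_bed(calls, out / "calls.bed")

    cnvrs = merge_calls(calls)
    cnvrs = validate_cnvrs(cnvrs, layout, min_probes=cfg["cnvr"]["min_probes"])
    matrix = genotype_op(cnvrs, calls, samples)
    rio.write_cnvrs(cnvrs, out / "cnvrs.tsv")
    rio.write_cnvrs_bed(cnvrs, out / "cnvrs.bed")
    rio.write_genotype(matrix, out / "genotype.tsv")

    diversity_table(matrix, metadata).to_csv(out / "diversity.tsv", sep="\t", index=False)
    subspecies_specific(matrix, metadata).to_csv(out / "subspecies_specific.tsv", sep="\t")
    group_frequency_screen(matrix, metadata, cfg["popgen"]["min_group_diff"]).to_csv(
        out / "group_screen.tsv", sep="\t"
    )
    summarize_panel(calls, metadata).to_csv(out / "panel_summary.tsv", sep="\t")
    coverage_stats(cnvrs, genome).to_csv(out / "coverage.tsv", sep="\t")

    recall, precision = truth_comparison(calls, truth)
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": cfg,
        "counts": {
            **counts,
            "calls": len(calls),
            "cnvrs": len(cnvrs),
            "self_self_calls": null_calls,
        },
        "recall": recall,
        "precision": precision,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def truth_comparison(calls: list[CnvCall], truth) -> tuple[float, float]:
    """(recall, precision) of calls against the planted truth set.

    An event is recovered iff overlapped by a same-sample, same-type
    call; a call is true iff it overlaps a same-sample, same-type event.
    """
    events = truth.events
    if events.empty:
        return float("nan"), 1.0 if not calls else 0.0
    recovered = 0
    for ev in events.itertuples(index=False):
        if any(
            c.sample == ev.sample
            and c.chrom == ev.chrom
            and c.type == ev.type
            and c.start <= ev.end
            and ev.start <= c.end
            for c in calls
        ):
            recovered += 1
    true_calls = 0
    for c in calls:
        sub = events[
            (events["sample"] == c.sample)
            & (events["chrom"] == c.chrom)
            & (events["type"] == c.type)
        ]
        if ((sub["start"] <= c.end) & (c.start <= sub["end"])).any():
            true_calls += 1
    recall = recovered / len(events)
    precision = true_calls / len(calls) if calls else 1.0
    return recall, precision
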