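"""Plain-text readers and writers for the pipeline's on-disk formats.

Conventions: BED-like files are 0-based half-open on disk and converted
to 1-based inclusive in memory; everything else is plain TSV with a
header row.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .call import CALL_COLUMNS, CnvCall, calls_to_frame, frame_to_calls
from .cnvr import Cnvr, GenotypeMatrix, ProbeValidationTable, cnvrs_to_frame
from .genome import GenomeModel
from .popgen import PanelMetadata
from .synthetic import LAYOUT_COLUMNS, ArrayScan, ProbeLayout, TruthSet


# ---------------------------------------------------------------- layout

def write_layout(layout: ProbeLayout, path: str | Path) -> None:
    """BED-like TSV: chrom, start0, end, probe_id, length, grid_x, grid_y."""
    df = layout.probes.copy()
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start0": df["start"] - 1,
            "end": df["end"],
            "probe_id": df["probe_id"],
            "length": df["length"],
            "grid_x": df["grid_x"],
            "grid_y": df["grid_y"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_layout(path: str | Path, genome: GenomeModel) -> ProbeLayout:
    df = pd.read_csv(path, sep="\t")
    probes = pd.DataFrame(
        {
            "probe_id": df["probe_id"],
            "chrom": df["chrom"],
            "start": df["start0"] + 1,
            "end": df["end"],
            "length": df["length"],
            "grid_x": df["grid_x"],
            "grid_y": df["grid_y"],
        }
    )[LAYOUT_COLUMNS]
    return ProbeLayout(genome, probes)


# ---------------------------------------------------------------- genome

def write_genome(genome: GenomeModel, path: str | Path) -> None:
    pd.DataFrame(genome.chromosomes, columns=["chrom", "length"]).to_csv(
        path, sep="\t", index=False
    )


def read_genome(path: str | Path) -> GenomeModel:
    df = pd.read_csv(path, sep="\t")
    return GenomeModel(tuple((str(r.chrom), int(r.length)) for r in df.itertuples()))


# ----------------------------------------------------------------- truth

def write_truth(truth: TruthSet, path: str | Path) -> None:
    truth.events.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> TruthSet:
    return TruthSet(pd.read_csv(path, sep="\t"))


# ------------------------------------------------------------------ scan

def write_scan(scan: ArrayScan, path: str | Path) -> None:
    scan.probes.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_scan(path: str | Path, sample: str, stage: str = "raw") -> ArrayScan:
    return ArrayScan(sample, pd.read_csv(path, sep="\t"), stage=stage)


# ----------------------------------------------------------------- calls

def write_calls(calls: list[CnvCall], path: str | Path) -> None:
    calls_to_frame(calls).to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[CnvCall]:
    return frame_to_calls(pd.read_csv(path, sep="\t")[CALL_COLUMNS])


def write_calls_bed(calls: list[CnvCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.chrom}\t{c.start - 1}\t{c.end}\t{c.sample}:{c.type}\t{c.mean_log2:.4f}\n"
            )


# ----------------------------------------------------------------- cnvrs

def write_cnvrs(cnvrs: list[Cnvr], path: str | Path) -> None:
    cnvrs_to_frame(cnvrs).to_csv(path, sep="\t", index=False)


def write_cnvrs_bed(cnvrs: list[Cnvr], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in cnvrs:
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.id}:{r.type}\n")


# -------------------------------------------------------------- genotype

def write_genotype(matrix: GenotypeMatrix, path: str | Path) -> None:
    df = matrix.states.copy()
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_genotype(path: str | Path, excluded_complex: set[str] | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample")
    return GenotypeMatrix(states=df, excluded_complex=frozenset(excluded_complex or ()))


# -------------------------------------------------------------- metadata

def write_metadata(metadata: PanelMetadata, path: str | Path) -> None:
    df = metadata.table.copy()
    df.index.name = "sample"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path) -> PanelMetadata:
    return PanelMetadata(pd.read_csv(path, sep="\t", index_col="sample"))


# ------------------------------------------------------- intervals (BED)

def read_bed_intervals(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """BED (0-based half-open) -> chrom -> [(start, end)] 1-based inclusive."""
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.setdefault(parts[0], []).append((int(parts[1]) + 1, int(parts[2])))
    return out


def write_bed_intervals(
    intervals: dict[str, list[tuple[int, int]]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(intervals):
            for start, end in sorted(intervals[chrom]):
                fh.write(f"{chrom}\t{start - 1}\t{end}\n")


# ------------------------------------------------------------ validation

def read_probe_validation(path: str | Path) -> ProbeValidationTable:
    return ProbeValidationTable(pd.read_csv(path, sep="\t"))


def write_probe_validation(table: ProbeValidationTable, path: str | Path) -> None:
    table.matches.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- go map

def read_go_map(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV (gene, GO id), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], comment="#")
    if str(df.iloc[0]["gene"]).lower() in ("gene", "gene_id"):
        df = df.iloc[1:]
    mapping: dict[str, set[str]] = {}
    for gene, term in df.itertuples(index=False):
        mapping.setdefault(str(gene), set()).add(str(term))
    return mapping


# ------------------------------------------------------------ gene files

def read_genes_bed(path: str | Path):
    """Genes from BED: chrom, start0, end, gene_id."""
    from .annotate import GeneModel

    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            genes.append(
                GeneModel(gene_id=parts[3], chrom=parts[0], start=int(parts[1]) + 1, end=int(parts[2]))
            )
    return genes


def read_genes_gff3(path: str | Path, feature_type: str = "gene"):
    """Minimal GFF3 gene reader: keeps ``feature_type`` rows, ID attribute."""
    from .annotate import GeneModel

    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != feature_type:
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID", attrs.get("Name", f"{parts[0]}:{parts[3]}"))
            genes.append(
                GeneModel(gene_id=gene_id, chrom=parts[0], start=int(parts[3]), end=int(parts[4]))
            )
    return genes
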