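"""Intersection of CNVRs with gene models, segmental duplications and
repeat annotations, plus the deleted-region repeat-content accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cnvr import Cnvr
from .intervals import contains, intersect_length, merge_intervals, overlaps

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "DNA", "simple", "other")


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    family: str | None = None
    go_terms: tuple[str, ...] = ()
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")


@dataclass(frozen=True)
class RepeatFeature:
    chrom: str
    start: int
    end: int
    repeat_class: str  # one of REPEAT_CLASSES

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("repeat feature start > end")


def classify_repeat(raw_class: str) -> str:
    """Map a RepeatMasker class/family string onto the coarse classes."""
    head = raw_class.split("/")[0]
    if head in ("LINE", "SINE", "LTR", "DNA"):
        return head
    if head in ("Simple_repeat", "Low_complexity"):
        return "simple"
    return "other"


def read_repeatmasker(path: str) -> list[RepeatFeature]:
    """Parse RepeatMasker ``.out`` (3 header lines, whitespace-delimited)
    or fall back to BED (0-based half-open, class in column 4)."""
    feats: list[RepeatFeature] = []
    with open(path) as fh:
        lines = fh.readlines()
    first = lines[0] if lines else ""
    is_bed = str(path).endswith(".bed") or (
        bool(first.strip())
        and "perc" not in first
        and "score" not in first
        and len(first.split("\t")) >= 4
    )
    if is_bed:
        for ln, line in enumerate(lines, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed BED line {ln}: {line.rstrip()!r}")
            chrom, start0, end, cls = parts[0], parts[1], parts[2], parts[3]
            feats.append(
                RepeatFeature(chrom, int(start0) + 1, int(end), classify_repeat(cls))
            )
        return feats
    for ln, line in enumerate(lines[3:], 4):  # skip the 3 header lines
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 11:
            raise ValueError(f"malformed RepeatMasker line {ln}: {line.rstrip()!r}")
        try:
            chrom, start, end = parts[4], int(parts[5]), int(parts[6])
        except ValueError as exc:
            raise ValueError(f"malformed RepeatMasker line {ln}: {exc}") from exc
        feats.append(RepeatFeature(chrom, start, end, classify_repeat(parts[10])))
    return feats


def write_repeatmasker(feats: list[RepeatFeature], path: str) -> None:
    """Emit a minimal RepeatMasker-style ``.out`` (round-trips through
    :func:`read_repeatmasker`)."""
    header = (
        "   SW  perc perc perc  query     position in query    matching repeat\n"
        "score  div. del. ins.  sequence  begin end (left)     repeat class/family\n"
        "\n"
    )
    back_map = {"simple": "Simple_repeat", "other": "Unknown"}
    with open(path, "w") as fh:
        fh.write(header)
        for f in feats:
            raw = back_map.get(f.repeat_class, f.repeat_class)
            fh.write(
                f"  225  10.0  0.0  0.0  {f.chrom}  {f.start}  {f.end}  (0)  +  "
                f"rep  {raw}  1  100  (0)  1\n"
            )


def gene_overlap(cnvrs: list[Cnvr], genes: list[GeneModel]) -> pd.DataFrame:
    """Per-gene status vs the CNVR set.

    ``wholly_contained`` iff the gene interval is inside some single
    CNVR (non-strict; coterminous counts); ``partial`` iff >=1 bp overlap
    without containment; ``none`` otherwise. The three statuses are
    mutually exclusive and exhaustive.
    """
    by_chrom: dict[str, list[Cnvr]] = {}
    for r in cnvrs:
        by_chrom.setdefault(r.chrom, []).append(r)
    rows = []
    for g in genes:
        giv = (g.start, g.end)
        status = "none"
        hit_ids = []
        for r in by_chrom.get(g.chrom, []):
            if overlaps(giv, (r.start, r.end)):
                hit_ids.append(r.id)
                if contains((r.start, r.end), giv):
                    status = "wholly_contained"
                elif status != "wholly_contained":
                    status = "partial"
        rows.append(
            {"gene_id": g.gene_id, "status": status, "cnvrs": ",".join(hit_ids)}
        )
    return pd.DataFrame(rows).set_index("gene_id")


def affected_genes(overlap_table: pd.DataFrame) -> list[str]:
    """Genes wholly or partially spanned by CNVRs."""
    return list(overlap_table.index[overlap_table["status"] != "none"])


def sd_overlap(
    cnvrs: list[Cnvr], sd_intervals: dict[str, list[tuple[int, int]]]
) -> tuple[int, float]:
    """(count, fraction) of CNVRs with >=1 bp segmental-duplication overlap."""
    if not cnvrs:
        return 0, 0.0
    n_hit = 0
    for r in cnvrs:
        ivs = sd_intervals.get(r.chrom, [])
        if any(overlaps((r.start, r.end), iv) for iv in ivs):
            n_hit += 1
    return n_hit, n_hit / len(cnvrs)


def repeat_content(
    regions: dict[str, list[tuple[int, int]]],
    repeats: list[RepeatFeature],
) -> pd.DataFrame:
    """Per-chromosome accounting of repeat/TE content in deleted regions.

    Overlapping repeat features are unioned before counting so each
    nucleotide is masked at most once (repeat_bp <= total_bp). Per-class
    columns report both how many regions contain >=1 feature of the
    class (``n_regions_<class>``) and the number of features overlapping
    any region (``n_feats_<class>``).
    """
    from ._util import round_half_up

    by_chrom_class: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for f in repeats:
        by_chrom_class.setdefault(f.chrom, {}).setdefault(f.repeat_class, []).append(
            (f.start, f.end)
        )
    rows = []
    for chrom in sorted(regions):
        ivs = regions[chrom]
        total_bp = sum(e - s + 1 for s, e in ivs)
        all_feats = [
            iv for cls_ivs in by_chrom_class.get(chrom, {}).values() for iv in cls_ivs
        ]
        masked = merge_intervals(all_feats) if all_feats else []
        repeat_bp = sum(intersect_length(iv, masked) for iv in ivs) if masked else 0
        row = {
            "chrom": chrom,
            "n_regions": len(ivs),
            "total_bp": total_bp,
            "repeat_bp": repeat_bp,
            "repeat_pct": round_half_up(100.0 * repeat_bp / total_bp, 1)
            if total_bp
            else 0.0,
        }
        for cls in REPEAT_CLASSES:
            cls_ivs = by_chrom_class.get(chrom, {}).get(cls, [])
            n_regions_with = sum(
                1 for iv in ivs if any(overlaps(iv, f) for f in cls_ivs)
            )
            n_feats = sum(1 for f in cls_ivs if any(overlaps(iv, f) for iv in ivs))
            row[f"n_regions_{cls}"] = n_regions_with
            row[f"n_feats_{cls}"] = n_feats
        rows.append(row)
    return pd.DataFrame(rows).set_index("chrom")
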