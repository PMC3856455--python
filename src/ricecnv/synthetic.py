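"""Synthetic two-channel tiling-array data.

Generates probe layouts over a :class:`~ricecnv.genome.GenomeModel`,
plants copy-number events (losses / gains) into per-sample truth sets,
and simulates noisy two-channel scans with the artifacts the
preprocessing stage is built to remove:

* a smooth additive surface in array grid coordinates (spatial bias),
* a monotone intensity-dependent distortion of the reference channel
  (dye bias),
* i.i.d. Gaussian noise on the log2 ratio.

With all three switched off, per-probe log2 ratios equal the planted
copy ratio inside events and 0 elsewhere, exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .intervals import probes_in_interval

LAYOUT_COLUMNS = ["probe_id", "chrom", "start", "end", "length", "grid_x", "grid_y"]
TRUTH_COLUMNS = ["sample", "chrom", "start", "end", "type", "copy_ratio"]

DEFAULT_LOSS_RATIO = -2.5
DEFAULT_GAIN_RATIO = 1.2

# Base log2-intensity distribution for simulated channels.
_BASE_MEAN = 10.0
_BASE_SD = 1.0


@dataclass(frozen=True)
class ProbeLayout:
    """Ordered probes shared by every sample of a simulated panel.

    ``probes`` columns: probe_id, chrom, start, end (1-based inclusive),
    length, grid_x, grid_y. Sorted by (chrom order, start).
    """

    genome: GenomeModel
    probes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.probes
        missing = [c for c in LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"layout missing columns: {missing}")
        if df["probe_id"].duplicated().any():
            raise ValueError("probe ids must be unique")
        if df.duplicated(subset=["grid_x", "grid_y"]).any():
            raise ValueError("grid coordinates must be unique per probe")

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def chromosome_probes(self, chrom: str) -> pd.DataFrame:
        return self.probes[self.probes["chrom"] == chrom]


@dataclass(frozen=True)
class TruthSet:
    """Planted events: sample, chrom, start, end, type, copy_ratio."""

    events: pd.DataFrame

    def for_sample(self, sample: str) -> pd.DataFrame:
        if self.events.empty:
            return self.events
        return self.events[self.events["sample"] == sample]

    @staticmethod
    def empty() -> "TruthSet":
        return TruthSet(pd.DataFrame(columns=TRUTH_COLUMNS))


@dataclass
class ArrayScan:
    """One sample's per-probe channel intensities and log2 ratios.

    ``probes`` columns: probe_id, test, ref, log2ratio; row order matches
    the layout. ``stage`` records provenance (raw / spatial / normalized).
    """

    sample: str
    probes: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if (self.probes["test"] <= 0).any() or (self.probes["ref"] <= 0).any():
            raise ValueError("channel intensities must be positive")

    @property
    def ratios(self) -> np.ndarray:
        return self.probes["log2ratio"].to_numpy()

    def with_channels(self, test: np.ndarray, ref: np.ndarray, stage: str) -> "ArrayScan":
        df = self.probes.copy()
        df["test"] = test
        df["ref"] = ref
        df["log2ratio"] = np.log2(test / ref)
        return ArrayScan(self.sample, df, stage=stage)


def make_probe_layout(
    genome: GenomeModel, median_spacing_bp: int = 500, seed: int = 0
) -> ProbeLayout:
    """Tile the genome with 50-75-mer probes at jittered spacing.

    Successive probe starts are separated by draws uniform on
    [0.5, 1.5] x ``median_spacing_bp``, so the empirical median gap
    matches the request. Probes are assigned to a square array grid in
    genome order and then shuffled, decoupling genomic and spatial
    neighbourhoods.
    """
    if median_spacing_bp < 100:
        raise ValueError("median_spacing_bp must be >= 100")
    rng = np.random.default_rng(seed)
    rows: list[tuple] = []
    idx = 0
    for chrom, length in genome.chromosomes:
        if length < median_spacing_bp:
            raise ValueError(
                f"chromosome {chrom!r} (length {length}) is shorter than one "
                f"spacing unit ({median_spacing_bp} bp)"
            )
        pos = int(rng.integers(1, median_spacing_bp + 1))
        while True:
            probe_len = int(rng.integers(50, 76))
            end = pos + probe_len - 1
            if end > length:
                break
            rows.append((f"P{idx:07d}", chrom, pos, end, probe_len))
            idx += 1
            gap = rng.uniform(0.5, 1.5) * median_spacing_bp
            pos += int(round(gap))
    n = len(rows)
    side = math.ceil(math.sqrt(n))
    order = rng.permutation(n)
    df = pd.DataFrame(rows, columns=["probe_id", "chrom", "start", "end", "length"])
    df["grid_x"] = order % side
    df["grid_y"] = order // side
    return ProbeLayout(genome, df[LAYOUT_COLUMNS])


def plant_cnvs(
    layout: ProbeLayout,
    n_events_per_sample: int,
    length_range: tuple[int, int] = (1000, 10_000),
    loss_fraction: float = 0.93,
    samples: list[str] | None = None,
    seed: int = 0,
    loss_ratio: float = DEFAULT_LOSS_RATIO,
    gain_ratio: float = DEFAULT_GAIN_RATIO,
    min_probes: int = 1,
    min_separation_bp: int = 5000,
) -> TruthSet:
    """Place disjoint loss/gain events per sample, uniformly over the genome.

    ``loss_fraction`` defaults to 0.93, matching the loss-dominated
    composition typical of stringent two-channel CNV panels. Events are
    rejected and re-drawn until they fit within a chromosome, contain at
    least ``min_probes`` fully-enclosed probes, and keep
    ``min_separation_bp`` clear of the sample's other events.
    """
    lo, hi = length_range
    if lo < 1000:
        raise ValueError("minimum event length must be >= 1000 bp (CNV definition)")
    if not 0.0 <= loss_fraction <= 1.0:
        raise ValueError("loss_fraction must be in [0, 1]")
    if samples is None:
        samples = ["S1"]
    rng = np.random.default_rng(seed)
    chroms = layout.genome.chromosomes
    weights = np.array([length for _, length in chroms], dtype=float)
    weights /= weights.sum()
    starts_by_chrom = {
        chrom: layout.chromosome_probes(chrom)["start"].to_numpy() for chrom, _ in chroms
    }
    ends_by_chrom = {
        chrom: layout.chromosome_probes(chrom)["end"].to_numpy() for chrom, _ in chroms
    }
    rows = []
    for sample in samples:
        placed: dict[str, list[tuple[int, int]]] = {chrom: [] for chrom, _ in chroms}
        for _ in range(n_events_per_sample):
            for _attempt in range(10_000):
                ci = int(rng.choice(len(chroms), p=weights))
                chrom, chrom_len = chroms[ci]
                ev_len = int(rng.integers(lo, hi + 1))
                if ev_len > chrom_len:
                    continue
                start = int(rng.integers(1, chrom_len - ev_len + 2))
                end = start + ev_len - 1
                clear = all(
                    end + min_separation_bp < s or start - min_separation_bp > e
                    for s, e in placed[chrom]
                )
                if not clear:
                    continue
                covered = probes_in_interval(
                    starts_by_chrom[chrom], ends_by_chrom[chrom], (start, end)
                ).sum()
                if covered < max(1, min_probes):
                    continue
                is_loss = rng.random() < loss_fraction
                rows.append(
                    (
                        sample,
                        chrom,
                        start,
                        end,
                        "loss" if is_loss else "gain",
                        loss_ratio if is_loss else gain_ratio,
                    )
                )
                placed[chrom].append((start, end))
                break
            else:
                raise ValueError(
                    "genome too small to place requested events disjointly "
                    f"(sample {sample!r})"
                )
    df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    df = df.sort_values(["sample", "chrom", "start"], kind="stable").reset_index(drop=True)
    return TruthSet(df)


def _spatial_surface(layout: ProbeLayout, spatial_amp: float) -> np.ndarray:
    """Smooth low-order polynomial surface in grid coordinates, mean zero."""
    if spatial_amp == 0:
        return np.zeros(layout.n_probes)
    gx = layout.probes["grid_x"].to_numpy(dtype=float)
    gy = layout.probes["grid_y"].to_numpy(dtype=float)
    u = gx / max(gx.max(), 1.0) - 0.5
    v = gy / max(gy.max(), 1.0) - 0.5
    raw = u + v + 1.5 * u * v + 0.8 * (u**2 - v**2)
    raw -= raw.mean()
    return spatial_amp * raw


def _dye_distortion(base_log2: np.ndarray, strength: float) -> np.ndarray:
    """Monotone intensity-dependent additive term on the reference channel
    (multiplicative on raw intensity)."""
    if strength == 0:
        return np.zeros_like(base_log2)
    return strength * np.tanh((base_log2 - _BASE_MEAN) / 1.5)


def truth_ratio_vector(layout: ProbeLayout, truth: TruthSet, sample: str) -> np.ndarray:
    """Per-probe planted log2 shift: copy ratio inside events, 0 outside.

    A probe counts as inside an event iff fully contained in its span.
    """
    shift = np.zeros(layout.n_probes)
    events = truth.for_sample(sample)
    if events.empty:
        return shift
    starts = layout.probes["start"].to_numpy()
    ends = layout.probes["end"].to_numpy()
    chrom_arr = layout.probes["chrom"].to_numpy()
    for ev in events.itertuples(index=False):
        mask = (chrom_arr == ev.chrom) & probes_in_interval(starts, ends, (ev.start, ev.end))
        shift[mask] = ev.copy_ratio
    return shift


def simulate_scan(
    layout: ProbeLayout,
    truth: TruthSet,
    sample: str,
    noise_sd: float = 0.15,
    spatial_amp: float = 0.0,
    dye_bias_strength: float = 0.0,
    seed: int = 0,
) -> ArrayScan:
    """Simulate one two-channel scan.

    log2(test) = base + planted shift + spatial surface + noise/sqrt(2)
    log2(ref)  = base + dye distortion(base)            + noise/sqrt(2)

    so the log2 ratio is the planted shift plus artifacts plus Gaussian
    noise with standard deviation ``noise_sd``. A sample absent from the
    truth set yields a valid event-free (self-self-like) scan.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = layout.n_probes
    base = rng.normal(_BASE_MEAN, _BASE_SD, n)
    shift = truth_ratio_vector(layout, truth, sample)
    surface = _spatial_surface(layout, spatial_amp)
    per_channel_sd = noise_sd / math.sqrt(2.0)
    e_test = rng.normal(0.0, per_channel_sd, n) if noise_sd > 0 else np.zeros(n)
    e_ref = rng.normal(0.0, per_channel_sd, n) if noise_sd > 0 else np.zeros(n)
    test_log2 = base + shift + surface + e_test
    ref_log2 = base + _dye_distortion(base, dye_bias_strength) + e_ref
    df = pd.DataFrame(
        {
            "probe_id": layout.probes["probe_id"].to_numpy(),
            "test": np.exp2(test_log2),
            "ref": np.exp2(ref_log2),
            "log2ratio": test_log2 - ref_log2,
        }
    )
    return ArrayScan(sample, df, stage="raw")


def simulate_self_self(
    layout: ProbeLayout,
    noise_sd: float = 0.15,
    spatial_amp: float = 0.0,
    dye_bias_strength: float = 0.0,
    seed: int = 0,
    sample: str = "self_self",
) -> ArrayScan:
    """Null scan: both channels from the same DNA, no planted events."""
    return simulate_scan(
        layout,
        TruthSet.empty(),
        sample,
        noise_sd=noise_sd,
        spatial_amp=spatial_amp,
        dye_bias_strength=dye_bias_strength,
        seed=seed,
    )
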