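import numpy as np
import pandas as pd
import pytest

from ricecnv.genome import GenomeModel, default_genome
from ricecnv.synthetic import make_probe_layout, plant_cnvs, simulate_scan


@pytest.fixture(scope="session")
def small_genome() -> GenomeModel:
    return default_genome(n_chromosomes=3, chrom_length=150_000)


@pytest.fixture(scope="session")
def layout(small_genome):
    return make_probe_layout(small_genome, median_spacing_bp=500, seed=11)


@pytest.fixture(scope="session")
def truth(layout):
    return plant_cnvs(
        layout,
        n_events_per_sample=3,
        length_range=(2600, 3500),
        loss_fraction=0.7,
        samples=["A", "B"],
        seed=5,
        min_probes=5,
    )


@pytest.fixture(scope="session")
def noiseless_scan(layout, truth):
    return simulate_scan(layout, truth, "A", noise_sd=0.0, seed=3)


@pytest.fixture(scope="session")
def noisy_scan(layout, truth):
    return simulate_scan(
        layout, truth, "A", noise_sd=0.15, spatial_amp=0.2, dye_bias_strength=0.2, seed=3
    )
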