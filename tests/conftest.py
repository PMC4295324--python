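import pandas as pd
import pytest

from methkin import calls as callsmod
from methkin import simulate
from methkin.config import SimulationConfig

SMALL_CLASS_COUNTS = {
    "protected": 2, "fast": 2, "slow": 2, "pm": 2, "gdmr": 2, "sdmr": 2, "xlinked": 2,
}


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Compact dataset: 3 x 150 kb chromosomes, 2 CGIs per class, 30x depth."""
    return SimulationConfig(
        seed=7,
        n_chromosomes=3,
        chrom_length=150_000,
        n_genes=14,
        n_cgis_per_class=SMALL_CLASS_COUNTS,
        n_te=9,
        mean_depth=30,
    )


@pytest.fixture(scope="session")
def small_artifacts(small_config):
    return simulate.generate_genome(small_config)


@pytest.fixture(scope="session")
def small_data(small_config, small_artifacts):
    return simulate.simulate_methylomes(small_artifacts, small_config)


@pytest.fixture(scope="session")
def small_qc_samples(small_artifacts, small_data) -> dict[str, pd.DataFrame]:
    """Strand-combined, 8x depth-filtered calls per sample."""
    out = {}
    for sid, raw in small_data.samples.items():
        merged, _ = callsmod.combine_strands(raw, small_artifacts.genome)
        out[sid] = callsmod.filter_depth(merged, 8)
    return out
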