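import numpy as np
import pytest

from recmap import pedsim, pipeline


@pytest.fixture(scope="session")
def small_config():
    """One 50 Mb chromosome, 300 markers, 6 families of 8 — a fast
    workload with a couple of hundred meioses."""
    return pedsim.SimConfig(
        chrom_lengths_bp=[50_000_000],
        n_markers_per_chrom=300,
        male_map_cM=[70.0],
        female_map_cM=[90.0],
        n_families=6,
        offspring_per_family=8,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    ped, markers, gm, truth = pipeline.simulate_dataset(small_config)
    return {"ped": ped, "markers": markers, "gm": gm, "truth": truth}


@pytest.fixture(scope="session")
def small_result(small_config):
    return pipeline.run_pipeline(small_config, qc=False)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
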