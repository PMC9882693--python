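import numpy as np
import pandas as pd
import pytest

from brainscape import simulate_cohorts
from brainscape import harmonize as hz
from brainscape.simulate import SimulationConfig, SubtypeSpec


def small_config(seed=1, **overrides) -> SimulationConfig:
    """A fast 3-subtype, 2-cohort scenario for unit tests."""
    defaults = dict(
        n_cohorts=2,
        samples_per_cohort_per_subtype=30,
        n_genes=400,
        subtype_specs=(
            SubtypeSpec("idh_wildtype", 20, 2.0, 1.0, 1.0),
            SubtypeSpec("astrocytoma", 20, 2.0, 3.0, 1.0),
            SubtypeSpec("oligodendroglioma", 20, 2.0, 8.0, 1.0),
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_sim():
    return simulate_cohorts(small_config())


@pytest.fixture(scope="session")
def corrected_small(small_sim):
    """Batch-corrected log2 matrix for the small scenario, with its metadata."""
    matrices, meta, _, truth = small_sim
    logged = [hz.log_transform(hz.fpkm_to_tpm(m)) for m in matrices]
    combined = logged[0].copy_with(
        pd.concat([m.values for m in logged], axis=1), "log2TPM"
    )
    batches = meta.table.loc[combined.sample_ids, "dataset"]
    corrected, report = hz.correct_batch(combined, batches)
    return corrected, meta, truth, report


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
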