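import numpy as np
import pytest

from meioquant import synthgen


@pytest.fixture(scope="session")
def clean_spec():
    """Noiseless render spec at a compact volume for fast tests."""
    return synthgen.RenderSpec(
        shape=(48, 192, 192), background=0.0, shot_noise=False,
        read_noise_sd=0.0, seed=7,
    )


@pytest.fixture(scope="session")
def genotypes():
    return synthgen.default_genotypes()


@pytest.fixture(scope="session")
def sim_cells(genotypes):
    """One simulated cohort renamed to measurement-table columns."""
    tab = synthgen.simulate_cell_table(genotypes, plants_per_genotype=4,
                                       cells_per_plant=40, seed=123)
    return tab.rename(columns={
        "H_true": "accumulation_pct",
        "asynapsis_true": "asy1_length_um",
        "n_prominent_true": "n_prominent",
    })


@pytest.fixture(scope="session")
def rendered_cell(clean_spec):
    """One noiseless rendered cell with known truth (H = 60)."""
    truth = synthgen.CellTruth(
        plant_id="p1", genotype="T", H_true=60.0, asynapsis_true=40.0,
        zyp1_total_true=80.0, n_prominent_true=9, dispersed_fraction_true=0.4,
        n_parallel_true=2, n_irregular_true=1,
    )
    spec = synthgen.RenderSpec(
        shape=(48, 192, 192), background=0.0, shot_noise=False,
        read_noise_sd=0.0, seed=42,
    )
    stack, masks, pre = synthgen.render_cell(truth, spec)
    return truth, stack, masks, pre
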