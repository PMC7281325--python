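import pytest

from phosmark.design import default_design
from phosmark.markers import classify_dataset, compute_signed_fcs
from phosmark.phospho import filter_class1, records_from_frame
from phosmark.synthetic import SimulationConfig, generate_silac_dataset


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, complete dataset: downstream recovery must be exact."""
    return SimulationConfig(
        n_sites=600,
        n_genes=400,
        noise_sd=0.0,
        missing_rate=0.0,
        n_expr_up=5,
        n_expr_down=5,
        n_expr_treatment_only=5,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_dataset(clean_config):
    tables, truth, design = generate_silac_dataset(clean_config)
    return tables, truth, design


@pytest.fixture(scope="session")
def clean_results(clean_dataset):
    tables, truth, design = clean_dataset
    filtered = {tp: filter_class1(records_from_frame(df)) for tp, df in tables.items()}
    return classify_dataset(filtered, design), truth


@pytest.fixture(scope="session")
def noisy_config():
    """Default study conditions at full scale (5000 sites, noise, missingness)."""
    return SimulationConfig(noise_sd=0.05, seed=20260921 % (2**31))


@pytest.fixture(scope="session")
def noisy_fcs(noisy_config):
    tables, truth, design = generate_silac_dataset(noisy_config)
    filtered = {tp: filter_class1(records_from_frame(df)) for tp, df in tables.items()}
    return compute_signed_fcs(filtered, design), truth
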