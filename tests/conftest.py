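import numpy as np
import pandas as pd
import pytest

from serprisk.synthetic_landscape import (
    LandscapeConfig, generate_eas, generate_rasters)


@pytest.fixture(scope="session")
def small_config() -> LandscapeConfig:
    """40x40 grid, 64 EAs, 3 species — fast enough for unit tests."""
    return LandscapeConfig(rng_seed=7, grid_rows=40, grid_cols=40,
                           n_eas=64, n_species=3, n_facilities=5)


@pytest.fixture(scope="session")
def small_rasters(small_config):
    return generate_rasters(small_config)


@pytest.fixture(scope="session")
def small_eas(small_config, small_rasters):
    eas, truth = generate_eas(small_config, small_rasters)
    return eas, truth


@pytest.fixture(scope="session")
def default_config() -> LandscapeConfig:
    return LandscapeConfig(rng_seed=1)


@pytest.fixture(scope="session")
def default_pipeline(default_config):
    """One full default-seed pipeline run, shared across tests."""
    from serprisk.pipeline import run_pipeline
    return run_pipeline(default_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(123)


@pytest.fixture(scope="session")
def table1_registry() -> pd.DataFrame:
    """Registry fixture reproducing the published per-category counts
    (n = 932): age bands, occupation and sex margins."""
    from serprisk.epi_stats import expand_counts
    age = expand_counts({
        "0-9": 116, "10-19": 252, "20-29": 174, "30-39": 135, "40-49": 65,
        "50-59": 45, "60-69": 23, "70-79": 17, "80+": 12, "missing": 93,
    }, "age_band")
    occupation = expand_counts({
        "professionals": 7, "technicians_associate_professionals": 2,
        "clerical_workers": 1, "services_sales_workers": 11,
        "skilled_agricultural_forestry_fishery": 20,
        "craft_related_trades": 14, "plant_machine_operators": 2,
        "elementary_occupations": 65, "armed_forces": 4,
        "unemployed": 212, "student": 327, "self_employed": 13,
        "retiree": 33, "pre_school_child": 53, "unknown": 168,
    }, "occupation")
    sex = expand_counts({"male": 511, "female": 421}, "sex")
    assert len(age) == len(occupation) == len(sex) == 932
    return pd.concat([age, occupation, sex], axis=1)
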