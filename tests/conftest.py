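import numpy as np
import pandas as pd
import pytest

from epimetab.simdata import SimConfig, generate_cohort
from epimetab.workflow import prepare_cohort


@pytest.fixture(scope="session")
def cohort():
    """Small cohort with planted age signal, SNP probes, missingness and QC bait."""
    cfg = SimConfig(
        n_samples=200,
        n_probes=400,
        n_metabolites=8,
        n_age_probes=60,
        n_snp_probes=4,
        cpgs_per_metabolite=4,
        metabolite_noise_sd=0.3,
        probe_missing_rate=0.002,
        n_bad_probes=6,
        n_duplicate_pairs=1,
        n_drug_metabolites=1,
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def prepared(cohort):
    return prepare_cohort(cohort, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def std_frame():
    """Standardise a DataFrame's columns (population SD)."""

    def _std(df: pd.DataFrame) -> pd.DataFrame:
        return (df - df.mean()) / df.std(ddof=0)

    return _std
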