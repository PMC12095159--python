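import numpy as np
import pandas as pd
import pytest

from pwabs.quantify import build_au_matrix
from pwabs.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default desk-scale cohort (18 AD / 8 DLB / 9 CNI, 300 antigens,
    10+10+10 planted at fold 4), seed 1."""
    fluor, subjects, truth = generate_cohort(SimConfig(seed=1))
    return fluor, subjects, truth


@pytest.fixture(scope="session")
def default_au(default_cohort):
    fluor, subjects, truth = default_cohort
    au = build_au_matrix(fluor)
    diagnosis = pd.Series(subjects["diagnosis"].to_numpy(),
                          index=subjects["subject_id"].to_numpy())
    return au, diagnosis, subjects, truth


@pytest.fixture(scope="session")
def strong_signal_cohort():
    """Strong-signal binary task: 10 planted AD drivers among 229 features."""
    cfg = SimConfig(seed=42, n_antigens=229, n_elev_ad_only=10,
                    n_elev_dlb_only=0, n_elev_shared=0)
    fluor, subjects, truth = generate_cohort(cfg)
    au = build_au_matrix(fluor)
    y = (subjects["diagnosis"] == "AD").astype(int).to_numpy()
    return au, y, truth


@pytest.fixture
def rng():
    return np.random.default_rng(0)
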