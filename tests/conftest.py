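import numpy as np
import pandas as pd
import pytest

from mc1rburden import yale_config, generate_cohort
from mc1rburden.spectrum import CONTEXTS96


@pytest.fixture(scope="session")
def small_yale_cohort():
    """One deterministic small Yale-scenario cohort shared across tests."""
    cfg = yale_config(n_samples=60, seed=42)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_spectra(counts: np.ndarray, sample_ids=None) -> pd.DataFrame:
    """Wrap a (samples x 96) count array as a spectra frame."""
    n = counts.shape[0]
    ids = sample_ids or [f"s{i}" for i in range(n)]
    return pd.DataFrame(counts, index=pd.Index(ids, name="sample_id"),
                        columns=list(CONTEXTS96))
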