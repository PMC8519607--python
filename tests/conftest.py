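import numpy as np
import pandas as pd
import pytest

from teanet import AbundanceMatrix, SyntheticConfig, default_config, generate_cohort


@pytest.fixture(scope="session")
def cohort():
    """Default planted cohort, generated once per session."""
    return generate_cohort(default_config(seed=7))


@pytest.fixture()
def tiny_matrix():
    """4 biological + 2 QC samples, 5 positive features."""
    rng = np.random.default_rng(0)
    vals = pd.DataFrame(
        10 ** rng.normal(4, 0.5, size=(6, 5)),
        index=[f"S{i}" for i in range(4)] + ["QC1", "QC2"],
        columns=[f"F{i}" for i in range(5)],
    )
    meta = pd.DataFrame({"is_qc": [False] * 4 + [True] * 2}, index=vals.index)
    return AbundanceMatrix(vals, meta)


def small_config(**kw) -> SyntheticConfig:
    defaults = dict(n_accessions=24, n_features=30, n_genes=8, n_qc=3, seed=0)
    defaults.update(kw)
    return SyntheticConfig(**defaults)
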