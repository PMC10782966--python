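import numpy as np
import pandas as pd
import pytest

from lipidome.preprocess import IntensityMatrix
from lipidome.synthetic import default_lipid_catalog


@pytest.fixture(scope="session")
def catalog194():
    """One shared 194-name catalog; generating it is deterministic."""
    return default_lipid_catalog(194, seed=0)


@pytest.fixture()
def small_matrix():
    """3 lipids x 2 samples, negative mode, raw state."""
    values = pd.DataFrame(
        {"s1": [2.0, 3.0, 5.0], "s2": [4.0, 8.0, 16.0]},
        index=pd.Index(["PG(16:0/18:1)", "PE(16:0/16:1)", "PA(18:1/18:1)"], name="lipid"),
    )
    mode = pd.Series("negative", index=values.index)
    return IntensityMatrix(values, mode, state="raw")


def random_raw_matrix(rng, n_lipids=12, n_samples=5, two_modes=False):
    """Random positive-intensity matrix helper used across tests."""
    neg = ["PG(16:0/18:1)", "PE(16:0/16:1)", "PA(18:1/18:1)", "CL(16:0/16:1/18:1/18:1)"]
    pos = ["PC(16:0/18:1)", "DG(16:0/18:1/0:0)", "TG(16:0/18:1/18:1)", "Cer(d18:1/16:0)"]
    names, modes = [], []
    pool = neg + pos if two_modes else neg
    for i in range(n_lipids):
        base = pool[i % len(pool)]
        names.append(f"{base}_{i}" if i >= len(pool) else base)
        modes.append("positive" if two_modes and base in pos else "negative")
    values = pd.DataFrame(
        rng.lognormal(10, 1, size=(n_lipids, n_samples)),
        index=pd.Index(names, name="lipid"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return IntensityMatrix(values, pd.Series(modes, index=values.index), state="raw")
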