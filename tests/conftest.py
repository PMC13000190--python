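import numpy as np
import pandas as pd
import pytest

from condorlead import synthetic


@pytest.fixture(scope="session")
def small_config():
    return synthetic.SimConfig(n_individuals=15, year_span=(2004, 2010),
                               seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    data = synthetic.generate_dataset(small_config)
    samples, truth = synthetic.generate_blood_samples(data)
    fates = synthetic.generate_fates(data, samples, truth)
    return data, samples, truth, fates


def make_samples(days, values, cid="A"):
    """Samples table from day offsets and values, for rule hand-traces."""
    base = pd.Timestamp("2010-01-01")
    return pd.DataFrame({
        "ID": cid,
        "date": [base + pd.Timedelta(days=int(d)) for d in days],
        "value": np.asarray(values, float),
    })
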