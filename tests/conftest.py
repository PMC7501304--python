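import numpy as np
import pytest

from glassyhrv.io import PipelineConfig
from glassyhrv.preprocess import StandardizedSeries, standardize_values


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_standardized(values, patient_id="p", class_label="UNKNOWN"):
    """Wrap raw values into a StandardizedSeries (standardizing them first)."""
    z, mean, std = standardize_values(np.asarray(values, dtype=float))
    return StandardizedSeries(
        values=z, patient_id=patient_id, class_label=class_label, mean_ms=mean, std_ms=std
    )


@pytest.fixture
def white_series(rng):
    return make_standardized(rng.standard_normal(2000))


@pytest.fixture
def small_config():
    return PipelineConfig(T=5, n_batches=4, batch_size=2, seed=0)
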