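import numpy as np
import pytest

from nirlod import (
    PreprocessOptions,
    SyntheticConfig,
    average_replicates,
    get_profile,
    loocv,
    pls_fit,
    preprocess_chain,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Default benchtop milled calibration campaign (seed 1), averaged."""
    spectra, table = simulate_dataset(SyntheticConfig(seed=1), get_profile("n500"))
    averaged = average_replicates(spectra)
    return spectra, averaged, table


@pytest.fixture(scope="session")
def fitted_default(default_dataset):
    """CV, pretreated matrix and fitted model (no OSC) for the default data."""
    _, averaged, table = default_dataset
    y = table.y("vitexin")
    cv = loocv(averaged.absorbance, y, 8)
    X, record = preprocess_chain(averaged.absorbance, y)
    model = pls_fit(X, y, cv.chosen_A)
    model.pretreatment = record
    return {"averaged": averaged, "y": y, "cv": cv, "X": X, "model": model,
            "record": record}


@pytest.fixture(scope="session")
def fitted_default_osc(default_dataset):
    """Same as fitted_default but with single-component OSC in the chain."""
    _, averaged, table = default_dataset
    y = table.y("vitexin")
    opts = PreprocessOptions(osc=True)
    cv = loocv(averaged.absorbance, y, 8, opts)
    X, record = preprocess_chain(averaged.absorbance, y, opts)
    model = pls_fit(X, y, cv.chosen_A)
    model.pretreatment = record
    return {"averaged": averaged, "y": y, "cv": cv, "X": X, "model": model,
            "record": record, "options": opts}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
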