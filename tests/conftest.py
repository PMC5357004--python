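import numpy as np
import pytest

import venomscan as v


@pytest.fixture(scope="session")
def default_study():
    """The default synthetic study (seed 42): 30 precursors, 6 families,
    4 pseudo-species, 20x depth, 0.5% substitution errors, 200 spectra."""
    return v.generate_study()


@pytest.fixture(scope="session")
def default_library(default_study):
    return v.build_library(default_study.reference_db)


@pytest.fixture(scope="session")
def default_run(default_study, default_library):
    result = v.run_study(default_study, library=default_library)
    metrics = v.evaluate_study(default_study, result)
    return default_study, result, metrics


@pytest.fixture(scope="session")
def noiseless_run():
    """A smaller error-free replicate: no sequencing errors, no rRNA or
    carry-over contamination, noise-free spectra."""
    config = v.default_config(
        toxins_per_family=3,
        error_rate=0.0,
        rrna_fraction=0.0,
        carryover_fraction=0.0,
        spectrum_noise_peaks=0,
        n_spectra=90,
        seed=7,
    )
    study = v.generate_study(config)
    result = v.run_study(study)
    metrics = v.evaluate_study(study, result)
    return study, result, metrics


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
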