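import warnings

import pytest

from colinshift import CCSPAnalysis, SyntheticConfig, generate_peaklists
from colinshift.io import assemble_series


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic dataset: 59 residues, 24 complexes, noise 0.0051."""
    config = SyntheticConfig(seed=11)
    free, ref, complexes, truth = generate_peaklists(config)
    return config, free, ref, complexes, truth


@pytest.fixture(scope="session")
def default_results(default_dataset):
    """Fitted CCSP analysis of the default dataset (no per-cell MC errors)."""
    _, free, ref, complexes, _ = default_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        series, _ = assemble_series(free, ref, complexes)
        model = CCSPAnalysis(series)
        return model, model.fit(errors="none")
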