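import dataclasses

import pytest

from protectomics.normalize import normalize_experiment
from protectomics.synthetic import default_config, generate_experiment


@pytest.fixture(scope="session")
def small_config():
    """A 60-gene default-noise experiment with planted regulation."""
    return default_config(seed=7, n_genes=60, panel_genes=False)


@pytest.fixture(scope="session")
def small_experiment(small_config):
    return generate_experiment(small_config)


@pytest.fixture(scope="session")
def small_matrix(small_experiment):
    spots, design, _ = small_experiment
    em, n_iter, delta = normalize_experiment(spots, design)
    return em


@pytest.fixture(scope="session")
def noiseless_experiment():
    """No planted effects, no noise, no label bias: downstream expression
    ratios must be exactly 1 for every quantifiable gene."""
    cfg = dataclasses.replace(
        default_config(seed=3, n_genes=40, panel_genes=False),
        planted_regulation=(),
        technical_cv=0.0,
        biological_cv_range=(0.0, 0.0),
        label_bias_factors=(1.0, 1.0),
        invalid_spot_fraction=0.0,
        expression_log_mean_range=(5.0, 8.0),
    )
    return generate_experiment(cfg)
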