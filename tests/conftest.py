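import numpy as np
import pandas as pd
import pytest

from tfap import synthetic as syn


@pytest.fixture
def small_config():
    return syn.SimulationConfig(
        n_tfs=6,
        n_genes=60,
        n_animals_per_group=4,
        n_drivers=2,
        battery_size=3,
        regulon_size=5,
        effect_log2fc=0.5,
        seed=7,
    )


@pytest.fixture
def small_truth(small_config):
    return syn.make_truth(small_config)


@pytest.fixture
def noiseless_config():
    return syn.SimulationConfig(
        n_tfs=6,
        n_genes=60,
        n_animals_per_group=4,
        n_drivers=2,
        battery_size=3,
        regulon_size=5,
        effect_log2fc=0.5,
        integer_counts=False,
        seed=11,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def measurements_fixture():
    """Two experiments, one TF each, with known control / treated ratios."""
    return pd.DataFrame(
        {
            "animal_id": ["c1", "c2", "t1", "c3", "t2"],
            "experiment_id": ["e0", "e0", "e0", "e1", "e1"],
            "tf_id": ["TF_A", "TF_A", "TF_A", "TF_B", "TF_B"],
            "reporter_copies": [200.0, 200.0, 400.0, 300.0, 150.0],
            "reference_copies": [100.0, 100.0, 100.0, 100.0, 100.0],
            "raw_activity": [2.0, 2.0, 4.0, 3.0, 1.5],
        }
    )


@pytest.fixture
def group_labels_fixture():
    return {
        "c1": "control",
        "c2": "control",
        "c3": "control",
        "t1": "susceptible",
        "t2": "susceptible",
    }
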