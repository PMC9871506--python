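import dataclasses

import pytest

from canopydx import (
    generate_feature_dataset,
    generate_scene,
    pool_pk_labels,
    reference_config,
    repeated_evaluation,
    screen_features,
)

SEED = 11


@pytest.fixture(scope="session")
def config():
    return reference_config()


@pytest.fixture(scope="session")
def small_config(config):
    """Reduced pot count for scene-rendering tests."""
    return dataclasses.replace(config, n_per_class=4)


@pytest.fixture(scope="session")
def small_scene(small_config):
    return generate_scene(small_config, day=38, agl=5.0, seed=SEED)


@pytest.fixture(scope="session")
def day38_table(config):
    """Full-size late-stress feature table (48 pots per treatment class)."""
    return generate_feature_dataset(config, days=[38], agl=5.0, seed=SEED)


@pytest.fixture(scope="session")
def day38_pooled(day38_table):
    return pool_pk_labels(day38_table)


@pytest.fixture(scope="session")
def day38_screening(day38_pooled):
    return screen_features(day38_pooled)


@pytest.fixture(scope="session")
def day38_lr_report(day38_pooled, day38_screening):
    """LR pipeline averaged over ten 7:3 splits on the late-stress table."""
    return repeated_evaluation(
        day38_pooled,
        algorithm="LR",
        n_repeats=10,
        base_seed=SEED,
        features=day38_screening.selected,
    )
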