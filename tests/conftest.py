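import warnings

import numpy as np
import pandas as pd
import pytest

from gcoupler.classify import TrainingConfig
from gcoupler.pipeline import train_models
from gcoupler.synthetic import (
    Determinant,
    FamilySpec,
    LoopLengthEffect,
    generate_family,
)

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


def small_spec(seed: int = 11, **overrides) -> FamilySpec:
    """A compact two-Gα family used across the integration tests."""
    defaults = dict(
        n_receptors=80,
        n_consensus_columns=44,
        determinants=(
            Determinant(column=6, residue="W", effect_size=1.0, galpha="GNAS"),
            Determinant(column=20, residue="K", effect_size=1.0, galpha="GNAS"),
            Determinant(column=12, residue="D", effect_size=1.0, galpha="GNAI1"),
            Determinant(column=33, residue="F", effect_size=1.0, galpha="GNAI1"),
        ),
        loop_length_effect=LoopLengthEffect("GNAS", 24.0, 8.0),
        seed=seed,
    )
    defaults.update(overrides)
    return FamilySpec(**defaults)


@pytest.fixture(scope="session")
def family():
    return generate_family(small_spec())


@pytest.fixture(scope="session")
def trained(family):
    """Per-Gα models trained on the small family (shared; treat as read-only)."""
    config = TrainingConfig(n_repeats=2, seed=5)
    models, report = train_models(
        family.rows, family.labels, family.region_map, config
    )
    return models, report, family


@pytest.fixture
def rng():
    return np.random.default_rng(202406)
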