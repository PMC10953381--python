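"""Shared fixtures: small seeded compendia and hand-built tables."""

import numpy as np
import pandas as pd
import pytest

from loadsense import CompendiumConfig, ExpressionMatrix, generate_compendium


SMALL_CONFIG = dict(
    n_genes=100,
    n_studies=4,
    samples_per_study=15,
    n_reference_per_study=2,
    n_loadstress_samples=20,
    planted_genes=(0, 1),
    effect_size=2.0,
    batch_sd=1.0,
    noise_sd=0.5,
    n_gene_sets=10,
    n_imodulons=6,
)


@pytest.fixture(scope="session")
def small_compendium():
    """60-sample, 100-gene compendium with two planted genes at 4x noise sd."""
    return generate_compendium(CompendiumConfig(seed=11, **SMALL_CONFIG))


@pytest.fixture
def tiny_expression():
    """3 genes x 5 samples over two studies, values chosen by hand."""
    data = pd.DataFrame(
        {
            "a1": [2.0, 1.0, 0.0],
            "a2": [4.0, 1.0, 2.0],
            "a3": [5.0, 3.0, 1.0],
            "b1": [1.0, 2.0, 3.0],
            "b2": [3.0, 0.0, 1.0],
        },
        index=["g1", "g2", "g3"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def tiny_samples():
    return pd.DataFrame(
        {
            "sample_id": ["a1", "a2", "a3", "b1", "b2"],
            "study_id": ["A", "A", "A", "B", "B"],
            "condition": ["control", "control", "load_stress", "control", "env"],
            "is_reference": [True, True, False, True, False],
            "is_loadstress": [False, False, True, False, False],
            "growth_rate": [np.nan] * 5,
        }
    )
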