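"""Shared fixtures: small synthetic worlds and pre-trained ensembles.

Everything is generated programmatically and seeded; the heavier trained
models are session-scoped so the suite trains them once.
"""

from __future__ import annotations

import dataclasses

import pytest
from hypothesis import settings

import clltim as ct
from clltim.features import FeatureMatrix

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=25)
settings.load_profile("suite")


SMALL_PANEL = ct.default_lab_panel()[:6]


def small_spec(seed: int, n: int, preset: str = "research") -> ct.CohortSpec:
    """A research/deployment-preset spec shrunk to a 6-lab panel."""
    base = (ct.research_preset if preset == "research" else ct.deployment_preset)(
        n, seed=seed
    )
    return dataclasses.replace(base, lab_panel=SMALL_PANEL)


SMALL_CONFIG = ct.EnsembleConfig(
    n_boosted=2, n_random_forest=1, n_extra_trees=1, n_elastic_net=1,
    n_logistic=1, n_treatment=1, n_infection=1, seed=0,
)


def featurize_cohort(cohort, registry):
    matrix = ct.extract_features(cohort, registry)
    labels = ct.training_labels(cohort)
    common = matrix.values.index.intersection(labels.index)
    return (
        FeatureMatrix(matrix.values.loc[common], matrix.registry),
        labels.loc[common],
        matrix,
    )


@pytest.fixture(scope="session")
def small_registry():
    return ct.default_registry([lab.name for lab in SMALL_PANEL])


@pytest.fixture(scope="session")
def small_world(small_registry):
    """A 150-patient research-style cohort with its feature matrix/labels."""
    cohort = ct.generate_cohort(small_spec(seed=11, n=150))
    train_matrix, labels, full_matrix = featurize_cohort(cohort, small_registry)
    return {
        "cohort": cohort,
        "matrix": train_matrix,
        "labels": labels,
        "full_matrix": full_matrix,
    }


@pytest.fixture(scope="session")
def small_model(small_world):
    """A 7-learner ensemble trained on the small world (one per family plus
    outcome-specific members)."""
    return ct.train_ensemble(small_world["matrix"], small_world["labels"],
                             SMALL_CONFIG)
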