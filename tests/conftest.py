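"""Shared fixtures: seeded synthetic screens and trained twin models.

The heavier fixtures (trained models) are session-scoped and reused by the
evaluation, stress-test and acceptance tests so each model is trained once.
"""

from __future__ import annotations

import numpy as np
import pytest

from phenotwin.activity_filter import label_wells, train_activity_classifier
from phenotwin.metric_models import build_twin_model, reduced_twin_config, train
from phenotwin.pair_builder import build_pair_dataset
from phenotwin.synthetic_data import SimConfig, generate_screen

#: canonical desk-scale benchmark: 24 pseudo-drugs x 8 replicates, 8 classes,
#: 5,000-frame traces, randomized layout
BENCH = dict(n_plates=8, n_drugs=24, replicates_per_drug=(8, 8),
             n_phenotype_classes=8, inactive_fraction=0.0, trace_length=5000,
             layout_mode="randomized", seed=0)

#: shortcut-learning conditions: subtle phenotypes + strong positional artifact
SHORTCUT = dict(n_plates=8, n_drugs=24, replicates_per_drug=(8, 8),
                n_phenotype_classes=8, inactive_fraction=0.0, trace_length=5000,
                class_separation=0.4, artifact_amplitude=400.0, seed=0)

#: null-control conditions: enough drugs that the held-out drug-drug pair set
#: exceeds 1,000 pairs
NULL = dict(n_plates=9, n_drugs=84, replicates_per_drug=(9, 9),
            n_phenotype_classes=8, inactive_fraction=0.0, trace_length=5000,
            layout_mode="randomized", seed=0)


def _screen_with_pairs(sim_kwargs, rf_mode="binary"):
    cfg = SimConfig(**sim_kwargs)
    dataset, gt = generate_screen(cfg)
    rf = train_activity_classifier(dataset, mode=rf_mode, seed=cfg.seed, n_trees=100)
    labels = label_wells(rf, dataset)
    pairs = build_pair_dataset(dataset, labels, seed=cfg.seed)
    return dataset, gt, labels, pairs


def _train_reduced(dataset, pairs, **cfg_overrides):
    model = build_twin_model(reduced_twin_config(seed=0, **cfg_overrides))
    return train(model, pairs, dataset.traces)


@pytest.fixture(scope="session")
def bench_screen():
    """(dataset, ground truth, activity labels, pair dataset) at benchmark scale."""
    return _screen_with_pairs(BENCH)


@pytest.fixture(scope="session")
def bench_model(bench_screen):
    dataset, _, _, pairs = bench_screen
    return _train_reduced(dataset, pairs)


@pytest.fixture(scope="session")
def shortcut_fixed():
    """Fixed-layout screen with planted artifact + model trained on it."""
    data = _screen_with_pairs({**SHORTCUT, "layout_mode": "fixed"})
    model = _train_reduced(data[0], data[3])
    return (*data, model)


@pytest.fixture(scope="session")
def shortcut_randomized():
    """Randomized-layout counterpart of the shortcut screen + its model."""
    data = _screen_with_pairs({**SHORTCUT, "layout_mode": "randomized"})
    model = _train_reduced(data[0], data[3])
    return (*data, model)


@pytest.fixture(scope="session")
def null_screen():
    """Large artifact-free screen + pairs for the null-control battery."""
    return _screen_with_pairs(NULL)


@pytest.fixture(scope="session")
def null_model_config():
    """Shortened training schedule for retrain-from-scratch null tests."""
    return reduced_twin_config(seed=0, max_epochs=60, patience=15)


@pytest.fixture(scope="session")
def library_screen():
    """Separately 'screened' compound library sharing the benchmark screen's
    phenotype classes (template_seed) but with new drugs, layout and noise."""
    cfg = SimConfig(n_plates=8, n_drugs=40, replicates_per_drug=(8, 8),
                    n_phenotype_classes=8, inactive_fraction=0.0,
                    trace_length=5000, layout_mode="randomized",
                    seed=11, template_seed=0)
    return generate_screen(cfg)


@pytest.fixture(scope="session")
def scaffold_screen():
    """Library for the scaffold-hopping scenario: 4 classes (6 drugs each)
    shared with the benchmark templates; class 0 is split between two
    disjoint structural families by the analysis fixtures."""
    cfg = SimConfig(n_plates=8, n_drugs=24, replicates_per_drug=(8, 8),
                    n_phenotype_classes=4, inactive_fraction=0.0,
                    trace_length=5000, layout_mode="randomized",
                    seed=12, template_seed=0)
    return generate_screen(cfg)


@pytest.fixture(scope="session")
def tiny_screen():
    """Small cheap screen for unit tests that need realistic structure."""
    cfg = SimConfig(n_plates=4, n_drugs=12, replicates_per_drug=(4, 4),
                    n_phenotype_classes=4, inactive_fraction=0.25,
                    trace_length=1000, layout_mode="randomized", seed=7)
    return generate_screen(cfg)


@pytest.fixture(scope="session")
def tiny_trained():
    """Very small trained twin model for API-level tests (seconds)."""
    cfg = SimConfig(n_plates=4, n_drugs=12, replicates_per_drug=(4, 4),
                    n_phenotype_classes=4, inactive_fraction=0.0,
                    trace_length=1000, layout_mode="randomized", seed=7)
    dataset, gt = generate_screen(cfg)
    labels = {w: "active" for w in dataset.wells["well_id"]}
    pairs = build_pair_dataset(dataset, labels, seed=7)
    model = build_twin_model(reduced_twin_config(
        seed=7, input_length=200, hidden_widths=(100, 50), embedding_dim=8,
        max_epochs=20, patience=8))
    train(model, pairs, dataset.traces)
    return dataset, gt, pairs, model
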