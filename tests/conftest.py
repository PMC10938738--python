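"""Shared fixtures: one small simulated registry carried through every
pipeline stage, so unit tests across modules exercise consistent data."""

import logging

import pytest

import rxrisk as rx

logging.getLogger("rxrisk").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def mapping():
    return rx.default_mapping()


@pytest.fixture(scope="session")
def small_config():
    return rx.SimulationConfig(n_persons=3000, seed=11)


@pytest.fixture(scope="session")
def registry(small_config):
    return rx.simulate_population(small_config)


@pytest.fixture(scope="session")
def category_sets(registry, mapping):
    _, dispensings, _ = registry
    return rx.assign_categories(dispensings, mapping)


@pytest.fixture(scope="session")
def weights(category_sets, registry):
    persons = registry[0]
    years = sorted(category_sets["year"].unique())
    cats = sorted(category_sets["category_id"].dropna().unique())
    return rx.calibrate_weights_range(category_sets, persons, years, cats)


@pytest.fixture(scope="session")
def scores(category_sets, weights):
    return rx.compute_scores(category_sets, weights)


@pytest.fixture(scope="session")
def slices(registry, scores):
    persons, dispensings, fractures = registry
    eligible = rx.apply_washout(persons, fractures)
    eligible = rx.require_dispensing(eligible, dispensings)
    return rx.build_slices(eligible, scores, fractures)


@pytest.fixture(scope="session")
def medium_slices_bundle():
    """Larger cohort for model recovery checks; built once per session."""
    cfg = rx.SimulationConfig(n_persons=30_000, seed=17)
    persons, dispensings, fractures = rx.simulate_population(cfg)
    sets = rx.assign_categories(dispensings, rx.default_mapping())
    years = sorted(sets["year"].unique())
    cats = sorted(sets["category_id"].dropna().unique())
    weights = rx.calibrate_weights_range(sets, persons, years, cats)
    scores = rx.compute_scores(sets, weights)
    eligible = rx.require_dispensing(rx.apply_washout(persons, fractures), dispensings)
    slices = rx.build_slices(eligible, scores, fractures)
    return {
        "config": cfg,
        "persons": persons,
        "dispensings": dispensings,
        "fractures": fractures,
        "category_sets": sets,
        "weights": weights,
        "scores": scores,
        "slices": slices,
    }
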