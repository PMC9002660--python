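"""Shared fixtures: synthetic planted-domain databases and libraries.

The heavyweight objects (profile databases, full pipeline runs) are
session-scoped so the suite builds them once.
"""

import pytest

from ltrsort import (
    FixtureSpec,
    PipelineConfig,
    generate_database,
    generate_library,
    run_pipeline,
)


@pytest.fixture(scope="session")
def default_spec():
    """The reference study conditions: 4 Copia + 4 Gypsy clades, 10 elements
    per clade, zero mutation, seed 42."""
    return FixtureSpec()


@pytest.fixture(scope="session")
def default_db(default_spec):
    db, ancestors = generate_database(default_spec)
    return db, ancestors


@pytest.fixture(scope="session")
def default_library(default_spec, default_db):
    _, ancestors = default_db
    return generate_library(default_spec, ancestors)


@pytest.fixture(scope="session")
def default_run(default_db, default_library):
    db, _ = default_db
    records, truth = default_library
    result = run_pipeline(records, db, PipelineConfig())
    return result, records, truth


@pytest.fixture(scope="session")
def small_spec():
    """A cheap two-clade library that exercises domain loss and rescue."""
    return FixtureSpec(
        seed=7,
        clades=(("Copia", "Ale"), ("Gypsy", "CRM")),
        n_elements_per_clade=5,
        substitution_rate=0.05,
        nonautonomous_fraction=0.4,
    )


@pytest.fixture(scope="session")
def small_db(small_spec):
    db, ancestors = generate_database(small_spec)
    return db, ancestors


@pytest.fixture(scope="session")
def small_library(small_spec, small_db):
    _, ancestors = small_db
    return generate_library(small_spec, ancestors)
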