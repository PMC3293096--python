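from __future__ import annotations

import pytest
from hypothesis import settings

from cellvocab import (
    StudyDesign,
    TableRow,
    VocabularyTable,
    build_tree,
    generate_study_fixture,
    load_fixture_into_catalog,
)

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def toy_table() -> VocabularyTable:
    """A hand-sized vocabulary covering all four root terms."""
    rows = [
        TableRow(("study", "personnel"), "investigator", "M. Reyes"),
        TableRow(("study",), "title", "toy study"),
        TableRow(("cell",), "cell_line", "A10"),
        TableRow(
            ("cell", "history", "maintenance_culture", "passaging"),
            "plating_density",
            "800 cells/cm2",
        ),
        TableRow(("assay", "image series details"), "collection basis", ""),
        TableRow(("assay", "datatype"), "derived", ""),
        TableRow(("instrument", "microscope"), "model", "inverted stand"),
    ]
    return VocabularyTable(rows)


@pytest.fixture
def toy_tree(toy_table):
    return build_tree(toy_table, on_collision="error")


@pytest.fixture
def small_design() -> StudyDesign:
    """A scaled-down design for fast end-to-end tests."""
    return StudyDesign(
        wells_per_type=2,
        fields_per_well=3,
        imaging_conditions=2,
        masks_per_type=4,
        benchmark_counts=(1, 1, 1),
        seed=7,
    )


@pytest.fixture
def small_catalog(small_design):
    return load_fixture_into_catalog(generate_study_fixture(small_design))


@pytest.fixture(scope="session")
def default_fixture():
    """The full default study design (generated once per test session)."""
    return generate_study_fixture(StudyDesign())


@pytest.fixture(scope="session")
def default_catalog(default_fixture):
    return load_fixture_into_catalog(default_fixture)
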