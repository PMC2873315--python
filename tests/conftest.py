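"""Shared fixtures: the Dictyostelium case study, computed once per session."""

import pytest

from discrimdesign import (
    dictyostelium_difference_system,
    dictyostelium_fixture,
    frequency_peak,
    l2_gain_bound,
    linearize,
    observability_gramian,
    storage_for_ic_design,
    storage_structural,
    structural_chart,
)


@pytest.fixture(scope="session")
def models():
    return dictyostelium_fixture()


@pytest.fixture(scope="session")
def models_struct():
    return dictyostelium_fixture("structural_design")


@pytest.fixture(scope="session")
def ds():
    return dictyostelium_difference_system()


@pytest.fixture(scope="session")
def lin(ds):
    return linearize(ds)


@pytest.fixture(scope="session")
def gramian(lin):
    return observability_gramian(lin)


@pytest.fixture(scope="session")
def fp_full(lin):
    return frequency_peak(lin)


@pytest.fixture(scope="session")
def fp_rstar(lin):
    return frequency_peak(lin, output_selector=[2])


@pytest.fixture(scope="session")
def ic_storage(ds):
    return storage_for_ic_design(ds)


@pytest.fixture(scope="session")
def gain_cert(ds):
    return l2_gain_bound(ds)


@pytest.fixture(scope="session")
def chart():
    return structural_chart()


@pytest.fixture(scope="session")
def struct_cert(models_struct, chart):
    return storage_structural(models_struct, chart)
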