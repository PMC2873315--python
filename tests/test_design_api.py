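"""High-level design workflows: reports, rankings, and invariants."""

import json

import numpy as np
import pytest

from discrimdesign import (
    DegenerateDesignError,
    DesignReport,
    design_initial_condition,
    design_input,
    design_structural,
)


@pytest.fixture(scope="module")
def ic_report(models):
    m1, m2 = models
    return design_initial_condition(m1, m2, method="all")


@pytest.fixture(scope="module")
def input_report(models):
    m1, m2 = models
    return design_input(m1, m2)


@pytest.fixture(scope="module")
def struct_report(models_struct):
    m1, m2 = models_struct
    return design_structural(
        m1,
        m2,
        method="brute",
        param_grid=3,
        dir_grid=20,
        steady_state_guess=[0.3, 2.0, 0.5],
    )


class TestInitialConditionDesign:
    def test_all_routes_agree_on_first_axis(self, ic_report):
        assert ic_report.design == "initial_condition"
        assert ic_report.method == "combined"
        assert abs(ic_report.chosen["direction"][0]) > 0.99
        assert ic_report.simulated_value == pytest.approx(0.729, abs=0.005)
        align = ic_report.diagnostics["direction_alignment"]
        assert all(v > 0.999 for v in align.values())
        assert {c["route"] for c in ic_report.candidates} == {"linear", "sos", "brute"}

    def test_beta_scaling_linear_regime(self, models):
        m1, m2 = models
        rep = design_initial_condition(m1, m2, beta=0.01, method="linear")
        lam = rep.predictions["gramian_eigenvalue"]
        assert rep.simulated_value == pytest.approx(0.01 * np.sqrt(lam), rel=1e-3)

    def test_contained_sos_bound_holds(self, models):
        m1, m2 = models
        rep = design_initial_condition(m1, m2, beta=0.05, method="sos")
        chk = rep.diagnostics["storage_bound_check"]
        assert chk["holds"]
        assert rep.simulated_value <= chk["bound"] + 1e-6

    def test_identical_models_degenerate(self, models):
        m1, _ = models
        with pytest.raises(DegenerateDesignError):
            design_initial_condition(m1, m1, method="brute", grid_size=10)

    def test_invalid_arguments(self, models):
        m1, m2 = models
        with pytest.raises(ValueError):
            design_initial_condition(m1, m2, beta=0.0)
        with pytest.raises(ValueError):
            design_initial_condition(m1, m2, method="telepathy")


class TestInputDesign:
    def test_sine_wins_and_ranking_holds(self, input_report):
        assert input_report.chosen["kind"] == "sine"
        order = [c["kind"] for c in input_report.candidates]
        assert order == ["sine", "square", "sinc", "constant"]
        assert input_report.simulated_value == pytest.approx(0.472, abs=0.005)

    def test_critical_frequency_recorded(self, input_report, fp_full):
        assert input_report.predictions["critical_frequency"] == pytest.approx(
            fp_full.omega0, abs=1e-9
        )
        # the linear gain bound caps every nonlinear unit-energy candidate
        for c in input_report.candidates:
            assert c["simulated_value"] <= input_report.predictions["linear_value_bound"] + 5e-3

    def test_zero_energy_all_silent(self, models):
        m1, m2 = models
        rep = design_input(m1, m2, energy=0.0)
        assert rep.simulated_value == 0.0
        assert all(c["simulated_value"] == 0.0 for c in rep.candidates)

    def test_invalid_arguments(self, models):
        m1, m2 = models
        with pytest.raises(ValueError):
            design_input(m1, m2, candidate_kinds=())
        with pytest.raises(ValueError):
            design_input(m1, m2, T_active=-1.0)


class TestStructuralDesign:
    def test_brute_route_finds_box_corner(self, struct_report):
        assert struct_report.design == "structural"
        p = struct_report.chosen["params"]
        assert p["RT"] == pytest.approx(3.0)
        assert p["kr"] == pytest.approx(1.5)
        assert abs(struct_report.chosen["direction"][0]) > 0.99
        assert struct_report.simulated_value == pytest.approx(0.747, abs=0.005)

    def test_structural_beats_plain_ic(self, struct_report, ic_report):
        # widening the design space can only improve the optimum
        assert struct_report.simulated_value >= ic_report.simulated_value - 1e-9

    def test_degenerate_box_reduces_to_ic(self, models_struct):
        m1, m2 = models_struct
        rep = design_structural(
            m1,
            m2,
            param_box={"kr": (1.0, 1.0)},
            method="brute",
            steady_state_guess=[0.3, 2.0, 0.5],
        )
        assert rep.design == "structural"
        assert rep.diagnostics["degenerate_box"]
        assert rep.chosen["params"] == {"kr": 1.0}
        assert abs(rep.chosen["direction"][0]) > 0.99

    def test_empty_box_rejected(self, models_struct):
        m1, m2 = models_struct
        with pytest.raises(ValueError):
            design_structural(m1, m2, param_box={})


class TestReports:
    def test_json_round_trip(self, ic_report, input_report, struct_report):
        for rep in (ic_report, input_report, struct_report):
            doc = json.loads(rep.to_json())
            assert doc["design"] == rep.design
            assert doc["simulated_value"] == pytest.approx(rep.simulated_value)
            assert isinstance(doc["config"]["timestamp"], str)

    def test_reproducible(self, models):
        m1, m2 = models
        r1 = design_initial_condition(m1, m2, method="linear")
        r2 = design_initial_condition(m1, m2, method="linear")
        assert r1.simulated_value == pytest.approx(r2.simulated_value, abs=1e-9)
        assert r1.chosen["direction"] == r2.chosen["direction"]
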