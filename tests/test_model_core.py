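"""Model parsing, steady states, and the concatenated difference system."""

import numpy as np
import pytest

from discrimdesign import (
    DegenerateDesignError,
    DimensionError,
    ModelSpecError,
    ParamBox,
    compute_steady_state,
    concatenate_models,
    dictyostelium_fixture,
    parse_model_spec,
    simulate_difference_system,
)

GUESS = [0.3, 2.0, 0.1]


def minimal_doc():
    return {
        "states": ["x"],
        "params": {"k": 1.0},
        "drift": ["-k*x"],
        "input_map": [["1"]],
        "output_map": ["x"],
        "basal_input": [0.0],
    }


class TestParsing:
    def test_roundtrip(self):
        m = parse_model_spec(minimal_doc())
        assert m.n == 1 and m.q == 1 and m.ell == 1
        again = parse_model_spec(m.to_document())
        assert again.to_document() == m.to_document()

    def test_missing_key_rejected(self):
        doc = minimal_doc()
        del doc["drift"]
        with pytest.raises(ModelSpecError, match="drift"):
            parse_model_spec(doc)

    def test_duplicate_states_rejected(self):
        doc = minimal_doc()
        doc["states"] = ["x", "x"]
        with pytest.raises(ModelSpecError, match="duplicate"):
            parse_model_spec(doc)

    def test_undeclared_symbol_rejected(self):
        doc = minimal_doc()
        doc["drift"] = ["-k*y"]
        with pytest.raises(ModelSpecError):
            parse_model_spec(doc)

    def test_param_range_becomes_box(self):
        doc = minimal_doc()
        doc["params"] = {"k": {"value": 1.0, "range": [0.5, 2.0]}}
        m = parse_model_spec(doc)
        assert m.param_boxes.intervals["k"] == (0.5, 2.0)
        assert m.param_values["k"] == 1.0

    def test_yaml_string_accepted(self):
        text = """
states: [x]
params: {k: 2.0}
drift: ["-k*x"]
input_map: [["1"]]
output_map: [x]
basal_input: [0.0]
"""
        m = parse_model_spec(text)
        assert m.param_values["k"] == 2.0


class TestParamBox:
    def test_contains_and_degenerate(self):
        box = ParamBox({"a": (0.0, 1.0), "b": (2.0, 2.0)})
        assert box.contains_point({"a": 0.5, "b": 2.0})
        assert not box.contains_point({"a": 1.5})
        assert not box.is_degenerate()
        assert ParamBox({"b": (2.0, 2.0)}).is_degenerate()

    def test_invalid_interval_rejected(self):
        with pytest.raises((ModelSpecError, ValueError)):
            ParamBox({"a": (1.0, 0.0)})

    def test_sample_inside(self):
        box = ParamBox({"a": (0.0, 1.0)})
        rng = np.random.default_rng(0)
        assert all(box.contains_point(p) for p in box.sample(rng, 10))


class TestSteadyState:
    def test_shared_dictyostelium_steady_state(self, models):
        m1, m2 = models
        for m in (m1, m2):
            s = compute_steady_state(m, initial_guess=GUESS)
            assert np.allclose(s.steady_state, [0.3, 2.0, 0.1], atol=1e-9)
            assert np.max(np.real(np.linalg.eigvals(s.jacobian))) < 0

    def test_shifted_drift_vanishes_at_origin(self, models):
        s = compute_steady_state(models[0], initial_guess=GUESS)
        assert np.allclose(s.f(np.zeros(3)), 0.0, atol=1e-12)

    def test_basal_input_dimension_checked(self, models):
        with pytest.raises(DimensionError):
            compute_steady_state(models[0], basal_input=[0.2, 0.1], initial_guess=GUESS)


class TestDifferenceSystem:
    def test_dimensions_and_output(self, ds):
        assert ds.n1 == ds.n2 == 3 and ds.n == 6 and ds.ell == 3
        x = np.arange(6, dtype=float) * 0.01
        y = ds.output(x)
        assert y.shape == (3,)

    def test_identical_models_zero_output(self, models):
        m1, _ = models
        s = compute_steady_state(m1, initial_guess=GUESS)
        ds_same = concatenate_models(s, s)
        traj = simulate_difference_system(ds_same, common_ic=[1.0, 0.0, 0.0], store=False)
        assert traj.l2_norm < 1e-9

    def test_polynomial_flag(self, ds):
        assert ds.is_polynomial()
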