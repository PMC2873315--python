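"""Dictyostelium discoideum chemosensory pathway: two rival perfect-adaptation models.

Both models describe the response regulator R* being activated by A and
inhibited by I under a chemoattractant stimulus S = S0 + u(t):

    dR*/dt = kr A (RT - R*) - k-r I R*

They differ only in what drives the inhibitor: in model 1 the stimulus does
(dI/dt = ki S - k-i I), in model 2 the activator does (dI/dt = ki' A - k-i I).
With the nominal rate constants the two models share the steady state
(A, I, R*) = (0.3, 2, 0.1) and are indistinguishable at rest, which makes
them a canonical test case for discriminating experiment design.
"""

from __future__ import annotations

import sympy as sp

from .model_core import (
    ModelSpecError,
    ParamChart,
    PolynomialModel,
    compute_steady_state,
    concatenate_models,
    parse_model_spec,
)

__all__ = [
    "NOMINAL_PARAMS",
    "STRUCTURAL_BOXES",
    "dictyostelium_fixture",
    "dictyostelium_difference_system",
    "structural_chart",
]

#: Nominal rate constants shared by the two models (arbitrary units).
NOMINAL_PARAMS = {
    "kr": 1.0,        # R* activation rate (by A)
    "kmr": 1.0,       # R* deactivation rate (by I)
    "ka": 3.0,        # A production rate (by S)
    "kma": 2.0,       # A degradation rate
    "kmi": 0.1,       # I degradation rate
    "RT": 23.0 / 30.0,  # total response-regulator concentration
}
#: Basal chemoattractant level S0.
BASAL_INPUT = [0.2]
#: Experimentally settable intervals for the structural-design variant.
STRUCTURAL_BOXES = {"kr": [0.5, 1.5], "RT": [0.5, 3.0]}


def _spec(model: int, variant: str) -> dict:
    params: dict = dict(NOMINAL_PARAMS)
    if model == 1:
        params["ki"] = 1.0        # I production rate from the stimulus S
        di = "-kmi*I"
        input_col = ["ka", "ki", "0"]
    else:
        params["kip"] = 2.0 / 3.0  # I production rate from the activator A
        di = "kip*A - kmi*I"
        input_col = ["ka", "0", "0"]
    if variant == "structural_design":
        params = {
            k: ({"value": v, "range": STRUCTURAL_BOXES[k]} if k in STRUCTURAL_BOXES else v)
            for k, v in params.items()
        }
    return {
        "name": f"dictyostelium_model{model}",
        "states": ["A", "I", "Rstar"],
        "params": params,
        "drift": ["-kma*A", di, "kr*A*(RT - Rstar) - kmr*I*Rstar"],
        "input_map": [[c] for c in input_col],
        "output_map": ["A", "I", "Rstar"],
        "basal_input": BASAL_INPUT,
    }


def dictyostelium_fixture(variant: str = "fixed_params") -> tuple[PolynomialModel, PolynomialModel]:
    """The two rival Dictyostelium models.

    ``variant='fixed_params'`` fixes all rate constants at their nominal
    values; ``variant='structural_design'`` additionally carries the
    experimentally settable boxes kr in [0.5, 1.5] and RT in [0.5, 3.0].
    """
    if variant not in ("fixed_params", "structural_design"):
        raise ModelSpecError(f"variant: unknown fixture variant {variant!r}")
    return parse_model_spec(_spec(1, variant)), parse_model_spec(_spec(2, variant))


def dictyostelium_difference_system(
    variant: str = "fixed_params", params: dict | None = None
):
    """Shifted, concatenated difference system of the two rival models."""
    m1, m2 = dictyostelium_fixture(variant)
    guess = [0.3, 2.0, 0.1]
    s1 = compute_steady_state(m1, params=params, initial_guess=guess)
    s2 = compute_steady_state(m2, params=params, initial_guess=guess)
    return concatenate_models(s1, s2)


def structural_chart() -> ParamChart:
    """Polynomial chart for the structural-design box (kr, RT).

    The steady state depends on the settable parameters: A* and I* are fixed
    by the stimulus branch (A* = ka S0 / k-a, I* = ki S0 / k-i), but

        R* = kr A* RT / (k-r I* + kr A*),

    so the shifted drift is *rational* in (kr, RT).  Replacing RT by the
    steady-state response rho = R*(kr, RT) gives chart coordinates (kr, rho)
    in which the shift is exactly polynomial:

        RT = rho (k-r I* + kr A*) / (kr A*).

    The box kr in [kr_lo, kr_hi], RT in [RT_lo, RT_hi] maps to the
    semialgebraic set  {(kr - kr_lo)(kr_hi - kr) >= 0,
    rho (k-r I* + kr A*) - RT_lo kr A* >= 0,
    RT_hi kr A* - rho (k-r I* + kr A*) >= 0}.
    """
    p = NOMINAL_PARAMS
    s0 = BASAL_INPUT[0]
    astar = p["ka"] * s0 / p["kma"]          # 0.3
    istar = 1.0 * s0 / p["kmi"]              # 2.0 (same in both models)
    kr, rho = sp.symbols("kr rho")
    denom = p["kmr"] * istar + kr * astar    # k-r I* + kr A*
    RT_expr = rho * denom / (kr * astar)
    (kr_lo, kr_hi) = STRUCTURAL_BOXES["kr"]
    (rt_lo, rt_hi) = STRUCTURAL_BOXES["RT"]

    def rho_of(kr_v, rt_v):
        return kr_v * astar * rt_v / (p["kmr"] * istar + kr_v * astar)

    rho_lo = min(rho_of(k, r) for k in (kr_lo, kr_hi) for r in (rt_lo, rt_hi))
    rho_hi = max(rho_of(k, r) for k in (kr_lo, kr_hi) for r in (rt_lo, rt_hi))
    kr_sym, RT_sym = sp.symbols("kr RT")
    return ParamChart(
        chart_names=["kr", "rho"],
        chart_boxes={"kr": (kr_lo, kr_hi), "rho": (rho_lo, rho_hi)},
        param_exprs={"kr": kr, "RT": sp.expand(RT_expr)},
        steady_state_exprs=[sp.Float(astar), sp.Float(istar), rho],
        domain_polys=[
            sp.expand((kr - kr_lo) * (kr_hi - kr)),
            sp.expand(rho * denom - rt_lo * kr * astar),
            sp.expand(rt_hi * kr * astar - rho * denom),
        ],
        inverse={
            "kr": kr_sym,
            "rho": kr_sym * astar * RT_sym / (p["kmr"] * istar + kr_sym * astar),
        },
    )
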