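"""High-level experiment-design workflows for model discrimination.

Each workflow assembles the concatenated difference system of the two rival
models, runs the requested design route(s) — linear (gramian / frequency
peak), SOS (storage-function certificates), or brute force (simulation
grids) — and ranks every candidate design by the nonlinear simulated
output-difference L2 norm.  Linear predictions and SOS bounds are reported
alongside, never used for the final ranking.

The result is a :class:`DesignReport`: a fully reproducible record of the
chosen perturbation, the per-candidate score table, cross-method agreement
diagnostics, and an echo of every tolerance and seed that entered the run.
"""

from __future__ import annotations

import datetime
import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np

from .linear_design import (
    frequency_peak,
    linearize,
    observability_gramian,
    optimal_common_initial_direction,
)
from .model_core import (
    DegenerateDesignError,
    DifferenceSystem,
    ParamBox,
    ParamChart,
    PolynomialModel,
    compute_steady_state,
    concatenate_models,
)
from .simulation import (
    brute_force_ic_search,
    brute_force_structural_search,
    make_input_signal,
    simulate_difference_system,
)
from .sos_engine import (
    CapabilityError,
    extract_optimal_ic,
    extract_structural_optimum,
    l2_gain_bound,
    storage_for_ic_design,
    storage_structural,
)

__all__ = [
    "DesignReport",
    "build_difference_system",
    "design_initial_condition",
    "design_input",
    "design_structural",
]

logger = logging.getLogger("discrimdesign")

#: nonlinear simulated values below this are treated as "outputs coincide"
DEGENERACY_TOL = 1e-9


@dataclass
class DesignReport:
    """Outcome of one experiment-design workflow.

    ``chosen`` describes the designed perturbation (initial direction and
    beta, input-signal parameters, or parameter point plus direction);
    ``simulated_value`` is its nonlinear ||y1 - y2||_2.  ``predictions``
    holds the linear prediction and/or SOS bound when computed, and
    ``candidates`` the full ranked score table.  ``config`` echoes every
    option, tolerance and seed, with a timestamp.
    """

    design: str                       # 'initial_condition' | 'input' | 'structural'
    method: str                       # 'linear' | 'sos' | 'brute' | 'combined'
    chosen: dict
    simulated_value: float
    predictions: dict = field(default_factory=dict)
    candidates: list = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(o):
            if isinstance(o, dict):
                return {k: conv(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [conv(v) for v in o]
            if isinstance(o, np.ndarray):
                return [float(v) for v in o.ravel()]
            if isinstance(o, (np.floating, np.integer)):
                return float(o)
            if isinstance(o, (np.bool_, bool)):
                return bool(o)
            return o

        return conv(
            {
                "design": self.design,
                "method": self.method,
                "chosen": self.chosen,
                "simulated_value": self.simulated_value,
                "predictions": self.predictions,
                "candidates": self.candidates,
                "diagnostics": self.diagnostics,
                "config": self.config,
            }
        )

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def _echo_config(**kwargs) -> dict:
    cfg = {k: v for k, v in kwargs.items()}
    cfg["timestamp"] = datetime.datetime.now().isoformat(timespec="seconds")
    return cfg


def _expand_methods(method: str) -> list[str]:
    if method == "all":
        return ["linear", "sos", "brute"]
    if method not in ("linear", "sos", "brute"):
        raise ValueError(f"method: expected linear|sos|brute|all, got {method!r}")
    return [method]


def build_difference_system(
    model1: PolynomialModel,
    model2: PolynomialModel,
    params: dict | None = None,
    steady_state_guess=None,
) -> DifferenceSystem:
    """Shift both rival models to their steady states and concatenate them."""
    s1 = compute_steady_state(model1, params=params, initial_guess=steady_state_guess)
    s2 = compute_steady_state(model2, params=params, initial_guess=steady_state_guess)
    return concatenate_models(s1, s2)


def _pairwise_alignment(directions: dict[str, np.ndarray]) -> dict:
    names = sorted(directions)
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            va, vb = directions[a], directions[b]
            out[f"{a}~{b}"] = float(
                abs(va @ vb) / (np.linalg.norm(va) * np.linalg.norm(vb))
            )
    return out


def design_initial_condition(
    model1: PolynomialModel,
    model2: PolynomialModel,
    beta: float = 1.0,
    method: str = "all",
    alpha: float = 0.1,
    deg_S: int = 2,
    deg_sigma: int = 2,
    grid_size: int = 300,
    seed: int = 0,
    sim_rtol: float = 1e-9,
    bound_tol: float = 1e-6,
    steady_state_guess=None,
    params: dict | None = None,
) -> DesignReport:
    """Most discriminating common initial perturbation of norm ``beta``.

    Every requested route proposes a unit direction; each proposal is scored
    by the nonlinear simulated ||y||_2 at amplitude beta and the best score
    wins.  When the SOS route runs and the trajectory stays inside the
    certified region, the report checks the storage-bound invariant
    simulated value <= sqrt(S(x0)) + ``bound_tol``.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    methods = _expand_methods(method)
    ds = build_difference_system(
        model1, model2, params=params, steady_state_guess=steady_state_guess
    )
    t_start = time.time()

    directions: dict[str, np.ndarray] = {}
    predictions: dict = {}
    diagnostics: dict = {}

    if "linear" in methods:
        gd = observability_gramian(linearize(ds))
        v, lam = optimal_common_initial_direction(gd)
        directions["linear"] = v
        predictions["linear_value"] = float(beta * np.sqrt(lam))
        predictions["gramian_eigenvalue"] = float(lam)
        diagnostics["gramian"] = {
            "lyapunov_residual": gd.residual,
            "eigen_gap": gd.eigen_gap,
            "tie": gd.tie,
        }
        logger.info("linear IC design: lambda=%.6g direction=%s", lam, v)

    if "sos" in methods:
        cert = storage_for_ic_design(
            ds, alpha=alpha, deg_S=deg_S, deg_sigma=deg_sigma
        )
        ex = extract_optimal_ic(cert, beta=beta)
        directions["sos"] = ex.x_hat / np.linalg.norm(ex.x_hat)
        predictions["sos_energy_bound"] = float(ex.value)
        predictions["sos_norm_bound"] = float(np.sqrt(max(ex.value, 0.0)))
        diagnostics["sos"] = {
            "storage_status": cert.status,
            "storage_objective": cert.objective,
            "verification": cert.verification,
            "extraction_route": ex.route,
            "rank_ratio": ex.rank_ratio,
            "containment": bool(beta <= cert.region_radius),
        }
        logger.info(
            "SOS IC design: status=%s bound=%.6g route=%s",
            cert.status,
            ex.value,
            ex.route,
        )

    if "brute" in methods:
        v, val = brute_force_ic_search(
            ds, beta=beta, grid_size=grid_size, final_rtol=sim_rtol
        )
        directions["brute"] = v
        diagnostics["brute"] = {"grid_size": grid_size, "coarse_value": float(val)}
        logger.info("brute IC design: value=%.6g direction=%s", val, v)

    candidates = []
    for name, v in directions.items():
        traj = simulate_difference_system(
            ds, common_ic=beta * v, rtol=sim_rtol, store=False
        )
        candidates.append(
            {
                "route": name,
                "direction": [float(c) for c in v],
                "beta": float(beta),
                "simulated_value": float(traj.l2_norm),
                "horizon": float(traj.T_end),
            }
        )
    candidates.sort(key=lambda c: -c["simulated_value"])
    best = candidates[0]
    if best["simulated_value"] <= DEGENERACY_TOL * max(1.0, beta):
        raise DegenerateDesignError(
            "all candidate initial perturbations produce numerically zero "
            "output difference: the two models are indistinguishable from "
            "common initial conditions (identical outputs along the common "
            "subspace)"
        )

    diagnostics["direction_alignment"] = _pairwise_alignment(directions)
    if "sos" in directions and diagnostics["sos"]["containment"]:
        sos_cand = next(c for c in candidates if c["route"] == "sos")
        bound = predictions["sos_norm_bound"]
        diagnostics["storage_bound_check"] = {
            "simulated": sos_cand["simulated_value"],
            "bound": bound,
            "holds": bool(sos_cand["simulated_value"] <= bound + bound_tol),
        }

    return DesignReport(
        design="initial_condition",
        method=method if len(methods) == 1 else "combined",
        chosen={
            "direction": best["direction"],
            "beta": float(beta),
            "route": best["route"],
        },
        simulated_value=best["simulated_value"],
        predictions=predictions,
        candidates=candidates,
        diagnostics=diagnostics,
        config=_echo_config(
            design="initial_condition",
            beta=beta,
            method=method,
            alpha=alpha,
            deg_S=deg_S,
            deg_sigma=deg_sigma,
            grid_size=grid_size,
            seed=seed,
            sim_rtol=sim_rtol,
            bound_tol=bound_tol,
            params=params,
            runtime_s=round(time.time() - t_start, 3),
        ),
    )


def design_input(
    model1: PolynomialModel,
    model2: PolynomialModel,
    output_selector=None,
    T_active: float = 60.0,
    energy: float = 1.0,
    candidate_kinds=("sine", "square", "sinc", "constant"),
    include_gain_bound: bool = False,
    alpha: float = 0.1,
    deg_S: int = 2,
    seed: int = 0,
    sim_rtol: float = 1e-9,
    bound_tol: float = 1e-6,
    steady_state_guess=None,
) -> DesignReport:
    """Most discriminating unit-energy stimulus over the candidate kinds.

    The critical frequency of the linearized difference system (for the
    selected output) parameterizes every frequency-bearing candidate; each
    candidate is simulated nonlinearly on [0, T_active] and ranked by
    ||y||_2.  ``include_gain_bound`` additionally computes the SOS-certified
    regional L2-gain bound (full-state output) and records the gain-bound
    invariant simulated value <= gamma * energy + ``bound_tol``.
    """
    kinds = list(candidate_kinds)
    if not kinds:
        raise ValueError("candidate_kinds must contain at least one signal kind")
    if T_active <= 0:
        raise ValueError("T_active must be positive")
    if energy < 0:
        raise ValueError("energy must be nonnegative")
    ds = build_difference_system(model1, model2, steady_state_guess=steady_state_guess)
    t_start = time.time()

    lin = linearize(ds)
    fp = frequency_peak(lin, output_selector=output_selector)
    predictions: dict = {
        "critical_frequency": float(fp.omega0),
        "linear_peak_gain": float(fp.gain),
        "linear_value_bound": float(fp.gain * energy),
    }
    diagnostics: dict = {"frequency_refinement": fp.refinement, "flat_peak": fp.flat}
    logger.info("input design: critical frequency %.6g, peak gain %.6g", fp.omega0, fp.gain)

    candidates = []
    for kind in kinds:
        if energy == 0.0:
            sig = make_input_signal("zero")
            value, horizon = 0.0, 0.0
        else:
            sig = make_input_signal(
                kind, omega=fp.omega0, T_active=T_active, energy=energy
            )
            traj = simulate_difference_system(
                ds,
                input_signal=sig,
                output_selector=output_selector,
                rtol=sim_rtol,
                store=False,
            )
            value, horizon = float(traj.l2_norm), float(traj.T_end)
        candidates.append(
            {
                "kind": kind,
                "omega": float(sig.omega),
                "amplitude": float(sig.amplitude),
                "T_active": float(T_active),
                "energy": float(energy),
                "simulated_value": value,
                "horizon": horizon,
            }
        )
        logger.info("input candidate %-9s value=%.6g", kind, value)
    candidates.sort(key=lambda c: -c["simulated_value"])
    best = candidates[0]

    if include_gain_bound:
        cert = l2_gain_bound(ds, alpha=alpha, deg_S=deg_S)
        predictions["sos_gain_bound"] = float(cert.gamma)
        predictions["sos_value_bound"] = float(cert.gamma * energy)
        diagnostics["gain_certificate"] = {
            "gamma": cert.gamma,
            "gamma_solver": cert.gamma_solver,
            "margin": cert.margin,
            "status": cert.status,
            "region_radius": cert.region_radius,
            "verification": cert.verification,
        }
        diagnostics["gain_bound_check"] = {
            "simulated": best["simulated_value"],
            "bound": float(cert.gamma * energy),
            "holds": bool(
                best["simulated_value"] <= cert.gamma * energy + bound_tol
            ),
        }

    return DesignReport(
        design="input",
        method="combined" if include_gain_bound else "linear",
        chosen={
            "kind": best["kind"],
            "omega": best["omega"],
            "amplitude": best["amplitude"],
            "T_active": float(T_active),
            "energy": float(energy),
        },
        simulated_value=best["simulated_value"],
        predictions=predictions,
        candidates=candidates,
        diagnostics=diagnostics,
        config=_echo_config(
            design="input",
            output_selector=None
            if output_selector is None
            else [int(i) for i in np.atleast_1d(output_selector)],
            T_active=T_active,
            energy=energy,
            candidate_kinds=kinds,
            include_gain_bound=include_gain_bound,
            alpha=alpha,
            deg_S=deg_S,
            seed=seed,
            sim_rtol=sim_rtol,
            bound_tol=bound_tol,
            runtime_s=round(time.time() - t_start, 3),
        ),
    )


def design_structural(
    model1: PolynomialModel,
    model2: PolynomialModel,
    param_box: ParamBox | dict | None = None,
    beta: float = 1.0,
    method: str = "all",
    chart: ParamChart | None = None,
    param_grid: int = 7,
    dir_grid: int = 60,
    alpha: float = 0.1,
    deg_S: int = 2,
    seed: int = 0,
    sim_rtol: float = 1e-9,
    steady_state_guess=None,
) -> DesignReport:
    """Most discriminating settable-parameter point plus initial perturbation.

    The brute route grids the parameter box and the direction sphere,
    re-shifting the steady state at every point; the SOS route solves the
    parametric storage programme on a polynomial chart of the box and
    extracts the optimizer from the dual moments.  Every proposed
    (parameter point, direction) pair is re-simulated nonlinearly and the
    best simulated value wins.  A degenerate (single-point) box reduces to
    initial-condition design at that point.

    The linear gramian route has no parametric analogue here, so
    ``method='all'`` runs the SOS and brute routes.
    """
    methods = [m for m in _expand_methods(method) if m != "linear"]
    if not methods:
        raise ValueError("structural design supports methods sos|brute|all")
    if param_box is None:
        param_box = model1.param_boxes
    if isinstance(param_box, dict):
        param_box = ParamBox(param_box)
    if len(param_box) == 0:
        raise ValueError("parameter box is empty: nothing to design")
    t_start = time.time()

    if param_box.is_degenerate():
        point = {k: lo for k, (lo, hi) in param_box.intervals.items()}
        ic_method = "all" if method == "all" else ("brute" if method == "brute" else "sos")
        sub = design_initial_condition(
            model1,
            model2,
            beta=beta,
            method=ic_method,
            alpha=alpha,
            deg_S=deg_S,
            seed=seed,
            sim_rtol=sim_rtol,
            steady_state_guess=steady_state_guess,
            params=point,
        )
        sub.design = "structural"
        sub.chosen = {"params": point, **sub.chosen}
        sub.diagnostics["degenerate_box"] = True
        return sub

    proposals: dict[str, tuple[dict, np.ndarray]] = {}
    predictions: dict = {}
    diagnostics: dict = {}

    if "brute" in methods:
        point, direction, value = brute_force_structural_search(
            (model1, model2),
            param_box=param_box,
            beta=beta,
            param_grid=param_grid,
            dir_grid=dir_grid,
            final_rtol=sim_rtol,
            steady_state_guess=steady_state_guess,
            log=logger.info,
        )
        proposals["brute"] = (point, np.asarray(direction))
        diagnostics["brute"] = {
            "param_grid": param_grid,
            "dir_grid": dir_grid,
            "coarse_value": float(value),
        }
        logger.info("brute structural design: %s value=%.6g", point, value)

    if "sos" in methods:
        if chart is None:
            raise CapabilityError(
                "the SOS structural route requires a polynomial ParamChart of "
                "the parameter box (the steady-state shift must be polynomial "
                "in the chart coordinates); pass chart=... or use method='brute'"
            )
        cert = storage_structural((model1, model2), chart, alpha=alpha, deg_S=deg_S)
        # extract inside the certified region, where the parametric storage
        # bound is meaningful; the returned direction/point are then re-scored
        # by full nonlinear simulation at the requested beta
        ex = extract_structural_optimum(cert, beta=min(beta, cert.region_radius))
        proposals["sos"] = (dict(ex.p_hat), ex.x_hat / np.linalg.norm(ex.x_hat))
        predictions["sos_energy_bound"] = float(ex.value)
        diagnostics["sos"] = {
            "storage_status": cert.status,
            "storage_objective": cert.objective,
            "verification": cert.verification,
            "extraction_route": ex.route,
            "rank_ratio": ex.rank_ratio,
            "chart_point": ex.diagnostics.get("chart_point"),
            "containment": bool(beta <= cert.region_radius),
        }
        logger.info("SOS structural design: p=%s route=%s", ex.p_hat, ex.route)

    candidates = []
    for name, (point, direction) in proposals.items():
        ds_p = build_difference_system(
            model1, model2, params=point, steady_state_guess=steady_state_guess
        )
        # the proposed direction, plus the axis directions as cheap refinements
        dirs = {"proposed": np.asarray(direction, dtype=float)}
        scored = []
        for tag, v in dirs.items():
            traj = simulate_difference_system(
                ds_p, common_ic=beta * v, rtol=sim_rtol, store=False
            )
            scored.append((float(traj.l2_norm), tag, v, float(traj.T_end)))
        val, tag, v, horizon = max(scored, key=lambda s: s[0])
        candidates.append(
            {
                "route": name,
                "params": {k: float(x) for k, x in point.items()},
                "direction": [float(c) for c in v],
                "beta": float(beta),
                "simulated_value": val,
                "horizon": horizon,
            }
        )
    candidates.sort(key=lambda c: -c["simulated_value"])
    best = candidates[0]
    if best["simulated_value"] <= DEGENERACY_TOL * max(1.0, beta):
        raise DegenerateDesignError(
            "no parameter point in the box separates the two models: all "
            "candidate designs give numerically zero output difference"
        )

    if len(proposals) == 2:
        pb, db = proposals["brute"], proposals["sos"]
        diagnostics["cross_check"] = {
            "param_distance": {
                k: abs(float(pb[0][k]) - float(db[0][k])) for k in pb[0]
            },
            "direction_alignment": float(
                abs(np.asarray(pb[1]) @ np.asarray(db[1]))
                / (np.linalg.norm(pb[1]) * np.linalg.norm(db[1]))
            ),
        }

    return DesignReport(
        design="structural",
        method=method if len(methods) == 1 else "combined",
        chosen={
            "params": best["params"],
            "direction": best["direction"],
            "beta": float(beta),
            "route": best["route"],
        },
        simulated_value=best["simulated_value"],
        predictions=predictions,
        candidates=candidates,
        diagnostics=diagnostics,
        config=_echo_config(
            design="structural",
            param_box={k: list(v) for k, v in param_box.intervals.items()},
            beta=beta,
            method=method,
            param_grid=param_grid,
            dir_grid=dir_grid,
            alpha=alpha,
            deg_S=deg_S,
            seed=seed,
            sim_rtol=sim_rtol,
            runtime_s=round(time.time() - t_start, 3),
        ),
    )
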