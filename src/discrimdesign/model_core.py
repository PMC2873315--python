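"""Rival ODE models, steady-state shifting, and the concatenated difference system.

A rival model is an input-affine ODE system

    dx/dt = f(x) + g(x) (u0 + u(t)),    y = h(x),

with polynomial (or rational) drift ``f``, input map ``g``, output map ``h``
and a basal input level ``u0``.  Model discrimination works in *deviation
coordinates*: each model is shifted so that its steady state under the basal
input sits at the origin, and the two shifted models are concatenated into a
single *difference system* whose output is the difference of the two model
outputs.  All downstream analysis (gramian design, simulation, sum-of-squares
certificates) operates on that difference system.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

__all__ = [
    "ModelSpecError",
    "SteadyStateError",
    "StabilityError",
    "DimensionError",
    "DegenerateDesignError",
    "PolynomialModel",
    "ShiftedModel",
    "DifferenceSystem",
    "ParamBox",
    "ParamChart",
    "parse_model_spec",
    "compute_steady_state",
    "concatenate_models",
]


class ModelSpecError(ValueError):
    """A model-spec document failed validation; the message names the field."""


class SteadyStateError(RuntimeError):
    """The steady-state root solve did not converge."""


class StabilityError(RuntimeError):
    """A Jacobian was not Hurwitz where asymptotic stability is required."""


class DimensionError(ValueError):
    """Input/output dimensions of two models do not match."""


class DegenerateDesignError(RuntimeError):
    """The design problem is degenerate (e.g. the two models are identical)."""


def _parse_expr(text, declared: dict[str, sp.Symbol], fieldname: str) -> sp.Expr:
    """Parse one expression in the plain infix grammar (+, -, *, /, ^, parens)."""
    if isinstance(text, (int, float)):
        return sp.sympify(text)
    if not isinstance(text, str):
        raise ModelSpecError(f"{fieldname}: expected an expression string, got {type(text).__name__}")
    try:
        expr = sp.sympify(text.replace("^", "**"), locals=dict(declared), evaluate=True)
    except (sp.SympifyError, SyntaxError, TypeError) as exc:
        raise ModelSpecError(f"{fieldname}: malformed expression {text!r} ({exc})") from exc
    extra = expr.free_symbols - set(declared.values())
    if extra:
        names = ", ".join(sorted(str(s) for s in extra))
        raise ModelSpecError(f"{fieldname}: undeclared symbol(s) {names} in {text!r}")
    return expr


@dataclass
class ParamBox:
    """Named closed intervals for experimentally settable parameters."""

    intervals: dict[str, tuple[float, float]]

    def __post_init__(self):
        clean = {}
        for name, (lo, hi) in self.intervals.items():
            lo, hi = float(lo), float(hi)
            if lo < 0:
                raise ModelSpecError(f"params.{name}: interval lower bound {lo} < 0")
            if hi < lo:
                raise ModelSpecError(f"params.{name}: interval [{lo}, {hi}] has hi < lo")
            clean[name] = (lo, hi)
        self.intervals = clean

    def __iter__(self):
        return iter(self.intervals.items())

    def __len__(self):
        return len(self.intervals)

    def __contains__(self, name):
        return name in self.intervals

    def contains_point(self, point: dict[str, float], tol: float = 1e-9) -> bool:
        return all(
            self.intervals[k][0] - tol <= float(v) <= self.intervals[k][1] + tol
            for k, v in point.items()
            if k in self.intervals
        )

    def is_degenerate(self, tol: float = 0.0) -> bool:
        return all(hi - lo <= tol for lo, hi in self.intervals.values())

    def sample(self, rng: np.random.Generator, size: int) -> list[dict[str, float]]:
        names = list(self.intervals)
        lows = np.array([self.intervals[k][0] for k in names])
        highs = np.array([self.intervals[k][1] for k in names])
        pts = rng.uniform(lows, highs, size=(size, len(names)))
        return [dict(zip(names, map(float, row))) for row in pts]


@dataclass
class PolynomialModel:
    """One rival model in raw coordinates (input-affine ODE system)."""

    state_names: list[str]
    param_values: dict[str, float]
    drift: list[sp.Expr]            # n expressions in states and parameters
    input_map: list[list[sp.Expr]]  # n x q expressions
    output_map: list[sp.Expr]       # ell expressions in states
    basal_input: list[float]        # q reals
    param_boxes: ParamBox = field(default_factory=lambda: ParamBox({}))
    name: str = ""

    def __post_init__(self):
        if isinstance(self.param_boxes, dict):
            self.param_boxes = ParamBox(self.param_boxes)
        n, q, ell = self.n, self.q, self.ell
        if n < 1:
            raise ModelSpecError("states: at least one state is required")
        if ell < 1:
            raise ModelSpecError("output_map: at least one output is required")
        if len(self.drift) != n:
            raise ModelSpecError(f"drift: expected {n} expressions, got {len(self.drift)}")
        if len(self.input_map) != n or any(len(row) != q for row in self.input_map):
            raise ModelSpecError(f"input_map: expected an {n} x {q} array of expressions")
        for bname in self.param_boxes.intervals:
            if bname not in self.param_values:
                raise ModelSpecError(f"params.{bname}: boxed parameter has no nominal value")

    # -- dimensions ----------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.state_names)

    @property
    def q(self) -> int:
        return len(self.basal_input)

    @property
    def ell(self) -> int:
        return len(self.output_map)

    @property
    def state_symbols(self) -> list[sp.Symbol]:
        return [sp.Symbol(s) for s in self.state_names]

    @property
    def param_symbols(self) -> list[sp.Symbol]:
        return [sp.Symbol(s) for s in self.param_values]

    # -- helpers -------------------------------------------------------
    def substituted(self, params: dict[str, float] | None = None):
        """(drift, input_map, output_map) with numeric parameter values."""
        vals = dict(self.param_values)
        if params:
            unknown = set(params) - set(vals)
            if unknown:
                raise ModelSpecError(f"params: unknown parameter(s) {sorted(unknown)}")
            vals.update(params)
        subs = {sp.Symbol(k): sp.Float(v) for k, v in vals.items()}
        f = [sp.expand(e.subs(subs)) for e in self.drift]
        g = [[sp.expand(e.subs(subs)) for e in row] for row in self.input_map]
        h = [sp.expand(e.subs(subs)) for e in self.output_map]
        return f, g, h, vals

    def is_polynomial(self, params: dict[str, float] | None = None) -> bool:
        """True when drift, input map and output map are polynomial in the states."""
        f, g, h, _ = self.substituted(params)
        xs = self.state_symbols
        return all(e.is_polynomial(*xs) for e in [*f, *h, *(e for row in g for e in row)])

    def to_document(self) -> dict:
        """Round-trip the model to a plain model-spec dictionary."""
        params: dict = {}
        for k, v in self.param_values.items():
            if k in self.param_boxes:
                lo, hi = self.param_boxes.intervals[k]
                params[k] = {"value": v, "range": [lo, hi]}
            else:
                params[k] = v
        doc = {
            "states": list(self.state_names),
            "params": params,
            "drift": [str(e) for e in self.drift],
            "input_map": [[str(e) for e in row] for row in self.input_map],
            "output_map": [str(e) for e in self.output_map],
            "basal_input": list(map(float, self.basal_input)),
        }
        if self.name:
            doc["name"] = self.name
        return doc


def parse_model_spec(spec_document) -> PolynomialModel:
    """Parse and validate a declarative model-spec document.

    Accepts a dictionary, a JSON/YAML string, or a path to a JSON/YAML file.
    Expressions use a plain infix grammar (+, -, *, /, ^, parentheses) over
    the declared state and parameter names.
    """
    doc = spec_document
    if isinstance(doc, Path) or (
        isinstance(doc, str) and "\n" not in doc and doc.strip().endswith((".json", ".yaml", ".yml"))
    ):
        doc = Path(doc).read_text()
    if isinstance(doc, str):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError:
            import yaml

            doc = yaml.safe_load(doc)
    if not isinstance(doc, dict):
        raise ModelSpecError(f"document: expected a mapping, got {type(doc).__name__}")

    for key in ("states", "params", "drift", "input_map", "output_map", "basal_input"):
        if key not in doc:
            raise ModelSpecError(f"{key}: required key missing")

    states = list(doc["states"])
    if len(set(states)) != len(states):
        raise ModelSpecError("states: duplicate state names")

    param_values: dict[str, float] = {}
    boxes: dict[str, tuple[float, float]] = {}
    for pname, pval in dict(doc["params"]).items():
        if isinstance(pval, dict):
            if "range" in pval:
                lo, hi = map(float, pval["range"])
                value = float(pval.get("value", 0.5 * (lo + hi)))
                if hi > lo:
                    boxes[pname] = (lo, hi)
            else:
                value = float(pval["value"])
        elif isinstance(pval, (list, tuple)):
            lo, hi = map(float, pval)
            value = 0.5 * (lo + hi)
            if hi > lo:
                boxes[pname] = (lo, hi)  # degenerate boxes collapse to fixed values
        else:
            value = float(pval)
        param_values[pname] = value
    # validate bounds (including collapsed ones) through ParamBox
    raw_boxes = {
        k: (tuple(map(float, v["range"])) if isinstance(v, dict) and "range" in v else tuple(map(float, v)))
        for k, v in dict(doc["params"]).items()
        if isinstance(v, (list, tuple)) or (isinstance(v, dict) and "range" in v)
    }
    ParamBox(raw_boxes)

    declared = {s: sp.Symbol(s) for s in states}
    declared.update({p: sp.Symbol(p) for p in param_values})
    overlap = set(states) & set(param_values)
    if overlap:
        raise ModelSpecError(f"params: name(s) {sorted(overlap)} also declared as states")

    drift = [_parse_expr(e, declared, f"drift[{i}]") for i, e in enumerate(doc["drift"])]
    input_map = [
        [_parse_expr(e, declared, f"input_map[{i}][{j}]") for j, e in enumerate(row)]
        for i, row in enumerate(doc["input_map"])
    ]
    output_map = [_parse_expr(e, declared, f"output_map[{i}]") for i, e in enumerate(doc["output_map"])]
    try:
        basal = [float(v) for v in doc["basal_input"]]
    except (TypeError, ValueError) as exc:
        raise ModelSpecError(f"basal_input: expected a list of reals ({exc})") from exc

    return PolynomialModel(
        state_names=states,
        param_values=param_values,
        drift=drift,
        input_map=input_map,
        output_map=output_map,
        basal_input=basal,
        param_boxes=ParamBox(boxes),
        name=str(doc.get("name", "")),
    )


@dataclass
class ShiftedModel:
    """A model in deviation coordinates: the steady state sits at the origin.

    The deviation dynamics are ``dX/dt = f_shifted(X) + g_shifted(X) u(t)``
    where ``X = x - x*`` and ``u`` is the input perturbation away from the
    basal level.  ``output_shifted`` is ``h(X + x*) - h(x*)``.
    """

    model: PolynomialModel
    params: dict[str, float]
    steady_state: np.ndarray
    drift_shifted: list[sp.Expr]
    input_shifted: list[list[sp.Expr]]
    output_shifted: list[sp.Expr]
    jacobian: np.ndarray
    eigenvalues: np.ndarray

    def __post_init__(self):
        xs = self.model.state_symbols
        self._f = sp.lambdify([xs], sp.Matrix(self.drift_shifted), "numpy")
        self._g = sp.lambdify([xs], sp.Matrix(self.input_shifted), "numpy")
        self._h = sp.lambdify([xs], sp.Matrix(self.output_shifted), "numpy")

    @property
    def n(self) -> int:
        return self.model.n

    @property
    def q(self) -> int:
        return self.model.q

    @property
    def ell(self) -> int:
        return self.model.ell

    def f(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self._f(list(x)), dtype=float).ravel()

    def g(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self._g(list(x)), dtype=float).reshape(self.n, self.q)

    def h(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(self._h(list(x)), dtype=float).ravel()

    def rhs(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        return self.f(x) + self.g(x) @ np.atleast_1d(u)

    @property
    def B(self) -> np.ndarray:
        """Input matrix of the linearization at the origin."""
        return self.g(np.zeros(self.n))

    @property
    def C(self) -> np.ndarray:
        """Output matrix of the linearization at the origin."""
        xs = self.model.state_symbols
        J = sp.Matrix(self.output_shifted).jacobian(xs)
        return np.array(J.subs({s: 0 for s in xs}), dtype=float)

    def is_polynomial(self) -> bool:
        xs = self.model.state_symbols
        exprs = [*self.drift_shifted, *self.output_shifted]
        exprs += [e for row in self.input_shifted for e in row]
        return all(e.is_polynomial(*xs) for e in exprs)

    def report(self) -> dict:
        """Shift provenance for serialized reports."""
        return {
            "model": self.model.name or "<unnamed>",
            "params": {k: float(v) for k, v in self.params.items()},
            "steady_state": dict(zip(self.model.state_names, map(float, self.steady_state))),
            "jacobian_eigenvalues": [
                {"re": float(np.real(l)), "im": float(np.imag(l))} for l in self.eigenvalues
            ],
            "convention": "deviation coordinates: X = x - x*, u = input - basal",
        }


def compute_steady_state(
    model: PolynomialModel,
    params: dict[str, float] | None = None,
    basal_input: list[float] | None = None,
    initial_guess: np.ndarray | None = None,
    tol: float = 1e-12,
    require_hurwitz: bool = True,
) -> ShiftedModel:
    """Locate the steady state under the basal input and shift it to the origin.

    Damped Newton iteration from the guess, with a fallback relaxation
    simulation if Newton stagnates.  The Jacobian at the equilibrium must be
    Hurwitz (asymptotic stability is assumed by every design method).
    """
    f, g, h, vals = model.substituted(params)
    u0 = np.asarray(model.basal_input if basal_input is None else basal_input, dtype=float)
    if u0.shape != (model.q,):
        raise DimensionError(f"basal_input: expected {model.q} entries, got {u0.shape}")
    xs = model.state_symbols
    F_sym = sp.Matrix(f)
    if model.q:
        F_sym = F_sym + sp.Matrix(g) * sp.Matrix(u0)
    F = sp.lambdify([xs], F_sym, "numpy")
    J_sym = F_sym.jacobian(xs)
    J = sp.lambdify([xs], J_sym, "numpy")

    def Fv(x):
        return np.asarray(F(list(x)), dtype=float).ravel()

    def Jv(x):
        return np.asarray(J(list(x)), dtype=float)

    def newton(x):
        x = np.array(x, dtype=float)
        for _ in range(200):
            r = Fv(x)
            if np.linalg.norm(r, np.inf) < tol:
                return x
            try:
                step = np.linalg.solve(Jv(x), -r)
            except np.linalg.LinAlgError:
                return None
            lam, base = 1.0, np.linalg.norm(r)
            for _ in range(40):
                xn = x + lam * step
                if np.all(np.isfinite(xn)) and np.linalg.norm(Fv(xn)) < base:
                    break
                lam *= 0.5
            else:
                return None
            x = xn
        return x if np.linalg.norm(Fv(x), np.inf) < tol else None

    guess = np.ones(model.n) if initial_guess is None else np.asarray(initial_guess, dtype=float)
    xstar = newton(guess)
    if xstar is None:
        # fallback: relax toward the attractor, then retry Newton
        relax = solve_ivp(lambda t, x: Fv(x), (0.0, 500.0), guess, rtol=1e-9, atol=1e-12)
        if relax.success:
            xstar = newton(relax.y[:, -1])
    if xstar is None:
        res = float(np.linalg.norm(Fv(guess), np.inf))
        raise SteadyStateError(
            f"steady-state solve did not converge from guess {guess.tolist()} "
            f"(initial residual {res:.3e})"
        )

    A = Jv(xstar)
    eig = np.linalg.eigvals(A)
    if require_hurwitz and np.max(np.real(eig)) >= 0:
        raise StabilityError(
            "Jacobian at the steady state is not Hurwitz "
            f"(eigenvalues {np.round(eig, 6).tolist()}); the design methods "
            "assume an asymptotically stable equilibrium"
        )

    shift = {s: s + sp.Float(v) for s, v in zip(xs, xstar)}
    drift_shifted = [sp.expand((fi + sum(gij * u0j for gij, u0j in zip(grow, u0))).subs(shift, simultaneous=True)) for fi, grow in zip(f, g)]
    input_shifted = [[sp.expand(e.subs(shift, simultaneous=True)) for e in row] for row in g]
    hstar = [complex(e.subs({s: v for s, v in zip(xs, xstar)})).real for e in h]
    output_shifted = [
        sp.expand(e.subs(shift, simultaneous=True) - sp.Float(v)) for e, v in zip(h, hstar)
    ]

    shifted = ShiftedModel(
        model=model,
        params=vals,
        steady_state=np.asarray(xstar, dtype=float),
        drift_shifted=drift_shifted,
        input_shifted=input_shifted,
        output_shifted=output_shifted,
        jacobian=A,
        eigenvalues=eig,
    )
    resid = np.linalg.norm(shifted.f(np.zeros(model.n)), np.inf)
    if resid > 1e-10:
        raise SteadyStateError(f"shifted drift at origin has residual {resid:.3e} > 1e-10")
    return shifted


@dataclass
class DifferenceSystem:
    """Concatenation of two shifted models with output y = y1 - y2."""

    m1: ShiftedModel
    m2: ShiftedModel

    def __post_init__(self):
        if self.m1.q != self.m2.q:
            raise DimensionError(f"input dimensions differ: {self.m1.q} vs {self.m2.q}")
        if self.m1.ell != self.m2.ell:
            raise DimensionError(f"output dimensions differ: {self.m1.ell} vs {self.m2.ell}")

    @property
    def n1(self) -> int:
        return self.m1.n

    @property
    def n2(self) -> int:
        return self.m2.n

    @property
    def n(self) -> int:
        return self.m1.n + self.m2.n

    @property
    def q(self) -> int:
        return self.m1.q

    @property
    def ell(self) -> int:
        return self.m1.ell

    def split(self, x: np.ndarray):
        x = np.asarray(x, dtype=float)
        return x[: self.n1], x[self.n1 :]

    def rhs(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        x1, x2 = self.split(x)
        return np.concatenate([self.m1.rhs(x1, u), self.m2.rhs(x2, u)])

    def output(self, x: np.ndarray) -> np.ndarray:
        x1, x2 = self.split(x)
        return self.m1.h(x1) - self.m2.h(x2)

    def is_polynomial(self) -> bool:
        return self.m1.is_polynomial() and self.m2.is_polynomial()


def concatenate_models(shifted1: ShiftedModel, shifted2: ShiftedModel) -> DifferenceSystem:
    """Build the difference system of two steady-state-shifted models.

    The raw outputs must coincide at the respective steady states (the two
    rival models are indistinguishable at rest); otherwise the deviation-
    coordinate difference output would silently hide a constant offset.
    """
    ds = DifferenceSystem(shifted1, shifted2)
    _, _, h1, _ = shifted1.model.substituted(shifted1.params)
    _, _, h2, _ = shifted2.model.substituted(shifted2.params)
    y1 = [complex(e.subs(dict(zip(shifted1.model.state_symbols, shifted1.steady_state)))).real for e in h1]
    y2 = [complex(e.subs(dict(zip(shifted2.model.state_symbols, shifted2.steady_state)))).real for e in h2]
    gap = float(np.max(np.abs(np.array(y1) - np.array(y2))))
    if gap > 1e-8:
        raise ValueError(
            f"steady-state outputs differ by {gap:.3e}; the difference output "
            "would not vanish at the combined origin"
        )
    return ds


@dataclass
class ParamChart:
    """A reparametrization of boxed parameters that makes the per-parameter
    steady-state shift polynomial.

    The shifted drift of a model is generally *rational* in the original
    parameters because the steady state itself depends on them.  A chart maps
    the original parameters to new coordinates (typically including steady-
    state components) in which the shifted dynamics are exactly polynomial.
    The image of the original parameter box is described by polynomial
    inequalities ``domain_polys >= 0`` in the chart coordinates.
    """

    chart_names: list[str]
    chart_boxes: dict[str, tuple[float, float]]   # bounding intervals, for scaling
    param_exprs: dict[str, sp.Expr]               # original param -> expr in chart symbols
    steady_state_exprs: list[sp.Expr]             # shared steady state in chart symbols
    domain_polys: list[sp.Expr]                   # >= 0 on the image of the box
    inverse: dict[str, sp.Expr]                   # chart coord -> expr in original params

    @property
    def chart_symbols(self) -> list[sp.Symbol]:
        return [sp.Symbol(s) for s in self.chart_names]

    def to_params(self, chart_point: dict[str, float]) -> dict[str, float]:
        subs = {sp.Symbol(k): float(v) for k, v in chart_point.items()}
        return {k: float(e.subs(subs)) for k, e in self.param_exprs.items()}

    def from_params(self, params: dict[str, float]) -> dict[str, float]:
        subs = {sp.Symbol(k): float(v) for k, v in params.items()}
        return {k: float(e.subs(subs)) for k, e in self.inverse.items()}

    def in_domain(self, chart_point: dict[str, float], tol: float = 1e-9) -> bool:
        subs = {sp.Symbol(k): float(v) for k, v in chart_point.items()}
        return all(float(p.subs(subs)) >= -tol for p in self.domain_polys)
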