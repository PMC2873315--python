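"""Multivariate polynomials in a fixed variable ordering.

Two containers are provided:

* :class:`PolynomialForm` - an ordinary polynomial with real coefficients,
  stored sparsely as ``{exponent tuple: coefficient}``.
* :class:`AffinePoly` - a polynomial whose coefficients are affine
  expressions in scalar decision variables (Gram-matrix entries of a
  sum-of-squares programme).  Decision polynomials never multiply each
  other in the programmes assembled here, so affine coefficients suffice.

Exponent tuples are always relative to a fixed list of variable names held
by the owner; the containers themselves only know the variable count.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping

import numpy as np
import sympy

__all__ = ["PolynomialForm", "AffinePoly", "LinExpr"]

_COEF_TOL = 0.0  # exact bookkeeping; pruning happens only on explicit request


def _add_expt(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
    return tuple(x + y for x, y in zip(a, b))


class PolynomialForm:
    """Sparse multivariate polynomial over a fixed number of variables."""

    __slots__ = ("nvars", "coeffs")

    def __init__(self, nvars: int, coeffs: Mapping[tuple[int, ...], float] | None = None):
        self.nvars = int(nvars)
        self.coeffs: dict[tuple[int, ...], float] = {}
        if coeffs:
            for e, c in coeffs.items():
                if c != 0:
                    self.coeffs[tuple(e)] = self.coeffs.get(tuple(e), 0.0) + float(c)

    # -- construction -------------------------------------------------
    @classmethod
    def zero(cls, nvars: int) -> "PolynomialForm":
        return cls(nvars)

    @classmethod
    def constant(cls, nvars: int, value: float) -> "PolynomialForm":
        p = cls(nvars)
        if value != 0:
            p.coeffs[(0,) * nvars] = float(value)
        return p

    @classmethod
    def variable(cls, nvars: int, index: int) -> "PolynomialForm":
        e = [0] * nvars
        e[index] = 1
        return cls(nvars, {tuple(e): 1.0})

    @classmethod
    def monomial(cls, expt: tuple[int, ...], coef: float = 1.0) -> "PolynomialForm":
        return cls(len(expt), {tuple(expt): coef})

    @classmethod
    def from_sympy(cls, expr: sympy.Expr, symbols: list[sympy.Symbol]) -> "PolynomialForm":
        poly = sympy.Poly(sympy.expand(expr), *symbols)
        out = cls(len(symbols))
        for expt, coef in zip(poly.monoms(), poly.coeffs()):
            out.coeffs[tuple(int(e) for e in expt)] = float(coef)
        return out

    # -- algebra -------------------------------------------------------
    def copy(self) -> "PolynomialForm":
        return PolynomialForm(self.nvars, dict(self.coeffs))

    def __add__(self, other: "PolynomialForm") -> "PolynomialForm":
        out = self.copy()
        for e, c in other.coeffs.items():
            out.coeffs[e] = out.coeffs.get(e, 0.0) + c
            if out.coeffs[e] == 0:
                del out.coeffs[e]
        return out

    def __sub__(self, other: "PolynomialForm") -> "PolynomialForm":
        return self + (other * -1.0)

    def __mul__(self, other):
        if isinstance(other, PolynomialForm):
            out = PolynomialForm(self.nvars)
            for e1, c1 in self.coeffs.items():
                for e2, c2 in other.coeffs.items():
                    e = _add_expt(e1, e2)
                    out.coeffs[e] = out.coeffs.get(e, 0.0) + c1 * c2
            out.coeffs = {e: c for e, c in out.coeffs.items() if c != 0}
            return out
        out = PolynomialForm(self.nvars)
        if other != 0:
            out.coeffs = {e: c * float(other) for e, c in self.coeffs.items()}
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "PolynomialForm":
        return self * -1.0

    def diff(self, index: int) -> "PolynomialForm":
        out = PolynomialForm(self.nvars)
        for e, c in self.coeffs.items():
            if e[index] > 0:
                ne = list(e)
                ne[index] -= 1
                out.coeffs[tuple(ne)] = out.coeffs.get(tuple(ne), 0.0) + c * e[index]
        return out

    def eval(self, point: Iterable[float]) -> float:
        x = np.asarray(list(point), dtype=float)
        total = 0.0
        for e, c in self.coeffs.items():
            total += c * np.prod(x ** np.asarray(e))
        return float(total)

    def substitute(self, images: list["PolynomialForm"]) -> "PolynomialForm":
        """Substitute variable i -> images[i] (polynomials over a new space)."""
        if len(images) != self.nvars:
            raise ValueError("need one image polynomial per variable")
        nv = images[0].nvars if images else 0
        out = PolynomialForm.zero(nv)
        for e, c in self.coeffs.items():
            term = PolynomialForm.constant(nv, c)
            for i, power in enumerate(e):
                for _ in range(power):
                    term = term * images[i]
            out = out + term
        return out

    # -- queries -------------------------------------------------------
    @property
    def support(self) -> set[tuple[int, ...]]:
        return set(self.coeffs)

    def total_degree(self) -> int:
        return max((sum(e) for e in self.coeffs), default=0)

    def prune(self, tol: float = 0.0) -> "PolynomialForm":
        return PolynomialForm(
            self.nvars, {e: c for e, c in self.coeffs.items() if abs(c) > tol}
        )

    def max_abs_coeff(self) -> float:
        return max((abs(c) for c in self.coeffs.values()), default=0.0)

    def to_string(self, names: list[str]) -> str:
        if not self.coeffs:
            return "0"
        parts = []
        for e in sorted(self.coeffs, key=lambda t: (sum(t), t), reverse=True):
            c = self.coeffs[e]
            mono = "*".join(
                f"{names[i]}^{p}" if p > 1 else names[i] for i, p in enumerate(e) if p
            )
            parts.append(f"{c:+.6g}" + (f"*{mono}" if mono else ""))
        return " ".join(parts)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"PolynomialForm(nvars={self.nvars}, terms={len(self.coeffs)})"


class LinExpr(dict):
    """Affine expression ``const + sum coef * var`` keyed by hashable var ids.

    The constant term is stored under the key ``None``.
    """

    def add(self, key, coef: float) -> None:
        if coef == 0:
            return
        self[key] = self.get(key, 0.0) + coef
        if self[key] == 0:
            del self[key]

    @property
    def const(self) -> float:
        return self.get(None, 0.0)

    def scaled(self, s: float) -> "LinExpr":
        out = LinExpr()
        if s != 0:
            for k, v in self.items():
                out[k] = v * s
        return out


class AffinePoly:
    """Polynomial whose monomial coefficients are :class:`LinExpr` objects."""

    __slots__ = ("nvars", "coeffs")

    def __init__(self, nvars: int):
        self.nvars = int(nvars)
        self.coeffs: dict[tuple[int, ...], LinExpr] = {}

    @classmethod
    def from_polynomial(cls, p: PolynomialForm) -> "AffinePoly":
        out = cls(p.nvars)
        for e, c in p.coeffs.items():
            le = LinExpr()
            le.add(None, c)
            out.coeffs[e] = le
        return out

    @classmethod
    def from_gram(
        cls, nvars: int, block: str, basis: list[tuple[int, ...]]
    ) -> "AffinePoly":
        """z' Q z for the monomial basis z, with Q entries as decision vars.

        Decision variable keys are ``(block, i, j)`` with ``i <= j``; the
        off-diagonal entries carry the conventional factor of two.
        """
        out = cls(nvars)
        for i, bi in enumerate(basis):
            for j in range(i, len(basis)):
                e = _add_expt(bi, basis[j])
                le = out.coeffs.setdefault(e, LinExpr())
                le.add((block, i, j), 1.0 if i == j else 2.0)
        return out

    def _acc(self, e: tuple[int, ...]) -> LinExpr:
        return self.coeffs.setdefault(e, LinExpr())

    def __add__(self, other):
        out = AffinePoly(self.nvars)
        for e, le in self.coeffs.items():
            out.coeffs[e] = LinExpr(le)
        if isinstance(other, AffinePoly):
            for e, le in other.coeffs.items():
                acc = out._acc(e)
                for k, v in le.items():
                    acc.add(k, v)
        elif isinstance(other, PolynomialForm):
            for e, c in other.coeffs.items():
                out._acc(e).add(None, c)
        else:
            raise TypeError(type(other))
        return out

    def __sub__(self, other):
        if isinstance(other, AffinePoly):
            return self + other.scaled(-1.0)
        if isinstance(other, PolynomialForm):
            return self + (other * -1.0)
        raise TypeError(type(other))

    def scaled(self, s: float) -> "AffinePoly":
        out = AffinePoly(self.nvars)
        for e, le in self.coeffs.items():
            out.coeffs[e] = le.scaled(s)
        return out

    def mul_poly(self, p: PolynomialForm) -> "AffinePoly":
        out = AffinePoly(self.nvars)
        for e1, le in self.coeffs.items():
            for e2, c in p.coeffs.items():
                acc = out._acc(_add_expt(e1, e2))
                for k, v in le.items():
                    acc.add(k, v * c)
        return out

    def diff(self, index: int) -> "AffinePoly":
        out = AffinePoly(self.nvars)
        for e, le in self.coeffs.items():
            if e[index] > 0:
                ne = list(e)
                ne[index] -= 1
                acc = out._acc(tuple(ne))
                for k, v in le.items():
                    acc.add(k, v * e[index])
        return out

    def embed(self, nvars_new: int, var_map: list[int]) -> "AffinePoly":
        """Rename/embed variables: old variable i becomes new variable var_map[i]."""
        out = AffinePoly(nvars_new)
        for e, le in self.coeffs.items():
            ne = [0] * nvars_new
            for i, p in enumerate(e):
                ne[var_map[i]] += p
            acc = out._acc(tuple(ne))
            for k, v in le.items():
                acc.add(k, v)
        return out

    @property
    def support(self) -> set[tuple[int, ...]]:
        return {e for e, le in self.coeffs.items() if le}

    def resolve(self, values: Mapping) -> PolynomialForm:
        """Fix decision variables to numbers, returning a plain polynomial."""
        out = PolynomialForm(self.nvars)
        for e, le in self.coeffs.items():
            c = le.const
            for k, v in le.items():
                if k is not None:
                    c += v * values[k]
            if c != 0:
                out.coeffs[e] = c
        return out
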