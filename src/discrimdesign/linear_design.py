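"""Linearized analysis of the difference system.

Observability-gramian machinery for initial-condition design (the output
energy of the unforced linear system is x(0)' P x(0), so the best common
initial perturbation is the top eigenvector of the block-restricted gramian),
plus frequency-response analysis for input design (the best stimulation
frequency is where the largest singular value of the transfer matrix
G(jw) = C (jwI - A)^{-1} B peaks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_continuous_lyapunov

from .model_core import DegenerateDesignError, DifferenceSystem, StabilityError
from .simulation import InputSignal, make_input_signal

__all__ = [
    "LinearDifference",
    "GramianDesign",
    "FrequencyPeak",
    "linearize",
    "observability_gramian",
    "optimal_common_initial_direction",
    "frequency_peak",
    "build_near_optimal_input",
]


@dataclass
class LinearDifference:
    """Block matrices of the linearized difference system.

    A = diag(A1, A2), B = (B1; B2), C = (C1, -C2), so that for small
    deviations y ~ C x with x the stacked deviation state.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    n1: int
    n2: int

    @property
    def n(self) -> int:
        return self.n1 + self.n2

    def select_outputs(self, output_selector=None) -> np.ndarray:
        """Rows of C for the requested output subset (indices or None=all)."""
        if output_selector is None:
            return self.C
        rows = np.atleast_1d(np.asarray(output_selector, dtype=int))
        return self.C[rows, :]

    def transfer(self, omega: float, C: np.ndarray | None = None) -> np.ndarray:
        """G(jw) = C (jwI - A)^{-1} B."""
        Cm = self.C if C is None else C
        M = 1j * omega * np.eye(self.n) - self.A
        return Cm @ np.linalg.solve(M, self.B)

    def gain(self, omega: float, C: np.ndarray | None = None) -> float:
        """Largest singular value of G(jw)."""
        return float(np.linalg.svd(self.transfer(omega, C), compute_uv=False)[0])


def linearize(diff_system: DifferenceSystem) -> LinearDifference:
    """Exact Jacobian linearization of the shifted difference system at the origin."""
    m1, m2 = diff_system.m1, diff_system.m2
    A = np.block(
        [
            [m1.jacobian, np.zeros((m1.n, m2.n))],
            [np.zeros((m2.n, m1.n)), m2.jacobian],
        ]
    )
    B = np.vstack([m1.B, m2.B])
    C = np.hstack([m1.C, -m2.C])
    eig = np.linalg.eigvals(A)
    if np.max(np.real(eig)) >= 0:
        raise StabilityError(
            f"linearized difference system is not Hurwitz (eigenvalues {np.round(eig, 6).tolist()})"
        )
    return LinearDifference(A=A, B=B, C=C, n1=m1.n, n2=m2.n)


@dataclass
class GramianDesign:
    """Observability gramian of the linearized difference system.

    P solves A'P + PA + C'C = 0; the output energy of the unforced linear
    system from x(0) is x(0)' P x(0).  For a *common* initial perturbation
    v applied to both models, the energy is v' R v with
    R = P11 + P12 + P21 + P22 (n x n blocks of P), so the optimal direction
    is the top unit eigenvector of R.
    """

    P: np.ndarray
    R: np.ndarray
    top_eigenvalue: float
    top_eigenvector: np.ndarray
    residual: float
    eigen_gap: float
    tie: bool = False
    tie_basis: np.ndarray | None = None

    @property
    def blocks(self):
        n = self.R.shape[0]
        return (
            self.P[:n, :n],
            self.P[:n, n:],
            self.P[n:, :n],
            self.P[n:, n:],
        )


def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: first nonzero component positive."""
    for c in v:
        if abs(c) > 1e-12:
            return v if c > 0 else -v
    return v


def observability_gramian(lin: LinearDifference, tie_tol: float = 1e-9) -> GramianDesign:
    """Solve the observability Lyapunov equation and assemble the restricted matrix."""
    CtC = lin.C.T @ lin.C
    try:
        P = solve_continuous_lyapunov(lin.A.T, -CtC)
    except Exception as exc:  # pragma: no cover - scipy failure path
        cond = np.linalg.cond(lin.A)
        raise RuntimeError(f"Lyapunov solve failed (cond(A) = {cond:.3e}): {exc}") from exc
    P = (P + P.T) / 2.0
    residual = float(
        np.linalg.norm(lin.A.T @ P + P @ lin.A + CtC) / max(np.linalg.norm(CtC), 1e-300)
    )
    if residual > 1e-8:
        raise RuntimeError(f"Lyapunov residual {residual:.3e} exceeds 1e-8 of ||C'C||")
    if lin.n1 != lin.n2:
        raise DegenerateDesignError(
            "common initial perturbations require both models to have the same state dimension"
        )
    n = lin.n1
    R = P[:n, :n] + P[:n, n:] + P[n:, :n] + P[n:, n:]
    R = (R + R.T) / 2.0
    w, V = np.linalg.eigh(R)
    lam = float(w[-1])
    gap = float(w[-1] - w[-2]) if n > 1 else np.inf
    tie = bool(gap <= tie_tol * max(abs(lam), 1.0))
    vecs = V[:, np.argsort(w)[::-1]]
    if tie:
        mask = w >= lam - tie_tol * max(abs(lam), 1.0)
        basis = V[:, mask]
        # deterministic representative: lexicographically greatest first component
        rep = _fix_sign(basis[:, np.argmax(np.abs(basis[0, :]))].copy())
        return GramianDesign(P, R, lam, rep / np.linalg.norm(rep), residual, gap, True, basis)
    v = _fix_sign(vecs[:, 0].copy())
    return GramianDesign(P, R, lam, v / np.linalg.norm(v), residual, gap)


def optimal_common_initial_direction(gd: GramianDesign, zero_tol: float = 1e-12):
    """Unit direction maximizing v'Rv and the resulting output-energy bound."""
    if np.linalg.norm(gd.R) <= zero_tol:
        raise DegenerateDesignError(
            "restricted gramian is numerically zero: the two models are "
            "indistinguishable from common initial perturbations"
        )
    return gd.top_eigenvector, gd.top_eigenvalue


@dataclass
class FrequencyPeak:
    """Peak of the largest singular value of G(jw) over frequency."""

    omega0: float
    gain: float
    grid: np.ndarray = field(repr=False)
    grid_gains: np.ndarray = field(repr=False)
    flat: bool = False
    refinement: dict = field(default_factory=dict)


def frequency_peak(
    lin: LinearDifference,
    output_selector=None,
    omega_range: tuple[float, float] = (1e-3, 1e3),
    n_grid: int = 2000,
    rel_width: float = 1e-6,
    flat_tol: float = 1e-9,
) -> FrequencyPeak:
    """Locate the peak gain: log-grid scan plus golden-section refinement.

    The scan uses a logarithmic grid on ``omega_range``; the refinement is a
    golden-section maximization of the gain in log-frequency between the grid
    neighbours of the scan maximizer, down to relative width ``rel_width``.
    """
    C = lin.select_outputs(output_selector)
    grid = np.logspace(np.log10(omega_range[0]), np.log10(omega_range[1]), n_grid)
    gains = np.array([lin.gain(w, C) for w in grid])
    k = int(np.argmax(gains))
    if gains.max() - gains.min() <= flat_tol * max(gains.max(), 1e-300):
        return FrequencyPeak(float(grid[0]), float(gains[0]), grid, gains, flat=True)

    lo = np.log(grid[max(k - 1, 0)])
    hi = np.log(grid[min(k + 1, n_grid - 1)])
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = lin.gain(np.exp(c), C), lin.gain(np.exp(d), C)
    iters = 0
    while (b - a) > rel_width:
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = lin.gain(np.exp(c), C)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = lin.gain(np.exp(d), C)
        iters += 1
    omega0 = float(np.exp((a + b) / 2.0))
    gain = float(lin.gain(omega0, C))
    if gain < gains[k]:
        omega0, gain = float(grid[k]), float(gains[k])
    return FrequencyPeak(
        omega0,
        gain,
        grid,
        gains,
        refinement={"iterations": iters, "bracket": (float(np.exp(a)), float(np.exp(b)))},
    )


def build_near_optimal_input(
    omega0: float, decay: float = 0.01, T_active: float = 60.0, energy: float = 1.0
) -> InputSignal:
    """Exponentially damped sinusoid at the critical frequency, exact energy.

    The signal is A exp(-decay t) cos(omega0 t) on [0, T_active] and zero
    afterwards, with A chosen so the L2 norm over the active window equals
    ``energy``.  With decay = 0 it coincides with the normalized cosine.
    """
    if omega0 < 0 or decay < 0 or T_active <= 0 or energy <= 0:
        raise ValueError("require omega0 >= 0, decay >= 0, T_active > 0, energy > 0")
    return make_input_signal(
        "eq10", omega=omega0, T_active=T_active, energy=energy, shape_params={"decay": decay}
    )
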