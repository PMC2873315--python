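"""The in-house SOS layer: polynomials, SDP solver, programme builder."""

import numpy as np
import pytest
import scipy.sparse as sp

from discrimdesign.sos import (
    AffinePoly,
    PolynomialForm,
    SDPProblem,
    SOSProgram,
    gram_basis,
    monomials_up_to,
    smat,
    solve_sdp,
    svec,
)
from discrimdesign.sos_engine import solve_sos_feasibility


class TestPolynomials:
    def test_arithmetic_and_eval(self):
        x = PolynomialForm.variable(2, 0)
        y = PolynomialForm.variable(2, 1)
        p = (x + y) * (x + y) - x * y
        # x^2 + xy + y^2 at (2, 3)
        assert p.eval([2.0, 3.0]) == pytest.approx(4 + 6 + 9)

    def test_substitute_is_composition(self):
        x = PolynomialForm.variable(1, 0)
        p = x * x + x * 2.0
        q = p.substitute([x * 3.0])  # p(3x)
        assert q.eval([2.0]) == pytest.approx(p.eval([6.0]))

    def test_monomials_up_to(self):
        ms = monomials_up_to(2, 2)
        assert (0, 0) in ms and (1, 1) in ms and (2, 0) in ms
        assert len(ms) == 6
        assert (0, 0) not in monomials_up_to(2, 2, min_deg=1)

    def test_gram_basis_newton_polytope(self):
        # support {x^4, x^2 y^2, y^4}: the constant cannot appear in any
        # Gram basis consistent with the support
        support = {(4, 0), (2, 2), (0, 4)}
        basis = gram_basis(support, 2)
        assert (0, 0) not in basis
        assert (2, 0) in basis and (1, 1) in basis


class TestSvec:
    def test_roundtrip_and_inner_product(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(4, 4))
        A = A + A.T
        B = rng.normal(size=(4, 4))
        B = B + B.T
        assert np.allclose(smat(svec(A), 4), A)
        assert svec(A) @ svec(B) == pytest.approx(np.trace(A @ B))


class TestSDPSolver:
    def test_analytic_two_by_two(self):
        # min x11 + x22  s.t.  x12 = 1, X >= 0  ->  X = [[1,1],[1,1]], obj 2
        c = svec(np.eye(2))
        A = sp.csr_matrix(svec(np.array([[0.0, 0.5], [0.5, 0.0]])))
        prob = SDPProblem([2], A, np.array([1.0]), c)
        res = solve_sdp(prob)
        assert res.status == "optimal"
        assert res.primal_objective == pytest.approx(2.0, abs=1e-6)
        assert np.allclose(res.X[0], np.ones((2, 2)), atol=1e-5)

    def test_duality_gap_closed(self):
        rng = np.random.default_rng(1)
        n, m = 5, 4
        # random feasible problem: X0 > 0 defines b, C > 0 keeps it bounded
        mats = [rng.normal(size=(n, n)) for _ in range(m)]
        mats = [M + M.T for M in mats]
        X0 = np.eye(n)
        A = sp.csr_matrix(np.vstack([svec(M) for M in mats]))
        b = np.array([svec(M) @ svec(X0) for M in mats])
        C = np.eye(n) * 2.0
        res = solve_sdp(SDPProblem([n], A, b, svec(C)))
        assert res.ok
        assert res.gap < 1e-6 and res.primal_residual < 1e-6

    def test_scalar_blocks(self):
        # min  s  s.t.  s - t = 1, s,t >= 0  ->  s = 1, t = 0
        A = sp.csr_matrix(np.array([[1.0, -1.0]]))
        res = solve_sdp(SDPProblem([1, 1], A, np.array([1.0]), np.array([1.0, 0.0])))
        assert res.ok
        assert res.X[0][0, 0] == pytest.approx(1.0, abs=1e-6)


class TestSOSProgram:
    def test_perfect_square_feasible(self):
        x = PolynomialForm.variable(2, 0)
        y = PolynomialForm.variable(2, 1)
        p = (x + y) * (x + y)
        assert solve_sos_feasibility(p).feasible

    def test_positive_quartic_feasible(self):
        x = PolynomialForm.variable(1, 0)
        p = x * x * x * x - x * x * 2.0 + PolynomialForm.constant(1, 2.0)
        assert solve_sos_feasibility(p).feasible

    def test_motzkin_infeasible(self):
        # x^4 y^2 + x^2 y^4 - 3 x^2 y^2 + 1: nonnegative but not SOS
        m = PolynomialForm(2, {(4, 2): 1.0, (2, 4): 1.0, (2, 2): -3.0, (0, 0): 1.0})
        r = solve_sos_feasibility(m)
        assert r.status == "infeasible"
        assert r.infeasibility_slack > 1e-4

    def test_negative_polynomial_infeasible(self):
        x = PolynomialForm.variable(1, 0)
        p = PolynomialForm.constant(1, -1.0) - x * x
        assert solve_sos_feasibility(p).status == "infeasible"

    def test_optimization_lower_bound(self):
        # max t such that x^2 - 2x + 3 - t is SOS  ->  t = 2 at x = 1
        prog = SOSProgram(1)
        t = prog.add_nonneg_scalar("t")
        expr = AffinePoly.from_polynomial(
            PolynomialForm(1, {(2,): 1.0, (1,): -2.0, (0,): 3.0})
        )
        expr._acc((0,)).add(t, -1.0)
        prog.add_sos(expr, "cert")
        prog.set_objective({t: -1.0})
        sol = prog.solve()
        assert sol.ok or sol.status == "inaccurate"
        assert -sol.objective == pytest.approx(2.0, abs=1e-6)

    def test_verify_rejects_corrupted_certificate(self):
        # max t with x^2 - 2x + 3 - t SOS; overclaiming t beyond the true
        # optimum 2 makes the resolved target non-SOS, which verify must catch
        prog = SOSProgram(1)
        t = prog.add_nonneg_scalar("t")
        expr = AffinePoly.from_polynomial(
            PolynomialForm(1, {(2,): 1.0, (1,): -2.0, (0,): 3.0})
        )
        expr._acc((0,)).add(t, -1.0)
        prog.add_sos(expr, "cert")
        prog.set_objective({t: -1.0})
        sol = prog.solve()
        assert all(r["passed"] for r in prog.verify(sol).values())
        sol.grams["t"] = sol.grams["t"] + 1.0  # claim t = 3
        assert not all(r["passed"] for r in prog.verify(sol).values())

    def test_psd_clip_projects(self):
        G = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        Gc = SOSProgram._psd_clip(G)
        assert np.linalg.eigvalsh(Gc).min() >= -1e-12
        assert np.linalg.norm(Gc - G) == pytest.approx(1.0, abs=1e-12)
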