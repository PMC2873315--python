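# Methods

This document describes the mathematics implemented by `discrimdesign` and
the numerical decisions behind it. Notation: the two rival models are

    dx_i/dt = f_i(x_i) + g_i(x_i) u,    y_i = h_i(x_i),    i = 1, 2,

with a shared input u (basal level u0), outputs of equal dimension, and a
common observed steady state.

## 1. The difference system

Each model is shifted so that the investigated steady state sits at the
origin: the steady state x\* is solved from f_i(x) + g_i(x) u0 = 0
(damped Newton from a user guess), the Jacobian at x\* is checked to be
Hurwitz, and the dynamics are rewritten in deviation coordinates. The two
shifted models are then concatenated into a single system with state
(x1, x2) ∈ R^(n1+n2), the same input entering both, and output

    y = y1 − y2,

which vanishes identically when the models coincide. All designs maximize
the L2 norm ‖y‖₂ of this difference output; a large value means an
experiment whose outcome separates the models.

Polynomiality of all expressions is detected at parse time; the SOS
machinery (sections 5–8) requires it, while the linear and simulation
machinery does not.

## 2. Linear initial-condition design

Linearizing the difference system at the origin gives block matrices
A = diag(A1, A2), B = (B1; B2), C = (C1, −C2). For the unforced linear
system the output energy from initial state z is z' P z, where P solves the
observability Lyapunov equation

    A' P + P A + C' C = 0,

solved directly (Kronecker/Bartels–Stewart via `scipy`); the residual is
recorded and required to be ≤ 1e−8 · ‖C'C‖. Experimentally one perturbs
both models by the *same* initial deviation v, i.e. z = (v, v). Writing P
in n×n blocks, the energy becomes v' R v with

    R = P11 + P12 + P21 + P22,

so the most discriminating common unit direction is the top eigenvector v̂
of the symmetrized R, with energy λ̂ (its top eigenvalue). For the case
study λ̂ = 0.5301 and v̂ = (1, 0, 0): perturbing the activator alone.
Degenerate designs (λ̂ ≈ 0, e.g. identical models) raise a dedicated error.
A near-tie between the top two eigenvalues is flagged in the report.

## 3. Frequency-domain input design

For the linearized difference system the induced L2 gain from input to
output is the H∞ norm: the peak over ω of the largest singular value of
G(jω) = C (jωI − A)⁻¹ B. The peak is located on a logarithmic frequency
grid and refined by golden-section search; the refinement trace and the
flatness of the peak are reported. The critical frequency ω₀ is the
recommended stimulation frequency. A near-optimal finite-duration input is
a slowly decaying cosine at ω₀, normalized to unit L2 energy by exact
quadrature; as the window grows and the decay vanishes its response norm
approaches the peak gain.

The candidate stimuli ranked by the input-design workflow — sine, square
wave, sinc, constant, each on a window [0, T] at unit energy — are all
parameterized by ω₀. Amplitudes are set from closed-form energy integrals
where available, otherwise by adaptive quadrature, so ‖u‖₂ = 1 holds to
1e−6 relative accuracy.

## 4. Nonlinear simulation and energy quadrature

All designs are ultimately scored by simulating the full nonlinear
difference system. The integrator is `scipy.solve_ivp` (LSODA/BDF for the
stiff case-study dynamics) with the *squared output norm appended as an
extra quadrature state*, so the reported energy ∫‖y‖² dt carries the same
accuracy as the trajectory (default rtol 1e−9). Discontinuities of square
waves and window edges are passed as breakpoints. Integration runs to an
effective infinity: after the active window, the horizon is doubled until
the remaining energy — bounded by the linearization's decay envelope from
the current state — is negligible relative to the accumulated energy; this
tail bound is reported. Brute-force searches (direction sphere, parameter
box × sphere) use a coarse tolerance for the scan and re-simulate the
winner at full tolerance.

## 5. Sum-of-squares machinery

A polynomial p is SOS if p = Σ q_k² for polynomials q_k, equivalently
p(z) = m(z)' Q m(z) for a PSD Gram matrix Q over a monomial basis m —
decidable by semidefinite programming. The SOS layer provides:

- sparse multivariate polynomial arithmetic over exponent tuples;
- Gram basis selection by Newton-polytope reduction (only monomials whose
  double lies in the convex hull of the support are kept);
- affine polynomial expressions in scalar/Gram decision variables;
- an SOS programme builder that assembles the coefficient-matching
  constraints into a standard-form SDP.

### The SDP solver

Since no external conic solver is a dependency, the package includes a
primal-dual interior-point method for semidefinite programming:

- Nesterov–Todd scaling; the scaling point W is computed per block from
  Cholesky factors.
- Predictor-corrector iterations with a second-order (Mehrotra) correction:
  after the affine predictor step (dXa, dZa), the complementarity
  right-hand side is corrected by sym(dXa · dZa · Z⁻¹) before the
  corrector solve. The Schur complement is formed once per iteration and
  factorized by Cholesky with diagonal regularization on failure.
- Stall recovery: if the corrected step collapses (step length < 1e−3),
  the step is retried without the corrector, then as a pure centering step
  (σ = 1) at half length. This lifts the achievable accuracy on
  near-degenerate certificates by several orders of magnitude.
- Infeasibility is reported via the standard residual/objective divergence
  heuristics; for feasibility-style programmes a `merit_mode` selects the
  best iterate by feasibility residuals rather than by objective.

### Independent certificate verification

Solver output is never trusted as a proof. Verification re-derives each
claimed identity: every Gram matrix is projected onto the PSD cone
(eigenvalue clipping), the certified polynomial identity is re-expanded,
and the coefficient mismatch is *absorbed* back into the Gram entries that
can represent each monomial (charging unrepresentable residuals at face
value). The certificate passes if the corrected Gram's minimum eigenvalue
is ≥ −(eig_tol + numerical slack). The verification tolerance is never set
stricter than the solve tolerance.

## 6. Storage functions for initial-condition design

On the region D = {‖x1‖ ≤ α, ‖x2‖ ≤ α} (default α = 0.1, the scale on
which the case-study deviations stay physical), a storage function S ≥ 0
with

    −∇S · f − y'y − σ1 (α² − ‖x1‖²) − σ2 (α² − ‖x2‖²)  SOS,   σ1, σ2 SOS

certifies that S(x(0)) bounds the unforced output-difference energy for
trajectories remaining in D. The SDP minimizes the trace of the quadratic
part of S (largest certified level sets). States are pre-scaled by α so the
SDP is well conditioned.

The most discriminating common initial direction at norm β is then found by
shrinking a level: minimize γ subject to

    γ − S(z, z) − σ(z)(β² − ‖z‖²)  SOS,

whose optimum touches the sphere ‖z‖ = β at the best direction. The
touching point is read off the dual moment matrix (accepted when its
second/first eigenvalue ratio certifies rank one) and cross-checked by a
multistart search of S on the sphere, which also serves as fallback.

## 7. Certified L2-gain bound (input design)

A gain bound γ on D follows from a storage function with supply rate
γ²u'u − y'y:

    ∇S · (f + g u) ≤ γ² u'u − y'y   on D for all u,

encoded as an SOS constraint in (x, u) with the same ball multipliers. Two
passes are used:

1. γ² enters the SDP linearly and is minimized, giving `gamma_solver`.
2. Because interior-point termination is approximate, the bound is then
   re-certified at a short ladder of safety margins above
   max(`gamma_solver`, linearized peak gain) — the H∞ norm of the
   linearization is a hard lower bound on the regional gain, so an
   undershooting solver value is raised to that floor. Each re-certification
   fixes γ and maximizes a uniform interior slack t over the constraint's
   slack basis; the certified identity p − t·Σ z^(2b) = z'Qz lets any
   τ ≤ t be moved back onto the Gram diagonal, so verification passes iff
   min_eig(Q) + t ≥ −eig_tol. The first margin that verifies is reported
   (for the case study: margin 5e−4, certified γ = 0.4773 at degree 2,
   0.4776 at degree 4, against the linearized floor 0.4766).

The bound is regional: it certifies ‖y‖₂ ≤ γ‖u‖₂ only while the state
stays in D, which the workflows check by simulation and report.

## 8. Structural design

Here the designable quantities are parameters p in a box Π; changing them
moves each model's steady state, so the shift itself depends on p. The
implementation uses a polynomial *chart* of the box: a reparameterization
under which both steady-state shifts and the shifted vector fields are
polynomial in the chart coordinates (supplied per model family; the
case-study chart covers (kr, RT) exactly). The parametric storage
certificate

    −∇_x S(x, p) · f(x, p) − y'y − σ1(α² − ‖x1‖²) − σ2(α² − ‖x2‖²)
        − Σ_j τ_j g_j(p)   SOS,    σ_i, τ_j SOS,

with g_j ≥ 0 describing the (chart image of the) box, bounds the unforced
energy jointly over D × Π. S is quadratic in the states with affine
parameter dependence by default.

Extraction again minimizes a touching level γ over the common subspace and
the box; the optimal parameter point comes from first-order dual moments
and the direction from the second-moment block, cross-checked by a
constrained multistart search. The box typically contains the point where
the rival models coincide, which pins the dissipation inequality to exact
tightness along that manifold — no strictly interior certificate exists, so
the structural verification accepts an eigenvalue slack of 1e−5, about four
orders of magnitude below the reported storage bound.

The brute-force route grids Π and the direction sphere, re-solving the
steady state at every parameter point, then refines the best cell. Both
routes' proposals are re-simulated and the best simulated value wins; for
the case study both agree on the box corner (RT, kr) = (3, 1.5) — the SOS
extraction recovers it to 1e−8 — with the simulation preferring the
direction (1, 0, 0) and value 0.746.

## 9. Tolerances and determinism

- Steady states: residual ≤ 1e−10 componentwise; Hurwitz check exact on
  the Jacobian eigenvalues.
- Lyapunov residual: ≤ 1e−8 relative (achieved ~1e−16).
- Simulation: rtol 1e−9 for reported values, 1e−5 for coarse scans; tail
  bounds reported.
- SDP: solve tolerance 1e−8; verification eig_tol 1e−9 (feasibility),
  1e−6 (gain certification ladder), 1e−5 (parametric structural, see §8).
- All searches use fixed seeds and deterministic grids; repeated runs give
  identical reports up to floating-point reproducibility.

## 10. Limitations

- SOS routes require polynomial dynamics; rational models fall back to
  linear/simulation/brute-force routes with an explicit capability error.
- Region containment (trajectories staying in D) is checked by simulation
  and flagged, not certified by reachability analysis.
- The structural SOS route needs a polynomial chart of the parameter box;
  generic model pairs without one run the brute-force route.
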