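# Methods

## Model

The solver targets the one-dimensional time-fractional reaction–diffusion
model of tumor-cell concentration

    D_t^α u = u_xx − k(x, t) u,   0 < α ≤ 1,  (x, t) ∈ [0, L] × [0, T],

with Dirichlet boundary data and a Caputo fractional time derivative.
α < 1 introduces memory: the rate of change at time t depends on the whole
history of u, weighted by a power-law kernel. At α = 1 the model is the
classical diffusion equation with a linear removal term; k(x, t) ≥ 0 acts
as a net killing rate of cancer cells. The validated scenario uses the
purely time-dependent rate k = t², for which a truncated series solution
is available (see Oracles).

Uncertainty is fuzzy, not stochastic: coefficients are triangular fuzzy
numbers scaling crisp kernels. A triangular number (a, c, b) has linear
membership with core c; its r-level cut is [a + r(c−a), b − r(b−c)]. The
double parametric substitution ũ(r, β) = β(ū − u̲) + u̲ turns the
interval pair at each level r into one scalar family over (r, β) ∈ [0,1]².
Because every fuzzy coefficient is a scalar times a crisp kernel, the
fuzzy problem at fixed (r, β) is an ordinary crisp PDE, which is what the
solver integrates; the bundle of crisp solutions over an (r, β) grid is
the fuzzy solution. The triangular shape is a modelling choice — the
worked example's scale is (−1, 0, 1), whose parametric value is
φ(r, β) = β(2 − 2r) + (r − 1). β = 0.5 is the "inflection value" at which
the family crosses from lower- to upper-branch behaviour; no special
computation attaches to it. Extension-principle min/max fuzzy arithmetic
is out of scope: the parametric scalar-times-kernel construction is all
the model needs, and for a linear scheme it yields the same envelope.

## Discretization

Node-centered grid x_i = iΔx (i = 0..M), t_n = nΔt (n = 0..N); L/Δx and
T/Δt must be whole numbers and evaluation points must coincide with nodes
(no interpolation). The Caputo derivative is discretized by the L1-type
sum with weights b_j = (j+1)^(1−α) − j^(1−α); the Laplacian by centered
differences at level n; the reaction term explicitly at (x_i, t_n) —
k carries no time level in the continuous model, and the explicit level is
consistent with every other n-level term. With ρ = Δt^α Γ(2−α) and
s = ρ/Δx² the interior update is

    u_i^{n+1} = s(u_{i+1}^n + u_{i−1}^n) + (1−2s)u_i^n − ρ k(x_i,t_n) u_i^n
                − Σ_{j=1}^{n} b_j (u_i^{n+1−j} − u_i^{n−j}).

Telescoping the sum gives the algebraically identical regrouped form

    u_i^{n+1} = s u_{i+1}^n + (1−2s−ρk−b_1) u_i^n + s u_{i−1}^n
                − Σ_{j=1}^{n−1} (b_{j+1}−b_j) u_i^{n−j} + b_n u_i^0,

which the production solver uses (O(n) work per step either way; the two
forms are cross-checked against each other and against a naive
direct-history oracle in the tests). Full history is retained — O(M·N)
memory, no short-memory truncation — favouring fidelity of the memory sum
over speed; all runs here are desk-scale. Γ is scipy's gamma. Boundary
values may be constants, functions of t, or delegated to the series
solution (used for the worked example, whose boundary data is stated only
abstractly). All arithmetic is double precision; algebraic-identity
assertions use 1e−12 relative tolerance.

Weight facts used by the stability argument: 0 < b_j ≤ 1, b_j strictly
decreasing, and with the convention b_0 = 1 the telescoping identity
Σ_{j=0}^{n−1}(b_j − b_{j+1}) = 1 − b_n. (Stated with the sum from j = 1
the identity would telescope to b_n − b_1 instead; the implementation
asserts the j = 0-based form.)

## Stability

Fourier analysis of the error recursion yields a sufficient bound on the
diffusion number. The operative check is

    s ≤ (1 − ρ k_max − b_1) / 4,

with b_1 = 2^(1−α) − 1 and k_max the max of |k| over all grid nodes and
levels of the run (evaluated at the β = 1 branch when k is fuzzy — worst
case). It reduces to the classical FTCS limit 1/4 as α → 1, k → 0, and is
non-increasing in both k_max and b_1. A companion bound of the form
s ≤ 1/(4 − s Δx² k_max) is also reported; its printed form is ambiguous
(it conflicts with the first bound), so it is implemented under a
documented literal reading, evaluated at the run's own s, and never used
as the operative check. A non-positive denominator is reported as
unbounded with a warning.

The solver emits a stability advisory and proceeds even when the bound is
violated, so instability experiments are runnable; non-finite values
abort with an error naming the offending level.

What stability means here — ‖ε^n‖₂ ≤ ‖ε^0‖₂ in the discrete norm
‖ε‖₂ = sqrt(Σ_i h ε_i²) — is also checked empirically: the perturbation
probe adds a seeded uniform perturbation to the interior initial nodes,
runs the solver twice and reports the per-level ratio of error norms.
For this linear scheme the difference of the two runs satisfies exactly
the homogeneous error recursion, so the probe is equivalent to evolving
the recursion while reusing the tested solver. On the worked example
(s ≈ 0.0603 ≤ 0.2320) the max ratio stays ≤ 1; a classical α = 1 run
driven at s = 0.6 > 1/2 amplifies, as von Neumann analysis predicts.

## Oracles

Three independent references validate the solver:

1. **Truncated series** for the k = t² worked example:
   u = φ(r, β) e^{kx} (1 + k² t^α/Γ(1+α) + k⁴ t^{2α}/Γ(1+2α)).
   This is a truncated series, not the full closed-form solution (it
   omits higher killing-rate correction terms), which is adequate at the
   short horizon t ≤ 0.05 where it is used. φ multiplies the entire
   series: the bracket placement is forced by the fact that the solution
   and its error must vanish identically at r = 1.
2. **Classical closed form** e^{−π²t} sin(πx) for the α = 1, k = 0 limit
   on [0, 1] with zero boundaries.
3. **Direct-history stepper**: scalar loops, full memory sum re-evaluated
   every level, no telescoping — deliberately naive so that it shares no
   algebra with the production path. Restricted to grids ≤ 200 × 200.

## Worked-example preset (eq30)

α = 0.9, Δx = 0.5, Δt = 0.01, domain [0, 8], horizon t = 0.05 (5 steps),
k(t) = t², IC φ(r, β) e^{kx}, fuzzy scale (−1, 0, 1), evaluation at
x = 4 (interior). Three quantities the source scenario leaves open are
fixed as package defaults, all CLI-overridable:

- **k = −1** in e^{kx}: the magnitude of the reference values at x = 4
  (≈ e^{−4}·O(1)) is consistent with decay and not with growth.
- **Domain [0, 8]** so that x = 4 is interior with an integral number of
  steps on both sides.
- **Dirichlet boundaries from the series solution** at x = 0 and x = 8,
  since the scenario states boundary data only abstractly.
- **Δt = 0.01**: the step is garbled in the source scenario; 0.01 reaches
  t = 0.05 in whole steps.

With these resolutions the solver reproduces the reference table's values
to better than 1% and its internal structure exactly (zeros at r = 1,
β = 1 values the negatives of β = 0, error columns proportional to
|φ(r, β)|). Exact agreement to the printed precision is not attainable:
the reference's own numerical/exact pairs cannot be reconciled with the
printed series under any choice of the open parameters, so the residual
~1% discrepancy is attributed to those unstated choices, and this package
reports its honestly computed values rather than tuning toward the table.

The r and β grids default to r ∈ {0, 0.2, 0.4, 0.6, 0.8, 1} and
β ∈ {0, 0.4, 0.6, 1}, the sampling the reference table uses; both are
overridable.

## Experiments and their problem sizes

- **table1**: the preset above; 17 nodes × 6 levels per (r, β) sample,
  24 samples — well under a second.
- **sweep-alpha**: the preset at α ∈ {0.5, 0.7, 0.9, 1.0} (default);
  reports the point error at (4, 0.05) and the max interior error at the
  final time. The error decreases monotonically as α → 1 here; note this
  is a statement about agreement with the truncated series at fixed
  (Δx, Δt), not a convergence order.
- **refine**: default ladder (Δx, Δt) = (0.5, 0.01), (0.25, 0.0025),
  (0.125, 0.000625), chosen so every rung satisfies the stability bound
  (each Δx halving pairs with a ~quartered Δt). Unstable rungs are
  refused with the bound printed unless forced; forced rungs that
  overflow are reported, not raised.
- **probe**: perturbation magnitude 1e−6 by default — far below solution
  scale, far above roundoff.

Fixtures ("eq30", "classical_heat", "random_tri_ic") are deterministic in
the seed; eq30 and classical_heat are fully determined and
seed-independent. The random fixture draws a triangular scale with core
in [−0.5, 0.5] and spreads in [0.1, 1], a random α ∈ [0.5, 1] and random
named kernels — small, stable desk-scale instances for regression
testing, not emulations of any particular tumor dataset.

## What the synthetic scenarios do and do not show

All validation here is against analytic references and internal
consistency (linearity, algebraic identities, stability theory) on the
model's own terms. Passing says the scheme solves the stated fuzzy
fractional PDE correctly and stably; it says nothing about whether that
PDE, its triangular uncertainty model, or the k = t² killing rate
describe any real tumor. Space-dependent and concentration-dependent
killing rates run through the same code path (generic crisp k(x, t)) but
are not validated against references, and α ∈ (1, 2] is not supported.

## Known limitations

- Explicit scheme only: the stability bound ties Δt to Δx² (fractionally
  worsened by b_1); implicit/Crank–Nicolson variants are out of scope.
- The series oracle degrades for longer horizons and larger |k| t^α.
- O(M·N) history memory and O(M·N²)-ish stepping cost; fine at desk
  scale, not tuned beyond that.
- One spatial dimension, Dirichlet boundaries, no adaptive stepping.
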