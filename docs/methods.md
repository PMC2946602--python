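# Methods

This note records the model as implemented, the numerical choices behind it,
what the synthetic experiments do and do not demonstrate, and the design
decisions that were genuinely open.

## Model and estimation procedure

The deformation model is geodesic shooting on point sets: a template surface
with `L` vertices and an initial momentum field `α ∈ (ℝ³)^L` determine a
deformation through the EPDiff Hamiltonian system with kernel
`γ(r²) = cst·exp(−r²/2τ²)`.  The system conserves the Hamiltonian
`H = ½ Σ_{kl} γ_{kl}(a_k·a_l)` and total linear momentum; both are used as
integrator diagnostics rather than enforced.

The observation likelihood is a currents metric: each face contributes a
point current at its center `c_f = (x₁+x₂+x₃)/3` with weight
`N_f = ½(x₂−x₁)×(x₃−x₁)`, and two surfaces are compared through the squared
RKHS distance induced by a Gaussian kernel `γ_obs` of width `σ_w`.  This
comparison requires no correspondence and tolerates different vertex counts
and meshings of the two surfaces; its blind spots are discussed below.

Estimation alternates two block descents on the joint posterior objective

    E_total = λ‖μ‖²_{T₀} + Σ_n [ ‖α⁽ⁿ⁾‖²_T + ‖S⁽ⁿ⁾ − T_{α⁽ⁿ⁾}‖²_obs / σ² ].

The matching step updates each `α⁽ⁿ⁾` at fixed template; the template step
updates `μ` at fixed `α⁽ⁿ⁾` (the `α` vectors are carried by vertex index
while the template moves — they are coefficients, not a transported field).
Each step runs a capped number of line-search iterations (generalized-EM
style): because every accepted line-search step decreases its block
objective, `E_total` is non-increasing across outer iterations regardless of
the caps.  The template-step objective is implemented in the form
`‖μ‖² + (1/λ)Σ(…)`, which differs from `λ‖μ‖² + Σ(…)` only by the positive
factor λ and has the same minimizers; the reported `E_total` uses the latter
convention so a single number is monotone under both steps.

### Gradients

Both steps need gradients through the geodesic flow.  Differentiating the
shooting system along a trajectory yields a linear system with blocks built
from γ, γ′, γ″; its transpose is integrated backward in time (the costate
sweep), delivering `(dx(1)/dα)*·v` as `η_α(0)` and `(dx(1)/dx(0))*·v` as
`η_x(0)` at the cost of one extra ODE solve.  The template gradient threads a
two-level chain: the currents gradient at each deformed surface is pulled
back through the corresponding `α`-flow (η_x leg), the direct derivative of
`‖α‖²_T` with respect to the template vertices
(`4Σ_l γ′(‖x_k−x_l‖²)(α_k·α_l)(x_k−x_l)`; the factor 4 — two appearances of
each vertex in the symmetric double sum times the inner chain factor 2 — is
validated against finite differences) is added, and the sum is pulled back
through the `μ`-flow.  The currents gradient itself carries a
center-transport term with factor 2/3 (from `∂c_f/∂x_l = I/3` and the
symmetric double count) and a normal-variation term `Q_f × e_l(f)` with
`e_l(f)` the edge opposite vertex `l` traversed in face orientation
(`δN_f = ½ e_l(f) × δx_l`); every term is checked against central finite
differences of the energy, which is the authority wherever a sign or factor
convention is ambiguous.

Descent directions are preconditioned by `Γ_T` (the gradient in the kernel
inner product), computed by conjugate gradient on the ridged scalar gram —
the Kronecker structure `Γ_T = G ⊗ I₃` means all linear algebra runs on the
L×L scalar gram `G`.

## Tunable parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| τ | deformation-kernel width (length) | 0.2 × hypertemplate bbox diagonal | smooth, large-scale deformations; exposed in every config |
| cst | kernel amplitude γ(0) | 1 | trades off exactly against momentum scale; fixing it loses no generality |
| σ_w | currents-kernel width (length) | 0.1 × bbox diagonal | mismatch resolved at ~10% of object size; finer detail is invisible to the likelihood |
| λ | hypertemplate weight | 1.0 | the reference setting of the estimation experiments |
| σ² | observation-noise variance | 1.0 (estimation); 0.01 for standalone registration | at σ²=1 the prior retains a visible pull; registration use weights the data term heavily |
| steps | RK4 steps on [0,1] | 20 (optimization), 100–200 (verification) | see numerical notes |
| ridge | gram regularization | 1e-7·γ(0) (generic solves), 1e-5·γ(0) (preconditioner) | the Gaussian gram is near-singular; the preconditioner only needs to be SPD |
| CG tol / maxit | gram solves | 1e-10 / 10·3L generic; 1e-8 for preconditioning | preconditioning does not need tight solves; the line search guards descent |

Line search: Armijo backtracking with constant 1e-4, halving factor 0.5, at
most 25 halvings, and a warm-started initial step of min(1, 2× the last
accepted step) — a well-scaled iteration then costs a single energy
evaluation.  Stopping: relative energy decrease below 1e-6 (matching) or
preconditioned-gradient norm below a relative threshold; the outer EM loop
stops at a 1e-6 relative decrease of `E_total`.

## Numerical choices

* **Integrator.** Classical fixed-step RK4 for both the forward shoot and the
  backward costate sweep.  Fixed steps keep the two passes on the same grid;
  the trajectory is stored densely (2·(steps+1)·3L floats) because the sweep
  needs the state at stage times.
* **Continuous adjoint.** The costate system uses the analytically transposed
  Jacobian, evaluated at states linearly interpolated between stored steps.
  This commits an O(h²) gradient inconsistency relative to the exact
  discrete adjoint of the RK4 forward pass — measured at ~1e-5 relative at 20
  steps and ~1e-6 at 100 on the verification fixtures — which the line
  search absorbs; verification tests use 100–200 steps.
* **Degenerate inputs.** Zero-area faces, out-of-range indices and repeated
  vertices are load-time errors naming the face; inconsistent orientation is
  an error for closed meshes and a warning for open ones (the currents
  metric is defined for both).  A blow-up of the flow (non-finite state)
  aborts with the step index; the usual cause is a momentum far too large
  for the kernel width.
* **Gram conditioning.** For the Gaussian kernel, the gram spectrum on fine
  meshes reaches numerical zero (min eigenvalue ~3e-9 on the 162-vertex
  sphere at the default τ).  Every solve is ridged, and the sampler and
  preconditioner use documented larger ridges (below).
* **Ties/order.** Population order never affects the objective (a sum over
  observations); targets are processed in input order and results are
  bit-reproducible for a fixed config and seed.

## The synthetic generator

`synthetic.generate_population` draws momenta from the model's own prior
(`α = scale·C⁻ᵀz` with `C` a Cholesky factor of the ridged gram, so
`‖α‖²_T/scale²` is χ²_{3L} up to the ridge) and shoots the base mesh — the
population is generated by the estimation model itself, which is what makes
template recovery a well-posed oracle.  Two deliberate departures from the
raw prior:

* **Spectral cutoff** (`sampling_ridge = 3e-2·γ(0)`).  An exact
  inverse-covariance draw on a fine mesh is dominated by the gram's
  noise-level eigenmodes; their nonlinear evolution systematically contracts
  the shape (~6% radial shrink on the 162-vertex sphere) — a sampling
  artifact of the ill-conditioned kernel, not the smooth anatomical
  variability being emulated.  The cutoff suppresses unresolved modes while
  leaving the moment check on well-conditioned coarse meshes (12 vertices)
  essentially exact.
* **Momentum scale** `0.9/√(3L)`, calibrated once so that mean vertex
  displacement is 5–10% of the shape radius — visible deformation with no
  face degeneracy across seeds.

What passing the synthetic experiments shows: the gradients, flows and both
optimization loops are correct and the estimator recovers the generating
template from its own model class.  What it does not show: robustness to
real segmentation noise, topology errors, boundary effects on open meshes,
or model misspecification (real shapes are not geodesic sprays of a sphere);
meshes here are two orders of magnitude smaller than clinical surfaces, so
no claims about large-L performance or runtime are made.

## Evaluation metric

Template recovery is scored by an exact symmetric mean point-to-surface
distance (vectorized point-triangle closest-point queries, brute force over
all pairs), deliberately independent of the currents kernel so a bug shared
with the fitting metric cannot hide.  The matching probe additionally checks
vertex-level recovery; note the currents metric is blind to tangential
reparameterization, so vertex recovery degrades with perturbation size even
when the surfaces coincide as currents — the probe uses a perturbation at
half the population scale, where vertex recovery is well-posed (measured
max vertex error 2.6% / 1.2% / 0.6% of diameter at 1.0/0.5/0.25× the
population scale).

## Open design decisions taken

* The continuum form of the momentum equation and the discrete system differ
  in one inner product; the discrete system is what the algorithms integrate
  and is implemented as such.
* The matching objective carries the 1/σ² weight on the mismatch term (the
  form consistent with the probabilistic model).
* The edge-term sign in the currents gradient follows the direct derivation
  `δN_f = ½ e_l(f)×δx_l`, confirmed by the finite-difference oracle.
* σ² is kept fixed.  A closed-form residual-based update would be possible
  (the mismatch term is quadratic in the observation noise) but is not
  implemented.
* The matching and template steps warm-start from the previous outer
  iteration's momenta, which preserves monotone descent and saves inner
  iterations; the very first iteration starts from zero momenta.
* No hard bound is enforced on `‖μ‖` (the prior's normalizability constraint
  is a theoretical device; the descent never approaches the regime where it
  would bind).

## Known limitations

* O(L²) kernel sums and O(M·M′) currents sums: fine to a few thousand
  vertices, no low-rank or grid acceleration.
* Currents blindness to orientation-preserving reparameterization (above)
  and to closed null currents; the population spread must be resolved by
  σ_w for the likelihood to discriminate.
* The mode-approximation EM is known to be biased for large noise; nothing
  here corrects that.
* Open meshes are accepted but the synthetic experiments exercise closed
  genus-0 surfaces only.
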