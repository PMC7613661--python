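# Methods

## Wall mechanics

### Kinematics and residual stress

The artery is a circular cylinder, meshed radially in its stress-free
configuration (inner radius r_i0 = 1.5 mm, thickness T0 = 0.32 mm). Residual
stress is introduced multiplicatively: an incompatible pre-stretch
`F_a = diag(λa_r, λa_θ(R), λa_z)` maps the stress-free state to an
incompatible, stress-free intermediate; the elastic deformation `F_e`
measured from that intermediate carries all stress. With the axial length
held fixed (λtot_z = 1) the elastic axial stretch is λe_z = λ_axial
everywhere, and for the total deformation r(R) of the closed (or cut-open)
wall, λe_θ = λtot_θ / λa_θ and λe_r = λtot_r / λa_r.

The circumferential pre-stretch λ_circ(R) (with λa_θ = 1/λ_circ) follows
the classical opening-angle construction: the stress-free state of a ring
with opening angle Φ is a circular sector of identical thickness, giving
λ_circ = k·R/R₀ with k = 2π/(2π − Φ). The construction needs one closure
to pin the sector radii; we take the mid-wall circumference as unstretched
(λ_circ(R_mid) = 1), which at Φ = 98.9° yields inner/outer endpoints
0.9715/1.0248. The profile is evaluated on stress-free radii and is
near-linear across the wall.

**Radial component of `F_a`.** Only the circumferential and axial
components are physically prescribed; the radial component is a modeling
choice. We close it by volume preservation, `det F_a = 1`
(λa_r = λ_circ·λ_axial). The alternative λa_r = 1 makes the pre-stretch
volumetrically incompatible through the compressible matrix response: the
wall then thins strongly under the axial pre-stretch, the trans-wall
stretch gradient steepens, and no opening angle below 180° homogenizes
the loaded wall. With the isochoric closure the homogenization objective
has a sharp interior minimum, and inner and outer elastic stretches agree
to four decimals at the optimum — this closure is therefore used
throughout.

### Constitutive model

Strain energy Ψ = Ψ_m + Ψ_f per unit incompatible-reference volume:

- matrix (volume fraction 1 − φ_f): compressible Neo-Hookean,
  `Ψ_m = (1−φ_f)[κ/2·ln²J_e + μ/2·(I1_e − 3 − 2 ln J_e)]` with
  κ = 2μ(1+ν)/(3(1−2ν)); ν = 0.498 makes the response slightly
  compressible (|J_e − 1| < 0.2 % in all equilibrium solutions up to
  200 mmHg).
- fibers: N = 60 directions equally spaced over one period [−90°, 90°) of
  the weight `B·exp[(cos 2(ω−α) + 1)/d]`, rescaled to sum to φ_f. Each
  direction stores `k1/(2k2)·(exp[k2(λ² − 1)] − k2(λ² − 1) − 1)` where λ is
  the elastic stretch of the direction *after* pushing it through `F_a`
  and renormalizing (ψ = atan2(λa_z sin ω, λa_θ cos ω)); fibers bear
  stress only in tension (λ > 1). Note the exponent is linear in
  (λ² − 1), not quadratic as in the classical
  Holzapfel–Gasser–Ogden form; it is implemented exactly as defined.

The Cauchy stress is the analytic derivative
σ = (2/J_e)·F_e·(∂Ψ/∂C_e)·F_eᵀ, with diagonal components
σ_kk = (λe_k/J_e)·∂Ψ/∂λe_k for the diagonal deformations handled here; it
is verified against central finite differences of Ψ (≤ 1e-5 relative over
random states). A single fiber family centered off-axis produces a θ–z
shear component; it is reacted by the circumferential symmetry constraints
of the cylindrical problem, never enters radial equilibrium, and is not
reported.

### Equilibrium solver

Radial equilibrium, `dσ_rr/dr + (σ_rr − σ_tt)/r = 0` with σ_rr = −P at the
inner and 0 at the outer surface, is discretized on n_radial = 33 uniform
reference stations (stations coincide with the 32 cell boundaries) with a
second-order midpoint-collocation (box) scheme in the unknowns
(r_j, σ_rr,j) and solved by `scipy.optimize.root`. Doubling the station
count changes λe_θ by < 0.1 %, and the interior residual of accepted
solutions is < 1e-3 of the peak hoop stress. A pressure-continuation
fallback handles poor initial guesses. λe_r at stations is recovered by
inverting the (monotone, fiber-free) radial constitutive relation for the
converged σ_rr, so the reported boundary tractions are exact to solver
tolerance.

Open sectors are handled by one extra parameter: a sector of angle
2π/k_o gives λtot_θ = ρ/(k_o R). The radial-cut release finds the opened
angle minimizing total strain energy over equilibrium open-sector states
at zero pressure — at the minimum the cut faces carry no net force or
moment. The release checks close the loop: imposing the calibrated profile
and cutting recovers the imposed angle within 0.05°, and the axial release
is the closed form L/λ_axial. The cut test applies to the circumferentially stressed artery
(λ_axial = 1); with the axial pre-stretch retained, the axial fiber
tension dominates the hoop imbalance and the sector would instead close.

### Opening-angle calibration

Φ minimizes Σ_j |λe_θ,j − mean(λe_θ)| over stations for the artery loaded
at 100 mmHg with λ_axial = 1.39 (bounded scalar minimization on
(1°, 179°), 0.05° tolerance; the objective is smooth and unimodal in
sweeps). Result: 98.93°, with a wall stretch CV of 0.03 % at the optimum
versus 4.4 % without residual stress.

## Notch signaling model

32 cells (wall thickness / 0.01 mm cell size) in a radial line, cell 1
luminal. Per cell, four ODEs in N, J, D, I with production, degradation
(γ = 0.1/h for N, J, D; γ_I = 0.5/h), cis-inactivation (k_c = 5e-4) and
trans-interaction (k_t = 2.5e-5) with the mean of the two neighbors'
counterparts; trans-binding of receptors releases NICD. Production is
modulated by `HS(I, Λ, n) = Λ + (1−Λ)/(1 + (I/I0)^n)` with I0 = 200 and
(Λ, n) = (2, 2) for Notch, (2, 5) for Jagged, (0, 2) for Delta, and — for
Notch and Jagged only — by exp(A·E_θθ) with A_N = −5.79, A_J = −4.17.
The NICD equation itself carries no Hill or strain factor. Boundary cells:
the luminal neighbor contributes only the constant endothelial Jagged pool
J_EC = 4000; beyond the abluminal cell everything is zero. The table
value of k_t is typeset ambiguously in its source; 2.5e-5 per
(molecules·h) is adopted for consistency with k_c and the antecedent
models, and is configurable.

Integration uses LSODA with rtol 1e-8 from `n_repeats` random initial
states (uniform 0–6000 molecules per protein per cell; sub-seeds spawned
deterministically from one master seed) over 250 h — about 25 degradation
time constants, after which the residual |dX/dt| is below 1e-6 of the
largest count. Endpoint disagreement beyond 0.1 % relative raises a
multistability warning; for the published parameter set all strain fields
tested converge to a unique steady state, so scenario runs default to 2–3
repeats while the dedicated uniqueness check uses 25.

Phenotype readout: per-cell NICD divided by the normotensive reference
(120/80 mmHg, full residual stress, unscaled expression, same stretch
hypothesis — the dynamic hypothesis has its own reference ratio field).
The continuous score is log(I/I_ref): 0 homeostatic/contractile, negative
synthetic-shifted, positive contractile-shifted. The mapping direction is
biological (Notch activation drives the contractile phenotype); the
magnitude is a reporting convention, so raw ratios are always reported
alongside.

## Coupling

Stretch profiles are computed by dedicated solves at systolic, mean
((p_sys+p_dia)/2) and diastolic pressures; the dynamic profile is the
station-wise systolic/diastolic ratio, and the strain conversion
E = (λ² − 1)/2 is applied to whichever measure the hypothesis selects.
Station profiles are interpolated to cell-center stress-free radii
(r_i0 + (j − ½)·0.01 mm) with monotone piecewise-cubic (PCHIP)
interpolation; stress-free radii are used consistently with the cell count
being set by the stress-free thickness.

## Scenarios

Default grids (config-overridable): ISH {140/80, 160/80, 180/80}, IDH
{120/90, 120/100, 120/110}, CH {140/90, 160/100, 180/110} mmHg, severe CH
= 180/110; expression scales {0.75, 0.9, 1.0, 1.1, 1.25}. Residual-stress
loss scales the deviation of the pre-stretches from unity:
λ_eff = 1 + retain_frac·(λ − 1). Grids run against a single cached
normotensive reference; per-condition failures are recorded in the output
table without aborting the sweep.

## Synthetic tensile fixtures and fitting

The experimental tensile dataset behind the material constants is not
redistributable, so stress–strain tables are generated synthetically from
the constitutive model itself: a residual-stress-free thin sheet with a
traction-free thickness direction (σ_rr = 0 solved for λ_r at every grid
point), two uniaxial tests to λ = 1.5 (transverse in-plane axis also
traction-free) and five biaxial tests to λ = 1.4 with axis pacing ratios
{1:1, 1:0.75, 0.75:1, 1:0.5, 0.5:1}, 20 points each — spanning the
biaxial deformation modes of the pressurized artery. Optional Gaussian
noise emulates measurement error. What these fixtures cannot stand in
for: real tissue heterogeneity, preconditioning history and
anisotropy/model mismatch — a perfect noiseless recovery therefore
validates the fitting machinery, not the constitutive model against
tissue.

Fitting minimizes the stacked residuals of both in-plane Cauchy stresses
over (μ, k1, k2, α, d) with `scipy.optimize.least_squares(method="lm")`
(ν, φ_f, N held fixed); per-test goodness of fit uses
R² = 1 − Σ(σ_obs − σ_fit)²/Σ(σ_obs − mean σ_obs)². Noiseless self-fits
recover all five parameters to machine precision, and initial guesses
perturbed +30 %/−10 % land on the same optimum.

## Numerical and reporting conventions

- Units: kPa for stress/energy, mm for length, mmHg converted at the I/O
  boundary (1 mmHg = 0.133322 kPa), radians internally / degrees at I/O,
  hours and molecules in the signaling model.
- The fiber exponent is capped at 500 inside the energy/stress kernels so
  that far-off optimizer trials stay finite; the cap is never active for
  physiological stretches.
- Determinism: identical configurations and seeds give bit-identical
  outputs; all stochastic draws derive from one master seed.

## Known limitations

- One-way coupling only: Notch states do not feed back on wall geometry or
  material properties, so the model predicts remodeling *propensity*, not
  remodeled geometry.
- No cell proliferation/apoptosis (fixed 32-cell array), no polarized
  Jagged clustering, no active VSMC tone, no viscoelasticity or damage.
- All deformations are diagonal in cylindrical coordinates; torsion and
  shear loading are out of scope.
- The default segment length L0 = 0.03 mm is the value used by the axial
  release check and is configurable; it is short for an arterial segment,
  but enters no other computation.
- Material parameters are wall-homogeneous; layer-specific (intima/media/
  adventitia) behavior is not represented.
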