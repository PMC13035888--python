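# Methods

## Scope and model

`indentfit` characterises soft tissue from flat-punch indentation of
cylindrical samples.  The sample (radius `R_s = 10` mm, height `H = 10` mm)
is treated as homogeneous, isotropic, fully incompressible and
hyperelastic; the punch (radius `a = 2.5` mm) is rigid and flat-ended, and
contact is frictionless.  Two strain-energy functions are implemented, in
units of N/mm² (= MPa) with stretches dimensionless:

* **Yeoh** — `ψ = Σ_{i=1..3} C_i (I₁ − 3)^i`, `I₁ = λ₁² + λ₂² + λ₃²`;
* **Ogden, N = 3** — `ψ = Σ_i (μ_i/α_i)(λ₁^{α_i} + λ₂^{α_i} + λ₃^{α_i} − 3)`
  (classical convention).

Commercial FE solvers commonly use the `2μ_i/α_i²` prefactor instead;
`ogden_classical_to_solver` / `ogden_solver_to_classical` convert between
the two (exponents unchanged, `μ_classical = 2 μ_solver / α`).  The bundled
breast-tissue reference coefficient tables (`indentfit.reference`) are
published in the solver convention and are converted on load; only under
that reading are all eight Ogden rows Drucker stable, which the source
identification study requires of its fits.  Coefficients are intentionally
unconstrained in sign everywhere; admissibility is screened, not imposed.

Incompressibility is handled two ways.  In homogeneous states (material
point evaluations, stability screening) the pressure is eliminated with
the traction-free gauge `σ₃ = 0`.  In the FE model the pressure is an
independent field.

## Drucker stability screen

For each of the three homogeneous modes (uniaxial, equibiaxial, planar —
"pure shear" in common usage), the base state is the mode's stretch triple
at `λ = 1 + ε` on a nominal-strain grid, default `ε ∈ [−0.9, 30]` in steps
of 0.01.  The 2×2 tangent `D`, mapping in-plane strain increments to
stress increments under `σ₃ = ∂σ₃ = 0`, is computed by symmetric finite
differences with relative log-strain step 1e-6; log-strain increments are
used because incompressibility then reads exactly `∂ε₃ = −∂ε₁ − ∂ε₂`.
`D` is symmetrised before testing `tr D > 0 ∧ det D > 0`, which for a
symmetric 2×2 matrix is exactly positive definiteness (the eigenvalue
oracle used in tests).  The first failing increment per mode is reported.
Power-law terms are evaluated in log space so stretches up to 31 with
exponents of magnitude ≲ 6 stay in double-precision range.

## Finite-element forward model

The quarter-symmetric 3-D treatment common in commercial solvers is
replaced by an axisymmetric section: geometry, loading and frictionless
contact are exactly axisymmetric, and the reduction makes desk-scale
inverse analysis feasible.  Discretisation: structured 4-node
quadrilaterals, bilinear displacement with element-constant pressure (the
axisymmetric analogue of linear hybrid bricks), 2×2 Gauss quadrature,
total-Lagrangian kinematics, monolithic Newton.  A mesh line always
coincides with the punch edge radius; grading (default 3:1) refines toward
the edge singularity.  Presets: coarse 8×8 (inverse-loop), medium 20×20
(production/synthesis), fine 40×40 (confirmation).

Element residuals are exact (first Piola–Kirchhoff stress; the Ogden
branch diagonalises the in-plane stretch tensor per quadrature point); the
tangent is assembled by symmetric finite differences of the element
residual (relative steps 1e-7 on displacements and 1e-7·μ₀ on pressure),
batched over all elements and the 18 perturbation directions.  Newton
convergence requires the free residual norm below `1e-9` of its step-start
value or `1e-12` N absolute; a residual-norm backtracking line search and
a secant predictor between load steps stabilise and accelerate the
iteration.  Loading uses 30 equal increments to 3 mm (30 % nominal strain)
by default, with up to four adaptive bisections of a diverging increment.

**Boundary conditions**: bottom face fixed vertically only (radially free),
axis fixed radially, punch footprint nodes prescribed `u_z = −δ` with free
radial sliding.  **Contact closure**: a flat punch has a nominally constant
contact patch, so no search is needed for the footprint, and non-adhesion
is enforced by releasing footprint nodes whose reaction turns tensile.  At
deep indentation, however, the free surface outside the rim bulges, flows
inward under the punch face and would penetrate the rigid punch; all
non-prescribed top-surface nodes are therefore guarded by a smooth
unilateral penalty against the signed distance of a rim-filleted punch
profile (fillet 0.1 mm, penalty stiffness `10³·μ₀·a`, force law blended
quadratically over 5 µm).  Nodes entering from the side are expelled
radially — they wrap around the rim — rather than being projected onto
the face plane, which keeps the response mesh-convergent and the Newton
iteration free of contact chatter.

**Volume conservation** is enforced per element: the mean element `J` is
driven to 1 at solver tolerance (measured ~1e-11).  Point-wise `J` at
quadrature points is *not* controlled inside an element; near the punch-edge
singularity its deviation is O(1) and grows under refinement — an
intrinsic property of corner singularities under element-average
incompressibility, not a solver defect (the homogeneous patch test
conserves volume point-wise to 1e-13).  `FESolution` exposes both metrics
(`volume_error_elem`, `volume_error_qp`).

**Verification**: (i) patch test — uniform compression of the whole top
face reproduces the incompressible uniaxial closed form
`σ₁ = 2(λ² − 1/λ)(C₁ + 2C₂(I₁−3) + 3C₃(I₁−3)²)` to machine precision on
any mesh (with the production 0.1 mm step size; coarser stepping can kick
the Newton path off the homogeneous branch on fine meshes); (ii)
small-strain punch stiffness against the rigid flat-punch half-space
closed form `2E*a`, `E* = E₀/(1−ν²)`, `ν = 0.5`, `E₀ = 3μ₀`, on a tall
sample (`H/a = 10`) — the finite layer must be at least as stiff;
(iii) scale linearity — the equilibrium equations are homogeneous in the
stress scale, so scaling all Yeoh coefficients scales the force curve
exactly (used heavily by the synthetic generator and tests).

**Mesh convergence**: Richardson extrapolation on three grids with ratio 2
(`p = ln((f_c−f_m)/(f_m−f_f))/ln r`).  The default study extrapolates the
punch force at 2 mm depth, where the family is cleanly asymptotic; at the
full 3 mm the discrete rim-contact state (node-wise release and penalty
engagement) flips between refinement levels and the extrapolation
correctly reports an asymptotic-range violation.

## Curve processing

Raw records are regularised by monotone piecewise-cubic (PCHIP)
interpolation of force onto a common displacement grid (default 0–3 mm at
0.01 mm), chosen shape-preserving because the raw force is coarsely
quantised relative to displacement; duplicate displacements are averaged
first, and fewer than four distinct points fall back to linear
interpolation with a logged warning.  Apparent stress–strain uses the
punch area and sample thickness: `σ = F/(πa²)`, `ε = d/h`.  The apparent
Young's modulus of a linear region is the OLS slope of stress on strain
over all in-window points (robust to quantisation, unlike a two-point
secant); the two default windows are 3.75–11.5 % and 22.5–30 % strain,
configurable because window selection is ultimately a judgement made on
the mean curves.  No Sneddon/Hayes geometry correction is applied — the
apparent modulus is punch pressure over nominal strain by definition here;
the half-space correction appears only as a verification oracle.

## Inverse calibration

Nelder–Mead simplex (reflection 1, expansion 2, contraction 0.5, shrink
0.5), implemented in-package because the forward model is derivative-free
territory: solver-tolerance noise and occasional failed solves (returned
as +inf and rejected) rule out gradient methods.  Initial simplex: each
seed coordinate perturbed ±20 % (1e-4 absolute at zero).  Stops on
relative simplex diameter < `tol_x` (default 1e-4; the recovery test
suites use 1e-3), objective spread < `tol_f` = 1e-12 N², or `max_iter` =
2000.  The objective is the sum of squared *force* residuals on the
forward model's displacement steps; with a constant punch area this is
proportional to the squared-stress form, so the minimisers coincide.
Forward evaluations are cached by parameter vector; the in-loop solver is
the coarse preset (8 load steps by default in the recovery experiments)
with an optional finer confirmation solve for the reported fit error,
`100·RMS(F_cal − F_exp)/max|F_exp|` — the normalisation is a package
definition, since "percent error" of a fit is otherwise ambiguous.  After
fitting, the result always carries a Drucker verdict for the fitted set.
Ogden (N = 3) non-identifiability from a single monotone curve is
accepted: success is judged on curve mismatch and stability, not on
coefficient match.

## Synthetic cohorts

The generator emulates the study design the statistics target: 8 patients
/ 33 specimens (19 from younger patients, 14 from older, mirroring the
emulated cohort), cylindrical specimens 20 mm × 10 mm, 5 mm punch, ramp to
30 % strain at 30 %/min sampled at 100 Hz.  Ground truth per specimen =
the age-stratum reference Yeoh set × a patient-level log-normal factor
(σ = 0.1) × a specimen-level factor (σ = 0.2); a scalar scale keeps every
truth Drucker stable and, by FE linearity, needs no re-solve.  Measurement
noise: multiplicative Gaussian force noise (σ = 2 %) then quantisation to
0.002 N — the load-cell step is deliberately coarse relative to
displacement resolution to exercise the regularisation path.  Menopause is
coupled deterministically to age (post iff ≥ 50) unless overridden, so the
age and menopause subgroups coincide, as they do in the emulated cohort.
Noise magnitudes are configurable assumptions: the emulated study reports
only "low relative resolution", not numbers.

What the generator does **not** emulate: within-specimen tissue
heterogeneity (adipose vs glandular composition), viscoelastic transients
(preconditioning, relaxation), instrument compliance, or contact-point
uncertainty — synthetic curves start at true contact.  Passing tests
therefore validate the pipeline's mathematics and statistical calibration,
not its robustness to those real-data artifacts.

## Group statistics

Four two-level partitions: age (threshold 50 y), BMI (threshold 25 kg/m²;
threshold cases land on the "≥" side), menopause, breast side.  Normality
is screened per subgroup (Shapiro–Wilk) and reported, never gating.
Routing: independent patient-level factors use the Wilcoxon rank-sum test;
breast side, the only factor with true within-patient pairing, uses the
signed-rank test on per-patient side means.  A `force_signed_rank` switch
reproduces the historically used (statistically irregular) routing of
signed-rank tests onto unpaired subgroups via truncated per-patient means.
Exact small-sample null distributions are used where tie-free (validated
against brute-force enumeration); Spearman correlations between
subgroup-membership indicators get exact permutation p-values for n ≤ 8.
All comparisons are Benjamini–Hochberg adjusted jointly; significance is
declared at adjusted p ≤ 0.05.  Patient clustering is otherwise not
modelled (no mixed-effects layer) — a known limitation shared with the
analysis the pipeline emulates.

Calibration experiments (sized to desk scale, reported by the acceptance
script at reduced replication): null cohorts with identical generating
truths stay under a 7 % adjusted-significant fraction; cohorts with the
1.4× first-region stiffness ratio between age strata at 20 % within-group
CV (patient factor off, so the CV is exactly the stated condition) are
detected at the emulated group sizes with high power.

## Numerical and degenerate-input choices

* Ogden with any `α_i = 0` is a domain error (division by zero in the
  energy); zero-length or constant statistical samples raise rather than
  return NaN.
* Tie handling: mid-ranks; zero paired differences dropped (Wilcoxon
  convention); all-zero differences → degenerate p = 1.
* Curve grids must match within 1e-12 mm for point-wise operations.
* All randomness flows from one seed through named `SeedSequence`
  substreams; artifacts embed the seed and a configuration hash, and the
  full pipeline is byte-reproducible from them.
* Serialisation uses 17 significant digits (lossless float round trip).

## Known limitations

* The rim penalty regularises the punch edge with a 0.1 mm fillet; peak
  forces at 30 % indentation carry a mesh-dependent contact-state
  discreteness of order 1 % between refinement levels.
* Q1/P0 elements control only element-average volume change; point-wise
  `J` is unreliable inside the edge-adjacent elements.
* Nelder–Mead is seed-sensitive; multi-start is left to the caller.
* Ogden coefficients from single-curve fits are reported as found, without
  uniqueness claims.
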