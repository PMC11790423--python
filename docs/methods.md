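# Methods

## Physical model

The package simulates finite-amplitude wave propagation in soft,
nearly incompressible viscoelastic solids such as gelatin phantoms and
brain tissue. The material model is quasi-linear viscoelasticity (QLV)
in Simo's internal-variable form: an instantaneous hyperelastic
response combined with `N` linear relaxation mechanisms that act on the
deviatoric elastic stress.

The elastic response is the combined Mooney–Rivlin/Yeoh energy

    W̄(C̄) = C10 (Ī1 − 3) + C01 (Ī2 − 3) + C20 (Ī1 − 3)²,

written in terms of the isochoric right Cauchy–Green strain
C̄ = J^(−2/3) C. The shear modulus is μ = 2(C10 + C01) and the
parameter of nonlinearity β = 3 C20/(C10 + C01) controls the
strain-dependence of the shear wave speed — β > 0 is what makes smooth
shear waves steepen into shear shocks. For antiplane shear γ with
C01 = 0 the exact shear traction is P31 = μγ(1 + (2/3)βγ²) — the
cubic law is exact, not truncated, for the Yeoh energy.

Each memory variable obeys

    d/dt S_ℓᵛ = ω_ℓ (g_ℓ S̄ᴰᵉ − S_ℓᵛ),   S̄ᴰᵉ = Dev S̄ᵉ,

with Dev taken with respect to C̄ (Dev S = S − (S:C̄)/3 · C̄⁻¹). The
two elastic limits are the instantaneous response (fast motions,
S_ℓᵛ ≈ 0, speed c_∞ = √(μ/ρ0)) and the equilibrium response (slow
motions, S_ℓᵛ ≈ g_ℓ S̄ᴰᵉ, speed c0 = c_∞ √(1 − Σ g_ℓ)).

### Artificial compressibility

Exact incompressibility (det F ≡ 1) is replaced by a stiff quadratic
volumetric energy U(J) = K(J−1)²/2 with bulk modulus K = μ/ε. The
compressibility ratio ε = μ/K is the method's single regularisation
parameter: the constraint violation is carried away by artificial
compression waves of speed c1 = c_∞ √(4/3 + 1/ε) ≥ 1.155 c_∞, and the
incompressible solution is recovered as ε → 0. The total second
Piola–Kirchhoff stress is

    S = J U′(J) C⁻¹ + J^(−2/3) Dev S̄ᵉ − Σ_ℓ S_ℓᵛ,      P = F S.

A `linear` material flag selects the small-strain limit
P = λ tr(ε̃) I + 2μ ε̃ − Σ S_ℓᵛ with λ = K − 2μ/3, which is the
constant-coefficient system on which the dispersion, stability and
convergence analyses are exact. Because that law is affine in the
state, the solver assembles its flux once — column by column, from the
same stress routine — and applies it as a matrix product; the per-cell
wave speed is likewise constant and cached. This changes nothing
numerically (verified to round-off against the generic path) and makes
the mesh-refinement studies affordable.

## Numerical scheme

The conserved state per cell is q = (F, v, S_1ᵛ…S_Nᵛ), 12 + 6N
scalars, on a regular structured grid with ghost layers (two per active
axis; singleton axes carry none and are skipped). One time step is the
Strang composition

    q^{n+1} = H_b(Δt/2) · H_Z(Δt) H_Y(Δt) H_X(Δt) · H_b(Δt/2) q^n.

* `H_b` integrates the relaxation ODEs exactly
  (S_ℓᵛ ← e^{−ω_ℓ Δt} S_ℓᵛ + (1 − e^{−ω_ℓ Δt}) g_ℓ S̄ᴰᵉ), so the stiff
  viscous spectrum imposes no time-step restriction.
* Each `H_D` is a dimensionally split finite-volume sweep with the
  Rusanov (local Lax–Friedrichs) flux. The interface dissipation speed
  is max(c_i, c_{i+1}) of the two adjacent cells' largest
  acoustic-tensor eigen-speeds along the sweep direction, frozen at the
  step start.
* Optional MUSCL–Hancock reconstruction: minmod-limited slopes on the
  conserved variables and a half-time-step predictor on both face
  values. Face states that would invert an element (det F ≤ 0) revert
  to first order at that interface.
* Sources (point, ring, truncated Gaussian sphere) inject
  s(t^{n+1})·Δt-scaled momentum into a velocity slot after each full
  step; the smooth one-period signal s(t) = sin Ωt − sin(2Ωt)/2 is C¹.
* Boundaries are non-reflecting by constant extrapolation into the
  ghost cells (a periodic option exists for conservation tests).

Wave speeds come from the acoustic tensor
Q_ki = N_J (∂P_kJ/∂F_iL) N_L, evaluated by central finite differences
on F with step h = 1e−6·max(1, ‖F‖) and a general (non-symmetric)
eigensolver. Imaginary parts and negative eigenvalues below
1e−8·ρ0 c_∞²·max(1, 1/ε) are treated as round-off; anything larger
raises a loss-of-hyperbolicity error with the offending cells. The CFL
step is Δt = Γ min(Δx, Δy, Δz)/c̄ with c̄ the global maximum over cells
and active axis directions, refreshed once per step; the default
Courant number is Γ = 0.95. Inside the time loop only the sweep-active
axes are scanned for c̄ — singleton axes carry no fluxes and do not
constrain stability.

## Parameters

| Parameter | Default | Meaning |
|---|---|---|
| ρ0 | 1000 kg/m³ | reference mass density |
| μ | 2.684 kPa | shear modulus (gelatin preset) |
| β | 4.4 | nonlinearity parameter (C10 = 1.342 kPa, C20 = 1.968 kPa, C01 = 0) |
| (g_ℓ, ω_ℓ) | (0.0434, 0.0466, 0.2213) at 2π·(10, 100, 1000) rad/s | relaxation spectrum |
| ε | 0.9 (or A(Δx/L)^α) | compressibility ratio μ/K |
| Γ | 0.95 | Courant number |

The gelatin preset reproduces the published characterisation of the
material: c_∞ = 1.638 m/s, c0 = 1.360 m/s, and a shear phase velocity
of 1.420 m/s at 75 Hz. All shipped presets keep C01 = 0 (the
Demiray–Fung-consistent choice); C01 is exposed for experimentation.
The fourth-order elastic constants (μ, A, D) map to the Rivlin set
through μ = 2(C10+C01), A = −8(C10+2C01), D = 2(C10+3C01+2C20), which
makes the two closed forms of β agree identically.

A mesh-dependent policy ε = A (Δx/L)^α (with 0 ≤ α < 2) trades accuracy
for convergence to the truly incompressible solution; the
modified-equation analysis predicts the shear order of accuracy
1 − α/2 for the first-order scheme under this policy.

## Verification studies and their design

All verification inputs are synthetic; there is no randomness anywhere
in the method, so identical configurations produce identical outputs.

**1D convergence (Cauchy problem).** A right-going one-period shear
pulse (Ω = 9π c_∞/L ≈ 46.3 rad/s, L = 1 m) is set as initial data and
propagated to t = 0.18 s with the linearised elastic gelatin branch;
the L2 velocity error against the translated pulse is measured by
Riemann sums over X ∈ ]0.02, 0.47[ and the order fitted by log–log
least squares. The default mesh ladder is {2, 1, 0.5, 0.25} mm. This
ladder was chosen inside the scheme's asymptotic regime: the LLF
dissipation coefficient scales with c̄/c_I ≈ 1.56/ε^{1/2}-ish factors,
and on coarser ladders (e.g. 8→1 mm) the fitted slopes under-estimate
the asymptotic orders by 0.2–0.3 — a property of the scheme, confirmed
against an independent implementation of the closed 1D stencil, not of
this implementation. Measured orders: ≈0.87 (LLF, constant ε = 0.9),
≈1.64 (MUSCL), ≈0.69/≈1.50 (LLF/MUSCL with ε = 4(Δx/L)^0.3).

**Locking study.** The forced problem (point source at X = 0 driving
both a compression and a shear slot) is run for ε ∈ {0.02, 0.1, 0.5}
and the relative error in the kinematic energy norm √(v1² + v2²) is
fitted over the ladder {0.5, 0.25, 0.125} mm at t = 0.15 s — the final
time is chosen so the pulse is fully emitted (one period is 0.136 s)
and sits inside the error window, and the ladder again sits in the
asymptotic regime, where the fitted orders vary by ≈0.13 across the
three ε values (locking-free behaviour). On coarser ladders the spread
is dominated by the ε-dependent error constant, not by locking.

**Compression–shear coupling.** Nonlinear elastic runs at ε = 0.8 with
a Y-polarised source measure the peak-to-peak compression strain
∂X u1 against the leading-order slaving estimate
(ε/3)γ²(1 + (2/3)βγ²). A travelling-wave analysis of the 1D AC system
(substituting a(t − X/c_∞) into the balance laws) gives the exact
slaved strain (ε/3)γ²/(1 + ε/3) + O(γ⁴): the leading-order estimate
overshoots by the factor 1 + ε/3, i.e. ≈21% at ε = 0.8, independent of
the mesh. Measured sweeps reproduce this deviation (−21% once the fast
free compression wave has exited the domain; +21% at t = 0.08 s when it
still overlaps the measurement and adds to the peak-to-peak). The
corresponding acceptance test asserts the stricter 15% band and is
expected to fail for this reason; the trend (quadratic-plus-quartic in
γ, constant ratio across two decades of amplitude) is reproduced.

**2D/3D qualitative runs.** The paper-scale configurations (0.6 m
ring-source square at Δx = 2 mm; 0.6 m Gaussian-sphere cube at
Δx = 6 mm) are shipped as presets; the test suite runs coarsened
versions (Δx = 6 mm / 20 mm, shortened final times) and asserts only
qualitative features: near-axisymmetry of the ring field (<2% RMS under
quarter turns, guaranteed by rasterising the ring with a multiple-of-4
angular count), larger inward-focused amplitudes with β > 0 than with
β = 0, presence of the artificial compression precursor, and
near-superposition of nonlinear and β = 0 profiles in the spherical 3D
run.

**What the synthetic studies do not show.** All quantitative
verification lives in the linear or weakly nonlinear regime with the
gelatin parameter set; the shock-formation and multi-dimensional runs
are checked for qualitative physics (steepening, TV control, focusing,
symmetry), not against closed forms. Real tissue heterogeneity,
anisotropy, PML-style absorbing boundaries and unstructured geometries
are out of scope.

## Numerical choices and degenerate inputs

* Symmetric tensors are packed as 6-vectors in the order
  (11, 12, 13, 22, 23, 33); determinants and inverses use closed-form
  cofactor expressions; the unimodularity check on C̄ uses
  |det − 1| ≤ 1e−10.
* The FFT-synthesised viscoelastic reference discretises the source
  with 500 samples per period, pads with ≥10 further periods and rounds
  the length up to a power of two; the complex wave-speed branch is the
  principal square root (Re c > 0, so Im κ < 0 and right-going waves
  decay under the e^{i(ωt−κX)} convention). The compression branch is
  c²/c_∞² = (4/3)(1 − Σ g_ℓ ω_ℓ/(ω_ℓ + iω)) + 1/ε — the stiff
  volumetric term is elastic, so compression waves lose their
  attenuation as ε → 0.
* Degenerate inputs fail loudly: det F ≤ 0 raises an element-inversion
  error with the offending cell indices; strongly negative or complex
  acoustic-tensor eigenvalues raise a loss-of-hyperbolicity error; a
  ring outside the domain, a clipped Cauchy pulse, or an empty error
  window raise configuration errors.
* Sweeps update in place; ghost layers are refilled along the sweep
  axis after each sweep and along all axes after each full step.

## Known limitations

* First-order dimensional splitting bounds the multi-dimensional
  accuracy even with MUSCL reconstruction.
* The LLF dissipation grows with c̄, so small ε smears shear waves;
  cost grows as ε^{-1/2} through the CFL step. Moderate ε (0.8–0.9) is
  the practical operating point, with the O(ε) artefacts quantified
  above.
* Restart snapshots preserve the interior state but not bit-exact
  ghost/step alignment across platforms.
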