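# Methods

This note records the models, numerical choices and design decisions
behind `vortexwell`, and what the synthetic data and desk-scale tests do
and do not demonstrate.

## The model

All quantities are dimensionless.  The package studies the vorticity form
of the Toner–Tu–Swift–Hohenberg (TTSH) continuum model of polar active
turbulence,

∂t ω + λ v·∇ω = a ω − b ∇×(|v|²v) − (1 + ∇²)² ω − γv ∇×(K v) − γω K ω,

with ω = ẑ·∇×v, incompressible v recovered from ω through a
streamfunction (v = (∂y ψ, −∂x ψ), ω = −∇²ψ).  The linear operator
a − (1+∇²)² amplifies structures near wavenumber |k| = 1, so the
free pattern has a characteristic vortex scale of 2π; the advective term
(strength λ) couples modes, and the cubic term (strength b) saturates
the local speed near √(a/b).  The static mask K confines the active flow
to circular wells: K ≈ 0 inside a well, K ≈ 1 outside, and the two
damping terms (γv on momentum, γω on vorticity) suppress motion where
K > 0.  Reference parameters throughout: (λ, a, b, γv, γω) =
(9, 0.5, 1.6, 40, 4).

## Linear stability in a disc

Linearizing about v = 0 and separating azimuthal harmonics, the mode
profiles are combinations of two Bessel functions with radial
wavenumbers k± = √(1 ± √(a − λn)); for λn < a − 1 the minus branch has
k² < 0 and the basis is realified with modified Bessel functions I_n
(a pure column phase that cannot move determinant roots).  The
streamfunction adds the origin-regular harmonic term h·r^|n| (the
r^−|n| and log r solutions are excluded by regularity).  Imposing
ω = v_r = v_θ = 0 at r = R gives a 3×3 characteristic determinant
(2×2 for n = 0, where v_r ≡ 0 and the additive streamfunction constant
drops out of the velocity).  Growth rates are the real determinant roots
scanned on λ ∈ [−5, a) in steps of 0.01 and refined by Brent's method;
complex-λ branches are out of scope and reported as "no real root".
With a = 0.5 the axisymmetric mode first destabilizes at R ≈ 4.18, and
the instability sequence n = 0, 1, 2 follows at increasing radii.

Eigenmodes are normalized to unit kinetic energy ∫|v|² dA = 1 and
phase-fixed so the tangential velocity is positive at its largest
extremum; with the realified basis all radial profiles are real and the
radial velocity is purely imaginary (in quadrature).  A detail that
matters downstream: the mode's tangential velocity crosses zero slightly
*inside* the disc radius (a weak counter-rotating rim), so profile-based
radius estimates sit a fraction of a unit below the disc radius.

## Three-mode amplitude equations

The ansatz ω = C(t)·ω0(r) + [A1(t)e^{iθ}ω1(r) + A2(t)e^{2iθ}ω2(r) + c.c.]
is substituted into the full equation (no damping terms: K ≈ 0 inside
the well) and each azimuthal harmonic is projected onto its mode.

**Projection.**  The kinetic-energy inner product ⟨u, w⟩ = ∫u*·w dA is
used, implemented as a streamfunction-weighted projection
∫ψn* N dA / ∫ψn* ωn dA; the two agree because the boundary terms vanish
under the wall conditions (ψ(R) = 0 for n ≥ 1; for n = 0 the harmonic-0
nonlinear tendencies integrate to zero over the disc, so the arbitrary
additive constant in ψ0 is immaterial).  An L²(ω)-weighted projection
was evaluated as an alternative and rejected: it produces no reversal
limit cycle at λ = 9 anywhere in the scanned radius window,
contradicting both the simulations and the energy-projected reduction.

**Coefficient extraction.**  The nonlinear terms are evaluated on a
polar grid (Gauss–Legendre in radius, uniform FFT grid in angle, exact
for the bandlimited integrands) at a handful of amplitude tuples chosen
so each monomial coefficient is isolated; the advective (quadratic) and
cubic families separate by construction.  Selected couplings were
re-derived by hand as closed-form radial quadratures and agree to
machine precision.  Azimuthal selection rules admit exactly the printed
monomials; forbidden projections vanish below 1e−10 and are asserted.

**Coefficient reality.**  In the real-profile gauge the cubic couplings
are real and the advective quadratic couplings are *purely imaginary*;
the phases of the δ-type couplings (A1C, A2C) are gauge-invariant, so no
phase convention makes every coupling real.  This is exactly the
structure demanded by the reflection symmetry (C, A1, A2) →
(−C, −A1*, −A2*) of the parent equation with real mode profiles.  The
package stores complex coefficients and asserts this structure, together
with rotation equivariance (C, A1, A2) → (C, A1 e^{iφ}, A2 e^{2iφ}) of
the assembled vector field.

**Dynamics.**  With increasing R the reduction produces: a pure vortex
equilibrium (C only); a weakly tilted mixed equilibrium (all amplitudes
steady) branching off near R ≈ 5.81; an infinite-period (SNIC-type)
onset of a limit cycle on which C reverses sign, with the period growing
without bound as the threshold is approached from above; and at larger
radii a pulsation with C suppressed and |A1|, |A2| oscillating in
antiphase.  In this reduction the cycle and the equilibria do not
measurably coexist (no bistable window at ΔR = 0.005 resolution): the
onset is a clean SNIC.  The hysteresis reported for the full PDE is not
reproduced by the truncation; the package's threshold scan reports the
(empty) overlap honestly rather than forcing one.

**Thresholds.**  Integration uses an adaptive RK45 path (rtol 1e−8) for
the public API and a compiled fixed-step RK4 (dt = 0.01) for bifurcation
sweeps; both paths agree on attractors.  The radius sweep (ΔR = 0.01,
t = 2000 per step, downward continuation of the cycle plus upward
continuation of the fixed point and 5 seeded random restarts per radius)
defines the reversal onset as the smallest radius sustaining ≥ 4 sign
changes of C after the transient.  Because the period diverges at the
SNIC, any finite integration window reports an onset slightly above the
true threshold; with the default window this bias is of order 0.01–0.03
in R.  The advection threshold λc sweeps λ downward (Δλ = 0.05) at a
radius inside the reversal window (default R = 5.9, where the λ = 9
attractor is a reversing cycle), recomputing coefficients (their
quadratic couplings scale linearly with λ) and asking for the smallest λ
sustaining any limit cycle.  Scanning *all* radii in [5.5, 7.5] instead
finds small-amplitude mixed-mode oscillations near R ≈ 6.2–6.5 that
persist to λ ≈ 1.8 in this reduction; the default protocol follows the
reversal branch, which is the regime the reported threshold refers to.
Both behaviours are reproducible through the public API.

## Pseudospectral solver

Fourier collocation on a periodic square (default desk scale: 20.48 box,
512² grid; tests use 128²), 2/3-rule dealiasing of the products, and
ETDRK2 time stepping (exact exponential treatment of a − (1−k²)²,
second-order explicit treatment of the advective, cubic and damping
terms) with Δt = 0.01.  The k = 0 mode is pinned to zero (zero-mean
vorticity).  One non-obvious implementation point: with a positive
linear growth band, round-off seeds an anti-Hermitian component in the
conjugate-redundant columns (ky = 0 and ky = Nyquist) of the real-FFT
array; that component is invisible to the inverse real transform — the
nonlinearity never saturates it — and grows exponentially until it
destroys the run.  The redundant columns are therefore re-symmetrized
every step.  This was diagnosed by observing the discrete energy exceed
the rigorous continuum bound dE/dt ≤ 2aE − 2b∫|v|⁴.

**Damping kernel.**  Each well contributes a half-cosine ramp of width
0.5 *centered on the nominal wall* (K = 0 up to R − 0.25, K = 1 beyond
R + 0.25); wells combine by minimum.  The exact kernel of the reference
study is unpublished, and the choice matters: with the ramp centered on
the wall the simulation reproduces the published sequence of states at
the published nominal radii (steady vortex at R = 5.2, reversal at 5.6,
four-vortex pulsation at 6.4, irregular flow at 7.6 — verified at 128²),
whereas ramps starting at the wall or beyond it shift the transitions to
smaller nominal radii (the R = 5.2 vortex then destabilizes).  The ramp
offset and width are configuration knobs.

**Effective radius.**  The confinement is soft, so the flow "feels" a
disc larger than the nominal radius.  The calibration implemented is the
first zero of the azimuthal-mean tangential velocity beyond its maximum
(linear interpolation between radial bins) in a converged single-vortex
state.  In this penalization the saturated vortex develops its natural
counter-rotating rim near the wall, which pins that first zero close to
the nominal radius (excess ≈ 0.05–0.1 across kernel variants spanning
offsets −0.25…+0.5 and widths 0.5…2.5, measured at 128²–256²), well
below the excess ≈ 0.5 quoted for the reference kernel.  The *dynamic*
effective radius — the ideal-disc radius whose stability behaviour
matches the simulation at a given nominal radius — is larger by roughly
0.4–0.7 depending on the kernel, consistent with the reference study's
comparison of theory at R = 5.9 with simulations at R = 5.4.  The
profile-based excess is reported as measured; the discrepancy with the
published value is a kernel-shape effect and is documented rather than
absorbed into the measurement.

**Initial conditions.**  Default runs start from zero-mean uniform noise
(amplitude 1e−3, seeded).  Near coexistence the noise-seeded transient
can wander between competing states for hundreds of time units, so
calibration and state-sequence runs seed with the axisymmetric disc
eigenmode (plus a small random perturbation to let non-axisymmetric
instabilities develop); the step operation accepts any supplied field.

## Observables

The per-well spin is S = Σ ẑ·(r−ri)×v / Σ|r−ri| over grid nodes within
the nominal radius; for rigid rotation at rate Ω it converges to
(3/4)ΩR.  Two azimuthal decompositions are used and must not be
confused: the *velocity-component* decomposition (Cartesian components
on circles; a single vortex appears at n = ±1) defines the mode-energy
amplitudes m_n = ∫|v̂_n(r)|² r dr, an energy, recorded in output
metadata; the *vorticity* decomposition (scalar ω; a single vortex
appears at n = 0) underlies the mode maps and the state classifier,
where the n = 1 harmonic carries the two-vortex structure and n = 2 the
four-vortex structure.  Spin statistics use the biased autocorrelation
with the record mean retained (the bimodal spin of a reversing well has
meaningful sign; mean subtraction is a flag), the 1/e crossing linearly
interpolated and capped at the record duration, the clockwise fraction
as the fraction of frames with S < 0, and a smoothed-histogram two-peak
test for bimodality.

The state classifier is rule-based with configurable thresholds:
`random` below an energy floor; `stable_vortex` for sign-constant spin
with the single-vortex harmonic dominant; `reversing` for ≥ 2 regular
sign changes (interval coefficient of variation < 0.5) with substantial
relative spin amplitude; `four_vortex` for antiphase two-vortex /
four-vortex harmonic energies with the spin suppressed; `turbulent`
otherwise.  The relative-spin threshold separates reversal (the well
spends long stretches as a full vortex) from four-vortex pulsation and
turbulence (spin near zero throughout); the default was set from
reference desk-scale runs of all four states, where the three classes
differ by an order of magnitude in this statistic.

## Governing-equation regression

The vorticity-form tendency ∂tω (centered differences between saved
frames) is regressed by ordinary least squares onto spectrally evaluated
term libraries: the TTSH library {ω, ∇²ω, ∇⁴ω, v·∇ω, ∇×(|v|²v)} (true
coefficients (a−1, −2, −1, −λ, −b)) and the Nikolaevskiy alternative
{∇²ω, ∇⁴ω, ∇⁶ω, v·∇ω}, which has a sixth-order operator but no linear
or cubic term.  Columns are standardized (scalings recorded), rows are
restricted to well interiors (K < 0.1), and the two libraries are
ranked by relative residual on identical rows, with an
"indistinguishable" flag when the residuals differ by less than 1%.
The vorticity route avoids the pressure constraint of the velocity form;
plain OLS suffices because the comparison is between two fixed
libraries, not a sparse selection problem.  Frame spacing matters only
through the centered-difference error; the desk-scale tests use spacing
0.05 on saturated 128² turbulence.

## Synthetic velocimetry data

The generator emulates PIV-like recordings of each confined state on a
coarse grid (default spacing 0.25, frame interval 0.04 — matching a
50 fps, 150 s recording when one time unit is half a second, with
duration a parameter).  Vortex-bearing states are built from the disc
eigenmodes: a constant-amplitude n = 0 mode (steady vortex); a
tanh-smoothed square-wave C(t) (transition width 5% of the period) mixed
with an n = 1 component (reversal); antiphase-modulated n = 1 / n = 2
amplitudes with C = 0 (four-vortex).  `random` is weak filtered white
noise and `turbulent` a superposition of |k| ≈ 1 plane waves with
diffusing phases, both envelope-confined to the well.  Measurement
imperfections are additive Gaussian velocity noise followed by Gaussian
smoothing, in that order (PIV then filtering); the stored vorticity is
recomputed from the degraded velocity by finite differences.  What
passing tests on these data show: the observables and the classifier
respond correctly to fields with the *designed* modal content and noise.
What they do not show: robustness to real PIV artefacts (correlated
noise, interrogation-window averaging, tracer depletion), none of which
are modelled.

## Problem sizes

Tests run the solver at 128² on the 20.48 box (wall ramp ≈ 3 grid cells;
the spectral band at |k| ≈ 1 is fully resolved) with runs of 300–900
time units per state, and the acceptance script runs the effective-radius
calibration at 512².  Threshold sweeps use the default protocol sizes
(ΔR = 0.01 over [5.5, 6.3]; Δλ = 0.05 over [3, 5]; t = 2000 per
parameter value).  These sizes were chosen as the smallest at which the
reported quantities are stable against refinement in spot checks
(doubling the grid or halving the time step moves the desk-scale
observables by a few percent).

## Known limitations

- The three-mode truncation misses the PDE-level coexistence of vortex
  and reversal states; its SNIC onset has no measurable hysteresis.
- The profile-based effective-radius excess is kernel-specific (see
  above) and does not match the published 0.5 for any kernel in the
  implemented family.
- Complex (oscillatory) linear eigenvalues, modes |n| ≥ 3, multi-well
  coupling studies and stochastic forcing are out of scope.
- The regression module assumes periodic, uniformly sampled, noise-free
  or mildly noisy fields; no weak-form or bootstrap machinery.
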