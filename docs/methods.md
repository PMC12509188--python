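# Methods

This note records the models implemented in `thermopsf`, the conventions and
numerical choices behind them, and the limits of what the synthetic tests
demonstrate.

## Vectorial confocal PSFs

The focal field of an aplanatic objective illuminated with x-polarised light
is assembled from three aperture-angle integrals (the classic vectorial
treatment of a focused beam),

    e0(r,z) = ∫ P(θ)(1+cosθ) J0(kr sinθ) e^{-ikz cosθ} sinθ dθ,
    e1(r,z) = ∫ P(θ) J1(kr sinθ) e^{-ikz cosθ} sin²θ dθ,
    e2(r,z) = ∫ P(θ)(1-cosθ) J2(kr sinθ) e^{-ikz cosθ} sinθ dθ,

over θ ∈ [θ_min, α], α = arcsin(NA/n), k = 2πn/λ.  A reflective
(Schwarzschild) objective contributes a nonzero θ_min.  The intensity PSF is
|e0|² by default; at the apertures modelled here (NA ≤ 0.55) the |e1|, |e2|
contributions to intensity are below 10⁻³ of the peak, and the instruments'
published resolution figures derive from the scalar form.  The full
vectorial sum |e0|² + 2|e1|² + |e2|² is available via `vectorial=True`.
Confocal PSFs are pointwise products of the two arm intensities,
renormalised to peak 1.

**Apodization.**  Three models are implemented: `uniform` (P = 1), `cosine`
(P = cosθ) and `sqrt_cosine` (P = √cosθ, the Abbe-sine energy-conservation
factor).  The default is `uniform`: for the two instruments modelled it
reproduces the quoted theoretical resolutions best (0.55/0.55 NA confocal at
633 nm: 421.7 nm radial / 2.451 μm axial; 0.5/0.5 NA: 464.6 nm / 3.015 μm).
The three models differ by under 2 % at these apertures, so the choice is a
convention, not a physics claim.

**Annular collection.**  The transmission instrument's reflective objective
obscures the central cone (θ_min ≈ 21°).  Applying that obscuration to the
collection arm of the *optical* confocal PSF narrows the radial FWHM to
≈ 415 nm and stretches the axial FWHM to ≈ 3.8 μm — the central obscuration
acts as an annular aperture, which sharpens laterally and elongates axially.
The instrument's quoted theoretical figures (460 nm / 3 μm) correspond to
the full-aperture 0.5/0.5 NA product, so that configuration is what the
acceptance computation reports; the annular variant remains available
(`--annular` on the CLI, `optir_collection` in the config).  The obscuration
*does* enter the photothermal detection cone, where it is essential.

**Quadrature.**  The aperture integrals use Gauss–Legendre nodes doubled
from 64 until the result is stable to 1e-8 (relative, whole-grid); the test
suite checks invariance under further doubling and agreement with a 2·10⁵
step midpoint rule.  FWHM values are read from profiles sampled at ≈ 1 nm
(radial, 1501 points over 1.5 μm) and 8 nm (axial, 2001 points over ±8 μm)
with linear interpolation of the half-maximum crossings; the sampling error
is far below the 1 nm level at which the figures are quoted.

## Gaussian beams and the steady-state thermal lens

Beams are TEM00: z_R = πω0²/λ, ω(z) = ω0√(1+z²/z_R²), R_c(z) = z(1+z_R²/z²)
(positive after the waist; the waist itself is reported as a flat wavefront
and consumed downstream as 1/R_c = 0).  The modulated pump has peak power
P_max = P_avg/β (β = duty cycle) and on-axis peak intensity
I0 = 2P_max/(πω0²).

The thermal diffusion length R_th = √(2κ/(C_p ρ Ω)) with Ω = 2πf governs
the steady-state condition: while R_th exceeds the probe spot radius, the
temperature field around the absorber is quasi-static over a modulation
period.  At the modelled operating point (air, 50 kHz) R_th ≈ 11.7 μm
against a 0.53 μm probe waist — a ratio of ≈ 22.  The angular-frequency
convention Ω = 2πf is the one that reproduces that quoted ≈ 12 μm value.
Air properties default to dry air at 294 K (C_p = 1006 J kg⁻¹K⁻¹,
ρ = 1.204 kg m⁻³); both are config-overridable.

Waist-from-FWHM conversion assumes the intensity-profile convention
ω0 = FWHM/√(2 ln 2); with it, the instrument's 0.624 μm measured radial
FWHM maps to the tabulated 0.53 μm probe waist.

## The nanolens signal model

A point-like absorber dissipates P = σ_abs·I_pump; in the steady state the
surrounding temperature field is ΔT(r) = P/(4πκr) and the refractive index
follows as n(r) = n0 + Δn·R/r with

    Δn(z, Δz) = σ_abs I0,h/(4πκR) · (dn/dT) · [1 + (z-Δz)²/z_R,h²]^{-1}.

z is the absorber position relative to the probe waist and Δz the pump-waist
offset; the Lorentzian is simply the on-axis pump intensity profile.  At the
default parameter set the peak phase strength is |k0·R·Δn| ≈ 0.012, well
inside the weak-lens regime (the code warns beyond 0.5).

The absorber plane acts as a thin phase screen advancing the probe phase by
Δχ(ρ) = const − 2k0RΔn ln ρ.  Propagating the Gaussian probe
U_a(ρ) = exp(−ζρ²), ζ(z) = 1/ω²(z) + ik/(2R_c(z)), through the Fresnel
integral and taking the far field yields the closed-form relative signal at
angle θ (a Hankel transform with kernel ρ^{1+2iη}, η = k0RΔn):

    Φ(θ,z) = e^{−k²tan²θ·Re(ζ⁻¹)/2} ( e^{2η·argζ} |Γ(1+iη)
             ₁F₁(−iη, 1, k²tan²θ/(4ζ))|² − 1 ).

The additive constant of Δχ and the Gouy phase are ρ-independent and cancel
in the relative-signal quotient; they are set to zero.  Re ζ > 0
everywhere, so arg ζ never leaves the principal branch (asserted at
runtime).  The detected signal integrates over the collection cone,

    Φ_tot(z) = A · 2π ∫_{θmin}^{θmax} Φ(θ,z) sinθ cos³θ dθ,

with A = (2z_R²/πω0²)/(e^{−2tan²θmin·z_R²/ω0²} − e^{−2tan²θmax·z_R²/ω0²})
built from the probe beam's waist and Rayleigh range (the normalisation of
the unperturbed collected power; the probe beam is the natural reading since
it is the probe's angular spectrum being collected).  The quadrature doubles
Gauss–Legendre nodes from 32 until the axial vector is stable to 1e-8 of
its peak.

**₁F₁ evaluation.**  ₁F₁(−iη, 1, x) with tiny imaginary first parameter and
|x| up to a few hundred is evaluated by a vectorised two-branch scheme
(power series for |x| ≤ 26, large-|x| asymptotic expansion beyond), accurate
to ~1e-8 worst case at the branch point; the test suite cross-checks both
branches against mpmath and against the raw power series.  An
arbitrary-precision path would be ~10³× slower and would make the recovery
simulations and offset sweeps impractical.  |Γ(1+iη)|² uses the exact
identity πη/sinh(πη).

**Validation oracle.**  `diffraction_oracle` evaluates the Fresnel integral
directly — panelised Gauss–Legendre with the panel count tied to the total
phase excursion (naive adaptive quadrature fails on this integrand: the
quadratic phase spans hundreds of radians).  Closed form and oracle agree
within 1 % (mostly ≪ 0.1 %) over θ ∈ {5°, 15°, 25°}, z ∈ {±1, ±5} μm; with
the phase screen disabled the oracle returns exactly zero, confirming
Gouy-phase independence.  The oracle's lower integration limit defaults to
0 (the idealisation under which the closed form holds) and can be set to
the bead radius to probe finite-size deviations.  It is never used in
production paths.

**Sign conventions.**  Probe propagates toward +z; bead at z = 0 coincides
with the probe waist; pump waist at z = Δz (positive = downstream).  In air
(dn/dT < 0) the on-axis signal is positive for z < 0 and negative for
z > 0.  Lock-in detection measures |Φ_tot|; the model keeps the sign and
comparisons to amplitude data take the absolute value.

## Lobe structure and the two-lobe threshold

At Δz = 0 the signal is two-lobed with extrema near z ≈ ±1.4 z_R,p and
equal amplitudes up to O(η) corrections (≈ 2 % at the default cross
section; exactly symmetric in the weak-lens limit).  In the weak-lens
regime Φ_tot factorises as Δn(z−Δz)·G(z) with G fixed by the probe
geometry.  Because Δn is a Lorentzian of half-width z_R,h ≈ 11.4 μm — much
wider than the lobe separation — the *ratio* of the two lobe amplitudes
never drops below ≈ 0.69 for any Δz: a purely relative lobe criterion
("secondary ≥ x % of primary") therefore never declares the signal
one-lobed.  What does change rapidly with Δz is the *absolute* signal
level, and Φ_tot is itself an absolute relative-power change.  Lobe
detectability is therefore defined against a noise floor on |Φ_tot|,
defaulting to 0.01 (a 1 % relative transmission change, a realistic lock-in
noise floor given that the peak signal at the expected σ_abs = 0.065 μm² is
≈ 2.9 %).  Under that criterion the default scene is two-lobed up to
Δz ≈ 13.5 μm, one-lobed to ≈ 18.5 μm, and undetectable beyond — matching
the instrument behaviour the model was built to describe (lobe suppression
at offsets around 15 μm, at a substantial signal-to-noise cost).  The floor
is a parameter, not a constant of nature: `lobe_analysis` accepts both a
relative fraction and an absolute floor, and `two_lobe_threshold` exposes
them.  |Φ_tot| also carries weak diffraction ripples (≲ 10 % of peak,
|z| ≳ 8 μm) originating from the interference term of the confluent
hypergeometric function; they sit below the default floor.

## Fitting (Δz, σ_abs)

`fit_axial_profile` runs bounded least squares of |Φ_tot(z; Δz, σ_abs)|
against a measured profile with all other parameters fixed.  Because the
signal is nearly symmetric under Δz → −Δz at small offsets, the optimiser
multi-starts from Δz ∈ {−10, −5, 0, 5, 10} μm; best residual wins, ties
toward smaller |Δz|.  Residual weighting is uniform.  With
`normalize=True` both sides are peak-normalised (matching the convention of
fitting normalised measured signals); σ_abs then acts only through lobe
shape and the fit warns about reduced identifiability — synthetic-recovery
studies use absolute amplitudes (`normalize=False`), where σ_abs enters
linearly.  1-σ errors come from the Gauss–Newton covariance at the
solution.  On synthetic scans (81 points over ±12 μm, 5 % multiplicative
amplitude noise, 50 seeds) the median recovery error is ≈ 0.12 μm in Δz and
≈ 1 % in σ_abs.

## Synthetic data

`make_axial_image` builds x–z scans as the outer product of |Φ_tot(z)| with
a Gaussian radial envelope (the measured x–z images are approximately
separable), rotated to emulate sample tilt and degraded with additive
Gaussian amplitude noise — a good model of lock-in amplitude noise at high
SNR, and a deliberate simplification: no shot noise, drift, or ambient-light
variation.  `make_radial_image` renders a radially symmetric Gaussian spot
on a 50 nm pixel grid.  Generators are pure functions of (parameters,
seed).  Passing tests on these images demonstrates the correctness of the
geometry, extraction and estimators — not robustness to real detector
physics.

Note on the rotation search: the score (peak of column sums) has a shallow
optimum for tall narrow features, so angle recovery to ±0.2° requires low
noise; at percent-level noise the recovered angle can be off by ~0.5°.

## Degenerate inputs and error behaviour

Null absorber (σ_abs = 0) short-circuits to an exactly zero signal.  A flat
image cannot be rotation-aligned; a profile without a resolvable peak (or a
Gaussian fit escaping the sampled range) raises rather than returning a
silent answer; FWHM extraction names the side on which the half-maximum
crossing is missing; quadrature non-convergence reports the achieved
tolerance.  Config files are schema-validated: unknown sections or keys are
rejected by name, and redundant parameter pairs (wavelength/wavenumber,
θ_max/NA) must agree within stated tolerances.

## Known limitations

* The inverse-aperture point-absorber idealisation: no finite-size
  reflections or internal standing waves, so multi-micrometre absorbers are
  outside the validity regime; the zero-crossing shift with absorber size is
  not modelled.
* Steady-state only — no lock-in frequency dynamics or thermal transients.
* No optical aberrations, no polarisation-resolved detection, no
  pinhole-size dependence in the confocal PSFs.
* The closed form is validated for |k0·R·Δn| ≲ 0.05 against the numerical
  oracle; it is asserted (warning) only up to 0.5.
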