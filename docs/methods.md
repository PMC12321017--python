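# Methods

This note records the model conventions, numerical schemes and design
choices behind `sastubes`, in enough detail to re-derive every result the
package produces.

## Scattering framework and normalization

All wavenumbers are in Å⁻¹ and lengths in Å; intensities are in arbitrary
units (no absolute calibration layer).  A composite model is

    I(q) = I0 · Σᵢ wᵢ Pᵢ(q) Sᵢ(q) + C,

weights free non-negative reals (not constrained to sum to 1), C a
constant background.  Contrasts are always excess densities: solvent
density is subtracted when parameters are ingested, never inside kernels.

Every tube-like form factor is normalized so that P(0) equals the squared
total excess mass, (contrast × volume)² — for decoupled models this means
the factor L² multiplies P_axial·|F_cross|², with F_cross per unit length.
This single absolute convention is what makes the cross-model checks
(full vs decoupled, ribbon vs tube, thin shell vs tube) parameter-free
comparisons rather than shape comparisons.  Cross-section-only helpers
(`p_cross_uniform`, the normalized multishell amplitude) keep their
conventional per-unit-length / unit-at-q→0 normalizations.

## Cylinder family

**Axial factor.** `p_axial(q, L) = 2 Si(qL)/(qL) − 4 sin²(qL/2)/(qL)²`,
the orientational average of the thin-rod interference function; equal to
1 at q = 0, asymptotically π/(qL).  Below qL = 10⁻⁶ a Taylor series
avoids cancellation.

**Multishell wall.** Shell boundaries R₁ < … < R_N with per-shell
contrasts ρᵢ give the amplitude Σᵢ (ρᵢ−ρᵢ₊₁) Rᵢ² g(qRᵢ), g(x) = 2J₁(x)/x
(ρ_{N+1} = 0).  The normalization constant C_shell = Σᵢ (ρᵢ−ρᵢ₊₁) Rᵢ²
makes the exposed amplitude 1 at q = 0; a wall whose contrasts integrate
to zero has no C_shell and raises a degenerate-contrast error.  Radius
polydispersity is a Gaussian rigid shift of all boundaries: wall
thicknesses are fixed, the radius is distributed.  The q = 0 limit of
g is evaluated analytically (never by division).

**Gaussian bilayer wall.** ρ(r) = ρ_C exp(−(r−R)²/2σ_C²) +
ρ_H exp(−(r−R∓r_H)²/2σ_H²): a chain-core Gaussian centred on the wall
radius R, headgroup Gaussians at R ± r_H.  The headgroup centres sit at
± r_H (half the head-to-head bilayer thickness), consistent with
integration limits R ± 2r_H for the wall.

**Full (non-decoupled) model.**
P(q) = L² ∫₀¹ sinc²(qLx/2) |F_c(q√(1−x²))|² dx, x the cosine of the tilt
angle, F_c(u) = 2π ∫ ρ(r) J₀(ur) r dr over the wall.  F_c is computed by
400-point Gauss–Legendre in r (dense enough for J₀ at the largest qR used
here), tabulated on a u grid of ≥16 points per Bessel period and
spline-interpolated inside the tilt quadrature.  The tilt integral is
panelized lobe-by-lobe in the sinc² factor (8-point Gauss per lobe, 16 in
the main lobe); beyond 400 resolved lobes the unresolved sin² is replaced
by its mean 1/2, an O(1/qL) tail approximation.  Polydispersity in R
shifts the whole profile rigidly.

## Helical ribbons

Geometry: surface points (R cos φ, R sin φ, pφ/2π + h), winding angle φ,
axial offset h spanning the width; the axial ribbon width δ is identified
with the input width w.  The pitch p is an independent parameter; the two
printed conventions p = 2πR·tanψ (surface parameterization) and
p = 2πR·tan²ψ (the full-wrapping example, 326 Å at R = 200 Å, ψ = 27°)
are both exposed through `pitch_from_angle` and neither is a silent
default.

**Oriented amplitude.** One turn is a 201-point Gauss quadrature of
exp(i[qR sinθ cos(φ−χ) + bφ]) with b = q cosθ·p/2π; m turns multiply by
the geometric factor Σₖ exp(i q_z p k); the h integral is δ·sinc(q_zδ/2);
the surface measure contributes R, so F(0) = ρ·2πRδm (density × area).

**Isotropic average.** Expanding the winding integral by Jacobi–Anger
makes the azimuthal average of |F|² exact:

    ⟨|F_m|²⟩_χ = (ρRδ)² sinc²(q_zδ/2) · 4(mπ)² Σ_k J_k(a)² sinc²(πm(k+b)),

a = qR sinθ.  The apparent poles at integer b are removable
(sin²(mπb) = sin²(mπ(k+b)) on the integers) and are evaluated through the
normalized sinc.  What remains is a single tilt quadrature, sized at 8
Gauss points per oscillation of the fastest factor (scale q·max(δ, mp));
the Bessel order is truncated at K = qR + 25 and J₋ₖ² = Jₖ² halves the
work.  This replaces the naive nested (θ, χ) quadrature — the test suite
verifies both routes agree to ~10⁻⁴ at m = 3 — and is what makes dense
grids affordable.

**Layer lines.** The m-repeat interference factor has principal maxima at
q_z = 2πn/p (consistent with the truncation rule n ≤ pq/2π of the
layer-line sum).  The half-spaced family q_z = nπ/p of the classical
helical-diffraction convention is reported by `layer_line_positions`; for
a single ribbon its odd members carry O(1/m²) of the intensity of the
even ones.  Integrating each interference peak across the tilt angle
gives the layer-line approximation

    P(q) = (ρRδ)² (8mπ³/(qp)) [ J₀(qR)²/2 + Σ_{n≥1} sinc²(πnδ/p) J_n(a_n)² ],

a_n = R√(q² − (2πn/p)²), valid for p > 2δ (enforced as a domain error).

**Pringle–Schmidt tape.** For an infinite tape of angular range ω and
radial cross section between aR and R, the per-unit-length isotropic
intensity is

    P(q) = (π/q) Σ_{n=0}^{⌊pq/2π⌋} εₙ ω² sinc²(nω/2) Bₙ(√(q²−(2πn/p)²))²,

ε₀ = 1, εₙ = 2, Bₙ(u) = Σ_slabs ρᵢ ∫ Jₙ(ur) r dr (piecewise-constant
slabs, Gauss quadrature).  The prefactor π/q is derived, not fitted: it
follows from averaging the layer-line delta functions over the sphere and
is confirmed by the exact infinite-tube limit (ω = 2π, thin annulus),
which the tests check against the closed finite-tube expression.

**Exact thin tube.** P(q) = (ρ2πRP)² ∫₀¹ J₀²(qR√(1−x²)) sinc²(qPx/2) dx —
the full-wrapping limit of the ribbon (δ = p) and the thin-wall limit of
the shell models.

## Cochleates

Surface (Dφ cos φ, Dφ sin φ, z) over m turns, axial extent δ; helical
variant advances by pφ (p in Å per radian of winding, following the
surface parameterization).  The oriented amplitude uses the true surface
measure D√(1+φ²) dφ dz, so F(0) is density × arc length × δ.  The
winding quadrature is sized to the total phase excursion
(≈ q_r D(φ_max + φ_max²/2)).

For the isotropic average the axial integral separates into sinc², and
for the plain cochleate the azimuthally averaged squared cross amplitude
H depends only on q_r.  H is evaluated by uniform azimuthal sampling,
which is *exact* for a bandlimited amplitude (Jacobi–Anger truncation at
K ≈ q_r D φ_max): K+4 samples on [0, π) suffice because a real density
makes |F(χ)|² π-periodic.  H is tabulated on a q_r grid resolving the
quasi-Bragg peak width ~1/(Dm) (≥10 points per width, capped at 384
table points) and spline-interpolated inside the same panelized tilt
quadrature as the cylinders.  Helical cochleates (p > 0) lose the
H(q_r)-only structure and fall back to pointwise evaluation — correct but
intended for small grids.

## Caillé structure factor

Modified Caillé theory for N layers at repeat d, normalized per layer:

    S(q) = 1 + (2/N) Σ_{k=1}^{N−1} (N−k) cos(kqd)
           exp(−(dq/2π)² η [γ_E + ln(πk)]),

γ_E the Euler–Mascheroni constant.  S → N as q → 0, S → 1 at high q, and
the quasi-Bragg peaks near 2πn/d shrink and broaden as η grows.  The
diffuse weight ν admixes an uncorrelated fraction; the default convention
is S_eff = (S + ν)/(1 + ν) with an explicit "additive" alternative
(S + ν) — the published fits do not pin the convention, so it is a
user-visible switch rather than a hidden choice.  The structure factor
multiplies the lamellar (flat-bilayer) component of a composite fit, not
the hollow-cylinder component.

## Polydispersity

Gaussian distributions are integrated by a fixed 51-node Gauss rule over
±5σ, truncated at the model's validity bound (e.g. innermost radius > 0)
with weights renormalized to unit probability.  Size parameters: outer
radius (multishell, rigid shift), wall-centre radius (Gaussian-bilayer
tube), layer thickness (flat bilayer).

## Fitting

χ² = Σ[(I_obs − I_model)/σ]², minimized by bounded trust-region-reflective
least squares with relative finite-difference step 10⁻⁶.  Parameters with
positive lower bounds are fitted internally as log-deviations from the
start value (exact at the start point, positivity enforced, no boundary
sticking) and reported in linear space.  Points with σ = 0 are excluded
with a warning; a missing σ column falls back to unit weights with a
warning.  The returned χ² never exceeds the start value (if the optimizer
fails to descend, the start point is returned flagged non-converged);
identical problem + seed is bitwise reproducible; optional multi-start
draws extra starts uniformly inside the bounds from the seeded generator.
Quoted parameter uncertainties come from the local Jacobian covariance
scaled by χ²/dof and are indicative only.

## Synthetic data

The generator emulates reduced beamline curves: 300 log-spaced points
over q = 10⁻³–0.5 Å⁻¹ (≈3 decades) by default, multiplicative Gaussian
noise I(1 + rel·Z) plus an additive floor, and a σ column equal to the
true per-point standard deviation.  Gaussian rather than Poisson noise
matches reduced data with propagated error bars — exactly the error model
the weighted fit assumes.  What it does *not* emulate: instrument
resolution smearing, beamstop masking, inter-particle structure factors,
or correlated reduction artefacts; a passing recovery test therefore
demonstrates identifiability under ideal error bars, not robustness to
instrument systematics.

Presets bundle published parameter sets: the two-component lipopeptide
nanotube fit (flat bilayer t = 23 Å with Caillé N = 2, d = 284 Å,
η = 0.063, ν = 18.3, plus hollow cylinder R = 1400 ± 27 Å, s = 23 Å),
a bare hollow cylinder, the full-wrapping ribbon (R = 200 Å, ψ = 27°,
w = 326 Å, m = 10) and a 2πD = 100 Å cochleate (ρ = 1, δ = 2000 Å).  The
hollow-cylinder preset uses L = 10⁵ Å as a representative "long tube"
(the published fits pin L only loosely, and the axial factor is already
asymptotic there).

## Comparing oscillatory curves

Several validation checks compare two oscillatory intensities at the 1% or
10⁻⁴ level.  Pointwise relative deviation is meaningless at interference
minima: both curves drop by ~4 decades and any finite-size or quadrature
difference is unboundedly amplified, so agreement is assessed on fringe
crests (local maxima of the reference curve), excluding crests inside
envelope nulls (below 30% of the running crest maximum) where a slowly
varying envelope zero — e.g. the wall-thickness minimum of a shell — plays
the same role.  The tube-limit chain is checked at m = 40 turns: the
full-wrapping statement is an m → ∞ limit with O(1/m) edge corrections
(≈1–2% at the plotted m = 10, <0.6% at m = 40 on crests).

Problem sizes used by the validation suite and the acceptance script:
4000-point dense reference grids for crest detection (40000 where fringes
are at the 10⁻³ Å⁻¹ scale), 12–20 crests per comparison, five synthetic
curves of 300 points for the recovery study, start perturbations of ±5%
in R and ±20% in s (a practitioner reads R from the fringe spacing to a
few per cent before fitting; the thickness is much less certain a priori).

## Known limitations

* Ribbon and cochleate sheets are infinitesimally thin by construction;
  finite thickness, elliptical cross sections and end caps are out of
  scope, as are oriented (2D) patterns and resolution smearing.
* The Pringle–Schmidt sum implements the single-ribbon simplification
  only, not the two-offset-ribbon generalization.
* The helical cochleate isotropic average is exact but slow (no H-table
  factorization).
* Caillé's ν convention and the placement of the structure factor after
  (not before) size-averaging are documented choices where the published
  analyses leave the order unstated.
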