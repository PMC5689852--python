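# Methods

## TG-43 engine

Dose around each dwell follows the 2D TG-43 line-source formalism in an
all-water medium; material heterogeneities (the air-filled grooves, the
plastic applicator) are outside the model by construction. Geometry is
carried in mm in the applicator frame (tip at z = 0, +z toward the
base); radial arguments are converted to cm at the engine boundary, and
the single s→h conversion (1/3600) is applied in the plan superposition.

The polar angle θ is measured from each dwell's axis direction; the real
source's azimuthal dependence is ignored, matching the planning-system
behavior the analysis emulates. g(r) is interpolated log-linearly in r
and F(r, θ) bilinearly; outside the tabulated grid both are clamped to
the nearest table value with a logged warning (configurable to a hard
error), because surface points can sit below the smallest tabulated
radius for some table sets. Points within 0.45 mm of a dwell (the v2
capsule half-width) are rejected.

No consensus dataset is bundled: the packaged table set is *synthetic*,
generated once from smooth analytic forms chosen to look like an Ir-192
HDR v2 source (g within 1±0.06 over 0.1–10 cm with g(1) = 1 exactly;
polar anisotropy dipping to ~0.64 at θ = 0 close in). Every operation is
table-agnostic and reads any (radial, anisotropy) CSV pair. Defaults:
Λ = 1.109 cGy·h⁻¹·U⁻¹, L = 3.6 mm, S_k = 40 800 U (a nominal 10 Ci
source; all normalized results are independent of S_k).

## Applicator and planning

The cylinder is 35 mm in diameter (17.5 mm surface radius; measured
value 35.07 mm kept separately), with two 5 mm deep grooves at 0°/180°
starting 60 mm from the tip. The peripheral channel circle radius is not
published; the default 13.0 mm is a configuration value, and the channel
azimuths are placed at 22.5° + k·45° so the grooves fall midway between
channels (also configurable — the vendor phase is unknown). None of the
headline results depend on either value beyond the qualitative 45°
periodicity.

Prescription: 240 points (15 z-levels × 16 azimuths) at the surface,
500 cGy. Geometric optimization is the classical one-shot rule — each
dwell's relative time is the inverse of the summed inverse-square
distances to the other dwells ("distance" mode within a single catheter;
"volume" mode, restricted to other catheters, when several are loaded).
A points-based variant (inverse summed inverse-square contribution to
the prescription points) is provided as an alternative. Normalization is
a single global time scale making the *mean* dose over all 240 points
equal to the prescription — the common convention when prescribing to a
point set.

A consequence worth stating: one-shot geometric optimization leaves a
±2% longitudinal nonuniformity over the prescribed 70 mm, so the mean
over the central 40 mm analysis band is 1–2% above the 500 cGy target
(508.6 cGy central, 505.1 cGy peripheral). Reproducing a clinically
optimized plan exactly would require the clinical dwell times, which are
not available; the azimuthal statistics are insensitive to this.

## Film model and reconstruction

Per channel the normalized response is X(D) = (a + bD)/(c + D) over
0–1000 cGy, decreasing (b·c < a), with X(0) = a/c. Fitting uses
effective-variance weighted least squares: weights
1/(σ_X² + (∂X/∂D)²σ_D²) are recomputed from the current fit in a short
outer loop around a Levenberg–Marquardt solve; the parameter covariance
is (JᵀJ)⁻¹ at the optimum with the weights treated as absolute. The
initial guess is the exact rational curve through the lowest, median and
highest dose points.

Triple-channel analysis models the measured pixel as X_ch(D)·(1+δ) with
one disturbance δ shared by the channels (a thickness proxy). The
estimator alternates (i) a dose update — per-channel inversion
D = (a − cX)/(X − b) of the δ-corrected responses, combined as a
weighted mean with weights 1/u_rel² from the calibration covariance plus
scanner noise propagated through the inverse — and (ii) a closed-form
log-space δ update, δ = exp(mean_ch(ln X̃ − ln X(D))) − 1. Iteration
stops when the dose moves < 0.1 cGy (cap 50 sweeps). Pixels with
|δ| > 0.1, out-of-range responses, or no convergence are masked, never
interpolated.

Statistical floor: with equal relative noise σ on the three channels,
the information available to separate D from δ lies in the *differences*
of the per-channel log sensitivities; the Cramér–Rao bound for EBT3-like
curves at 500 cGy and σ = 0.3% is ≈1.1% (1σ) on dose. Per-pixel
accuracies quoted for the pipeline respect this floor; azimuthal
profiles average ~100 rows and are limited by systematics instead.

Uncertainties follow the standard combination: expanded uncertainty
k·√(typeA² + (typeB_rel·mean)²) with k = 2 throughout; type B defaults
are 3.4% for TG-43 doses and the calibration-chain estimate for film. A
difference of two profile values carries √2 of the point uncertainty,
which is what makes a ±48 cGy companion on a ~500 cGy mean's variation
metric.

## Profiles and metrics

Profiles average 100 rows (35.28 mm at 72 dpi) centered on the
prescribed region, then apply a 5-pixel moving average with truncated
(non-wrapping) edges — physical film has cut edges; a circular option
exists for closed synthetic profiles. Columns map to azimuth through the
wrap diameter, by default the film active-layer diameter consistent with
the IS-correction convention. The groove-peak windows are ±15° around
0°/180° (configurable); `baseline_variation` is max − min outside the
windows and `largest_peak` the in-window maximum above the outside mean.
The engine-side curve averages nine z-levels spanning 40 mm centered at
z = 95 mm — the band center is taken as the midpoint of the prescribed
region, which is not stated explicitly in coordinates anywhere.

IS corrections: central loading uses the purely lateral (17.635/17.5)² =
1.0155. For peripheral loadings the correction at each of 16 surface
points is the dwell-time-weighted mean of per-dwell (d_film/d_surf)²
with full 3-D distances, averaged over the points (1.006 at the default
channel radius). Time weighting (rather than dose-contribution
weighting) matches the description of the measurement analysis this
reproduces; contribution weighting would give ≈1.014.

## Offset-source model

The acceptance-path estimate is deliberately pure inverse-square — no
g(r) or F(r, θ) — mirroring how the original estimate was made: with all
dwells displaced 0.9 mm toward the near side, near/far lateral distances
are 17.635 ∓/± (offset, offset + 0.2 mm gap), and the far/near ratio is
the *time-weighted mean of per-dwell ratios* (d_near²+Δz²)/(d_far²+Δz²)
at z = 95 mm, giving 0.915 for the optimized central plan. Two
cross-checks are provided: the ratio of time-weighted inverse-square
*sums* (0.872) and a full TG-43 two-point evaluation (0.874). The
distinction matters: the summed ratio is what a film physically
measures (the synthetic end-to-end test recovers it within 1%), while
the averaged-IS form is what the relocation convention defines; both are
exposed, and only the latter is the headline number.

## Synthetic data generator

The generator emulates the *measurement chain*, not transport physics:
TG-43 ground-truth dose at the film active layer (radius 17.5 + 0.135 mm
plus an azimuthal air-gap profile, cosine-shaped with its maximum at a
configurable azimuth, ≤0.2 mm), a smooth multiplicative thickness field
(Gaussian-filtered white noise, 10 mm correlation length, peak |δ| = 2%
by default), per-channel relative Gaussian scanner noise (0.3% default),
and 16-bit quantization at 72 dpi. Calibration pieces are 64×64 px
uniform-dose squares at 13 levels over 0–1000 cGy. A single seeded
generator drives each run; the seed is recorded in image metadata and
identical seeds give bit-identical scans.

What passing tests therefore show: the reconstruction chain (curve fit,
triple-channel inversion, relocation, profile statistics) is correct and
self-consistent at realistic noise. What they cannot show: groove
scatter physics (the measured ~11% groove peak has no counterpart here —
synthetic central-loading films assert a peak < 1% of the mean),
scanner lateral-response or orientation effects, and film registration
errors, all outside the model.

## Numerical choices and limitations

- Geometry function: on-axis limit 1/(r² − L²/4) taken when sinθ
  vanishes; points on the source segment are domain errors.
- Dose domain [0, 1000] cGy; inversion clamps (map path) or raises a
  side-identifying saturation error (scalar path) outside the attainable
  response interval.
- The default test/analysis problem sizes (120×314 px films, 64 px
  calibration pieces) were chosen as the smallest sizes that exercise
  every averaging window at the native 72 dpi scan resolution.
- Uncertainty of the fitted calibration parameters is the local
  quadratic approximation; no bootstrap.
- The applicator grooves exist only as metadata (peak-window azimuths);
  their geometry never enters the dose model.
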