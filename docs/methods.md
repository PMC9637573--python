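# Methods

This note documents the models implemented in `hemodrop`, the conventions and
defaults chosen where the underlying methodology leaves them open, what the
synthetic-data generator emulates, and the limits of what a green test
establishes.

## Thermophysical property models (`properties`)

* **Water viscosity.** Vogel-type correlation
  η_w(T) = 2.414×10⁻⁵ · 10^(247.8/(T+133)) Pa·s, T in °C. Validated against
  tabulated water viscosity at 20 °C (1.005×10⁻³ vs 1.002×10⁻³ Pa·s, 0.3 %).
* **Blood viscosity.** Relative viscosity
  η_r = 2.03·exp[(0.0332 − 1.08×10⁻⁴ T)·Ht + 0.02 T] times η_w. The model is
  implemented verbatim, including the exp(0.02 T) factor that makes the
  *relative* viscosity rise with temperature; the absolute viscosity still
  falls because water viscosity drops faster. Default hematocrit Ht = 35 %
  (typical ovine range) — a configurable default, not a measured constant.
* **Thermal diffusivity.** α = λ/(ρ·Cp) with λ = 0.52 W/(m·°C),
  ρ = 1.04873 g/ml, Cp = 3617 J/(kg·°C). Two modes: `si` converts ρ to kg/m³
  (α = 1.3709×10⁻⁷ m²/s); `paper_numeric` plugs the g/ml numeral directly,
  reproducing the conventionally quoted 1.37×10⁻⁴ for these constants. The
  `si` mode is the default everywhere the number enters physics; the other is
  kept as a regression anchor because the quoted literature value uses it.
* **Surface tension.** σ(T) = a·ln(T) + b (mN/m, T > 0 °C), fitted by OLS on
  (ln T, σ); dσ/dT = a/T. The default coefficients a = −11.5, b = 88 are an
  invented but plausible curve for ovine blood over 24–90 °C (σ ≈ 51→36
  mN/m); no public tabulation of the real fit exists. The Marangoni driver
  uses the mean of dσ/dT at the contact-line and center temperatures.

## Droplet geometry (`geometry`)

* **Contact angle** is extracted by a local circle (Kåsa) fit of each contour
  flank over points with 0 < z ≤ 0.35·z_max, followed by the tangent angle at
  the circle's baseline crossing, θ = atan2(√(ρ²−z_c²), −z_c). Circle fits
  are standard in drop-shape analysis and robust to pixel noise; a
  tangent-line fallback handles degenerate (near-flat) flanks. Exact
  baseline points are excluded from the fit: a resting flat run would bias
  the circle.
* **Shrinkage slope.** The "initial linear segment" of V(t) is defined
  operationally: the OLS window grows from the first max(10, 20 % of N)
  samples while the window r² stays ≥ 0.98. On a line-then-plateau signal the
  rule admits a few plateau samples before r² breaks (≈10 % slope dilution at
  the default threshold) — this is the documented cost of a parameter-free
  window rule.
* **Dome onset.** The height series is smoothed with a 5-sample moving
  average; onset is the first time H exceeds its running minimum by more
  than 5 % *of the initial height* with a sustained rise over the next 3
  samples. The threshold is referenced to H(0) rather than to the running
  minimum because the minimum tends to zero near full evaporation, where any
  relative threshold is crossed by ~1 % measurement noise.
* **V–D relation.** A per-temperature power law V = c·D^k fitted on log–log
  axes; the family nests the spherical-cap law (k = 3 at fixed contact
  angle), which is also the closure used to tie deposit diameter to dose
  volume in the generator.

## Thermography (`thermography`)

T_center is the mean over a 2-px-radius disc at the drop center; T_TPCL the
mean over the annulus [R−2, R] px. Single-pixel reads would be noise-limited;
the exact sampling region at the contact line is a convention of this
package. ΔT = T_TPCL − T_center is invariant to global frame offsets.
`locate_tpcl` finds the contact radius as the maximum absolute radial
gradient of the azimuthally averaged profile, falling back to a caller-
provided mask radius on gradient-free frames.

## Marangoni analysis (`marangoni`)

Ma = −(dσ/dT)·R·ΔT/(η·α), with dσ/dT converted from mN to N internally.
Open conventions, decided and configurable:

* η is blood viscosity at the film-mean temperature (T_TPCL + T_center)/2;
* α uses SI mode by default;
* R is the constant contact radius D/2 (pinned line).

The **breakpoint** of Ma(t) is the SSE-minimizing knot of a continuous
two-segment piecewise-linear least-squares fit over candidate knots at the
sample times; a knot is only reported when it improves SSE over a single
line by ≥ 5 % (an exhaustive scan on pure noise always finds *some* knot —
the 5 % default, rather than 1 %, absorbs the best-of-n-candidates bias at
~100-sample trajectories; exact lines are short-circuited at rounding
level). **Rates**: early = (Ma(t_b) − Ma(t₀))/(t_b − t₀); late over a fixed
100 s window after the break; both by linear interpolation at the evaluation
times. **Regime classification**: no dome and no genuine breakpoint →
capillary; dome onset after 10 % of the lifetime → delayed Marangoni; dome
from the start → immediate Marangoni. A detected breakpoint counts as
"genuine" only when the late/early rate ratio is ≥ 3, so a noisy linear
trajectory stays capillary. The two heated labels jointly correspond to the
Marangoni-dominated category of experiments.

## Areal texture engine (`topography`)

All parameters are computed on plane-leveled (least-squares F-operator),
mask-aware height grids; no S-filter is applied by default (the optional
smoothing a commercial package may apply before parameter extraction is not
emulated).

* **Height family**: Sq (RMS), Sa (mean |z|), Sp, Sv, Sz = Sp+Sv.
* **Abbott–Firestone curve**: sorted-heights construction with midpoint
  plotting positions p_k = 100(k−½)/N and linear interpolation; Smc(p) is its
  inverse at p = 10 % by default.
* **Functional family**: equivalent line = minimum-slope 40 %-wide secant of
  the curve extended to 0 %/100 %; Sk is the height span of that line; Smr1/
  Smr2 are the crossings of the curve with the line's end heights; Spk/Svk
  follow from the triangle-equivalence rule on the areas beyond them. The
  40 % width and the construction are the standard defaults.
* **Volume family**: Vv(p) = (1/100)∫_p^100 [c(p) − c(s)] ds,
  Vm(r) = (1/100)∫_0^r [c(s) − c(r)] ds, Vmc = Vm(80) − Vm(10),
  Vvc = Vv(10) − Vv(80), all in μm³/μm².
* **Feature family**: significant hills/dales are the regional maxima/minima
  surviving an h-transform with relief threshold 5 % of Sz — the h-transform
  is exactly a relief-based (Wolf) pruning of the watershed feature tree.
  S5p/S5v are the means of the 5 highest peaks / deepest pits (fewer are
  used, with a flag, when fewer survive); S10z = S5p + S5v.
* **Pattern family**: plates are 8-connected components of z ≥ Otsu threshold
  with ≥ 20 px; circularity = area/(π(d_max/2)²) with d_max the maximum Feret
  diameter, compactness = d_equiv/d_max, coplanarity = max peak difference
  to neighboring plates (label contact after 5-px expansion; isolated plates
  use their nearest neighbor by centroid). Sample means are reported.
  Rasterization can push a disc's circularity slightly past 1 (the Feret
  diameter of a pixelated disc overshoots 2r by about a pixel); values are
  clipped at 1.

Known numerical behavior: plane leveling is exactly invariant to constant
offsets, but *translating* a deposit across a finite substrate canvas changes
the fitted plane whenever the content carries net mass (the first moments of
z couple to position). Parameters are translation-invariant for mask-
restricted or zero-mean content; the test suite pins exactly that statement.

## Statistics (`stats`)

One-way fixed-effects ANOVA (p from the F distribution; the all-equal,
zero-variance corner returns p = 1 with a flag). Tukey-Kramer uses the
studentized-range distribution evaluated numerically (any k, ν), with
Kramer's √((1/nᵢ+1/nⱼ)/2) correction. Group comparison intervals are drawn
with halfwidth q·s/(2·√n_h) (harmonic-mean n), which makes the graphical
"disjoint intervals ⇔ significant" rule exactly equivalent to the pairwise
test for balanced groups and approximate otherwise. p-values per parameter
are reported without correction across the 16 parameters, matching the
original analysis protocol. Regressions against T and against (T, V) are
plain least squares with r².

## Synthetic data (`synthetic`) — the stated world

The generator's defaults are the study conditions: 4 substrate temperatures
(23/37/60/90 °C) × 18 replicates, 11 μl dose (σ = 0.2 μl doser jitter),
initial contact angle 50°, CCR mode throughout, lifetime 1200 s for an 11 μl
drop at 23 °C and shorter at higher temperatures (1100/600/400 s), 1 %
additive Gaussian noise on trajectory channels.

* **Trajectories**: linear decay of V, H, θ at 23 °C; a dome rebound
  (amplitude 25 % of H₀) starting at 900 s at 37 °C; rebounds from t ≈ 0
  with amplitude 50 % at 60/90 °C (the larger amplitude is needed for the
  rebound to outrun the faster baseline decay of short-lived drops).
* **Thermal frames**: the 37 °C prescribed Ma(t) is piecewise linear with
  rates 1.66 and 55 units/s and a break at 900 s — a deliberate calibration
  so the full IR → Ma pipeline reproduces those rates as a round trip. The
  other temperatures use plain linear targets (0.02, 8, 20 units/s) chosen
  to make ΔT magnitudes span ~0.05–5 °C, which is the plausible scale for
  these substrate temperatures; absolute ΔT levels are invented defaults.
  Ma(t) is inverted pointwise to ΔT(t) by fixed-point iteration (η and dσ/dT
  depend on T_TPCL = T_center + ΔT; tolerance 10⁻⁶ °C), rendered as
  T(r) = T_center + A·(r/R)² inside a 40-px drop on a 128² grid with
  0.02 °C pixel noise. The amplitude A is inverse-calibrated with the exact
  disc/annulus pixel responses of the reduction step, so the rendered field
  returns the programmed ΔT to machine precision before noise.
* **Deposits**: a radial morphology backbone (rim + coronal pedestal +
  cavity at low T, central dome at high T) scaled by an overall relief that
  rises with Ts (3 → 9 μm), cut by radial and ring crack grooves whose count
  rises with Ts (10 → 22), with per-sector height modulation (15 %), smooth
  random texture (10 % of relief) and 0.05 μm pixel noise; 128² grid, pitch
  tied to the predicted drop diameter. This is phenomenological pattern
  statistics, *not* a crack-mechanics model.

What the generator does **not** emulate: real pixel-level IR calibration and
emissivity effects, focus-variation artifacts (no-data pixels, stitching
seams — though the texture engine is mask-aware for them), non-CCR
depinning, sedimentation/gelation rheology, and instrument-resolution
height maps (the synthetic pitch is ~40 μm vs 1.76 μm on the instrument:
maps are scaled down ~20× to keep runs desk-sized). A green pipeline test
therefore establishes internal consistency of the measurement chain on the
stated world — not agreement with any laboratory's raw data, which is not
public.

Known limitation: the group means of the 11 relief-scaled texture
parameters are strictly monotone in Ts by construction; Sk, Svk and the
three pattern parameters separate the groups strongly (ANOVA p ≪ 0.05 at 18
replicates) but not strictly monotonically, because they respond to plate
shape and regime morphology rather than pure relief scale.

## Reproducibility

All randomness is spawned from one master seed through
`numpy.random.SeedSequence` (per-record, per-stage child streams); a
pipeline run records the seed and a SHA-256 of its configuration in
`manifest.json`, and synthetic runs are bit-identical under the same pair on
one platform.
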