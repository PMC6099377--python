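# Methods

This note documents the models implemented in `wingsignal`, the assumptions
behind the synthetic-data generator, and the numerical and design choices a
user should know before trusting results on their own data.

## Working range and spectral primitives

All spectra live on a shared 1-nm grid over 300–700 nm, the window passed by
quartz optics with a UV/IR blocking filter. The illuminant is a smooth
analytic daylight-like curve (steep near-UV rise, broad visible plateau)
rather than tabulated standard-illuminant data: quantum catches are von Kries
normalised and camera calibration is anchored to in-frame grey standards, so
only the relative spectral shape enters any downstream quantity. Receptor
sensitivities are log-normal functions of wavelength (log-domain sd 0.055
for single cones, 0.12 for the broad double cone) with peaks at 371, 445,
508, 565 nm (UVS class) and 420, 455, 505, 567 nm (VS class); these preserve
the UVS/VS contrast without requiring tabulated empirical curves. Relative
cone abundances are 1 : 1.92 : 2.68 : 2.7 (UVS) and 1 : 1.9 : 2.2 : 2.1 (VS),
and the Weber fraction ω = 0.05 attaches to the most abundant cone.

## Camera model and calibration

The simulated camera has three Gaussian visible channels (peaks 600, 540,
468 nm, cut off below ~405 nm) and a UV channel (peak 352 nm, hard filter
edge at 400 nm). Its response is a single power law `v = (g·L·(1+ε))^γ`
applied to the linear radiance integral `L`, with frame gain `g`,
multiplicative sensor noise ε (photon/read noise acts on the linear signal,
before the response curve) and default exponent γ = 0.45. Calibration
estimates γ from the two grey standards, γ = ln(v₉₃/v₇)/ln(0.93/0.07),
averaged over channels, then applies a per-channel affine map sending the
linearized standards to (0.07, 0.93). The affine (two-point) form removes
both gain and any black-level offset; a ratio-to-white normalization would
not. Negative normalized values (possible for very dark patches under noise)
are clipped to 0 with a logged warning because log-ratio contrasts need
positive catches.

Recovery convention: calibration error is quoted on the reflectance scale
(absolute, i.e. "within 0.01" = within one percentage point of reflectance).
Relative error on a near-black channel is unbounded under any finite noise,
so a relative sup-norm is not a meaningful target. At 0.5% sensor noise, 95%
of channel values recover within 0.01; noise-free recovery is exact to
numerical precision.

## Camera-to-cone-catch mapping

Calibrated channel values are mapped to the five catches (four single cones
plus double cone) by per-receptor polynomial regression, default degree 2
with all pairwise channel interactions (15 terms), trained on a parametric
reflectance library spanning red markings, melanic scales, leaves and
flowers. The fit minimises *relative* residuals (weighted least squares with
1/catch weights): catches span roughly two orders of magnitude and an
unweighted fit leaves ~10% relative bias on near-black UV catches while
gaining nothing visible elsewhere. Held-out accuracy is reported per
receptor from a fixed 80/20 split (every fifth spectrum held out). The UV
receptor's mapping uses all four channels, since filter overlap makes the
visible channels informative about the UV catch. End-to-end accuracy (render
→ calibrate → map vs direct quadrature) is summarised by the median and 95th
percentile of relative error across held-out patch × receptor values; at
0.5% sensor noise both sit well under 5%, but single near-zero catches can
exceed it for purely stochastic reasons.

## Colour metrics

Relative catches (proportion of summed single-cone catch) position a colour
in a regular tetrahedron with unit centre-to-vertex distance; all
regular-tetrahedron conventions agree up to a positive scale factor, which
cannot affect any correlation or regression downstream. Saturation is the
Euclidean distance from the centre (0 achromatic, 1 at a vertex). Hue is the
ratio LW/((UV+SW+MW)/3) of *relative* catches — "standardized" here means
proportion-of-total, not z-scores, which would produce negative values and
an ill-defined ratio. The PCA helper (covariance of relative catches, sign
fixed so the LW loading is positive) lets users verify on their own ensemble
that a single long-vs-short axis dominates before trusting the scalar hue.
Luminance is reported on the normalized catch scale (white = 1).

## Discrimination model

Chromatic distance uses the log form of the receptor-noise-limited model for
a tetrachromat: the pairwise/triple expansion over receptor noise values
eᵢ = ω√(η_max/ηᵢ), applied to Δfᵢ = ln(qᵢᴬ/qᵢᴮ). The noise model is
abundance-only (no photon-shot term), matching the bright-light photography
regime. The implementation is cross-checked in the tests against an
independently written projection form of the same model and against the
dichromat closed form |Δf₁−Δf₂|/√(e₁²+e₂²) in the two-receptor limit.
Luminance contrast is |ln ratio|/ω of double-cone catches; the absolute
value makes "contrast" symmetric. Catches are floored at 1e-6 before
log-ratios; the floor is surfaced as a logged warning when hit. Plant
backgrounds are averaged per tissue type *before* contrast computation, one
value per plant species and tissue.

## Synthetic cohorts

`ScenarioConfig` defines a simulated field study. Each specimen has a sex,
population, body mass (females heavier: 65 ± 8 mg vs 48 ± 6 mg), a lognormal
toxin concentration (log-mean −0.5, log-sd 0.4, in nmol per mg fresh mass —
the package's declared unit convention), and per-wing colour latents
(luminance, redness, darkness, spot area) built as population effect
(sd 0.25) + male offset + honesty term + noise. The honesty term is
`honesty_slope × standardized log-concentration` on one designated latent
(default luminance, slope +0.6 honest / 0 null / −0.6 dishonest); latent
noise sds (0.8 for luminance, darkness and spot area; 0.5 for redness) make
the slope a standardized effect. Male offsets (+0.8 redness, −0.8 spot area)
encode redder, more saturated males with relatively smaller spots.

Latents parameterise reflectance templates: red markings are a logistic step
(amplitude ← luminance latent; short-wavelength pedestal ← redness latent;
edge position, steepness and a weak UV sheen jittered independently), and
the melanic background varies in level, in a level-proportional spectral
slope (deeper melanin absorbs relatively more at short wavelengths) and in a
weak UV sheen. These independent chromatic nuisances matter: without them the
internal chromatic contrast is a deterministic function of marking saturation
and the within-population regression design would be singular, which real
wing data are not. Everything the camera "photographs" — wing regions and
grey standards — goes through the identical forward model, one frame gain
per wing.

What the generator does **not** emulate: iridescence and viewing-angle
effects (the photography protocol holds geometry fixed), spatial pattern
texture (patches are mean-value regions), ocular-media transmission, and
spectral shapes of real burnet wings (the templates are parametric
stand-ins). Passing tests therefore demonstrate that the *pipeline* recovers
what the generator encodes, not that the templates are accurate burnet
spectra.

Chromatograms are three m/z traces (270, 284, 480) on a 0–17 min grid with
Gaussian peaks (sd 0.045 min) at retention times 2.6, 5.5 and 6.6 min; peak
area = amount × per-compound response factor × whole-run drift × lognormal
peak noise, over a flat 30-count baseline with optional additive noise. The
amygdalin internal standard is always spiked at 44 nmol (0.044 mM in a 1 ml
extraction).

## Quantification

EIC windows default to ±0.3 min around the catalogued retention times
(peaks are well separated). Integration is trapezoidal above a linear
baseline through the window endpoints, floored at 0. Calibration is a
straight line of IS-normalised area ratio on amount with free intercept —
nothing at the low-nmol range suggests curvature. The IS ratio cancels any
multiplicative whole-run drift exactly; with 1% multiplicative peak noise the
median absolute relative error of total amount stays below 3% over hundreds
of specimens.

## Statistical pipeline

*Among populations*: ordinary regression of population-mean colour on
population-mean concentration, run per sex because sampling is sex-unbalanced
in real collections. Adjusted R² is reported everywhere (it can be negative
for uninformative models).

*Within populations*: concentration is the response and the wing's colour
metrics are predictors; saturation and hue derive from the same catches
(correlation ≳ 0.99 along the colour-purity axis) so only one of them is
offered, chosen by `channel_choice`. A guard rejects predictor pairs with
|r| > 0.995 and any fit with VIF ≥ 10, naming the offending pair so a caller
can drop one member — the pipeline does exactly that and records the drop.
Model simplification is backward elimination at α = 0.05 (dropping one term
at a time; for a single term the t-test equals the nested-model F-test).
Note the operating characteristics of this classical procedure: each null
predictor survives to the minimal model with probability ≈ α, so with four
null candidates the minimal model contains only the true predictor in
roughly 0.95⁴ ≈ 81% of replicates even at unit power — the retained-term
false-positive rate, not the power, is the limiting factor. Observations
with Cook's distance > 1 in the full model are flagged and the entire
procedure is re-run without them; both fits are returned.

*Dimorphism*: metric ~ sex × population, interaction dropped when its nested
F-test p ≥ 0.05. Main effects are tested marginally against the additive
model (Type II): in a balanced design the main-effect sums of squares are
orthogonal to the interaction, and making the test unconditional on the
interaction pre-test keeps its size at the nominal 5% level (the
conditional version rejects ~8% under the null, because whenever a null
interaction survives its pre-test the joint comparison is almost always
significant). Population
pairs compared by Tukey HSD on adjusted means with Tukey–Kramer standard
errors (populations are unbalanced), p-values from the studentized-range
distribution at the model's residual df.

*Plant-contrast mixed models*: random intercept per individual (each
specimen is scored against several plant backgrounds), fitted by maximum
likelihood. The within-individual term (plant type) is tested by
likelihood-ratio chi-square. For between-individual terms (sex, population)
the asymptotic chi-square tail is anticonservative at realistic cohort sizes
(simulated type-I error 7–13% across 12–72 individuals), so those terms are
tested at the individual-mean level, where the nested F test is exact under
balanced sampling; the reported chi-square for them is the mean-level
deviance n·ln(RSS₀/RSS₁). Luminance JNDs are unbounded above, so the logit
transform divides by 1.05 × max first — the rescaling constant is a declared
convention and cannot change the ordering of values. Mixed-model Tukey
tables use Wald contrasts of the fixed effects with studentized-range
adjustment.

No multiple-testing correction is applied across the ~11 metrics × 2 sexes,
matching standard practice in this literature; the raw p-value tables allow
any correction to be applied afterwards.

## Calibration of the tests themselves

`wingsignal.validation` re-derives the type-I error of every test from
matched null simulations (2,000 replicates in the acceptance run): the
nested F-test, the among-population regression, the within-population
full-model F, the dimorphism sex test, family-wise Tukey error, and all
three mixed-model fixed-effect tests (null design: individuals balanced over
two sexes and three populations × three plant types with a true random
intercept; 36 individuals by default, which keeps 2,000 replicates fast —
the between-individual tests are exact-F at any size). Sign recovery is
estimated from honest-scenario cohorts (single population, n = 25,
standardized slope 0.6 on the luminance latent): the fraction of replicates
in which the full within-population model gives the target metric a
positive coefficient, measured at ~96%.

## Problem sizes and determinism

The default end-to-end run uses a focal set of 3 populations × 12 per sex
(72 specimens, 288 photographed patches) plus an 11-population survey of
4 per sex (88 specimens), 5 plant samples per tissue type, a 240-spectrum
mapping library, and a 5-point calibration series (2–40 nmol) — sizes chosen
to mirror a realistic single-season collection while keeping any analysis
re-runnable in seconds. All randomness flows from one master seed through
`numpy.random.SeedSequence`; repeat runs produce byte-identical CSVs.

## Known limitations

- Single-exponent linearization; real cameras may need per-channel curves.
- Template spectra and log-normal sensitivities are stand-ins, not measured
  data; absolute JND values should not be compared against field studies.
- The polynomial mapping is only as good as the training library's coverage;
  extrapolated channel vectors are clipped at a 1e-6 catch floor.
- The mixed model fits a single random intercept; no random slopes and no
  REML-based inference.
- Retention-time drift across LC-MS batches is not modelled; windows are
  fixed.
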