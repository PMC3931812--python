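# Methods

## Scope and model

`camfret` analyzes in vitro FRET-biosensor titrations of calmodulin (CaM)
against candidate binding fragments. Two experiment types are supported, each
with its estimator and a matching synthetic generator:

1. **CaM titrations at saturating Ca²⁺** → apparent K_d of the
   biosensor–CaM complex (single-site isotherm, with or without ligand
   depletion).
2. **Ca²⁺ titrations at saturating CaM** → EC₅₀(Ca²⁺) and Hill coefficient of
   complex formation, with a segmented decomposition for biphasic curves.

All volumes are µL, concentrations µM (totals unless named "free"),
intensities arbitrary units; assays are modeled at 22 °C.

## Fractional response and dilution

The emission ratio R = F475/F535 is normalized affinely between the unbound
(R_min) and maximally bound (R_max) states. Single-channel normalizations are
provided for the donor (rises on binding) and acceptor (falls on binding);
these require dilution-corrected intensities, whereas the ratio is invariant
under the common dilution factor. Per addition k the cumulative titrant total
is C_k = Σ(v_i·S_i)/(V₀+ΣV_i) and intensities are corrected by (V₀+ΣV_i)/V₀.

Clamp policy: fractional responses outside [0, 1] by ≤ 0.05 are clamped with
a warning (endpoint noise must not abort fits); larger excursions raise
errors. When a fraction *trace* is derived from a noisy series, it is
normalized by the observed ratio extrema (guaranteeing [0, 1]); the
first/last-point endpoints are recorded separately and only seed fits.

## Apparent-K_d fitting

Default fitting operates in measured-ratio space with R_min, R_max and K_d
jointly free (`affine_ratio`), because the final titration point need not be
saturating and pre-normalizing by observed endpoints would bias K_d low (the
package's fraction-space mode demonstrates this bias, several percent at a
100×K_d endpoint). A `spectral_ratio` mode fits
R(f) = (R_min + p·f)/(1 − q·f), p = R_max(1−q) − R_min, the exact ratio form
when both emission channels are affine in bound fraction; the extra
denominator slope q ∈ [0, 0.95] absorbs the acceptor's decline. This
parametrization removes the scale degeneracy of a general
ratio-of-affine-forms model.

Optimization: `scipy.optimize.least_squares` (trust-region reflective) in
log₁₀K_d, multi-started from 7 log-spaced seeds spanning 0.01–1000 µM plus a
data-driven half-response seed; lowest-RSS convergent start wins, RSS ties
(< 1e−12) broken toward smaller K_d. Model `auto` keeps the quadratic
(depletion) fit when its K_d estimate is below 10×[BS] — where the
hyperbola's depletion error exceeds a few percent — and otherwise reports the
hyperbolic fit; the choice is recorded on the result. A titration whose
observed fold response is below 1.02 returns a no-binding result (K_d NaN)
rather than a meaningless fit. Standard errors are 1-σ from the Jacobian;
they describe within-fit uncertainty, not between-experiment scatter.

## Free-Ca²⁺ calibration and Hill fitting

Free Ca²⁺ is always read from the indicator channel,
[Ca²⁺] = K_d,ind·(F−F_min)/(F_max−F) with K_d,ind = 1.6 µM by default.
Endpoints F_min/F_max must come from calibration records — the nominally
Ca²⁺-free start and a Ca²⁺-saturating addition at the end of the assay —
never from automatic guessing. Readings at/above F_max raise a saturation
error (such points serve only as endpoints and are excluded from fits);
readings below F_min by ≤ 2% of the dynamic range clamp with a warning.
Because the saturating spike sits at finite free Ca²⁺, the calibrated F_max
slightly underestimates the asymptote; with the default spike (5 mM free
Ca²⁺) the induced EC₅₀ bias is below 0.2% for EC₅₀ ≤ ~5 µM.

Hill fits run multi-start (5 log-spaced EC₅₀ seeds × n ∈ {0.8, 1.5, 2.5} plus
a data-driven seed) with bounds n ∈ [0.3, 6] and EC₅₀ ∈ [10⁻³, 10³] µM.

**Biphasic decomposition.** Species 1 is fit with free amplitude on points
with free Ca²⁺ ≤ 1 µM (breakpoint configurable); the global fit over all
points stands for species 2 — deliberately reproducing the segmented
procedure in which the dominant species governs the whole-population fit,
rather than a statistically purer mixture model (a two-component sum-of-Hills
fit, `fit_hill_mixture`, is provided as a labelled alternative and is never
the default; note the global fit of a true mixture is contaminated by
species 1 and lands below the generating species-2 EC₅₀). The biphasic call
is a formalization of what is usually judged by eye: species-1 amplitude
≥ 0.05, species-1 EC₅₀ below the breakpoint, global EC₅₀ at or above it, and
a segmented model (independent low/high-segment fits, 6 parameters) beating
the global fit (2 parameters) in an F-ratio test at p < 0.05. On monophasic
data at 1% channel noise this rule's false-positive rate is at the test
level (≤ 5% over 100 seeds, measured in the test suite).

## Synthetic generator

The generator emulates the study conditions: 0.5 µM biosensor in a 2 mL
cuvette; CaM schedules of 30 log-spaced totals spanning 0.01–100× the true
K_d, delivered from a stock at 20× the top concentration so total added
volume stays ~5%; Ca²⁺ assays of 25 log-spaced target free-Ca²⁺ values
(0.01–100× the extreme EC₅₀s) plus a saturating calibration spike, buffered
by 0.25 mM chelator (site K_d 1.6 µM, a Br₂BAPTA-like value; BAPTA-like
0.16 µM also provided), 2 µM indicator, and CaM modeled as four identical
independent Ca²⁺ sites of K_d 10 µM — a deliberate simplification of EF-hand
cooperativity. Chelator constants are package conventions for the assay's
ionic conditions, configurable per assay. Free Ca²⁺ is solved from the total
by safeguarded Brent root-finding on the mass balance (conservation residual
< 1e−9 relative), with buffer totals diluted per addition.

Channel models:

* `ideal_ratio` — the acceptor channel is constant and the donor carries the
  whole response, making the ratio (and the donor intensity) exactly affine
  in bound fraction. This is the only construction in which ratio- and
  donor-normalized fractional responses both equal the generating fraction
  point-wise; it is the reference mode for round-trip validation.
* `spectral` — physically reciprocal channels (donor rises, acceptor falls by
  a configurable fraction, default 30%), realized as Gaussian donor/acceptor
  peaks (475/535 nm, σ 15/12 nm) whose 470–480 and 530–540 nm band integrals
  equal the channel intensities. The ratio is then a Möbius function of
  fraction: the `spectral_ratio` fit recovers K_d exactly on such data while
  the affine approximation shows a finite, reported bias.

Noise is multiplicative Gaussian per channel per point (photomultiplier shot
noise scales with signal), i.i.d., seeded; all generators are pure functions
of (config, seed). Measured intensities carry the biosensor/indicator
dilution factor, which the analysis inverts from the recorded volume
schedule.

What the generator does **not** emulate: photobleaching, spectral cross-talk
beyond Gaussian tails, baseline drift, pipetting volume error, Ca²⁺
contamination of stocks, and indicator/biosensor spectral overlap. Passing
round-trips therefore validate the estimators against the stated statistical
model, not against every artifact of real cuvette data.

## Numerical choices and edge cases

* Quadratic isotherm: the discriminant is analytically ≥ (K_d + |[BS]−[CaM]|)²;
  only rounding residue is clipped at zero.
* Degenerate endpoints (R_max = R_min), indicator saturation, missing
  indicator channels, negative volumes, and cuvette overflow raise typed
  errors; flat responses return explicit no-binding / no-fit results.
* Fits are invariant to point order; determinism is bit-for-bit given a seed.
* Problem sizes used in validation (30-point titrations, 25-point assays,
  100-seed noise ensembles) are the package's reference conditions and keep
  every round-trip under a second.

## Known limitations

* Single-site isotherms only; no cooperative multi-site CaM binding, no
  global multi-curve fitting, no kinetics.
* The segmented species-2 estimate inherits species-1 contamination by
  design (procedure fidelity); use the mixture fit when a purer estimate is
  wanted.
* Reported standard errors assume independent homoscedastic residuals, which
  multiplicative noise only approximates.
* Construct bookkeeping carries residue ranges, not sequences; no
  sequence-based CaM-motif prediction is attempted.
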