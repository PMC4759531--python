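# Methods

This note records the models, algorithmic conventions and numerical
choices behind `afmcp`, and what the synthetic benchmark can and cannot
say about real data.

## Contact mechanics

A rigid cone of half-opening angle θ indenting a linear elastic,
non-adhesive half-space follows Sneddon's relation

    F = (2/π) · E/(1−ν²) · tanθ · δ²,

with F in nN, δ in nm and E in kPa (1 kPa·nm² = 10⁻⁶ nN). For a film of
thickness h bonded to a rigid substrate, the substrate's image stress
field stiffens the apparent response. The bottom-effect cone correction
(BECC) multiplies the Sneddon force by a polynomial in the dimensionless
parameter χ = δ·tanθ/h (of the order of contact radius over thickness):

    F = F_Sneddon(δ) · B(χ),
    B(χ) = 1 + b₁χ + b₂χ²,   b₁ = 4·1.7795/π² ≈ 0.7212,   b₂ = b₁².

1.7795 is the image-series constant of the bonded solution; the
first-order coefficient is consistent with the known bonded-sphere
correction (1.133·a/h) once the cone's contact radius a = (2/π)δ·tanθ is
inserted, which is the cross-check a transcription of this series should
pass. B(0) = 1 recovers the half-space limit, B is monotone increasing,
and the model is meaningful only for δ < h; the public `becc_force`
enforces δ < h, while the fitting basis evaluates the polynomial for any
δ ≥ 0 so that trial fits at absurd candidate CPs stay finite instead of
aborting a search. Note that the relative deviation from Sneddon at
δ/h = 10⁻⁴ is b₁·tanθ·10⁻⁴ ≈ 5·10⁻⁵ — first-order in δ/h, as any
physical thin-film correction must be.

Poisson's ratio defaults to 0.5 (incompressible soft matter); the tip
half-angle to 35°.

## Modulus fitting

Both contact models are *linear* in E, so the least-squares problem with E
as the only free parameter has the closed-form solution
Ê = ⟨φ,F⟩/⟨φ,φ⟩ with φ(δ) the unit-modulus model response. Clipping a
convex quadratic objective onto the bound interval E ∈ (10⁻³, 10⁴] kPa
preserves optimality, so the closed form equals the bounded nonlinear
least-squares solution exactly and deterministically; the test suite
cross-checks it against an independent `scipy.optimize.least_squares` run.
Negative-indentation points are excluded from every fit (the models
describe contact only), and r² is computed on the fitted range only.

The power-law fit F = A·δˣ profiles out the prefactor — for fixed x the
optimal A is a linear projection — leaving a bounded one-dimensional
minimization in x (Brent, xatol 10⁻⁵), initialized from the log–log
linear regression and with δ rescaled to its geometric mean for
conditioning. Points with δ ≤ 0 or F ≤ 0 are dropped; at least five must
remain.

## Sequential contact-point search

Every approach sample (stride 1 by default) is a candidate CP; the search
is exhaustive because combined traces are in general multimodal, which
rules out golden-section-style bracketing. Conventions that matter:

- **Orientation.** Approach Z increases toward the sample; files recorded
  the other way are sign-flipped on read. "Later index" always means
  "deeper".
- **Edge margins.** RoV needs a full window (50 nm, ≥ 5 samples) on each
  side; the ΔE stencil needs three candidates per side; PLE needs 250 nm
  of travel ahead; GoF fits need ≥ 10 samples ahead. A strategy's valid
  range is the intersection; an empty intersection is an error, not a
  silent fallback.
- **GoF.** For each trial point the curve is re-zeroed there (δᵢ = 0,
  Fᵢ = 0) and the model fitted to the whole contact part (`gof_whole`) or
  the first ⌈N_c/3⌉ contact points (`gof_low`) — one fit per candidate.
  The trial thickness is taken per-candidate from the glass reference
  (h_i = |Z_glass − Z_i|) unless a fixed h is supplied. The r² trace is
  floored at 0: r² is unbounded below, and a single catastrophic trial fit
  (SS_tot ≈ 0 in a pure-noise window) would otherwise stretch the min–max
  normalization until the whole trace compresses toward 1 and the
  combined product is driven by the other components' noise.
- **RoV.** RoVᵢ = var(d over (i, i+w]) / var(d over [i−w, i)), trial point
  excluded from both windows, contact side in the numerator. The
  denominator is floored at (10⁻³ nm)² so noiseless baselines cannot
  divide by zero. With 20-sample windows the exact null mean of the
  variance ratio is 19/17 ≈ 1.12, which is why the "near 1" acceptance
  band is asymmetric ([0.8, 1.25]).
- **ΔE.** −d(ln E)/di with the 6th-order central stencil
  (−1, 9, −45, 0, 45, −9, 1)/60, exact for series with log-linear decay
  and scale-invariant under E → λE. Standalone ΔE computes whole-contact
  fits itself; in combinations containing a GoF component it consumes that
  component's modulus series (preferring `gof_low`'s), so one fitting pass
  per candidate serves both.
- **PLE.** −|x − 2| over a 250 nm vicinity ahead of the trial point. The
  vicinity restriction keeps thin-film higher-order terms from dominating
  the exponent; any strictly decreasing function of |x − 2| has the same
  argmax, which is the invariant that matters.
- **Normalization and combination.** Min–max onto [0, 1] (argmax
  preserving; keeps strictly negative raw scores valid as product
  factors); entries invalid in any component are invalid in the product;
  global-maximum ties break toward the smaller index (the earlier,
  conservative CP). A constant combined trace raises a detection-failure
  error; a result whose best r² < 0.5 or RoV peak < 1.5 is returned but
  flagged `low_confidence`, so contact-free curves are never reported
  silently.

## Assessment metrics

σ²(E) and σ(E,h) use the n−1 sample estimators and s(E) the
Fisher–Pearson moment coefficient g₁ — the distinction from other
estimator conventions is below the precision at which such tables are
printed. SR counts moduli inside an inclusive acceptance range, with
failed detections in the denominator; the default ranges are
(0.3–60) kPa for 10 kPa gels, (0.15–9) for 1 kPa, (0.02–1) for 0.1 kPa.
The global metric M = σ²(E)·|σ(E,h)|·|s(E)|/SR (kPa³·nm) takes absolute
values so rows with negative covariance or skew remain comparable;
SR = 0 yields +∞ with a warning. All moment-based metrics in one report
are computed on the identical valid-curve subset.

## Synthetic generator

`SampleProfile` defaults encode the emulated regime: 5 µm ramps sampled at
2048 points per approach (≈ 2.44 nm/sample), k = 0.03 N/m, θ = 35°,
ν = 0.5, E_true = 10 kPa, thickness uniform over 2–8 µm, i.i.d. Gaussian
deflection noise of 1 nm, and a true CP drawn in the 30–60 % stretch of
the ramp. The contact part solves the implicit balance
k·d = F_BECC((Z − Z_CP) − d) per sample by vectorized Newton iteration
(the balance is strictly monotone, so the root is unique; g is concave in
d, so Newton from 0 converges monotonically; every residual is checked
against 10⁻⁶ nN). The small-deflection shortcut δ ≈ Z − Z_CP is *not*
used: at kPa moduli probed with a 0.03 N/m lever the deflection is a
non-negligible fraction of the travel and would bias the ground truth.
Indentation is capped at 0.8·h by pushing the CP later on thin spots,
keeping the generated contact inside the thin-film model's validity. The
withdraw half retraces the approach elastically; an optional stiffening
factor generates controlled hysteresis for approach/withdraw analyses;
an optional linear baseline drift (off by default) never moves the ground
truth. The glass reference is placed consistently, Z_glass = Z_CP + h.

Deliberately *not* modelled: adhesion snap-in, viscoelastic hysteresis,
1/f or drift noise, hydrodynamic drag, and heterogeneous stiffness
fields.

## What the benchmark shows — and does not

Because the generator produces exactly the response the fitted model
assumes, plus i.i.d. noise, the whole-curve goodness-of-fit statistic is
close to a matched-filter optimum on these curves: in the 200-curve noisy
experiment it localizes the CP to a median of ~2 nm and recovers E to a
median of ~0.2 %. Two structural behaviours of the other test parameters
are worth knowing (both are computed by the acceptance tests):

- **RoV carries a contact-side bias of order half a window.** The
  numerator window's variance keeps growing as the trial point moves into
  contact while the denominator stays at the noise floor, so the expected
  trace peaks roughly w/2 *inside* the contact region (~ +18 samples
  ≈ 44 nm at 0.1 nm noise). RoV finds the CP's vicinity — within about
  one window — not the CP sample.
- **The ΔE inflection peak is a noisy-curve feature.** On ideal noiseless
  curves ln E(i) has a locally *maximal* slope at the CP (a valley of
  −d(ln E)/di), and over a full-range search the monotone deep-baseline /
  deep-contact behaviour dominates the global maximum. The inflection that
  makes ΔE useful on real curves plausibly needs the noisy-baseline
  plateau of E(i); accordingly ΔE is best used inside a combination
  (where the other factors suppress the trace edges) or over a restricted
  search window near the expected CP, for which `StrategySpec.search_range`
  exists.

Consequently the combined gof_low·rov·delta_e strategy — the best
performer on real curves, whose baselines contain drift and artifacts
that break whole-curve fitting — inherits jitter from its RoV and ΔE
factors on these idealized curves (median CP error ~160 nm, median
modulus error ~23 % at 1 nm noise) and does *not* out-rank `gof_whole`
here. A passing synthetic benchmark therefore validates the machinery
(transforms, fits, traces, metrics, determinism), not the real-world
superiority of any particular strategy; establishing the latter requires
curves whose artifact structure the generator intentionally omits.

One published-table note: recomputing M from the printed component
metrics reproduces seven of the eight strategy rows to ≤ 1 % (the
classical whole-fit row to three significant figures), while the printed
M of the three-way combined row cannot be reached within any rounding of
its printed components (computed 3.18·10⁴ vs printed 3.54·10⁴, ~10 %
apart) — an internal inconsistency of the source table that the
acceptance suite surfaces rather than hides.

The modulus-asymmetry check uses a thin curve (h = 3 µm): forcing the CP
200 nm into the contact side inflates ln E slightly more than the
mirror-image shift deflates it, the seed of log-normal-looking modulus
distributions. The effect weakens with thickness and inverts near the
half-space limit (h = 8 µm), where the thin-film nonlinearity vanishes.

## Problem sizes and determinism

The shipped experiments use 20 noiseless curves for localization, 200
noisy curves for the ranking/recovery experiment, and 100 contact-free
curves for the RoV null — sizes at which every quoted statistic is stable
run-to-run. All randomness flows from explicit seeds (per-curve seeds
derive from one master seed), identical inputs give bit-identical
results, and hypothesis-based property tests run derandomized.

## Known limitations

- Conical tip only: no pyramidal (Betti–Rayleigh), spherical or
  flat-punch geometry, no adhesive (JKR/DMT) or viscoelastic models.
- No vendor binary formats and no photodiode-sensitivity or
  spring-constant calibration: deflection must already be in nm.
- CP detection operates on the approach only; withdraw fits reuse the
  approach CP.
- The depth-dependent modulus pair splits the contact points at N/2 by
  index, the simplest of several published depth-resolved schemes.
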