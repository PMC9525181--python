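# Methods

## Model and coupling statistic

The package quantifies phase–amplitude coupling by asking how much a slow
rhythm's instantaneous phase helps predict a fast rhythm's instantaneous
envelope.  The envelope `y` (unit-norm, so high-band power does not leak
into the statistic) follows an autoregressive model of order `p` whose lag
coefficients depend statically on the scheduling signal
`s = [cos P_L, sin P_L]` through a polynomial basis.  Using both cosine and
sine avoids the null-phase problem of encoding the phase as a single angle.
Of the full bivariate polynomial of degree `q`, only the constant and the
degree-q monomials `s1^i s2^(q−i)` are retained, keeping models of
different polynomial order well separated; each lag then carries `q + 2`
coefficients (`1` when q = 0, which is a plain AR model).

Two numerical consequences of this basis are worth knowing:

* For even q the monomials are exactly collinear with the constant
  (`s1² + s2² = 1`), so the coefficient vector is identifiable only up to
  the regressor row space.  The ridge penalty resolves the degeneracy; the
  test suite checks recovery of the identifiable representative (the
  projection of the generating coefficients onto the row space), which the
  λ → 0 ridge limit attains.
* Degree-2 monomials of a phase advancing at frequency f oscillate at 2f.
  The q = 2 model therefore responds to coupling at *twice* the nominal
  phase frequency — a sub-harmonic sensitivity discussed under
  Limitations.

Fitting is ridge regression on the extended regressor matrix (rows for
samples `n = p..N−1`; no fabricated pre-sample history).  The coupling
index is `|log(e'e / e0'e0)|`, where `e0` comes from applying the fitted
coefficients to a regressor matrix rebuilt after one random permutation of
the scheduling signal's time order.  Both components are permuted jointly
so cos/sin pairs stay on the unit circle; permuting the columns
independently would create scheduling states that cannot correspond to any
phase.  An option averages `e0'e0` over m permutations, trading runtime
for a lower-variance index; the default is a single permutation.

## Structure selection

1. **Orders (p, q)** — grid search (defaults p ∈ 1..15, q ∈ 0..4) at a
   fixed, relatively large ridge parameter (default λ = 10), scored by
   in-sample mean squared residual over the retained rows.  Ties break
   toward smaller q, then smaller p.  The step exists mainly to pin q; on
   the monophasic simulation it selects q = 2 in every seed at λ = 10.
   At λ = 0.01 roughly a quarter of seeds still select q = 2 and the rest
   q = 3 — in-sample MSE at weak regularization rewards the extra
   harmonics — so the modal order across seeds and both settings is 2.
2. **Ridge parameter** — with (p, q) fixed, λ is the grid argmin of the
   U-curve `U(λ) = 1/‖w(λ)‖ + 1/‖e(λ)‖` over {10⁻³,…,10³} (plain norms;
   log-log plotting does not affect the argmin).  Ties break toward the
   smaller λ.

## Preprocessing

* **Filter** — linear-phase least-squares FIR band-pass applied
  forward–backward (zero net phase).  Order is `round(3·fs/low_cutoff)`
  (three cycles of the band's low cut-off), tap count forced odd.
  Transition bands are explicit linear ramps extending 25 % of each
  cut-off, and the taps are rescaled to unit gain at the band center:
  with the three-cycle rule, narrow bands get short filters whose
  unnormalized pass-band gain is off by up to ±20 %, which would inject
  band-dependent scale into downstream estimates.  Rescaling leaves the
  relative selectivity unchanged.  Note the short filters of high-frequency
  bands are deliberately tolerated: a 2 Hz-wide amplitude band can only
  carry modulation sidebands at ±4 Hz because its filter is broad; a
  maximally selective amplitude filter would remove the very sidebands
  that encode the coupling.
* **Short signals** — when a trial is too short for the nominal order
  (e.g. a delta-band filter of order 1440 on a 720-sample trial), the
  feature-extraction path caps the order at N/3 − 1 with a warning
  (`cap_order=True`); the low-level API raises instead unless asked.
* **Phase/envelope** — angle and magnitude of `scipy.signal.hilbert`.
* **Edge handling** — `trim_edges` discards filter-length samples at each
  end (capped at an eighth of the signal per side) before estimation.
  It is **off by default**: estimation uses the whole record.  Empirically,
  at the 6 s / 240 Hz problem sizes used here, shrinking the analysis
  window inflates the LPV-AR index in slow-phase cells (fewer phase
  revolutions per window make in-sample phase-conditional overfitting
  easier) by more than residual edge transients bias it.
* **Dominant sub-band** — for wide named phase bands the phase driver is
  the 1 Hz sub-band (step 0.5 Hz) with maximal band-passed variance, so
  the phase estimate tracks a genuine spectral peak rather than a
  broadband mixture.  Ties break toward the lower sub-band; the scan is
  exhaustive over the candidate list.

## Synthetic data

`simulate` generates the study conditions: a driver of band-limited white
Gaussian noise (1 Hz band around f_L = 4 Hz, i.e. 3.5–4.5 Hz, rescaled to
unit sample variance) modulating a f_H = 60 Hz carrier at fs = 240 Hz for
6 s, plus white noise with σ_u = 0.5.  Set I uses the logistic factor
`1/(1+exp(−3 x_L))` (monophasic); set II subtracts 0.5, making the
envelope magnitude peak at both driver peaks and troughs (biphasic).
σ_u = 0.5 is taken as the normative noise parameter.  Batches derive
per-realization seeds from a master seed by a fixed affine counter,
`(master·1000003 + i) mod (2³¹−1)`, so realization i can be regenerated
alone.

Labeled multi-channel trials for the decoding pipeline interpolate, per
class and channel, between a constant-amplitude carrier (gain 0) and full
monophasic modulation (gain 1), each channel with an independent driver
and noise.  This is a synthetic stand-in that carries only the coupling
structure the decoder is meant to find: no 1/f background, volume
conduction, artifacts, or nonstationarity.  Passing tests therefore show
the pipeline recovers class-dependent coupling under ideal conditions, not
that it would survive real EEG noise.

## Comodulograms

Amplitude bands tile 20–80 Hz edge-to-edge (2 Hz step and width → 30
bands); phase bands of 0.5 Hz width are centered on 2, 3, …, 10 Hz (9
bands; "4 Hz" means 3.75–4.25 Hz).  One estimator value per cell; for
LPV-AR, structure selection runs per cell, and per-cell permutation seeds
are spawned from the map seed so results do not depend on traversal
order.  Batch maps are averaged element-wise *before* normalizing by the
global maximum.  Marginal profiles average over the other axis and are
normalized to their own maximum.  Whether 60 Hz falls in the 58–60 or
60–62 band is convention-dependent; peak location checks use "the band
whose closed interval contains 60 Hz", with argmax ties resolving toward
lower bands.

## Decoding pipeline

Trial features are coupling indices for the 15 ordered pairs of the six
canonical bands (delta 0.5–3, theta 4–8, alpha 8.5–12, beta 12.5–30,
gamma 30.5–60, high-gamma 60–70 Hz) × regions of interest, pair-major.
The classifier is multiclass LDA with the pooled covariance shrunk toward
scaled identity, intensity chosen analytically (Ledoit–Wolf).  Feature
selection is backward elimination driven by permutation importance: per
step, stratified five-fold CV; per fold, each surviving feature's
importance is the mean accuracy drop over 10 test-set shuffles of that
feature column; importances are averaged per fold then across folds (the
per-fold-then-average convention), and the minimum-importance feature is
removed.  The surviving-set size at the internal-CV accuracy maximum is
"optimal" (ties toward fewer features).  Validation repeats a stratified
10 % hold-out (default 50 repeats; the bundled study and acceptance runs
use 10), rerunning the elimination on each training portion and scoring
every surviving-set size on the hold-out after retraining on all internal
data.  The label-permutation control shuffles labels once per repeat while
keeping the identical partitions, giving an empirical chance level
(theoretical 20 % for five balanced classes).

## Problem sizes

The bundled simulation study uses 20 realizations (the estimator-ranking
figures this package reproduces used 100) with per-cell order selection
restricted to p ∈ {2,4,6,8,10}, q ∈ {0,…,3}; the biphasic ranked check
uses 10 realizations on a coarser phase grid (centers 2,4,…,10 Hz);
Monte-Carlo ordering checks in the unit suite use 10 seeds.  These sizes
were chosen so the whole suite runs in minutes on a single core while
keeping the compared effects far larger than their Monte-Carlo error.

## Known limitations

* **Background noise floor.**  With a single permutation, `|log(e'e/e0'e0)|`
  at uncoupled cells is the absolute value of a near-zero noisy quantity,
  whose mean is positive and does not shrink when averaging maps across
  realizations.  Normalized LPV-AR comodulograms therefore show a higher
  off-peak background than MI or GLM (whose null values are near zero),
  even though the peak is sharper in phase frequency.  Averaging `e0'e0`
  over several permutations lowers the floor at proportional cost.
* **Sub-harmonic response.**  Because the q = 2 basis oscillates at twice
  the scheduling frequency, the phase column at half the true driver
  frequency (2 Hz for a 4 Hz driver) shows a genuine, systematic response.
  Interpreting comodulogram columns at sub-harmonics of a strong driver
  requires care; restricting q to odd orders removes the effect but also
  the ability to represent biphasic coupling.
* **In-sample selection.**  Step-1 MSE is computed on the whole record
  (no hold-out), so at weak initial regularization it drifts toward larger
  q; the default λ_init = 10 is part of the method.
* The trial generator models coupling only; claims about real-EEG decoding
  accuracy are outside what these simulations can support.
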