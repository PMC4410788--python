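# Methods

## Model and estimands

The pipeline analyses repetitive timed tapping under the two-process
timing model: independent clock intervals C_j (mean = target interval +
drift) and independent motor delays D_j produce inter-response intervals

    I_j = C_j - D_{j-1} + D_j.

Because D_{j-1} enters two neighbouring intervals, the detrended series
has autocovariances G(0) = sigma_C^2 + 2 sigma_D^2, G(1) = -sigma_D^2 and
zero beyond lag 1, so rho(1) = G(1)/G(0) lies in [-0.5, 0]: 0 when the
motor delay is noiseless and -0.5 when the clock is.  Inverting gives the
estimands reported per session: motor variance -G(1), clock variance
G(0) + 2 G(1), total variance G(0), the modelled mean inter-response
interval, and drift (modelled IRI at the final analysed stimulus minus at
the first; positive = slowing).  Estimates are deliberately not clamped:
negative variance components are the observable signature of sessions
with empirical rho(1) outside [-0.5, 0] and are reported as such.

For the self-paced task the motor component is typically negligible
(group-mean rho(1) near zero), so total variance is the headline
between-group metric there; clock and motor components are still computed
and reported for comparability with the paced task.

## Per-session estimation

1. **Interval extraction.**  Intervals are formed between consecutive
   recorded taps.  For the self-paced task, taps within half a target
   interval of a pacing tone are synchronization-phase taps and are
   discarded first.  Each tap is tracked to a stimulus slot
   sequentially: the first tap anchors to the nearest tone and each
   subsequent tap advances the slot by round(gap / target).  An advance
   of 0 flags a double-tap candidate (`unassigned`); an advance >= 2 (or
   any gap > 1.5 x target) flags the spanning interval
   `missing_neighbor` — it is never emitted as if it were a genuine
   interval, and intervals are never reconstructed across a gap.
   Sequential tracking rather than absolute nearest-tone matching is
   used because a continuation process without phase correction (and the
   simulator below models none) wanders relative to the metronome by
   sigma_C * sqrt(j); absolute matching would spuriously unassign
   phase-wandered taps in long series while sequential tracking applies
   the same +/- half-interval tolerance locally, where it is meaningful.
2. **Prefilter.**  Intervals terminating at the first 2 taps (paced) or
   first 7 taps (self-paced, counted after the synchronization phase)
   are removed to eliminate atypical early responses.  At least 10 valid
   intervals must remain.
3. **Trend + lag-1 fit.**  A polynomial in stimulus index — quadratic
   (paced) or cubic (self-paced) — is fitted with a lag-1 serially
   correlated error.  The index is centred (and scaled to [-1, 1] for
   the cubic model) before powers are formed; coefficients and drift
   metrics are reported on the original index scale.  Two estimators sit
   behind a switch:
   - `acf` (default): trend by least squares, then G(0) as the mean
     squared residual over the n valid intervals (no bias correction, no
     re-centring) and G(1) as the mean product over pairs of residuals
     whose terminating taps are exactly 1 apart, divided by the number
     of contributing pairs.  Excluded or missing intervals contribute no
     pairs.  This normalization is fixed so that an independent
     double-loop computation reproduces it exactly, and it places no
     constraint on rho(1), which real sessions do violate.
   - `ar1`: trend and AR(1) error fitted jointly by state-space maximum
     likelihood (missing intervals handled by the Kalman filter);
     G(0) is the implied stationary variance (innovation variance
     optionally, via `ar1_innovation_variance`) and G(1) = rho_hat G(0).
     This variant constrains rho(1) to (-1, 1) smoothly and cannot
     produce the out-of-range values the acf estimator reports, which is
     why it is not the default.
4. **Outlier exclusion.**  Intervals with |residual| > 2 x sqrt(G(0))
   are excluded and the model refitted, iterating to a fixed point (max
   5 rounds).  The threshold is anchored to the initial fit's residual
   SD: re-deriving it from each round's shrunken residual variance
   contracts the yardstick and would exclude 8-10% of perfectly clean
   Gaussian data, whereas the anchored rule excludes the nominal
   2*Phi(-2) ~ 4.6% tail.  The multiplier (2.0) and round cap are
   configurable.

### Small-sample behaviour of the acf estimator

Two biases matter at typical session lengths (~47 analysed intervals)
and are quantified by the validation suite rather than hidden:

- Least-squares detrending with p+1 parameters shrinks the residual
  variance by ~(n-p-1)/n and pushes the residual lag-1 autocovariance
  more negative by O(G(0)/n).  At n = 47 with a quadratic trend this
  biases mean recovered clock variance downward by roughly 20%.
- The 2-SD exclusion, applied to data that are in fact clean Gaussian,
  truncates the residual distribution: G(0) shrinks by the factor 0.774
  and the retained adjacent-pair covariance by ~0.60.  On long series
  this moves an estimated rho(1) of -0.5 to about -0.41.

Consequently the `validate` recovery check reports clock variance well
below truth under simulated small-sample conditions; this reflects the
published estimator faithfully reimplemented, not an implementation
defect, and the biases vanish as series length grows when exclusion is
disabled.  The analytic rho(1)-limit checks therefore run the estimation
pipeline without the exclusion step, whose purpose is artifact removal,
not inference on clean data.

## Group-level inference

Point estimates are group-indicator coefficients from linear regression
(age in years and a male-gender indicator as covariates when adjusted),
with HC3 robust standard errors reported because group variances differ.
Interval inference uses the bias-corrected and accelerated bootstrap:
participants (the independent unit) are resampled with replacement
within groups, the regression is refitted per replicate (default 2000),
z0 comes from the fraction of replicates below the point estimate and
the acceleration from jackknife skewness.  Degenerate situations are
flagged, not masked: identical replicates give a zero-width interval;
an undefined z0 falls back to the percentile interval.  For the
drift-direction interaction model, resampling is stratified by
group x direction cell so every replicate retains all four cells.
Association models regress a metric on score, group and (optionally)
their interaction with the same covariates, dropping participants with
missing scores listwise and logging the count.

The rho(1)-violation test counts participants with rho(1) > 0 per group
and computes an exact Fisher p for the r x 2 table by full enumeration
of tables with the observed margins (grand total <= 60), otherwise by
Monte Carlo sampling from the margin-conditional null with a fixed seed.

## Synthetic cohorts

The simulator draws C_j and D_j as independent Gaussians — the
conventional assumption, which also makes the exclusion rate analytic —
with the drift polynomial injected into the clock mean so that the
estimation trend is correctly specified and parameter recovery is
well-posed.  The paced task anchors the first tap to the first tone;
self-paced sessions emit synchronization-phase taps on the beat, then
apply the participant's rate offset and drift from the first
continuation interval.  Recording artifacts are applied to the realized
tap train: each tap is deleted with probability `p_miss` (the mask is
resampled if it would remove more than half the taps) and a spurious tap
is inserted uniformly inside an interval with probability `p_double`.
Tap times are rounded to the 0.1 ms granularity of the tap-log format,
so write -> read round-trips are exact.

The built-in two-group cohort (31 controls, 20 patients) sets group
sizes, age and gender distributions, condition-specific variance
components, self-paced rate offsets (-132 vs -277 ms), drift
distributions and cognitive-score distributions to the magnitudes
reported for healthy controls and bvFTD patients in this paradigm;
artifact rates (p_miss 0.02, p_double 0.01) are a modest choice since
capture-error rates are not published.  Between-participant SDs of the
variance components are set so that group-level spreads are of the
reported order.

What the simulator does *not* model — and what passing tests therefore
cannot show about real data: phase correction toward the metronome in
the paced task (real tappers are phase-locked; simulated tap times
wander), tap-tone asynchronies, fatigue or attention dynamics beyond a
smooth polynomial drift, non-Gaussian heavy-tailed motor delays, and any
dependence of artifact rates on the participant's state.

## Numerical choices and degenerate inputs

- G(0) <= 0 makes the decomposition undefined: NaN markers are returned,
  never zeros.
- The identity clock + 2 motor = total holds to machine precision by
  construction and is verified over random (G0, G1) pairs.
- Sessions with fewer than 2 analysable taps, fewer than 10 valid
  intervals, or a rank-deficient trend design raise a tagged error;
  the pipeline logs and skips such sessions rather than aborting a run.
- Stimulus-slot ties round half-gaps toward the earlier slot via
  banker's rounding of round(); in practice ties have measure zero.
- All randomness flows from integer seeds through numpy Generators;
  cohort simulation spawns per-participant child seeds so output is
  byte-identical for a fixed (spec, seed) regardless of chunking.

## Reference experiment sizes

The validation suite uses 5000-interval series for the analytic limits
and exclusion calibration, 200 simulated participants for parameter
recovery, and 200 replications x 999 bootstrap resamples for BCa
coverage and type-I error (long-run type-I measured at 0.055 over 1000
replications).  These sizes keep each check's Monte-Carlo error well
inside the tolerance it asserts.
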