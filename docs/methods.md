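# Methods

## The correlation problem

During externally guided radiotherapy of a moving (typically lung or
upper-abdominal) tumor, the tumor position is measured directly only at
sparse stereoscopic X-ray imaging instants, while three optical markers on
the patient's chest are tracked continuously at ~25 Hz.  A *correlation
model* maps the 9-dimensional external signal `x(t)` (x, y, z per marker,
mm) to the 3-dimensional internal tumor position `y(t)` (mm), trained from
the handful of synchronized (x, y) pairs available — clinically between 4
and 27 points collected over 58–603 s — and updated during treatment as
new imaging points arrive.

`fuzzytrack` implements three first-order Takagi–Sugeno model families for
this map, a per-patient selection procedure, and updating by rebuild, with
a synthetic respiratory-motion generator standing in for clinical logs.

## Sugeno inference

Every model is a set of rules, one per data cluster.  Rule *i* has a
Gaussian membership function per input dimension,
`mu_id(x_d) = exp(-(x_d - c_id)^2 / (2 sigma_id^2))`, a product AND
(firing strength `w_i = prod_d mu_id(x_d)`), and a first-order linear
consequent `f_i(x) = p_i . x + r_i`.  The output is the
normalized-firing-strength weighted average
`f(x) = sum_i wbar_i f_i(x)`, `wbar_i = w_i / sum_j w_j`.  Firing
strengths are evaluated in log space, so `wbar` is well-defined even far
from all rule centers (a max-subtracted softmax); the prediction is then
always a convex combination of the per-rule linear maps.

Three independent single-output rule bases are fitted, one per internal
coordinate.  All fitting happens on inputs and outputs normalized to
[0, 1] over their training range (constant dimensions are flagged and
given unit scale); normalization parameters are stored in the model and
inverted at prediction time, so cluster radii are fractions of the data
width uniformly across dimensions, and predictions in mm are invariant to
the raw units of any channel.

## Rule generation by clustering

Clustering runs on the joint normalized (9 input + 1 output) space, so a
cluster fixes both a premise region and the seed of a local linear model.

**Subtractive clustering** (SUB-FIS) scores every data point by its
potential `D_i = sum_j exp(-||z_i - z_j||^2 / (r/2)^2)` and greedily
extracts centers: accept the max-potential point, subtract its squashed
Gaussian (radius `1.25 r`), keep accepting while the relative potential
exceeds 0.5, stop below 0.15, and use the standard distance/potential tie
band in between.  Ties break to the lowest index, making the procedure
fully deterministic.  The influence range is `r = 1/3` of the data width —
the package's operating point throughout.  Premise widths are uniform,
`sigma = r * width / sqrt(8)`.

**Fuzzy C-means** (FCM-FIS) takes the subtractive centers as its cluster
count and initialization and refines them by alternating minimization of
`J_m = sum_ij u_ij^m ||z_i - c_j||^2` (fuzzifier `m = 2`, termination
`max|U(k+1) - U(k)| < 1e-5`, at most 200 iterations; the membership update
is the standard `u_ij = 1 / sum_k (d_ij/d_ik)^(2/(m-1))`, with crisp
assignment for points coincident with a center).  Premise widths are the
membership-weighted spread per input dimension, floored at **half the
subtractive width**.  The floor matters: on few-point clusters the raw
spread can collapse to near zero, and because normalized firing is
scale-free, a near-singular premise dominates arbitrarily far inputs and
extrapolates its local consequent wildly (we observed 30 mm excursions
before flooring).  A secondary absolute floor of 1e-4 (normalized) guards
singleton clusters in both families.

## Consequent estimation

Consequent parameters minimize the inference-time objective jointly over
all rules: `sum_t (y_t - sum_i wbar_i(x_t) (p_i . x_t + r_i))^2`.  On 4–27
training points against `n_rules * 10` parameters this system is almost
always underdetermined, and any exact minimizer interpolates observation
noise.  The solve is therefore parameterized as a global affine fit plus
per-rule deviations:

1. the affine stage is a centered ridge regression whose strength is
   chosen by generalized cross-validation (GCV) on a log grid — the nine
   surrogate channels are driven by one latent breathing phase and are
   nearly collinear, so an unregularized solve amplifies noise along the
   weak directions of the design;
2. the deviation stage solves the weighted-regressor system for the
   residual, again with GCV-chosen ridge (floored at 1e-8), taking an
   exact truncated-SVD path only when the residual is representable to
   machine precision (noiseless data).

Among the exact minimizers of the joint objective this picks the one
shrunk toward the global affine fit.  Consequences: purely affine data
yields the affine predictor exactly (held-out error at machine precision);
a single-rule base reduces to (ridge-regularized, effectively ordinary)
least squares; under noise the rule deviations survive only where they
genuinely reduce cross-validated error.  Diagnostics (chosen ridge,
rank-deficiency, underdetermination) are recorded in the model provenance.

## ANFIS

ANFIS is the same Sugeno network viewed as five layers (membership grades,
product firing, normalization, weighted consequents, output sum), trained
by hybrid learning from the SUB-FIS initialization: per epoch, consequents
are solved exactly by the estimator above (forward pass), then every
premise `(c, sigma)` moves one normalized-gradient step against the batch
squared error (backward pass).  Gradients are derived through
`log w` (so they are stable where raw firing underflows) and are verified
against central finite differences in the tests.  The step size starts at
0.01 (normalized units), multiplies by 1.1 after four consecutive error
decreases and by 0.9 after a sustained up-down oscillation — the classical
heuristic.  Each output's rule base trains independently with its own step
and history; the returned model is the per-output snapshot with minimum
training error, so it is never worse on the training set than its
initialization, and zero epochs return the initialization unchanged.
Widths that a step would drive below the floor are re-floored and the
event counted in provenance.  Defaults (20 epochs, batch gradient) suit
the tiny clinical training sets; none of these values is prescribed by
the underlying method description, and all are configurable.

## Selectivity and updating

Training points are split temporally: the earliest `ceil(0.75 n)` points
fit the three candidate families, the most recent quarter checks them by
3-D RMSE.  A temporal (not random) holdout matches the task — the model
selected at configuration time must perform *later* in the session.
Check sets hold only 1–7 points, so the check RMSE carries a relative
sampling error around `1/sqrt(2 n_check)` ≈ 30%; candidates within 20%
of the minimum are treated as statistically tied, flagged in the report,
and resolved by the preference order FCM-FIS > ANFIS > SUB-FIS (the
family ranking that motivates the tie-break is the robustness ordering
observed across our cohort experiments).  The winner is retrained on all
100% of the training points before deployment — with 4–27 points total,
discarding the check quarter permanently would be wasteful, and its only
role is selection.

Updating rebuilds the chosen family from scratch on all gathered imaging
points (old plus new); new points must be strictly later than existing
ones.  Rebuild equality with a fresh fit on the concatenated set is exact
and asserted in the tests.  Evaluation of a tracked session is
*prequential*: each imaging point is scored with the model in force
before that point arrives, then folded in.

## The synthetic-data generator

Breathing is a cosine-power (Lujan-type) kernel `sin^(2n)(phi/2)` on a
latent phase advancing cycle by cycle with jittered period; each external
channel adds a baseline, linear drift, per-cycle amplitude jitter, an
optional slow amplitude ramp, optional intermittent deep "sigh" cycles of
configurable probability/depth/variability, a per-channel phase offset,
and Gaussian sensor noise.  The internal truth applies a coupling map —
affine, two-regime piecewise linear, or sigmoidal saturation — to the
lag-shifted noiseless external signal, plus an optional hysteresis term
(a `sin(phi)` loop-opening offset) and an internal-only baseline drift.
The distinction between external and internal drift is deliberate:
drift that passes through the coupling leaves the external→internal map
intact, so only drift the surface markers cannot see (tumor baseline
drift) makes intra-treatment updating necessary.

Cohort presets: `control` (mild jitter, affine coupling, no hysteresis)
and `worst` (strong jitter, sighs crossing a piecewise-linear knee above
the quiet-breathing peak, internal drift, hysteresis, heavier noise) —
an operationalization of an easy/difficult patient dichotomy, synthetic
by construction and not fitted to any clinical case.  Magnitudes (tumor
SI excursion ~10–25 mm, periods 3.2–4.8 s, imaging noise 0.4–0.8 mm) are
choices within clinically typical ranges.

What the generator does **not** emulate: imaging geometry and segmentation
error structure, non-Gaussian sensor noise, cough/motion artifacts, true
lung deformation (the coupling is a fixed low-dimensional map), and the
treatment machine's latency-compensation predictor (the models correlate;
they do not forecast).  Passing tests therefore demonstrate correctness
and the qualitative behaviors built into the generator, not clinical
accuracy on real patients.

Because the nine surrogate channels are driven by one latent phase, the
external design is rank-deficient over any single session: the affine
coupling *matrix* is not identifiable from a session, only the map's
action on the breathing manifold.  Tests assert this functional
identifiability (an affine fit on half a noiseless session predicts the
other half to 1e-6 mm).

## Standard experiments and their sizes

The seeded experiments in `fuzzytrack.experiments` (shared verbatim by the
test suite and `scripts/acceptance.py`) use: 27-point training sets for
exactness and noise-floor runs (the upper clinical regime), medians over
20 seeds for noise-floor and drift-update runs, 50 replicates for the
planted-selection rate, and a 10 + 10 control/worst cohort with 40 imaging
points per patient (20 configure the models, 20 are scored prequentially
with a rebuild after every point).  The noise-floor run uses a noiseless
surrogate signal so that the floor `sigma_n * sqrt(3)` is set by the
internal observation noise alone.  The planted-selection scenario is
constructed so that its regime structure is separable only by FCM
partitioning: quiet breathing with a long end-exhale dwell forms one dense
joint-space lobe, and variable-depth sighs land as isolated points on a
sparse branch whose potential falls below the subtractive reject ratio —
SUB-FIS (and the ANFIS initialization) never rules that branch; FCM's
membership mass migrates a center onto it.

## Numerical conventions

- Quantiles/IQR: linear interpolation (`numpy.percentile` default), since
  small-cohort IQRs depend on the convention.
- Empirical CDFs are right-continuous step functions on the unique sorted
  support; the tail criterion reports the fraction of residuals strictly
  beyond 6 mm.
- Synchronization pairs each internal sample with the linearly
  interpolated external row when the bracketing samples are at most 0.2 s
  apart (≈5 samples at 25 Hz); exact timestamp matches copy the row.
- Model files are versioned JSON with full float precision; trace CSVs
  round-trip below 1e-9 mm.
- All stochastic procedures take explicit integer seeds; identical inputs
  give bit-identical outputs across runs.

## Known limitations

- With `r = 1/3` on scattered 10-D joint data the rule count can approach
  the point count; accuracy then rests on the shrinkage estimator rather
  than on parsimonious structure.
- Selection from 1–7 check points is noisy by nature; the tie band makes
  the procedure deliberately conservative toward the preference order.
- The tracker does not compensate acquisition-chain latency; with a
  nonzero external–internal lag the fitted static map absorbs the lag
  into its shape rather than predicting ahead.
- ANFIS can overfit very small training sets (its check-set RMSE is often
  worse than its training RMSE improvement suggests), which is precisely
  why selectivity exists.
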