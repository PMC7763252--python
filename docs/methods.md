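# Methods

## Scope and data model

The pipeline operates on a panel of raw indicator values keyed by
(region, year, indicator). The default indicator catalogue is the
20-indicator PESN system — four Population, six Eco-environment, six
Socioeconomic, four Natural-resource indicators — each tagged with a
direction: *positive* means larger raw values indicate a safer ecology
(e.g. forest cover), *negative* the opposite (e.g. pesticide application
intensity). Years within a region must form a contiguous ascending run;
duplicate (region, year) rows are rejected. Interior missing cells are
filled by linear interpolation between the nearest observed years of the
same (region, indicator) series; missing endpoints are refused rather than
extrapolated, since interpolation between neighbours is the only filling
rule adopted.

## Normalization

Each indicator is min-max rescaled to [0, 1], with the direction deciding
the orientation, so that 1 always means safest. The min and max are pooled
over **all** (region, year) observations jointly. This is a deliberate
choice where per-year or per-region pooling would also be defensible:
global pooling is the only option under which the composite index is
comparable across years, which the downstream grey model on the index
*time series* requires. A `pooling="per-year"` mode exists for sensitivity
analysis only. An indicator that is constant over the pooled set has no
min-max image; by default this is an error, optionally (`constant_policy=
"midpoint"`) the column is set to 0.5 with a logged warning — such a column
carries no information and would receive near-zero entropy weight anyway.

## Entropy weights

For indicator j over the m pooled observations, relative frequencies
f_ij = y_ij / Σ_i y_ij, normalized entropy e_j = −(1/ln m) Σ_i f_ij ln f_ij,
difference coefficient b_j = 1 − e_j, and comprehensive weight
w_j = b_j / Σ_k b_k. Type weights renormalize w within each PESN subsystem.
Zero frequencies are replaced by the fixed constant 10⁻⁴ before the entropy
sum, **without** renormalizing the vector; the induced deviation of Σf from
1 is bounded by (number of zeros)·10⁻⁴ and logged. Two consequences worth
knowing:

* min-max normalization guarantees at least one exact zero per column
  (whichever observation attains the pooled extremum), so the substitution
  is always active on real panels;
* because the substitute is fixed rather than proportional, exact
  invariance of the weights under duplicating all observations (which holds
  analytically for zero-free columns, where all difference coefficients
  rescale by ln m / ln 2m) degrades to about 10⁻⁴ on min-max columns. The
  tests assert exact invariance on zero-free columns only.

Weights can alternatively be frozen from an external table
(`WeightTable.from_fixed`), e.g. to score new observations under published
weights; rounded published weights are renormalized to sum exactly to 1.

## Composite index and grading

The early-warning value of a region-year is P_i = Σ_j w_j y_ij ∈ [0, 1];
subsystem subscores use the type weights, so each subscore is itself a
[0, 1] index and the subscores, weighted by their subsystem's share of
comprehensive weight, recompose P_i exactly. Grades are the five half-open
bands listed in the README, lower bound inclusive. The band table covers
[0, 1) only; values at or above 1 — which grey forecasts of a growing index
produce — clamp to grade V, negatives to grade I, each with a logged
warning. Forecast values themselves are reported unclamped.

## GM(1,1)

The model is fit exactly as the classical construction prescribes: 1-AGO,
adjacent-pair mean sequence, least squares on the grey difference equation
x(0)(k) + a z(1)(k) = b over k = 2..n (solved via `numpy.linalg.lstsq`; the
normal-equations solution agrees with the simple-regression closed form to
10⁻¹⁰ and is tested to). Minimum length n = 4: with design rows (−z, 1),
fewer points leave at most one residual degree of freedom. Two restoration
variants return to the original scale, both pinning x̂(0)(1) = x(0)(1):

* **difference** (default for in-sample fit): first differences of the
  time-response curve;
* **derivative** (default for forecasts): x̂(0)(k+1) = −a(x(0)(1) − b/a)e^(−ak).

### Discretization bias of the restorations

A series satisfying the grey difference equation exactly grows at the ratio
(1 − a/2)/(1 + a/2), while both restorations grow at e^(−a). The two agree
only to third order: the difference restoration misfits an exact
grey-difference series by O(a³/12) per step and the derivative form by
O(a/2). Parameter recovery, by contrast, is exact (to ~10⁻¹⁴) at any
|a| < 2, because the fitted equation is linear in (a, b) with zero
residual. The test suite therefore checks

* exact (a, b) recovery on constructed series across the full admissible
  range of a;
* machine-precision end-to-end recovery (C < 10⁻⁶, mean relative error
  < 10⁻⁶) in the small-coefficient regime |a| = 10⁻³, where the O(a³) bias
  sits below tolerance — this exercises the *plumbing* (normalization
  identity, weight conservation, composition) rather than the asymptotics;
* parameter recovery with an O(a²) bound on C at a study-scale coefficient
  (a = −0.15).

No class-ratio admissibility pre-check is enforced before fitting; the
stage-ratio deviation is computed and reported as part of diagnostics
instead.

## Double accuracy test

All diagnostic statistics use k = 2..n and population (divide-by-count)
standard deviations. The first residual is identically zero by the
boundary condition and is excluded so it cannot flatter S2; this convention
reproduces the reference posterior error ratio of the worked example to
printed precision, whereas including k = 1 shifts it by ~0.07.

* C = S2/S1 with S1 the std of the observed values, S2 of the residuals;
* p = fraction of k with |ε(k) − ε̄| < 0.6745·S1, computed on absolute
  residuals (not relative errors) per the standard construction;
* per-point relative errors Φ(k) = |ε(k)|/x(0)(k), summarised by mean and
  max, with mean < 20% reported as the residual-test pass flag;
* stage-ratio deviations ρ(k) = |1 − ((1 − a/2)/(1 + a/2))·λ(k)| with
  λ(k) = x(0)(k−1)/x(0)(k), aggregated by the maximum against a 0.2
  threshold.

C and p are graded on the four-level table (README); the overall verdict is
the **worse** of the two grades, and a "Failed" verdict excludes the region
from the forecast stage (fits and diagnostics are still written for
inspection). The relative-error and stage-ratio flags are advisory and do
not enter the verdict: the stage-ratio maximum in particular is a
sufficient but strict criterion, and the reference composite series itself
shows max ρ = 0.29 against mean ρ = 0.13 while passing both C and p
comfortably. The small-error probability on an 8-point series is a fraction
with denominator 7, so its resolution is coarse (1, 6/7, 5/7, ...);
published p values with denominator 17 cannot arise from such series under
this (or any standard) convention, and no attempt is made to match them.

## Synthetic data

`generate_panel` emulates the study's data shape — 7 regions × 8
consecutive years × the 20-indicator catalogue — as
baseline + slope·(year index) + Gaussian noise, truncated at 10⁻⁶ for
determinism, with one seeded generator per config and no global state.
Baselines are log-uniform over two decades (indicator units differ wildly
in real yearbook data); slopes are 2–10% of baseline per year with the sign
chosen so positive-direction indicators drift up and negative ones down,
i.e. a gradually improving region, the regime the grey model targets. The
default noise scale is 5% of baseline. What the generator deliberately does
**not** emulate: cross-indicator correlation, autocorrelated shocks,
policy breaks, or the actual yearbook marginal distributions — so passing
tests demonstrate correctness of the computation under the stated model,
not robustness to real-data pathologies.

`generate_grey_series` constructs series satisfying the grey difference
equation exactly (recursion x(0)(k) = (b − a x(1)(k−1))/(1 + a/2)), the
package's parameter-recovery oracle. `exact_pipeline_panel` embeds such a
series as the composite index of a noise-free panel by adding a
calibration region that pins every pooled column extremum to {0, 1}, making
normalization the identity on the target rows; the composite index then
equals the ground-truth series for any weight vector summing to 1.

## Determinism and numerics

Pipeline outputs are plain CSV with fixed column order and no timestamps;
identical inputs and configuration give byte-identical files. Panel CSVs
are written with pandas' shortest round-tripping float representation, so a
write/read cycle reproduces every cell bit-exactly. Tolerances used in the
tests: 10⁻⁹ for weight conservation and recomposition identities, 10⁻¹⁰
for least-squares equivalence and scale equivariance, 10⁻⁸ for parameter
recovery, 5·10⁻⁴/5·10⁻⁵/5·10⁻⁶ for reference values at the precision they
are printed.

## Known limitations

* GM(1,1) extrapolates a fixed exponential; it is a short-horizon tool and
  the unbounded forecast of a [0, 1] index is a structural artifact,
  surfaced (values above 1 reported unclamped, grades clamped with a
  warning) rather than hidden.
* The entropy weights depend on the pooled observation set; adding a year
  changes all weights. The frozen-weights mode is the remedy when scores
  must be stable across updates.
* The stage-ratio pass flag under max aggregation is strict on short noisy
  series; treat it as a screening signal.
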