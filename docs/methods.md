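# Methods

## The score

`esperbench` benchmarks classification models on a joint axis of diagnostic
performance and operational carbon footprint. For a comparison series of
models *i* with performance metric M<sub>i</sub> ∈ [0, 1] and emission
C<sub>i</sub> (grams CO2eq), the environmentally sustainable performance
score is

```
score_i = M_i^2 / exp(w · C'_i),      C'_i = (C_i − min_j C_j) / (max_j C_j − min_j C_j)
```

with weighting factor w ∈ [0, 1]. The squared metric rewards highly accurate
models; range normalization maps the series' emissions to [0, 1] regardless
of their absolute scale; and the exponential makes the penalty non-linear in
relative emissions while keeping the denominator ≥ 1 (no division by zero).
Two flavours differ only in which emission enters:

* **iESPer** uses the per-inference emission (g CO2eq per slide) — the
  steady-state cost of one more prediction.
* **fpESPer** uses the combined emission
  C<sub>i</sub>(n) = C<sub>train,i</sub> + n · C<sub>per-use,i</sub> for a
  projected usage count n, with the normalization bounds recomputed at every
  n. Re-normalizing per time point is what makes projection curves of models
  that trade training cost against inference cost intersect; normalizing once
  at n = 0 would freeze the ranking.

Direct consequences, all enforced as tests: 0 ≤ score ≤ M² (equality iff
w = 0 or the model has the series-minimum emission); scores are invariant
under affine rescaling of all emissions (units cancel); increasing a model's
emission never raises its own score, increasing its metric always does; a
degenerate series (all emissions equal, or a single model) normalizes to 0
everywhere and every score collapses to M² — with no emission spread there is
nothing to discriminate on, and this choice preserves the w = 0 limit.

**Series-relativity.** The score is defined only relative to its comparison
series: adding or removing one model moves the min/max bounds and can change
*every* score. Scores from different series are not comparable, and the
package never pools them.

## Emission accounting

Grams CO2eq = energy [kWh] × regional carbon intensity [g CO2eq/kWh], the
yearly averaged grid value. Facility overhead enters through PUE (power usage
effectiveness, default 1.58, the reference GPU server room); meters that
already report facility-level energy carry `pue_applied=True` and are not
multiplied again. Internal canonical units are Wh and grams — benchmark
tables conventionally mix kWh/kg (training) with Wh/g (inference), and a
single canonical pair prevents silent factor-of-1000 errors. Values are
rounded (3 decimals) only at report time, never in storage.

The bundled reference fixture reproduces a published five-model
computational-pathology benchmark (TransMIL, CLAM, InceptionV3, ViT,
Prov-GigaPath on RCC subtyping and kidney-transplant classification). The
German intensity it uses, 361 g/kWh, is *recovered* from the fixture's own
training emission/energy ratios (consistent to <0.1 g/kWh across all five
models), not taken from a grid dataset; `fixtures.py` labels it as such. The
fixture also preserves, deliberately, an internal inconsistency of the
source measurements: ViT's tabulated inference emission (0.065 g/slide)
disagrees with both the accompanying text (0.062 g) and the energy × intensity
product (0.061 g). Loaders take files at face value and never "correct" data;
the emission tests assert the mismatch rather than hiding it. The KTX-task
AUROCs for four of the five models are back-derived from the published score
column (only TransMIL's 0.763 is printed directly) and marked reconstructed.

## Performance metrics

Macro AUROC is one-vs-rest: per class, the rank-based Mann–Whitney statistic
with midranks (ties get half credit), averaged without class weights over the
classes present. The midrank convention makes the statistic invariant under
permutation of equal scores and under any strictly increasing transform.
One-vs-rest was chosen over pairwise class–class averaging as the standard
reading of "macro averaged over class scores". Balanced accuracy is the mean
of per-class recalls from argmax decisions (ties to the lowest class index);
precision/recall/F1 are macro-averaged, with never-predicted classes
contributing precision 0 (logged). scikit-learn's implementations serve as
independent cross-checks in the test suite only.

Confidence intervals for scores are percentile bootstrap (2.5/97.5, default
1000 replicates): cases are resampled with replacement for the performance
side and per-slide energy replicates for the emission side, then the whole
series is rescored. The resampling loop retries draws that lose a class
entirely (AUROC undefined). Seeded and reproducible.

## Mortality cost of carbon

The mortality-cost constant — 4400 metric tons CO2eq per temperature-related
excess death by 2100, over the 2020 baseline — converts per-use emissions
into a usage budget: floor(4.4 × 10⁹ g / per-use grams). Budgets are floored
because "usages before one death" is a count. Zero per-use emission yields an
explicit unbounded signal (`inf`), not an error. Because grid intensity
multiplies every model's per-use emission identically, the model ranking by
budget is country-independent; `country_comparison` asserts this on its
output. Disease-prevalence rates for positive-prediction counts are
user-supplied configuration; the bundled multi-country intensity table is
illustrative except for the recovered German value.

## Data-reduction sweeps

A tile-resolution or tile-fraction sweep is scored as *its own* comparison
series — the sweep's min/max emissions set the normalization bounds. Merging
a sweep into a model zoo would change every number; the reference sweep
column is only reproducible under the own-series reading. `tiles_per_slide`
uses a ceiling (boundary tiles are still processed). Fraction sweeps must be
strictly increasing, end at 1.0, and have emissions strictly increasing in
the fraction (checked, since per-slide energy is linear in tile count); the
reported plateau fraction is the smallest whose performance is within an
absolute tolerance (default 0.005 AUROC — the source of the sweep protocol
says only "comparable") of the 100 %-tiles value.

## Synthetic benchmark

Desk-scale substitutes for GPU metering and patient cohorts:

* **Mock meter**: energy = n_tiles × Wh/tile × PUE × (1 + ε),
  ε ~ N(0, cv) truncated at −0.99; training additionally × epochs ×
  training-set slides × a backprop/amortization multiplier. The protocol
  constants (1000-tile slides, 1000 training slides, 300 epochs, 15
  inference replicates) mirror the reference benchmark's measurement
  protocol.
* **Model zoo**: per-tile energies drawn uniformly in [0.8, 4.0] × 10⁻⁴ Wh
  and multipliers in [0.10, 0.40], which place training emissions in
  ≈1.3–27 kg and inference in ≈0.05–0.23 g/slide at 361 g/kWh — the
  magnitudes of the reference benchmark. Skill is drawn independently of
  cost so performance–emission trade-offs occur. Deterministic per seed via
  spawned `SeedSequence`s.
* **Binormal predictions**: evidence for the true class is N(d′, 1), others
  N(0, 1). For two classes the evidence is mapped to a probability by the
  normal CDF — the textbook binormal ROC model — so the expected AUROC is
  exactly Φ(d′/√2) and d′ is recoverable by probit inversion. For K ≥ 3 the
  evidence vector is softmaxed; the softmax mixes evidences across classes
  and inflates the empirical one-vs-rest AUROC above Φ(d′/√2) (e.g. ≈0.85
  at d′ = 1.19 for K = 3), so the closed form is exact only for K = 2.
  A plain softmax was rejected for K = 2 precisely because ranking by the
  softmax of two scores is ranking by their difference, which doubles the
  effective separation (AUROC Φ(d′) instead of Φ(d′/√2)).

What the generator does **not** emulate: correlated errors across models
scored on the same cohort, class imbalance, per-slide tile-count variation,
non-Gaussian energy noise, and any real association between model capacity,
accuracy and energy. Passing tests therefore demonstrate the correctness of
the scoring machinery under controlled conditions, not the behaviour of real
pathology models.

## Numerical choices

* Crossing detection brackets sign changes of the sampled curve difference,
  then refines by Brent's method on the continuous score formula (relative
  tolerance 10⁻⁶). Coincident curves return no crossings; an isolated zero at
  a grid node counts only when the difference changes sign across it.
* Projection usage counts are integral (rounded from annual_usage × t);
  refinement may return fractional n, reported as-is.
* Ranking ties break toward lower emission, then lexicographic model id, so
  all outputs are deterministic.
* Validation rejects rather than clips: metrics outside [0, 1], negative
  energies/emissions/intensities, duplicate model ids and malformed
  probability rows are errors naming the offending row and field.
* CLI machine outputs embed the resolved configuration and library version;
  timestamps appear only in stderr logs so identical invocations produce
  byte-identical files.

## Problem sizes

The test suite and the acceptance script run the binormal simulator at
n = 20,000 cases (Monte-Carlo error ≈ 0.003 on AUROC, comfortably inside the
±0.01 check), bootstrap checks at 100–200 replicates, and zoos of 3–5 models
with cohorts of 80–300 cases; the whole suite completes in a few seconds on
one CPU. Projection grids use 100–200 points, enough to bracket every
crossing the refinement step then sharpens.

## Known limitations

* The score is not comparable across series or tasks by design; no absolute
  sustainability scale is offered.
* Only operational electricity is accounted: no hardware life cycle, water,
  cooling beyond PUE, scanning or storage.
* The mortality-cost conversion is a single published linear constant with
  no uncertainty propagation.
* Historical static intensity tables only; no live grid APIs.
* The KTX projection example inherits the reconstructed AUROCs and the ViT
  emission inconsistency of the reference fixture, so its crossing time is
  indicative, not a measured result.
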