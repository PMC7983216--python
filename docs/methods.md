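# Methods

This note records the models, defaults and numerical choices behind
`kbplan`, and what the synthetic experiments do and do not demonstrate.

## Dose-volume curves and endpoints

The cumulative DVH `V(D)` — the fraction of a structure receiving at
least dose `D` — is the canonical representation. Curves must start at
`(0 Gy, 1.0)`, be non-increasing and bounded in `[0, 1]`; monotonicity
glitches up to 1e−9 (floating-point noise in interchange files) are
repaired by a running minimum, anything larger is rejected with the
structure named. Interpolation is linear in both axes everywhere.

* `D_x%` is the largest dose at which coverage is still ≥ x/100, by
  inverse linear interpolation; `D_x% ` at full coverage (x = 100)
  returns the end of the ≥ 1 − 1e−9 plateau.
* `V_xGy` is reported in percent to match clinical tables; internal
  storage stays fractional.
* `D_mean` is the trapezoid integral of the cumulative curve over dose
  (identical to the mean of the differential DVH when the curve reaches
  zero inside the grid).
* `D_min` is the end of the full-coverage plateau at tolerance 1e−6 in
  relative volume — an exact minimum, not a near-minimum percentile.
* `D_xcc` converts the absolute volume to a fraction of the structure
  volume and reuses `D_x%`.

The conformity index CI = (V_Tref/V_T)·(V_Tref/V_ref) multiplies target
coverage by dose selectivity. One `iso_fraction` parameter (default
0.95, i.e. the 95% isodose of the prescription) is applied to **both**
V_Tref and V_ref; using a single reference isodose for both factors is
the standard convention, and the level is configurable because usage in
the literature varies between 95% and 98%. V_ref is read off the body
(external-contour) DVH. The homogeneity index HI = (D_2% − D_98%)/D_50%
is zero only for a perfectly uniform target dose.

The default internal dose grid is 0–75 Gy in 0.05 Gy steps (1501
samples): endpoint errors from re-gridding are below 0.1% at negligible
memory cost.

## Plan Quality Metric

Nineteen criteria totalling exactly 100 points cover both targets
(coverage, hot-spot volume, minimum dose, CI, HI) and all seven OARs.
Threshold rows carry an *acceptable* and an *excellent* level whose
points ratio is fixed at 0.6: a value worse than acceptable scores 0
(hard step), exactly acceptable scores 60% of the row's points, and the
score rises linearly to full points at the excellent level, clipping
beyond. `"= 100%"` excellent levels are ordinary thresholds — a value of
exactly 100 scores full points. Ties at a threshold take the better
bracket. CI rows score `max_points·CI`; HI rows `max_points·(1 − HI)`,
both clipped to `[0, max_points]`.

Consequences worth knowing: each sub-score is monotone in its endpoint,
continuous on the better side of the acceptable level, and the only
discontinuity is the drop to zero when a value slips below acceptable.

## DVH prediction model

The proprietary estimation engines used clinically do not publish their
regression; `kbplan` implements a transparent stand-in in the same
spirit: principal-component regression of DVH shape on anatomy.

Per OAR: training curves are resampled to the common grid, mean-centered
and decomposed by PCA keeping `k = 3` modes (three modes capture bulk
coverage, falloff steepness and tail weight of these single-knee
curves). A ridge regression (`alpha = 1e−3`) maps standardized features
— overlap fraction `f` with the high-dose envelope, `log` falloff scale
τ, `log` organ volume, `log` target volume — to the mode scores.
Zero-variance features (e.g. the spinal cord's identically-zero overlap)
are dropped with a logged warning; if nothing informative remains the
model falls back to the mean training curve. Training needs at least
`k + 1` plans.

Prediction rebuilds `mean + Σ score_i·component_i`, then projects onto a
valid DVH: clip to `[0, 1]`, pin the origin to 1, running minimum from
dose 0 (the minimal-distortion monotone projection). The estimate band
is the pointwise propagation of per-mode RMS residuals through the
basis, at `z` standard deviations (default 1); Gaussian-style residual
scales are preferred over empirical quantiles because they are stable at
small training sizes. Optimization objectives are the endpoints
evaluated on the **lower** band, pushing plans toward the best sparing
the model deems achievable.

A known limitation: near-maximum endpoints such as the spinal-cord
D_0.03cc live in the deep tail of the curve (relative volumes ~1e−4),
where a small curve-space residual translates into a dose error of
several Gy. Endpoint-specific regression would predict these tighter;
curve-space regression is kept because the whole curve is what drives
objective generation.

## Closed-loop evolution

`run_evolution` reproduces a progressive-training protocol:

1. Train C_0 on the initial database (default 25 plans).
2. Round 1 is pure closed-loop refinement: plans whose achieved endpoint
   exceeds the model's prediction by more than a margin are flagged as
   relatively suboptimal, re-optimized under the estimated DVHs, and the
   model is retrained (C_1). Nothing is added or removed.
3. Rounds 2–6 additionally admit new plans: each candidate is
   re-optimized, then a self-checking gate accepts it only if **every**
   monitored OAR endpoint is at or below the model's prediction (ties
   accepted — "superior" is unquantified, and rejecting ties stalls a
   loop whose plans have converged to optimal). Default 15 admissions
   per round, the unique uniform schedule reaching 100 plans in five
   adding rounds; the candidate stream is consumed until the quota is
   filled.

Monitored endpoints (all lower-better): cord D_0.03cc, bladder D_35%,
rectum D_60%, kidney V_18Gy, femoral-head V_35Gy per side. The
suboptimality margin has no published numeric criterion; the default is
2% of the 45 Gy pelvic prescription (0.9 Gy) for dose endpoints and 2
percentage points for volume endpoints — small, but tolerant of
prediction noise. Re-optimization in the synthetic world shrinks the
plan's excess-dose parameter geometrically (`ε ← 0.5·ε`, at most 8
iterations, stopping early when endpoint changes fall below 1e−3 in
their own units — beyond that, further shrinking cannot cross any
remaining gap). Re-optimization can only improve endpoints, so database
quality ratchets; the gate admits only prediction-beating plans.
External (non-synthetic) plans can be re-optimized by passing a planner
surrogate callable.

The per-round trace records database size, mean per-OAR endpoint
prediction error on a fixed evaluation cohort, and the database's mean
plan-quality score. The evaluation cohort uses best-effort (ε = 0)
reference plans, mirroring the clinical use of approved plans — the
product of KBP guidance plus manual polish — as the reference standard.
Note that the *cohort mean* plan quality can dip by a few hundredths of
a point when a round admits patients whose anatomy caps their attainable
score; every retained plan individually never gets worse.

## Rank-based model comparison

For one patient and OAR, competing models are ranked by ascending
absolute endpoint prediction error; M models receive M, M−1, …, 1
points, and tied errors share the average of the spanned points (the
convention that preserves the per-patient points sum M(M+1)/2 exactly).
Averaging over patients de-emphasizes individual outlier cases. Points
are scale-invariant in the errors.

## Synthetic cohort

The generator emulates the study conditions: prescriptions of 60 Gy
(PGTVnd) and 45 Gy (PCTV) in 25 fractions, seven pelvic OARs, and
planner-to-planner variability.

* Target curves are near-rectangular: full coverage to the prescription,
  linear ramp to zero at `rx·(1 + 2h)` with `h = 0.03`, giving
  HI ≈ 2h ≈ 0.06 — the magnitude seen clinically for a well-planned
  boost volume.
* An OAR's achievable curve is `V(D) = T(D)·(f + (1 − f)·e^{−D/τ})`:
  overlap fraction `f` rides the target-region curve `T`, the rest
  decays exponentially with falloff scale τ; the `T` factor caps all
  normal tissue at the hottest target dose, keeping near-maximum
  endpoints finite. Priors: bladder/rectum `f ~ 0.6·Beta(4,4)` (abutting
  the clinical target), femoral heads `0.2·Beta(2,8)`, kidneys
  `0.1·Beta(1,60)` (essentially out of field), cord `f = 0`. Falloff
  scales are log-normal with medians 8 Gy (bladder/rectum), 9 Gy
  (femoral heads), 4 Gy (kidneys), 2.5 Gy (cord) and sigma 0.15 —
  moderate inter-patient proximity variation.
* Planner skill is one parameter: the plan of skill ε dilates the
  achievable OAR dose axis by `1 + ε` (`V_planned(D) =
  V_achievable(D/(1+ε))`), leaving target coverage untouched. Skill is
  drawn half-normal with scale σ_ε = 0.08. One knob yields strictly
  ordered plan quality, which makes flag/gate/re-optimize semantics
  exact and testable.
* The body curve mixes the two target plateaus (weighted by a dose-spill
  factor 1.3 relative to target volume) with a 9 Gy-scale dose bath that
  dilates with ε, so the conformity index is computable, lands in a
  plausible 0.5–0.85 range, and degrades with poor skill. This is
  order-of-magnitude realism only.

What the synthetic world does **not** model: voxel anatomy and real
fluence optimization, correlated multi-organ trade-offs, target coverage
compromises (targets are always met), intra-structure dose heterogeneity
beyond the two-component mixture, and DICOM-RT specifics. Passing tests
therefore demonstrate the correctness and internal consistency of the
pipeline mechanics — not clinical performance on real plans.

## Experiment sizes and determinism

The default evolution experiment (initial 25, five adding rounds of 15,
35-patient evaluation cohort) runs in ~10 s; the test suite repeats it
over 20 seeds to check the refinement trend on medians, and the
noiseless parameter-recovery check trains on 100 patients and evaluates
the mean over 35 held-out patients of the maximum pointwise curve error
(< 0.01). All randomness flows through `numpy.random.default_rng`
seeds; identical seeds give bit-identical cohorts, models and traces.
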