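# Methods

This note documents the statistical model behind `pdxsig`, the defaults of
the synthetic-study generator, the numerical choices made where the design
was genuinely open, and the limitations a user should know about. It states
no empirical result that the test suite or `scripts/acceptance.py` do not
themselves compute.

## 1. Growth-response analysis

**Volume and RTV.** Caliper volume is `V = a·b²/2` with `a` the largest and
`b` the smallest diameter (`a < b` is rejected as a measurement-order error).
Relative tumor volume is per-mouse, `RTV(t) = V(t)/V(0)`, so it is invariant
to rescaling a mouse's whole series; a missing or non-positive day-0 volume
is an error, not imputed.

**TGI.** Per day with ≥ 2 mice alive in each arm,
`TGI% = 100·(1 − meanRTV_t/meanRTV_c)`; the *optimal* TGI is the maximum over
post-baseline days, ties resolved to the earliest day. The orientation
(larger = more inhibition) makes a reported "TGI of 65%" mean the treated arm
grew to 35% of the control RTV. Mice absent at a day (sacrificed at the
volume endpoint) are excluded from that day's means — no interpolation.

**Significance.** The test on individual RTVs at the optimal day is a
*two-sample* t-test: the arms are independent groups of animals, so a paired
test is not meaningful; Welch's unequal-variance form is the default with an
`equal_var=True` switch. Two degenerate arms with equal means give p = 1.
The test tracks the exhaustive permutation distribution closely at these
group sizes; the suite asserts agreement within 0.12, which is the
granularity/approximation error observed for n = 4+4 designs (the exact null
has only 70 atoms).

**RTVV and waterfall.** `RTVV = Vt/Vc − 1`, with `Vc` the *median* control
volume at the end-of-treatment day (last scheduled day observed in both
arms). A mouse already sacrificed contributes its last observed volume —
carrying forward is conservative in the right direction, since such mice
progressed. Responder iff `RTVV < −0.5`, strictly: a mouse exactly at the
threshold is a non-responder. The model-level call requires optimal
TGI > 50% *and* p ≤ 0.05.

**Relapse.** Maintenance-arm relapse times are compared by per-arm incidence,
Kaplan–Meier median time-to-relapse, and the log-rank test; times beyond the
follow-up end are censored there.

## 2. qPCR quantification

**Anchored comparative Ct.** Raw expression is
`2^(Ct_control − Ct_target)` against the combined human+mouse `Total-TBP`
control. The anchored form is

```
N = 2^(35 − Ct_target) · 2^(Ct_ref − Ct_Total-TBP)
```

where `Ct_ref` is a per-run reference control Ct, by default the cohort
median of the replicate-averaged `Total-TBP` values. The first factor pins a
target at the basal threshold (Ct = 35) to exactly 1; the second makes the
anchor robust to control shifts: a sample whose control sits above or below
the reference is corrected by exactly that difference. Applying the anchor
per cohort (not per plate) is the default; pass `ref_control_ct` explicitly
for per-plate anchoring.

**Zero rule and undetected values.** Replicates are averaged over *detected*
wells only; all-undetected stays undetected. A target whose averaged Ct
exceeds 38 (or never amplifies) scores 0 — applied after replicate
averaging. Undetected is a distinguished token (`undetected` in CSV, NaN in
memory); no 40/45-cycle sentinel ever enters arithmetic. An undetected
`Total-TBP` control invalidates the whole sample (dropped with a logged
warning).

**Mouse-cell contamination.** `raw = 2^(Ct_Total − Ct_Mm-TBP)` is scaled by
`100 / median(raw over four pure mouse reference tissues)`. Because TBP is
expressed comparably per cell in both species, the scaled value reads as the
percent of mouse cells. The estimate is invariant to a common additive shift
of both Ct inputs. Values above 100 arise from sampling noise and are
clamped with a warning; the clamp is skipped when re-scoring the reference
tissues themselves, whose scaled values straddle 100 by construction (their
median is exactly 100).

## 3. Signature selection

**Filtering.** Genes are removed when (a) their coefficient of variation
across all samples is below tolerance — in practice the never-detected,
all-zero genes — or (b) their nonzero expression is confined to a single
model, where a model effect and a response effect are confounded. Each
removal is logged with its reason.

**Transform.** `log2(N + 1)` then per-gene standardization across *all*
samples. The pseudocount of 1 maps the zero-scored targets to 0 on the log
scale and keeps the transform monotone. Standardization is computed once on
the full data; resampled subsets inherit it, so subset analyses test the
same contrasts on the same scale. A zero-variance gene after the transform
is an error (the filter should have removed it).

**Nested ANOVA.** For each gene, a two-factor ANOVA with *model* nested
within *response*:

```
F = MS_response / MS_model(response),  df = (a−1, Σ(b_i−1))
```

with `a` response levels and `b_i` models within level `i`. Testing against
the model-within-response mean square is what makes the procedure honest
about intra-model correlation: replicate tumors of one model are not
independent evidence about response. The sums of squares use the general
weighted (group-size) form, which reduces to the balanced textbook formulas
and remains a valid nested linear-model decomposition for unbalanced inputs.
Degenerate cases: all values equal → (F = 0, p = 1); zero model-within-response
variance with a nonzero response effect → p = 0. A response level containing
a single model is an error (the effect is unidentifiable), as is a model
with fewer than two samples or a model appearing in both response levels.

**Stability selection.** 30 subsets, each drawing 3 tumors per model without
replacement (preserving model proportions), drawn independently per subset
from the seeded generator and recorded for audit. A gene is selected iff its
BH-adjusted p on the full data is `< α` **and** its p is `< α` in *every*
subset. Inside subsets the *raw* p is thresholded by default: BH across ~42
genes within a 24-sample subset would make the subset criterion depend
strongly on the other genes' noise; a `subset_adjusted` switch restores
adjusted-p mode. Direction is the sign of the responder-minus-non-responder
mean on the standardized scale.

**Operating characteristics.** Under the null (no planted effects) the
selection is strongly conservative — requiring 30/30 subset significances on
top of BH makes false selections rare (the suite checks ≥ 90% empty
selections over 50 null seeds; in practice it is nearly 100%). The flip side
is a hard power ceiling at small effects: in a subset with 3 tumors per
model and 4+4 models, the t-equivalent noncentrality of the nested test is
capped at `2√6 ≈ 4.9` for a 2-SD effect *regardless of how the noise splits
between model and residual variance*, because the denominator d.f. is only
6. A single subset then passes with probability ≈ 0.97, but demanding all 30
(partially correlated) subsets drops per-gene joint recovery to ≈ 0.75, and
recovering an entire 8-gene signature simultaneously becomes a minority
event. The recovery test in the suite documents this: at 2-SD planted
effects it measures full-signature recovery in only a few of 50 seeds (with
per-gene directions always correct), while effects around 3 SD are recovered
nearly always. This is a property of the stability-selection design itself —
it trades power for reproducibility — and is left visible rather than
papered over by enlarging the planted effects.

**Clustering.** Sample distance is `1 − Spearman ρ` (average ranks on ties)
over the selected genes' standardized profiles; agglomeration is Ward
linkage applied to that distance directly — Ward formally assumes squared
Euclidean distances, and accepting the mismatch is the price of the stated
combination. The tree is cut into 2 groups and cross-tabulated against the
response labels. The heatmap export writes a TSV twin in dendrogram order
for regression testing.

## 4. IHC cohort statistics

H-score is `percent × intensity` with integral intensity 0–3 (fractional
intensities are rejected; sections scored "1 to 2" must be resolved by the
pathologist before entry). Median-rule positivity is strict (`> 30`) so that
about half the cohort is positive when 30 is the median; a `strict=False`
switch gives `≥`. Percentages are rounded half-away-from-zero, matching
hand-rounded tables. Association uses Pearson chi-square without continuity
correction; when any expected count is below 5 the 2×2 case falls back to
Fisher's exact test, while larger sparse tables keep the Pearson statistic
and are flagged (`pearson-lowcount`) — no exact r×c test is attempted.
BH adjustment is the standard step-up. Survival uses lifelines'
product-limit estimator and log-rank test; the median is the first time the
survival estimate reaches 0.5 or below, reported as missing when never
reached. Cox regression is deliberately out of scope: the package reports
KM medians and log-rank p-values only.

## 5. Synthetic-study generator

The generator is first-class, tested code; its defaults *are* the emulated
study conditions.

**Growth.** 8 models (`PDX1..PDX8`, the first 4 responders), 10 mice per
arm, measurements twice weekly (days 0–35), initial volumes uniform on
60–200 mm³, exponential growth at 0.085/day (≈ 130 → 2500 mm³ over 35 days),
multiplicative lognormal measurement noise with CV 0.15, sacrifice-censoring
above 2500 mm³. Treated-arm growth rates are scaled per model to hit target
optimal TGIs of 65/59/80/91% at day 35 (`f = 1 + ln(1−TGI/100)/(r·T)`), so
noise-free runs reproduce the targets exactly and noisy runs stay within a
few points. Diameters are emitted with fixed aspect ratio `a/b = 1.3`
(`b = (2V/1.3)^{1/3}`) — arbitrary, but exactly invertible through
`V = a·b²/2`.

**Relapse.** Exponential times at hazards `ln2/66` vs `ln2/116` per day
(medians 66 and 116 days), 11 control / 10 treated mice, censoring at the
120-day follow-up.

**Expression.** 57 candidates (49 human, 8 murine) over 5 control tumors per
model. Per-gene baselines uniform on 2–8 log2 units above basal; per-model
random effects N(0, 0.3²) and residual tumor-to-tumor noise N(0, 0.95²) on
the log2 scale, i.e. a total per-tumor SD of ≈ 1.0 log2 — the typical spread
of qPCR expression across xenograft tumors. Planted response genes (default:
the six up / two down signature genes at 2 "SD units") are shifted by
`effect × 1.0 log2` in responder models; the unit is fixed at 1 log2 — equal
to the default total noise SD — rather than recomputed from the noise dials,
so closed-form checks with noise off remain meaningful (a 3-SD plant gives
exactly a 2³ expression ratio). Fifteen genes (14 human, 1 murine) are
planted as uninformative — eight never detected, seven detected in a single
model only — so the invariance filter retains exactly 42. Mouse-cell
contamination is uniform on 5–30% per sample; murine transcripts scale with
it on the linear 2^−Ct scale, and `Hs-TBP`/`Mm-TBP` Ct values derive from the
same fraction, so contamination enters exactly as PCR physics dictates.
Ct rows are emitted in duplicate with replicate noise SD 0.15 cycles around
a `Total-TBP` control at Ct ≈ 27; "not expressed" reactions draw a Ct above
38.5. Conversion to Ct inverts the anchored formula against the generator's
own cohort-median control, which is what makes noise-free round trips exact.

**Cohort.** 134 patients in fixed subtype counts 39/31/28/36 (basal-like /
ERBB2+ / luminal A / luminal B). Intensities 0–3 with probabilities
(0.25, 0.30, 0.30, 0.15) and Beta(1.2, 2.2)-distributed staining percentages
put roughly half the cohort above the median-H-score threshold. A binary
covariate can be tied to positivity through a configurable log-odds (0 by
default, for type-I calibration), and survival is exponential (median 47
months) with a configurable log hazard ratio on positivity, censored
uniformly within the follow-up window.

**Determinism.** All streams derive from `(seed, stream-index)` seed
sequences; identical configs give byte-identical tables. The pipeline fans
one root seed out to per-stage child seeds via `SeedSequence.spawn`, so
stages are independently reproducible.

**What the generator does not emulate.** No pharmacokinetics or mechanism
(ADCC, NF-κB signaling); no growth-curve shapes beyond exponential (no
Gompertzian slowdown); gene-gene correlation is absent (genes are
conditionally independent given model and response, so the generator cannot
probe collinearity between signature genes); qPCR efficiencies are exactly 2
(no amplification-efficiency correction, which is also out of scope for the
quantifier); IHC scores are inputs, not images. Passing tests therefore
demonstrate correctness of the *computations* under the stated statistical
structure, not robustness to every artifact of real laboratory data.

## 6. Problem sizes used by the automated checks

The suite's calibration and recovery experiments use 50 generator seeds of
the default study (40 tumors × 57 genes each, 31 nested-ANOVA passes per
seed, vectorized across genes) and 500 replicates of the 134-patient cohort
for the chi-square and log-rank type-I checks; the whole suite runs in a few
minutes on one core. These sizes give Monte-Carlo standard errors around one
percentage point on the calibrated rates, which is what the stated tolerance
bands assume.
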