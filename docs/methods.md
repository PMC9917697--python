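# Methods

## The scoring model

The package quantifies how difficult a diseased mitral valve is to repair
by a **lesion complexity score**: an integer-weighted sum over
echocardiographic findings on the leaflets, annulus and sub-valvular
apparatus.  The default weights are

| component | weight |
|---|---|
| posterior segment prolapse (P1/P2/P3) | 1 each |
| anterior segment prolapse (A1/A2/A3) | 2 each |
| commissural prolapse (anterolateral/posteromedial) | 2 each |
| ruptured chordae tendineae | 1 |
| leaflet morphology normal/thickening/redundant | 0 / 1 / 3 |
| calcification of leaflet / annulus / chordae | 1 / 3 / 3 |
| commissural fusion | 2 |
| perforation or cleft count 0 / 1 / ≥2 | 0 / 1 / 2 |
| vegetation count 0 / 1 / ≥2 | 0 / 1 / 2 |
| leaflet motion normal/excessive/restricted | 0 / 1 / 2 |

The weights are a clinical convention rather than fitted quantities, so
they live in a `WeightTable` that can be overridden from YAML; the
defaults above are locked by golden tests.  Totals stratify patients into
*simple* (≤ 4), *intermediate* (5–8) and *complex* (≥ 9) valves.  A total
of 0 (no scored lesion) falls outside the published strata, which start at
1; it is mapped to *simple* with a warning rather than rejected, since a
structurally near-normal valve (e.g. annular-dilatation regurgitation) is
the easiest possible repair.

Scoring conventions that were genuinely open, and the choices made:

- **Pooled vs separate infective lesions.** One convention pools
  vegetation with perforation/cleft (1 point for a single lesion, 4 for
  more than one); the normative weight table scores them separately with
  the ≥2 class capped at 2.  The separate-category table is the default;
  the pooled rule is available via
  `WeightTable(pooled_vegetation_perforation=True)`.
- **Motion is scored once per patient.**  Restriction (2) dominates
  hypermobility (1) when both are reported, matching both the numeric
  ordering and the clinical reading that any restricted segment limits
  repairability.
- **Calcification sites are additive** across leaflet, annulus and
  chordae, and commissural fusion is an independent additive term: the
  sites co-occur freely in rheumatic disease and each independently
  complicates repair.

The **technique score** counts the principal maneuvers used to repair a
valve: annuloplasty, chordal replacement (one point per resuspended
segment), cleft closure, leaflet resection, vegetation removal and
commissurotomy, plus one point for a re-repair and one more when the
annuloplasty ring is revised during it.  The per-commissure weight of a
commissurotomy defaults to 1 (techniques are counted); a convention that
charges 2 per incised commissure exists and is available through the
`commissurotomy_weight` argument.

## Synthetic cohort generator

The anchor study population — 143 valve-surgery patients, 86 repairs and
57 replacements across six etiologies — is not publicly available, so all
cohort-level analyses run on a synthetic stand-in.  Only
stratum-conditional marginal frequencies of that population are published,
and the stratum is a deterministic function of the features, so the
generator samples in the causal direction:

1. etiology from the published mix (55/24/39/16/4/5 over 143);
2. lesion features from per-etiology Bernoulli/categorical tables
   (`data/default_config.yaml`, each value annotated with its anchor);
3. complexity score and stratum computed by the scoring engine;
4. surgical approach from a logistic model of the lesion profile;
5. for repairs, an adverse-event flag (stratum rates 0.121/0.133/0.556,
   the published unsuccessful-repair fractions 4/33, 6/45, 5/9) and a
   mechanistic draw of the repair maneuvers — chords resuspend prolapsed
   segments, clefts are closed and vegetations removed one-for-one, fused
   commissures are incised — which induces the observed positive
   technique-vs-complexity correlation without a dedicated parameter.

The per-etiology tables are the free knobs.  They were calibrated once,
by iterating large-cohort simulations, until the induced
stratum-conditional marginals reproduced the anchor patterns (P2 prolapse
dominant in degenerative disease at ~3/4; restriction, fusion and
leaflet/chordal calcification concentrated in the rheumatic/complex group;
calcification absent and scores near zero for annular-dilatation
regurgitation) with the intermediate stratum the largest.

**Outcome model.**  The log-odds of replacement are

    a + b·score + c·restriction + d·calc_leaflet + e·(perforation/cleft ≥ 1)

with defaults (−1.90, 0.06, 2.2, 1.2, 1.0).  A score-only link (c = d =
e = 0) was tried first and rejected: it makes the summed score a
sufficient statistic for the label, so a single cutoff on the true score
is already the Bayes classifier and no feature-based learner can
systematically beat it — contradicting the anchor finding that the
boosted model improves on the score cutoff by roughly twelve accuracy
points and that restricted motion dominates feature importance.  The
direct lesion terms encode exactly those reported high-risk lesions, with
their relative sizes following the reported importance ordering
(restriction ≫ leaflet calcification > perforation/cleft); all slope
coefficients are constrained non-negative, keeping the link monotone in
the score.  (a, b) were grid-searched against three anchors measured on
large simulated cohorts: score-vs-approach concordance 0.75, replacement
fraction 57/143 ≈ 0.399, and a Bayes advantage of the full lesion model
over the best score-only cutoff of about ten accuracy points.

**Randomness.**  One root seed; patient *i* uses the substream
`default_rng([seed, i])`, so cohorts are pure functions of (config, seed)
and the first *m* patients are identical whenever the seed is shared —
growing a cohort never reshuffles its prefix.

**What the generator does not emulate.**  Features are sampled
independently within etiology (only marginals are published), so
within-etiology lesion correlations are understated except where the
etiology structure itself induces them; ages and sexes are decorative
draws (they are excluded from the model as ineffective variables); there
is no time-to-event follow-up.  Passing tests therefore demonstrate that
the pipeline recovers the structure this generator encodes, not that the
published cohort-level statistics would be reproduced on the real data.

## ROC analysis

The score is an integer, so candidate cutoffs are placed at midpoints
between consecutive distinct observed scores (plus sentinels beyond the
extremes) — the only convention that produces half-integer cutoffs such
as 8.5.  A patient is called *replacement* at score ≥ cutoff; higher
scores mean less repairable valves, which fixes the ROC polarity.  The
AUC is the trapezoidal area under the resulting polygon and equals the
Mann–Whitney concordance probability with ties counted ½ (asserted
exactly, against rational-arithmetic pair counting, in the tests).  The
95% CI is a 2,000-replicate stratified percentile bootstrap (cases and
controls resampled separately, seeded); the cutoff maximizes the Youden
index J = sensitivity + specificity − 1 with ties broken toward the lower
threshold, favoring sensitivity as appropriate for a screening decision.

## Cross-validated boosted classifier

Features enter the model under a declared encoding: effective variables
(ruptured chordae 0/1; morphology 0/1/2; motion 0/1/2; vegetation and
perforation/cleft count classes 0/1/2; the three calcification indicators
and commissural fusion) followed by the eight prolapse indicators — 17
columns; sex, age and diagnosis are excluded by construction.  Folds come
from a seeded permutation cut into contiguous near-equal blocks (143 → 48,
48, 47 at seed 0); class-stratified splitting is available by flag but is
not the default, matching the simple random protocol.  Each fold is held
out once against an XGBoost classifier with 15 base learners, learning
rate 0.3, maximum depth 2 (other hyperparameters at library defaults,
recorded in the run manifest).  Reported: per-fold 2×2 confusion matrices
(rows true, columns predicted, order repair/replacement), per-fold
accuracy (TP+TN)/(TP+FN+FP+TN), their unweighted mean (the average of the
k experiments) alongside the pooled-prediction accuracy, and per-fold
feature importances using the boosting *gain* measure normalized to
percentages (weight/cover available), aggregated across folds by
superposition — elementwise sum renormalized to 100, ranked with ties
broken by declared feature order.

A baseline classifier thresholds the complexity score at the
Youden-optimal cutoff fit on each training split; comparing its fold
accuracies with the boosted model's on identical folds is how the
"boosting beats the summed score" property is tested.

## Problem sizes and numerical choices

Cohort-level tests use n = 600 (20 replicates) for model comparisons,
n = 10,000–20,000 for calibration checks and n = 50,000 for the binomial
frequency audit (4 standard errors, with a 2/n floor for zero-probability
cells).  The analysis scripts run the study-scale n = 143.  Exact
comparisons on float AUCs use 1e-12 tolerances; importance normalization
is checked to 1e-6.  Degenerate inputs fail loudly: single-class labels,
zero-variance correlations, empty cohorts, all-zero confusion matrices
and single-class training folds raise typed errors rather than returning
NaNs.

## Known limitations

- The published fold accuracies (0.833/0.833/0.766), AUC 0.75 with CI
  0.67–0.83, operating point (0.73, 0.33) and r = 0.6317 are functions of
  the unavailable raw data; the pipeline reproduces their *mechanisms*
  and uses them only as calibration anchors.
- Gain-based importance on collinear lesion blocks (restriction, fusion,
  chordal calcification all track rheumatic disease) splits credit
  arbitrarily within the block when the outcome loads on the block rather
  than a member; the direct-lesion outcome terms are what make the
  restriction ranking stable.
- A 15-tree depth-2 booster cannot represent the 17-feature additive
  score threshold exactly; deterministic single-lesion rules are
  recovered perfectly, score-threshold rules to ~0.9 accuracy.
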