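# Methods

`progsub` identifies progression subphenotypes in a mild cognitive
impairment (MCI) to Alzheimer's dementia (AD) cohort from longitudinal
EHR-style tables.  This note records the model, its assumptions, the
tunable parameters, what the synthetic cohort generator does and does not
emulate, and the numerical choices made where the design was open.

## Pipeline

1. **Cohort filters.**  Patients enter the analysis if they have an MCI
   diagnosis, are at least 50 years old at the first MCI code, have no AD
   code before MCI, have at least 365 days of record before and after the
   index (first MCI) date, and — if they convert — convert more than 183
   days after the index date.  The six-month and one-year thresholds are
   fixed constants (183 and 365 days) so the filters are deterministic.
   Excluded patients are attributed to the first failing rule in a fixed
   funnel order (no MCI, age, AD-before-MCI, look-back/follow-up,
   six-month conversion).

2. **Encounter featurization.**  Each encounter becomes a binary vector
   concatenating: uniform 5-year age bins (origin 50, nine bins, open
   top), sex and race-ethnicity one-hots, Phecode indicators for diagnoses
   and ATC level-3 indicators for medications observed in the half-open
   three-month window (t − 91 d, t], BMI categories (underweight < 18.5 ≤
   normal < 25 ≤ overweight < 30 ≤ obese; half-open bins remove the
   boundary double-assignment), the five ACC/AHA 2017 blood-pressure
   classes (more severe component wins), and smoking status
   {current, former, non-smoker, other}.  Missing vitals leave their block
   all-zero rather than being imputed, which keeps the vectors purely
   binary and the Jaccard similarity well defined.  Each vector carries
   the patient's stage on the AD continuum (preclinical < MCI < AD,
   derived from the code-defined onset dates, boundaries inclusive for the
   later stage) and the stage at the next encounter — the supervision
   target.  Stage labels are always re-derived from diagnosis codes, never
   stored, so filters and labels cannot disagree.

3. **Directed progression graph (DPG).**  Nodes are encounter vectors.
   Each node queries its k most similar nodes (Jaccard index over the full
   vector; k = 50 by default, grid 25–200) and each qualifying pair
   becomes one directed edge oriented from the earlier to the later
   encounter (same-date ties broken by (date, patient id, node id)).
   Pairs with zero similarity never link (strict floor at 0).  Consecutive
   encounters of the same patient are linked by chain edges so each
   trajectory is a directed path.  Edge weights store elapsed days.

4. **Outcome-oriented encoder.**  A two-layer directed-graph
   convolutional encoder plus a fully connected softmax head predicts the
   next-encounter stage.  The default convolution is a magnetic-Laplacian
   (MagNet-style) operator: with normalized weights w, the propagation
   matrix is D_s^{-1/2}(A_s + I)D_s^{-1/2} ⊙ exp(iΘ) with
   A_s = (A + Aᵀ)/2 and Θ = 2πq(A − Aᵀ); the charge parameter q (default
   0.25) encodes edge direction in the phase, and q = 0 reduces exactly to
   a GCN on the symmetrized graph.  Complex features are carried as
   (real, imaginary) pairs with a shared real weight matrix; the bias acts
   on the real part only, which preserves the q = 0 reduction exactly.
   GCN, GAT (4 heads) and GraphSAGE (mean aggregator) variants are
   provided.  Elapsed-time weights enter the convolution as
   w = 1/(1 + days/365) so recent transitions couple more strongly; an
   unweighted mode is available.

   **Embedding assembly.**  The generic layer h_v = φ(F_v, ⊕_u ψ(F_v,
   F_u, a_vu)) leaves φ and the nonparametric ⊕ open, and concatenation is
   one of ⊕'s admissible forms.  We exploit that freedom: the node
   embedding concatenates the learned second-layer convolution output with
   the two-hop nonparametric neighborhood aggregate of the raw input
   features (a jumping-knowledge-style skip).  The reason is empirical and
   general: softmax training on a three-class outcome concentrates the
   learned dimensions' variance on outcome geometry, which is exactly what
   the head needs but starves any *unsupervised* downstream use of the
   embeddings of the patient-level clinical structure the outcome does not
   require.  The nonparametric aggregate cannot be collapsed by training,
   so the embeddings stay simultaneously outcome-predictive (via the
   learned part) and clinically descriptive (via the aggregate).  Setting
   `skip_aggregate=False` recovers the pure convolutional embedding.

   Training is transductive (all nodes propagate; losses are restricted to
   masks), with Adam at learning rate 1e-3, up to 200 epochs, early
   stopping with patience 20 on validation loss, and parameters restored
   from the best validation epoch.  The loss is focal (γ = 2) by default;
   γ = 0 recovers cross-entropy exactly.  Splits are patient-level
   70:10:20 (floor allocation, remainders to the largest fractional
   shares), so no patient contributes nodes to two splits.  Last
   encounters have no next-stage label and are excluded from loss and
   metrics.

5. **Trajectory clustering.**  Per-patient embedding sequences
   (chronological) are clustered with time-series K-means under dynamic
   time warping.  DTW is the classical dynamic program over monotone,
   continuous, boundary-anchored warping paths summing Euclidean pointwise
   distances; no warping window is imposed by default.  Centroids are DBA
   barycenters (target length = median member length, 10 refinement
   iterations, refinement and centroid updates guarded so the summed DTW
   to members never increases); empty clusters are reseeded from the
   member farthest from its centroid; 5 restarts, 50 iterations maximum,
   all seeded.  The recorded objective trace is non-increasing by
   construction (an increase, only possible through empty-cluster repair,
   reverts the step and stops).  K is scanned over 2–10 and screened with
   the DTW silhouette (> 0.25) and DTW Davies–Bouldin index (< 1); the
   chosen K is the admissible K with the highest silhouette, ties to the
   smaller K.  This quantitative screen stands in for the qualitative
   multi-reviewer consensus used with real cohorts; the per-K summaries
   (cluster sizes, mean transition times) that such a review would consult
   are emitted alongside.  If no K is admissible the report says so and
   downstream stages fall back to the configured subphenotype count.

6. **Characterization.**  Per cluster: MCI→AD transition-time mean/sd
   (converters only), first-record→AD means, Kaplan–Meier survival over
   the 1826 days (5 years) after the first AD diagnosis (event = death,
   censoring at the horizon or last encounter) with a multi-group log-rank
   test, patient-level prevalence of the top-20 cohort features, and
   pairwise chi-square tests per feature (no Yates correction by default,
   no multiplicity adjustment by default — raw p-values with a 0.05
   filter; Benjamini–Hochberg available).  "Prevalence" is any occurrence
   in the patient's full record; a baseline-only mode exists.

7. **Subphenotype prediction.**  Baseline features aggregate each
   patient's record from the first visit up to and including the index
   date (leakage impossible by construction).  Families: logistic, lasso,
   ridge, elastic-net (saga solver) and gradient-boosted trees (XGBoost);
   optional random over/under-sampling applied to the training portion
   only; hyperparameters by 5-fold cross-validated random search over 25
   configurations (documented spaces per family); metrics macro one-vs-rest
   AUROC/sensitivity/specificity/precision on a held-out patient-level
   test set.  Attributions: exact TreeSHAP (`pred_contribs`) for trees,
   |coefficient| × feature SD for linear families.

## Synthetic cohort generator

The generator emulates the study conditions so the whole pipeline is
testable without access to clinical data.  Per patient: a subphenotype
drawn uniformly; entry age N(72, 8.9) (≈ 76 at first MCI); sex 61.7%
female; race-ethnicity 64.8/16.5/10.9/7.8% NHW/NHB/Hispanic/other;
irregular encounters with N(105, 50)-day gaps (≥ 1 day) over up to 12
years; MCI onset after a 1–3 year run-in; MCI→AD time drawn from a gamma
distribution parameterized by the subphenotype's (mean, sd) — defaults
854/577, 1236/725, 952/628, 805/563 days — truncated below at one day;
post-AD death from a constant per-day hazard (defaults 1/2400, 1/1100,
1/1300, 1/2600, giving the slower, comorbidity-heavy subphenotypes worse
five-year survival).  Stage-onset encounters carry the standard MCI/AD
ICD code sets, recurring afterwards with probability 0.8, so stage dates
are derivable from the diagnosis table alone.

Comorbidity structure is patient-level: each subphenotype has a chronic
condition prevalence profile (signature conditions at 0.90, background
at 0.05, essential hypertension ≥ 0.55 everywhere), a patient's condition
set is drawn once, and possessed conditions are coded at each encounter
with probability 0.6.  The 12-year window (rather than a hard 10) is
deliberate: it leaves the slowest planted transition distribution
effectively uncensored, so planted means are recoverable — at 10 years
the 1236-day subphenotype's recovered mean is biased low by ~8%.
Near-deterministic signatures are equally deliberate: with weaker
contrasts (e.g. 0.7 vs 0.1) the within-subphenotype condition-set
heterogeneity alone makes the planted labels unidentifiable for *any*
method, and a planted-recovery benchmark must be identifiable in
principle.

What the generator does **not** emulate: realistic code co-occurrence and
progression of comorbidity onset (conditions are present from entry),
coding intensity that varies with care setting, measurement error in
vitals, competing risks before AD, loss to follow-up other than death or
window end, and any dependence of encounter timing on health state.
Passing tests therefore demonstrate that the machinery recovers planted
structure of this kind at these sizes — not that real EHR cohorts carry
recoverable structure of the same strength.

## Numerical choices and degenerate inputs

- Jaccard of two empty supports is 0; all-zero vectors acquire no
  similarity edges.
- DTW of empty sequences is an error; single-point sequences reduce to
  the pointwise metric.
- Silhouette: singleton clusters and a = b = 0 samples contribute 0; a
  single-cluster labeling is an error (reported as NaN inside the K
  scan).  Davies–Bouldin with coincident centroids is an error (reported
  as ∞ inside the K scan).
- Chi-square tests with a zero row/column margin are skipped and flagged;
  identical prevalences short-circuit to statistic 0, p = 1.
- Training divergence (non-finite loss) raises an error naming the epoch.
- All randomness flows from explicit integer seeds; repeated runs with
  the same configuration are bit-identical, including written artifacts.

## Problem sizes

Default demonstration scale is 300 patients (≈ 10–12 thousand encounter
nodes), where the full pipeline runs in a few minutes on one CPU.
Parameter-recovery checks use 500 converters per subphenotype
(2,000 patients).  The K scan at this scale is the most expensive stage
(DTW distances dominate); the Sakoe–Chiba band option and the
`codes_only` similarity switch are the provided levers for larger
cohorts.

## Known limitations

- The DTW K-means objective is a local optimum; restarts mitigate but do
  not eliminate initialization sensitivity.
- The silhouette screen is conservative on encoder embeddings whose
  learned dimensions carry outcome variance; on the default synthetic
  cohort the admissibility thresholds are typically not met even when the
  assignments recover the planted labels well, and the pipeline then
  falls back to the configured cluster count.
- GAT and GraphSAGE variants are implemented at desk scale (full
  neighborhoods, no sampling).
- The built-in vocabulary is a small demonstration map; real deployments
  must supply full ICD→Phecode and drug→ATC-3 tables as delimited text.
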