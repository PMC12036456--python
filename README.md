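# progsub

Outcome-oriented graph framework for identifying **disease-progression
subphenotypes** from longitudinal electronic health records, built around
the mild cognitive impairment (MCI) → Alzheimer's dementia (AD) continuum.

Patients with the same diagnosis often progress along very different
pathways — some convert from MCI to AD within two years, others remain
stable for four or more, with different comorbidity burdens and post-AD
survival.  `progsub` is for biostatisticians and clinical informaticians
who want to discover such subphenotypes from routinely collected encounter
data, and to test whether membership is predictable before the index
diagnosis.  Because real progression cohorts are privacy-restricted, the
package ships a synthetic cohort simulator with planted subphenotypes so
the entire pipeline is testable end to end with no data access.

## Method

1. **Featurization.**  Every encounter t of patient n becomes a binary
   vector x̂ₜⁿ: one-hot age bins / sex / race, Phecode and ATC level-3
   indicators over a 3-month look-back, and discretized vitals (BMI
   categories, ACC/AHA blood-pressure classes, smoking status).

2. **Directed progression graph.**  Nodes are encounter vectors; each
   node links to its top-k neighbors by Jaccard similarity
   S(F_v, F_u) = |F_v ∩ F_u| / |F_v ∪ F_u|, with edges oriented by
   chronology, plus same-patient chain edges; weights are elapsed days.

3. **Outcome-oriented encoder.**  A two-layer directed-graph
   convolutional encoder (magnetic Laplacian
   L = I − D_s^{−1/2}(A_s+I)D_s^{−1/2} ⊙ exp(i·2πq(A−Aᵀ)); GCN / GAT /
   GraphSAGE variants) plus a softmax head y = θ(W h_u + b) is trained
   with cross-entropy or focal loss to predict the *next* encounter's
   stage (preclinical | MCI | AD).  Node embeddings h_v concatenate the
   learned convolution output with a nonparametric neighborhood aggregate
   of the input features, so they stay clinically descriptive as well as
   outcome-predictive.

4. **Trajectory clustering.**  Per-patient embedding sequences
   H_Tⁿ = (h₁ … h_T) are clustered by time-series K-means under dynamic
   time warping, minimizing J = Σᵢ Σ_{j∈Cᵢ} DTW(H⁽ʲ⁾, μᵢ) with DBA
   centroids; K = 2…10 is screened by the DTW silhouette (> 0.25) and
   Davies–Bouldin index (< 1).

5. **Characterization & prediction.**  Per-cluster MCI→AD transition
   statistics, 5-year post-AD Kaplan–Meier survival with log-rank
   comparison, prevalence and pairwise chi-square feature profiling, and
   pre-index subphenotype prediction (linear models / XGBoost, optional
   resampling, cross-validated search, TreeSHAP attributions).

See `docs/methods.md` for assumptions, parameter defaults and numerical
conventions.

## Worked example

```python
import numpy as np
from sklearn.metrics import adjusted_rand_score
from progsub import (CohortSpec, EncoderConfig, GraphConfig,
                     apply_inclusion_criteria, build_dpg,
                     build_encounter_vectors, build_feature_space,
                     collect_sequences, simulate_cohort, train_encoder,
                     tskmeans)

cohort, funnel = apply_inclusion_criteria(
    simulate_cohort(CohortSpec(n_patients=80, seed=11)))
space = build_feature_space()
vectors = [v for t in cohort if len(t.encounters) >= 2
           for v in build_encounter_vectors(t, space)]
graph = build_dpg(vectors, GraphConfig(k=25))
params, report, emb = train_encoder(graph, EncoderConfig(epochs=120, seed=0))
print(report["macro"])

sequences = collect_sequences(emb, graph)
result = tskmeans(sequences, 4, seed=0)
truth = {t.patient_id: t.true_subphenotype for t in cohort}
print("ARI:", adjusted_rand_score(
    [truth[s.patient_id] for s in sequences], result.assignments))
```

Output (fixed seeds):

```
{'auroc': 0.912, 'sensitivity': 0.750, 'specificity': 0.887, 'precision': 0.782}
ARI: 0.96
```

The macro AUROC of 0.91 says the encoder predicts the stage of the next
encounter well on held-out patients; the adjusted Rand index of 0.96 says
the DTW clustering of the embedding sequences essentially recovers the
four planted subphenotypes.  On the same cohort the per-subphenotype
MCI→AD means recovered by `transition_stats` (845 / 1266 / 1008 / 862
days against planted 854 / 1236 / 952 / 805) and the post-AD survival
contrast (log-rank p ≈ 4e-06) come out as in
`examples/05_characterize_and_predict.py`.

The `examples/` directory holds one short narrative script per stage
(simulation and filters, graph construction, encoder training, trajectory
clustering, characterization and prediction).  A thin CLI mirrors the
pipeline (`progsub run`, or stage by stage `simulate`, `filter`,
`featurize`, `build-graph`, `train`, `embed`, `select-k`, `cluster`,
`characterize`, `predict`, `report`):

```bash
progsub run --workdir demo --n-patients 300 --seed 1
progsub report --workdir demo
```

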