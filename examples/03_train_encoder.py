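"""Train the magnetic-Laplacian encoder to predict the next-encounter stage.

The three outcome classes are the AD continuum stages (preclinical, MCI,
AD) of each node's chronologically next encounter.  Metrics are computed
on held-out patients (patient-level 70:10:20 split).
"""

from progsub import (
    CohortSpec, EncoderConfig, GraphConfig, apply_inclusion_criteria,
    build_dpg, build_encounter_vectors, build_feature_space, simulate_cohort,
    train_encoder,
)

cohort, _ = apply_inclusion_criteria(simulate_cohort(CohortSpec(n_patients=80, seed=11)))
space = build_feature_space()
vectors = []
for t in cohort:
    if len(t.encounters) >= 2:
        vectors.extend(build_encounter_vectors(t, space))
graph = build_dpg(vectors, GraphConfig(k=25))

config = EncoderConfig(variant="magnet", embedding_size=32, loss="focal",
                       epochs=120, seed=0)
params, report, embeddings = train_encoder(graph, config)

print(f"graph: {graph.n_nodes} nodes; embeddings: {embeddings.shape}")
print(f"best epoch {report['best_epoch']}, "
      f"train loss {report['initial_train_loss']:.3f} -> {report['final_train_loss']:.3f}")
print("held-out test metrics (macro over the three stages):")
for m, v in report["macro"].items():
    print(f"  {m:12s} {v:.3f}")
# Macro AUROC near 1 means the encoder separates upcoming preclinical/MCI/AD
# encounters; the embedding also retains the nonparametric neighborhood
# aggregate, so comorbidity structure survives for clustering.
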