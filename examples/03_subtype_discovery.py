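"""Discover survival risk groups from the bottleneck features.

Each latent feature is screened by a univariable Cox proportional-hazards
score test (p < 0.05); survivors are clustered by K-means with the number
of clusters chosen over k=2..6 by Silhouette and Calinski-Harabasz; groups
are renamed so G1 has the better Kaplan-Meier survival.
"""

from sklearn.metrics import adjusted_rand_score

import omisurv as om

cfg = om.SyntheticConfig(n_samples=300, hazard_ratio=3.0, effect_size=1.0, seed=5)
blocks, clinical, truth = om.generate_cohort(cfg)
clean = {k: om.preprocess_block(b) for k, b in blocks.items()}
stacked = om.stack_unit_norm([clean["rna"], clean["mirna"], clean["methylation"]])
model = om.train(stacked, om.AutoencoderConfig(seed=5))
latent = om.transform(model, stacked)

labels, screen, k = om.discover_subtypes(latent, clinical, seed=5)
print(f"Cox screen kept {screen.n_selected}/{latent.shape[1]} latent features at p<0.05")
print(f"chosen number of clusters: k={k}")
sizes = labels.labels.value_counts().to_dict()
print(f"group sizes: {sizes}; higher-risk group: {labels.higher_risk}")

report = om.evaluate_labels(clinical, labels)
ari = adjusted_rand_score(truth.true_group.to_numpy(), labels.labels.to_numpy())
print(f"log-rank p = {report.logrank_p:.2e}, C-index = {report.c_index:.3f}, "
      f"Brier = {report.brier:.3f} (t* = {report.brier_horizon:.2f} y)")
print(f"adjusted Rand index vs planted groups: {ari:.3f}")
# ARI near 1 means the pipeline recovered the planted two-group structure;
# the log-rank p quantifies the survival separation between G1 and G2.
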