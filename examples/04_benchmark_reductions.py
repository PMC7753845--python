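"""Benchmark the autoencoder against PCA, NMF and the univariable Cox baseline.

Every method produces a feature matrix that runs through the same path:
Cox screen -> cluster-number selection -> K-means -> survival evaluation.
t-SNE (exact solver) is also supported but slow at high component counts;
this example uses a reduced component count to keep runtimes short.
"""

import omisurv as om

cfg = om.SyntheticConfig(
    n_samples=150,
    n_features={"rna": 200, "mirna": 40, "methylation": 200},
    n_informative={"rna": 30, "mirna": 8, "methylation": 30},
    hazard_ratio=3.0,
    seed=9,
)
blocks, clinical, _ = om.generate_cohort(cfg)
clean = {k: om.preprocess_block(b) for k, b in blocks.items()}
stacked = om.stack_unit_norm([clean["rna"], clean["mirna"], clean["methylation"]])
model = om.train(stacked, om.AutoencoderConfig(hidden_widths=(100, 40, 200), seed=9))
latent = om.transform(model, stacked)

table = om.run_benchmark(
    stacked, clean, clinical,
    methods=["autoencoder", "pca", "nmf", "coxph"],
    latent_autoencoder=latent,
    n_components=40,
    seed=9,
)
cols = ["n_selected", "k", "logrank_p", "c_index", "brier"]
print(table[cols].to_string(float_format=lambda v: f"{v:.3g}"))
# Each row is one reduction method; logrank_p measures how well its feature
# space separates the survival groups after the shared clustering path.
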