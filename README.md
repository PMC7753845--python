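# omisurv

Autoencoder-based multi-omics integration for survival subtyping.

`omisurv` implements a complete pipeline for discovering prognostic patient
subgroups from paired tumour omics profiles — RNA expression, miRNA
expression and promoter DNA methylation — together with overall-survival
follow-up, and for transferring the discovered risk groups to held-out and
external cohorts. It is aimed at computational biologists who want a tested,
scriptable implementation of this class of deep-learning survival-subtyping
workflow, with a synthetic cohort generator providing ground truth for every
stage.

## The method

1. **Preprocessing.** Features missing in more than 50% of samples are
   removed, then samples missing more than 20% of the remaining features;
   the rest is filled by feature-wise k-nearest-neighbour imputation
   (k = 10). Methylation probes are averaged per promoter to a gene-level
   beta value. Count blocks are log1p variance-stabilized, each sample row
   is scaled to unit Euclidean norm within its block, the blocks are stacked
   column-wise, and each stacked feature is min–max rescaled to [0, 1].

2. **Feature transformation.** A fully connected autoencoder
   *d* → 550 → 275 → 1100 → *d* with tanh hidden activations and a logistic
   output is trained for 10 epochs of minibatch SGD with 50% dropout on the
   penalized cross-entropy objective

   L(x, x′) = −Σₖ [xₖ log x′ₖ + (1−xₖ) log(1−x′ₖ)]
            + Σᵢ α_w‖Wᵢ‖₁ + α_a‖F₁→ₖ(x)‖₂²,

   where F₁→ₖ(x) is the bottleneck activation. The 275 bottleneck features
   are the transformed representation.

3. **Subtype discovery.** Each bottleneck feature enters a univariable Cox
   proportional-hazards model; features with score-test p < 0.05 survive.
   K-means clusters the survivors, with k chosen over 2..6 by the Silhouette
   index and the Calinski–Harabasz criterion. Groups are renamed so G1 has
   the better Kaplan–Meier survival. Separation is quantified by the
   log-rank test, Harrell's C-index and the IPCW Brier score.

4. **Label transfer.** Samples are split into 5 folds; all C(5,3) = 10
   combinations of 3 training / 2 test folds are evaluated. Per training
   set, features are ranked per omic by one-way ANOVA F against the risk
   groups (top 40 RNA / 30 methylation / 30 miRNA) and a soft-margin SVM is
   grid-searched by inner 5-fold accuracy. External cohorts are harmonized
   by common-gene restriction, median centering and IQR scaling before
   classification.

5. **Comparators and downstream analysis.** PCA, NMF and exact-gradient
   t-SNE at the same number of components, plus a univariable Cox baseline
   (top 13 raw features by C-index), share the screen/cluster/evaluate path.
   A Pearson screen (r < −0.5, p < 1e−4) flags genes whose promoter
   methylation anticorrelates with expression, and a miRNA–target network is
   assembled by intersecting two score-filtered target lists with the
   differential-gene set.

## Worked example

```python
import omisurv as om
from sklearn.metrics import adjusted_rand_score

cfg = om.SyntheticConfig(n_samples=300, hazard_ratio=3.0, effect_size=1.0, seed=5)
blocks, clinical, truth = om.generate_cohort(cfg)
clean = {k: om.preprocess_block(b) for k, b in blocks.items()}
stacked = om.stack_unit_norm([clean["rna"], clean["mirna"], clean["methylation"]])
latent = om.transform(om.train(stacked, om.AutoencoderConfig(seed=5)), stacked)
labels, screen, k = om.discover_subtypes(latent, clinical, seed=5)
report = om.evaluate_labels(clinical, labels)
```

Running this (it is `examples/03_subtype_discovery.py`) prints:

```
Cox screen kept 177/275 latent features at p<0.05
chosen number of clusters: k=2
group sizes: {'G1': 150, 'G2': 150}; higher-risk group: G2
log-rank p = 1.40e-12, C-index = 0.620, Brier = 0.373 (t* = 1.20 y)
adjusted Rand index vs planted groups: 1.000
```

The generator planted two equal groups whose hazards differ threefold; the
pipeline recovers them exactly (ARI = 1.0) and the recovered groups separate
survival decisively (log-rank p ≈ 1e−12). The C-index of 0.62 reflects that
a binary group indicator can order only between-group pairs; the Brier score
is evaluated at the cohort's median follow-up.

The other scripts in `examples/` demonstrate simulation and preprocessing,
autoencoder training, the reduction benchmark, external-cohort label
transfer, and the integration analyses. A thin CLI mirrors the stages:

```bash
omisurv simulate --outdir cohort --seed 7
omisurv preprocess --rna cohort/rna.tsv --mirna cohort/mirna.tsv \
    --meth cohort/methylation.tsv --outdir work
omisurv train --stacked work/stacked.tsv --out work/model.pkl
omisurv transform --model work/model.pkl --stacked work/stacked.tsv --out work/latent.tsv
omisurv subtype --latent work/latent.tsv --clinical cohort/clinical.tsv --out work/labels.tsv
omisurv evaluate --labels work/labels.tsv --clinical cohort/clinical.tsv --out work/report.json
```

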