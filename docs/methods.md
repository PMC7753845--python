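# Methods

This note records the models, parameter choices and numerical conventions
behind `omisurv`, in the order the pipeline runs them, together with the
design decisions that were genuinely open and the limitations a user should
know about.

## Synthetic cohort model

The generator is the package's source of ground truth: a cohort in which a
single latent binary group drives both the omics profiles and survival, so
every downstream stage can be scored against a known answer.

**Groups.** Of `n_samples`, a fraction `group_proportion` (default 0.5) is
assigned to group 2; assignment order is shuffled by the seeded RNG.

**Count blocks (RNA, miRNA).** Each feature has a baseline mean drawn
log-normally — log10(mean) ~ Normal(3, 1) for RNA, Normal(2.5, 1) for miRNA,
floored at 1 — giving the several-decade abundance spread of real
sequencing data. Counts are negative-binomial via a gamma–Poisson mixture
with dispersion r = 10 (variance = mu + mu²/r, a mid-range overdispersion
for bulk data). The first `n_informative` features of each block are
informative: their group-2 mean is multiplied by exp(±effect_size), the sign
alternating so both up- and down-regulation are present. `effect_size` is a
natural-log fold change; the default 1.0 (~2.7-fold) is a strong but not
extreme transcriptomic effect.

**Methylation block.** Feature-wise baseline beta means are uniform on
[0.2, 0.8]; values are Beta-distributed with concentration a + b = 30
(typical array-level noise). Informative features shift the group-2 mean by
±effect_size/10 on the beta scale (0.1 at the default effect size, matching
the conventional "delta-beta > 0.1" notion of a meaningful methylation
difference), clipped so means stay in [0.02, 0.98].

**Survival.** Event times are exponential with hazard
lambda = baseline_hazard × hazard_ratio^(group−1): the simplest law
satisfying the proportional-hazards assumption the downstream screen makes.
Censoring is an independent exponential whose rate is solved by Brent's
method so the marginal censored fraction equals `censoring_rate` (the
mixture identity P(censored) = sum over groups of pi_g · c/(lambda_g + c)).
Observed time is the minimum; the event flag indicates death. With
`censoring_rate = 0` no censoring occurs.

**Missingness** is missing-completely-at-random at rate `missing_rate`,
applied per block with seeds spawned from the global seed. All randomness
flows through `numpy.random.SeedSequence` spawning, so cohorts are bitwise
reproducible.

**What the generator does not emulate:** batch effects, platform-specific
probe behavior, library-size variation, correlated co-expression modules
beyond the single group factor, informative censoring, and non-proportional
hazards. Passing tests therefore show the pipeline recovers a clean shared
two-group signal — not that it is robust to the full messiness of real
tumour cohorts.

## Preprocessing

Filtering order is fixed: features missing in > 50% of samples are removed
first, then samples missing > 20% of the *remaining* features (the sample
pass sees the feature-reduced matrix). Imputation is k-nearest-neighbour
over features (neighbours ranked by Euclidean distance across co-observed
samples, plain mean of k = 10 neighbours), delegated to
`sklearn.impute.KNNImputer` on the transposed matrix. Promoter-level
methylation is the arithmetic mean of a gene's probes per sample; the
probe→gene map is supplied by the user, so the promoter definition is not
baked in. All-zero features are dropped.

Stacking applies, in order: log1p to count blocks (see below), per-sample
unit-norm scaling within each block, column-wise concatenation, and a
per-feature min–max rescale to [0, 1]. Two of these steps deserve comment:

- **log1p on count blocks (default on, toggleable).** Without variance
  stabilization, the handful of highest-abundance features dominate every
  sample's norm denominator, and their sampling noise imprints a shared
  "pseudo-library-size" factor on all other features. In roughly one in
  five synthetic cohorts that artifact carried more variance than the
  planted group structure and K-means clustered on it instead. log1p is
  what any practitioner applies to counts before a Euclidean-geometry
  method; it removes the artifact at its source.
- **min–max rescale to [0, 1].** The cross-entropy reconstruction objective
  requires targets in [0, 1]; unit-norm rows alone do not guarantee that.
  Disable with `minmax_rescale=False` if a different objective is used.

All-zero sample rows are retained as zero vectors (logged) rather than
dropped: deterministic behavior for degenerate input. Constant stacked
features map to 0.

## Autoencoder

Architecture d → 550 → 275 → 1100 → d. The widths are the one arrangement
using all three published layer sizes with 275 as the narrowest layer, and
are configurable. Hidden layers use tanh; the output layer is logistic so
reconstructions lie in (0, 1) as the cross-entropy requires. The objective
per sample is

    L = −Σₖ [xₖ log x′ₖ + (1−xₖ) log(1−xₖ′)] + Σᵢ α_w‖Wᵢ‖₁ + α_a‖h_bottleneck‖₂²

minimized by minibatch SGD (batch 16) for 10 epochs with inverted dropout
(rate 0.5) on the three hidden layers; dropout is off at inference.
Reconstructions are clipped to [1e−7, 1−1e−7] inside the logarithms.
Penalties default to α_w = 1e−4, α_a = 1e−5 (no published values exist;
these keep the penalty terms one to two orders below the data term at the
default scale). Weights are Glorot-uniform initialized, seeded.

Numerical conventions that mattered:

- **Per-feature gradient scale.** The objective sums over d features, so raw
  gradients grow linearly with input width and no single learning rate works
  across widths. SGD therefore steps on the per-feature mean loss
  (gradient/d) — the same convention as the major deep-learning frameworks'
  mean-reduction losses. The default `learning_rate = 5.0` on that scale was
  calibrated on a rank-2 reconstruction task and then frozen.
- **Output-bias initialization** at logit of the per-feature mean: the first
  epochs otherwise go entirely to learning the marginals, and with only 10
  epochs nothing else gets learned.
- The training-loss trace records the dropout-mode batch loss per epoch;
  inference-mode loss is lower.
- Dropout applies to hidden layers only, not the input (one reading of an
  ambiguous protocol; exposed in config).
- With both penalties zero the objective is exactly the negated
  cross-entropy, and the analytic backprop matches central finite
  differences to < 1e−5 relative error (tested).

Because the entropy of a continuous target in (0, 1) is nonzero, the loss
has an irreducible floor (the entropy of x itself); training progress should
be judged against that floor, not against zero.

## Cox screening and clustering

The per-feature selection p-value is the partial-likelihood **score test at
beta = 0** with the Efron correction for tied event times — the continuous-
covariate generalization of the log-rank test, computed vectorized over all
features. For a binary ties-free covariate it reproduces the classical
log-rank chi-square exactly (tested to 1e−6). Per-feature hazard
coefficients and standard errors come from `lifelines.CoxPHFitter`
(`fit_coefficients=False` skips them when only selection is needed).
Zero-variance features are excluded and logged. Selection uses raw
p < alpha = 0.05; no multiplicity correction, matching the protocol this
package implements (an FDR-minded user can apply one to the returned table).

K-means (scikit-learn, 20 seeded restarts, best inertia) runs for k = 2..6;
the mean Silhouette and the Calinski–Harabasz index are recorded per k and
the Silhouette's argmax wins when the two disagree (a fixed, logged
arbitration; the indices usually agree on separable data). Groups are
renamed G1..Gk by decreasing Kaplan–Meier median survival, ties broken by
the area under the KM curve, so G1 is always the better-survival group and
the recorded orientation makes "risk score = indicator of the higher-risk
group" well defined.

## Survival metrics

Kaplan–Meier estimation and the two-group log-rank test are lifelines'.
Harrell's C wraps lifelines' concordance with the risk-score convention
(higher score = earlier death); a pair is comparable iff the shorter
observed time is an event, tied scores count 1/2. The Brier score at
horizon t* is inverse-probability-of-censoring weighted: events before t*
weighted by 1/G(T−), subjects at risk at t* by 1/G(t*), censored-before-t*
subjects excluded, with G the Kaplan–Meier estimate of the censoring
distribution. With no censoring this reduces exactly to the mean squared
error of the binary outcome (tested, and cross-checked against
scikit-survival on censored data). The default horizon is the cohort's
median follow-up time — the only defensible data-driven default, since no
published horizon exists; Brier values are therefore comparable only at a
common horizon.

## Classification and harmonization

Folds are near-equal random partitions; all C(5,3) = 10 train/test
combinations are enumerated (each sample lands in 4 test and 6 training
sets). ANOVA F is computed vectorized (between-group over within-group mean
square); count blocks are log1p-transformed first (toggleable). Features
with zero within-group variance but a between-group difference get F = +inf
and rank first (logged). Ranks are unique, ties broken by feature ID.

The SVM is a scikit-learn pipeline (standardize on training statistics →
SVC), grid-searched over linear and RBF kernels with C in {0.01, 0.1, 1,
10, 100} and gamma in {1e−3..10} by stratified inner 5-fold accuracy; the
grid is fixed for reproducibility since no published grid exists. ANOVA
selection runs inside each training split, never on the full cohort, to
avoid leakage — a stricter protocol than a single global selection.

"Median scale normalization and robust scale normalization" are interpreted
as per-feature median centering followed by interquartile-range scaling,
applied within each dataset independently after restriction to common
features — the standard robust cross-platform recipe consistent with those
names. Zero-IQR features are divided by 1 and logged. The transform is
invariant to per-feature affine shifts of the external cohort (tested).

## Comparators

PCA uses the full SVD with a fixed sign convention (largest-|loading| entry
of each component positive), NMF uses NNDSVD-A initialization with
coordinate descent, and t-SNE uses the exact-gradient solver, which is the
only one valid above 3 output dimensions; at 275 components it is slow, so
tests and examples use reduced dimensionality. The univariable Cox baseline
standardizes each raw feature, fits a univariable Cox model, scores the
fitted linear predictor by in-sample C-index, and keeps the top 13. The
benchmark runner records per-method failures as rows rather than aborting.
No superiority ordering among methods is asserted on synthetic data: which
method wins there is data-dependent and is not the claim this package tests.

## Integration analyses

Pearson r between promoter methylation and expression per gene, two-sided p
from the exact t transform with n−2 degrees of freedom; a gene passes at
r < −0.5 and p < 1e−4 (both thresholds configurable; the stricter of the
two published variants is the default). Zero-variance vectors yield a
flagged record, not an error. The miRNA–target network keeps, per
differential miRNA, the genes present in both score-filtered target lists
and in the differential-gene set; the result is invariant to row order and
duplicates, and empty inputs give an empty network. Differential expression
itself is out of scope: the module consumes externally produced
differential lists as inputs.

## Pipeline orchestration

`run_full_pipeline` derives every stage's RNG from one global seed by
stage-keyed `SeedSequence` spawning, persists every intermediate (TSV/JSON
plus the pickled model), and aggregates log-rank p across the 10 CV
combinations by geometric mean. Reruns of the same config are
byte-identical. A stage failure aborts with the stage name after persisting
partial outputs.

## Problem sizes used in tests and the acceptance script

Recovery and transfer checks run at n = 300 and n = 200 samples with
500/100/500 and 200/40/200 features per block respectively; null
calibrations use 200 replicate cohorts (n = 100) and 200 null features
(n = 300); metric oracles enumerate n ≤ 30. These sizes give the Monte-Carlo
checks ~1.5-percentage-point standard errors while keeping a full run in
minutes on one CPU.

## Known limitations

- Ten epochs of SGD is a very short training budget; the bottleneck
  representation retains dominant data directions rather than a deeply
  compressed code, and results inherit K-means' sensitivity to nuisance
  variance directions if variance stabilization is disabled.
- The score-test screen assumes proportional hazards per feature; the
  generator satisfies this by construction, real data need not.
- Group-label risk scores make the C-index and Brier score coarse (binary
  predictor); they are reported for comparability, not as calibrated
  predictions.
- t-SNE at hundreds of output dimensions is of questionable geometric
  meaning and is supported for protocol fidelity, not recommended.
- The Brier scores of different cohorts/horizons are not comparable; the
  package always reports the horizon alongside the score.
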