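"""Label transfer: ANOVA feature ranking, SVM classifier, CV scheme,
and cross-cohort harmonization.

The cross-validation scheme splits samples into five near-equal folds and
enumerates all C(5,3) = 10 ways of using three folds for training and the
remaining two for testing.  Within each training set, features are ranked
per omic block by the one-way ANOVA F statistic against the risk-group
labels (defaults: top 40 RNA, 30 methylation, 30 miRNA) and a soft-margin
SVM is grid-searched (linear and RBF kernels) by inner 5-fold accuracy.
External cohorts are harmonized to the reference by restriction to common
features followed by per-feature median centering and interquartile-range
scaling within each dataset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .containers import OmicsMatrix, RiskLabels

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = {"rna": 40, "methylation": 30, "mirna": 30}

DEFAULT_SVM_GRID = [
    {"svc__kernel": ["linear"], "svc__C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    {"svc__kernel": ["rbf"], "svc__C": [0.01, 0.1, 1.0, 10.0, 100.0],
     "svc__gamma": [1e-3, 1e-2, 1e-1, 1.0, 10.0]},
]


@dataclass
class CvPartition:
    """Fold assignment plus the enumerated train/test fold combinations."""

    fold: pd.Series                       # sample -> fold id in 1..n_folds
    combinations: list[tuple[tuple[int, ...], tuple[int, ...]]]

    @property
    def n_folds(self) -> int:
        return int(self.fold.max())

    def split(self, combo_index: int) -> tuple[pd.Index, pd.Index]:
        """Sample IDs of the (train, test) sets for one combination."""
        train_folds, test_folds = self.combinations[combo_index]
        train = self.fold.index[self.fold.isin(train_folds)]
        test = self.fold.index[self.fold.isin(test_folds)]
        return train, test


def make_cv_partitions(
    sample_ids, n_folds: int = 5, train_folds: int = 3, seed: int = 0
) -> CvPartition:
    """Random near-equal folds and all C(n_folds, train_folds) combinations."""
    ids = pd.Index(sample_ids)
    if train_folds >= n_folds:
        raise ValueError(f"train_folds ({train_folds}) must be < n_folds ({n_folds})")
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} samples, have {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    fold = np.empty(len(ids), dtype=int)
    for f, chunk in enumerate(np.array_split(perm, n_folds), start=1):
        fold[chunk] = f
    combos = [
        (train, tuple(sorted(set(range(1, n_folds + 1)) - set(train))))
        for train in combinations(range(1, n_folds + 1), train_folds)
    ]
    return CvPartition(fold=pd.Series(fold, index=ids), combinations=combos)


@dataclass
class FeatureRanking:
    """Per-feature one-way ANOVA F statistics with a top-N cut."""

    table: pd.DataFrame       # index: feature; columns: F, rank
    top_n: int

    @property
    def top_features(self) -> list[str]:
        return list(self.table.index[self.table["rank"] <= self.top_n])


def anova_f(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Vectorized one-way ANOVA F per column: between-group MS / within-group MS.

    Zero within-group variance with a between-group difference yields +inf.
    """
    values = np.asarray(values, dtype=float)
    labels = np.unique(groups)
    n = values.shape[0]
    grand = values.mean(axis=0)
    ssb = np.zeros(values.shape[1])
    ssw = np.zeros(values.shape[1])
    for g in labels:
        sub = values[groups == g]
        m = sub.mean(axis=0)
        ssb += len(sub) * (m - grand) ** 2
        ssw += ((sub - m) ** 2).sum(axis=0)
    df_b = len(labels) - 1
    df_w = n - len(labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df_b) / (ssw / df_w)
    F = np.where(ssw == 0, np.where(ssb > 0, np.inf, 0.0), F)
    return F


def anova_rank(
    block: pd.DataFrame | OmicsMatrix,
    labels: RiskLabels,
    top_n: int,
    log_transform: bool = False,
) -> FeatureRanking:
    """Rank features by descending ANOVA F against the group labels.

    ``log_transform=True`` applies log1p first (recommended for raw counts).
    Ranks are unique; ties break by feature ID.
    """
    values = block.values if isinstance(block, OmicsMatrix) else block
    common = values.index.intersection(labels.labels.index)
    values = values.loc[common]
    groups = labels.labels.loc[common].to_numpy()
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("ANOVA needs >= 2 groups with >= 2 samples each")
    arr = values.to_numpy(dtype=float)
    if log_transform:
        arr = np.log1p(arr)
    F = anova_f(arr, groups)
    n_inf = int(np.isinf(F).sum())
    if n_inf:
        logger.info("anova_rank: %d features with zero within-group variance ranked first", n_inf)
    # sort by descending F, then feature ID, for deterministic unique ranks
    sort_key = -np.nan_to_num(F, posinf=np.finfo(float).max)
    order = np.lexsort((values.columns.to_numpy().astype(str), sort_key))
    table = pd.DataFrame({"F": F}, index=values.columns).iloc[order]
    table["rank"] = np.arange(1, len(table) + 1)
    if top_n > len(table):
        logger.warning("anova_rank: top_n=%d exceeds %d features; returning all", top_n, len(table))
        top_n = len(table)
    return FeatureRanking(table=table, top_n=top_n)


@dataclass
class LabelClassifier:
    """Fitted SVM label-transfer model with its feature list and scaler."""

    pipeline: Pipeline
    features: list[str]
    risk_order: list[str]
    best_params: dict = field(default_factory=dict)
    cv_accuracy: float = float("nan")

    def classes(self) -> list[str]:
        return list(self.pipeline.named_steps["svc"].classes_)


def fit_label_classifier(
    features: pd.DataFrame,
    labels: RiskLabels,
    grid: list[dict] | None = None,
    inner_cv: int = 5,
    seed: int = 0,
) -> LabelClassifier:
    """Grid-search a soft-margin SVM (linear + RBF) by inner k-fold accuracy.

    Features are standardized on training statistics inside the pipeline;
    the best configuration is refit on all training data.
    """
    common = features.index.intersection(labels.labels.index)
    X = features.loc[common]
    y = labels.labels.loc[common].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    cv = min(inner_cv, int(counts.min()))
    if cv < inner_cv:
        logger.warning("fit_label_classifier: reducing inner CV folds to %d", cv)
    if cv < 2:
        raise ValueError(f"need >= 2 samples per class for inner CV, have {counts.min()}")
    pipe = Pipeline([("scaler", StandardScaler()), ("svc", SVC())])
    search = GridSearchCV(
        pipe,
        grid or DEFAULT_SVM_GRID,
        scoring="accuracy",
        cv=StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    search.fit(X.to_numpy(dtype=float), y)
    logger.info("fit_label_classifier: best %s (inner-CV accuracy %.3f)",
                search.best_params_, search.best_score_)
    return LabelClassifier(
        pipeline=search.best_estimator_,
        features=list(X.columns),
        risk_order=list(labels.risk_order),
        best_params=dict(search.best_params_),
        cv_accuracy=float(search.best_score_),
    )


def predict_labels(model: LabelClassifier, features: pd.DataFrame) -> RiskLabels:
    """Apply the trained scaler + decision rule; carries the risk orientation."""
    missing = [f for f in model.features if f not in features.columns]
    if missing:
        raise ValueError(f"input is missing model features: {missing}")
    X = features[model.features].to_numpy(dtype=float)
    pred = model.pipeline.predict(X)
    labels = pd.Series(pred, index=features.index)
    present = set(labels.unique())
    order = [g for g in model.risk_order if g in present]
    return RiskLabels(labels=labels, risk_order=order)


def harmonize_external(
    reference: pd.DataFrame, external: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict to common features, then median-center and IQR-scale each
    dataset independently (robust cross-platform normalization).

    Zero-IQR features are divided by 1 (logged).
    """
    common = reference.columns.intersection(external.columns)
    if len(common) < 2:
        raise ValueError(
            f"need >= 2 common features between cohorts, found {len(common)}"
        )
    logger.info("harmonize_external: %d common features", len(common))

    def robust(df: pd.DataFrame) -> pd.DataFrame:
        arr = df.to_numpy(dtype=float)
        med = np.median(arr, axis=0)
        q75, q25 = np.percentile(arr, [75, 25], axis=0)
        iqr = q75 - q25
        flat = iqr == 0
        if flat.any():
            logger.info("harmonize_external: %d zero-IQR features left unscaled", int(flat.sum()))
        iqr[flat] = 1.0
        return pd.DataFrame((arr - med) / iqr, index=df.index, columns=df.columns)

    return robust(reference[common]), robust(external[common])
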