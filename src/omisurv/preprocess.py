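"""Cleaning, imputation, promoter averaging, scaling and stacking.

The cleaning protocol drops features observed in too few samples first, then
samples missing too many of the *remaining* features; missing entries are
filled by feature-wise k-nearest-neighbour imputation; methylation probes
are averaged per promoter; all-zero features are removed; finally each block
is unit-norm scaled per sample, the blocks are concatenated column-wise, and
every stacked feature is min-max rescaled to [0, 1] so that a cross-entropy
reconstruction objective is well defined downstream.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .containers import OmicsMatrix, StackedMatrix

logger = logging.getLogger(__name__)


def clean_matrix(
    block: OmicsMatrix,
    max_feature_missing: float = 0.5,
    max_sample_missing: float = 0.2,
) -> OmicsMatrix:
    """Drop features missing in > ``max_feature_missing`` of samples, then
    samples missing > ``max_sample_missing`` of the remaining features.

    The two passes run in that fixed order; the second pass computes its
    missing fractions on the feature-reduced matrix.
    """
    for name, thr in (("max_feature_missing", max_feature_missing),
                      ("max_sample_missing", max_sample_missing)):
        if not (0.0 < thr <= 1.0):
            raise ValueError(f"{name} must lie in (0, 1], got {thr}")
    vals = block.values
    feat_missing = vals.isna().mean(axis=0)
    keep_features = feat_missing.index[feat_missing <= max_feature_missing]
    dropped_f = vals.shape[1] - len(keep_features)
    if len(keep_features) == 0:
        raise ValueError(
            f"{block.omic}: all {vals.shape[1]} features exceeded the "
            f"{max_feature_missing:.0%} missingness threshold (feature filter stage)"
        )
    reduced = vals[keep_features]
    sample_missing = reduced.isna().mean(axis=1)
    keep_samples = sample_missing.index[sample_missing <= max_sample_missing]
    dropped_s = reduced.shape[0] - len(keep_samples)
    if len(keep_samples) == 0:
        raise ValueError(
            f"{block.omic}: all samples exceeded the {max_sample_missing:.0%} "
            "missingness threshold (sample filter stage)"
        )
    if dropped_f or dropped_s:
        logger.info(
            "clean_matrix[%s]: dropped %d features and %d samples",
            block.omic, dropped_f, dropped_s,
        )
    return OmicsMatrix(reduced.loc[keep_samples], block.omic)


def impute_knn(block: OmicsMatrix, k: int = 10) -> OmicsMatrix:
    """Fill missing entries from the ``k`` nearest features.

    Neighbours are features (not samples), ranked by Euclidean distance over
    co-observed samples; a missing entry becomes the plain mean of its
    neighbours' values in that sample.  Features with no observed co-neighbour
    for some entry fall back to the feature mean.
    """
    if block.is_complete():
        return OmicsMatrix(block.values.copy(), block.omic)
    n_features = block.n_features
    if n_features < k + 1:
        raise ValueError(
            f"need at least k+1={k + 1} features for k-NN imputation, have {n_features}"
        )
    # rows of the transposed matrix are features, so neighbours are features
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    arr = imputer.fit_transform(block.values.to_numpy().T).T
    if arr.shape != block.values.shape:  # KNNImputer drops all-NaN rows
        raise ValueError("imputation failed: a feature has no observed values; run clean_matrix first")
    out = pd.DataFrame(arr, index=block.sample_ids, columns=block.feature_ids)
    if block.omic == "methylation":
        out = out.clip(0.0, 1.0)
    n_filled = int(block.values.isna().to_numpy().sum())
    logger.info("impute_knn[%s]: filled %d entries with k=%d", block.omic, n_filled, k)
    return OmicsMatrix(out, block.omic)


def average_promoter_beta(
    probe_matrix: OmicsMatrix, probe_to_gene: Mapping[str, str]
) -> OmicsMatrix:
    """Collapse methylation probes to genes: per sample, the mean beta over
    the probes mapping to each gene.  Probes absent from the map are dropped
    and counted in the log."""
    if not probe_to_gene:
        raise ValueError("probe-to-gene map is empty")
    vals = probe_matrix.values
    mapped = [p for p in vals.columns if p in probe_to_gene]
    unmapped = vals.shape[1] - len(mapped)
    if not mapped:
        raise ValueError("no probe in the matrix maps to a gene")
    if unmapped:
        logger.info("average_promoter_beta: dropped %d unmapped probes", unmapped)
    genes = pd.Series({p: probe_to_gene[p] for p in mapped})
    collapsed = vals[mapped].T.groupby(genes).mean().T
    collapsed.columns.name = None
    return OmicsMatrix(collapsed, probe_matrix.omic)


def drop_uninformative(block: OmicsMatrix) -> OmicsMatrix:
    """Remove features that are zero in every sample."""
    if not block.is_complete():
        raise ValueError("drop_uninformative expects a complete matrix; impute first")
    vals = block.values
    all_zero = (vals == 0).all(axis=0)
    if all_zero.all():
        raise ValueError(f"{block.omic}: every feature is all-zero")
    n_dropped = int(all_zero.sum())
    if n_dropped:
        logger.info("drop_uninformative[%s]: removed %d all-zero features", block.omic, n_dropped)
    return OmicsMatrix(vals.loc[:, ~all_zero], block.omic)


def unit_norm_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Rescale each sample row to unit Euclidean norm; all-zero rows stay zero."""
    arr = values.to_numpy(dtype=float)
    norms = np.linalg.norm(arr, axis=1)
    zero = norms == 0
    if zero.any():
        logger.warning("unit_norm_rows: %d all-zero sample rows left as zeros", int(zero.sum()))
    norms[zero] = 1.0
    return pd.DataFrame(arr / norms[:, None], index=values.index, columns=values.columns)


def stack_unit_norm(
    blocks: Sequence[OmicsMatrix],
    minmax_rescale: bool = True,
    log1p_counts: bool = True,
) -> StackedMatrix:
    """Unit-norm scale each block per sample, concatenate column-wise, then
    min-max rescale every stacked feature to [0, 1].

    Sample IDs are intersected across blocks (logged when samples are lost).
    With ``log1p_counts`` (default), count blocks (rna, mirna) are log1p
    variance-stabilized before the unit-norm step; without it, a handful of
    very high-abundance features dominate every sample's norm denominator
    and imprint a spurious shared factor on all other features.  The min-max
    step puts reconstruction targets in [0, 1] for the cross-entropy
    objective; pass ``minmax_rescale=False`` to disable it.
    """
    if not blocks:
        raise ValueError("no blocks to stack")
    common = blocks[0].sample_ids
    for b in blocks[1:]:
        common = common.intersection(b.sample_ids)
    if len(common) == 0:
        raise ValueError("sample intersection across blocks is empty")
    lost = max(b.n_samples for b in blocks) - len(common)
    if lost:
        logger.info("stack_unit_norm: intersection kept %d samples", len(common))

    scaled = []
    origin = {}
    for b in blocks:
        if not b.is_complete():
            raise ValueError(f"{b.omic} block has missing values; impute before stacking")
        vals = b.values.loc[common]
        if log1p_counts and b.omic in ("rna", "mirna"):
            if (vals.to_numpy() < 0).any():
                raise ValueError(f"{b.omic} block has negative values; disable log1p_counts")
            vals = np.log1p(vals)
        part = unit_norm_rows(vals)
        part.columns = [f"{b.omic}:{c}" for c in part.columns]
        for c in part.columns:
            origin[c] = b.omic
        scaled.append(part)
    stacked = pd.concat(scaled, axis=1)

    if minmax_rescale:
        arr = stacked.to_numpy()
        lo = arr.min(axis=0)
        hi = arr.max(axis=0)
        span = hi - lo
        constant = span == 0
        if constant.any():
            logger.info("stack_unit_norm: %d constant features mapped to 0", int(constant.sum()))
        span[constant] = 1.0
        arr = (arr - lo) / span
        arr[:, constant] = 0.0
        stacked = pd.DataFrame(arr, index=stacked.index, columns=stacked.columns)

    return StackedMatrix(values=stacked, block_of_origin=pd.Series(origin).loc[stacked.columns])


def preprocess_block(
    block: OmicsMatrix,
    probe_to_gene: Mapping[str, str] | None = None,
    max_feature_missing: float = 0.5,
    max_sample_missing: float = 0.2,
    knn_k: int = 10,
) -> OmicsMatrix:
    """Run the per-block protocol: clean -> impute -> (promoter average) -> drop."""
    out = clean_matrix(block, max_feature_missing, max_sample_missing)
    if not out.is_complete():
        out = impute_knn(out, k=knn_k)
    if probe_to_gene is not None and block.omic == "methylation":
        out = average_promoter_beta(out, probe_to_gene)
    return drop_uninformative(out)
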