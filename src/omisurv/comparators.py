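"""Baseline dimensionality reductions sharing the screen/cluster/evaluate path.

Four baselines are benchmarked against the autoencoder: PCA, NMF and t-SNE
at the same number of components (275 by default), and a univariable
Cox-PH baseline that ranks every raw feature across the three omics blocks
by the C-index of its fitted linear predictor and keeps the top 13.  Each
feature set then runs through the same Cox screen -> choose k -> K-means ->
evaluation path as the autoencoder features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from sklearn.decomposition import NMF, PCA
from sklearn.manifold import TSNE

from .containers import ClinicalTable, EvalReport, OmicsMatrix, StackedMatrix
from .metrics import concordance_index, evaluate_labels
from .subtype import assign_risk_groups, choose_k, cox_screen

logger = logging.getLogger(__name__)


@dataclass
class ReductionSpec:
    """One reduction method and its settings."""

    method: str                      # pca | nmf | tsne | autoencoder
    n_components: int = 275
    seed: int = 0
    nmf_max_iter: int = 500
    tsne_perplexity: float = 30.0
    tsne_n_iter: int = 500

    def __post_init__(self) -> None:
        if self.method not in ("pca", "nmf", "tsne", "autoencoder"):
            raise ValueError(f"unknown reduction method {self.method!r}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


def reduce(stacked: StackedMatrix, spec: ReductionSpec) -> pd.DataFrame:
    """Samples x n_components matrix for pca / nmf / tsne.

    PCA scores are computed on centered data with a fixed sign convention
    (the loading of largest magnitude in each component is positive).  NMF
    requires non-negative input (guaranteed by the [0, 1] stacking rescale).
    t-SNE uses the exact-gradient solver, required for output dimensions
    above 3.
    """
    X = stacked.values.to_numpy(dtype=float)
    n, d = X.shape
    if spec.method in ("pca", "nmf") and spec.n_components > min(n, d):
        raise ValueError(
            f"n_components={spec.n_components} exceeds min(n_samples, n_features)={min(n, d)}"
        )
    if spec.method == "pca":
        pca = PCA(n_components=spec.n_components, svd_solver="full")
        scores = pca.fit_transform(X)
        # sign convention: largest-|loading| entry of each component positive
        flip = np.sign(
            pca.components_[np.arange(pca.components_.shape[0]),
                            np.abs(pca.components_).argmax(axis=1)]
        )
        flip[flip == 0] = 1.0
        scores = scores * flip[None, :]
        cols = [f"PC{j + 1}" for j in range(scores.shape[1])]
    elif spec.method == "nmf":
        if np.any(X < 0):
            raise ValueError("NMF requires non-negative input")
        nmf = NMF(
            n_components=spec.n_components,
            init="nndsvda",
            random_state=spec.seed,
            max_iter=spec.nmf_max_iter,
        )
        scores = nmf.fit_transform(X)
        cols = [f"NMF{j + 1}" for j in range(scores.shape[1])]
    elif spec.method == "tsne":
        perplexity = min(spec.tsne_perplexity, (n - 1) / 3.0)
        tsne = TSNE(
            n_components=spec.n_components,
            method="exact",
            init="random",
            random_state=spec.seed,
            perplexity=perplexity,
            max_iter=spec.tsne_n_iter,
        )
        scores = tsne.fit_transform(X)
        cols = [f"TSNE{j + 1}" for j in range(scores.shape[1])]
    else:
        raise ValueError("use omisurv.autoencoder.transform for the autoencoder")
    return pd.DataFrame(scores, index=stacked.sample_ids, columns=cols)


def cox_baseline_features(
    blocks: dict[str, OmicsMatrix],
    clinical: ClinicalTable,
    top_k: int = 13,
) -> pd.DataFrame:
    """Top raw features by the C-index of their univariable Cox fit.

    Every feature in every block gets a univariable Cox-PH fit; features are
    ranked by the in-sample C-index of the fitted linear predictor and the
    ``top_k`` columns are returned (prefixed by block).  Degenerate or
    non-converging features are skipped and logged.
    """
    if clinical.n_events < 2:
        raise ValueError("need at least 2 events")
    frames = []
    for name, block in blocks.items():
        if not block.is_complete():
            raise ValueError(f"{name} block has missing values")
        vals = block.values.loc[clinical.sample_ids]
        vals.columns = [f"{name}:{c}" for c in vals.columns]
        frames.append(vals)
    allfeat = pd.concat(frames, axis=1)
    t = clinical.time.to_numpy()
    e = clinical.event.to_numpy()
    df_base = pd.DataFrame({"os_time": t, "os_event": e})
    scores = {}
    skipped = 0
    for feat in allfeat.columns:
        x = allfeat[feat].to_numpy(dtype=float)
        if x.std() == 0:
            skipped += 1
            continue
        df = df_base.copy()
        df["x"] = (x - x.mean()) / x.std()
        cph = CoxPHFitter()
        try:
            cph.fit(df, duration_col="os_time", event_col="os_event")
        except Exception:
            skipped += 1
            continue
        risk = df["x"].to_numpy() * float(cph.params_["x"])
        scores[feat] = concordance_index(risk, clinical)
    if skipped:
        logger.info("cox_baseline_features: skipped %d degenerate/non-converging features", skipped)
    if not scores:
        raise ValueError("no feature could be fit")
    ranked = sorted(scores, key=lambda f: (-scores[f], f))
    top = ranked[: min(top_k, len(ranked))]
    return allfeat[top]


@dataclass
class BenchmarkRow:
    method: str
    n_selected: int
    k: int
    report: EvalReport | None
    error: str | None = None


def run_benchmark(
    stacked: StackedMatrix,
    blocks: dict[str, OmicsMatrix],
    clinical: ClinicalTable,
    methods: list[str],
    latent_autoencoder: pd.DataFrame | None = None,
    n_components: int = 275,
    alpha: float = 0.05,
    top_k: int = 13,
    seed: int = 0,
) -> pd.DataFrame:
    """Run each method through screen -> choose_k -> cluster -> evaluate.

    ``latent_autoencoder`` supplies the pre-computed bottleneck features when
    ``"autoencoder"`` is among the methods.  A failing method becomes a row
    with its error message rather than aborting the benchmark.
    """
    rows: list[BenchmarkRow] = []
    for method in methods:
        try:
            if method == "autoencoder":
                if latent_autoencoder is None:
                    raise ValueError("autoencoder latent features not supplied")
                feats = latent_autoencoder
            elif method == "coxph":
                feats = cox_baseline_features(blocks, clinical, top_k=top_k)
            else:
                feats = reduce(stacked, ReductionSpec(method=method, n_components=n_components, seed=seed))
            if method == "coxph":
                selected, n_sel = feats, feats.shape[1]
            else:
                screen = cox_screen(feats, clinical, alpha=alpha, fit_coefficients=False)
                sel = screen.selected_features
                if not sel:
                    raise ValueError("Cox screen selected no features")
                selected, n_sel = feats[sel], len(sel)
            k, _ = choose_k(selected, seed=seed)
            labels = assign_risk_groups(selected, clinical, k=k, seed=seed)
            if labels.n_groups != 2:
                # metrics below are two-group; re-cluster at k=2 for the report
                labels = assign_risk_groups(selected, clinical, k=2, seed=seed)
                k = 2
            report = evaluate_labels(clinical, labels)
            rows.append(BenchmarkRow(method, n_sel, k, report))
        except Exception as err:
            logger.warning("run_benchmark: method %s failed: %s", method, err)
            rows.append(BenchmarkRow(method, 0, 0, None, error=str(err)))

    records = []
    for r in rows:
        rec = {"method": r.method, "n_selected": r.n_selected, "k": r.k, "error": r.error}
        if r.report is not None:
            rec.update(r.report.to_dict())
        records.append(rec)
    return pd.DataFrame(records).set_index("method")
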