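"""Cox screening of latent features and K-means survival subtyping.

Each latent feature is screened with a univariable Cox proportional-hazards
model; the selection p-value is the partial-likelihood score test evaluated
at beta = 0 (the generalization of the log-rank test to a continuous
covariate), with the Efron correction for tied event times.  Coefficients
and standard errors come from the fitted Cox model (lifelines).  Selected
features are clustered with K-means; the number of clusters is chosen over
k = 2..6 by the mean Silhouette index and the Calinski-Harabasz criterion,
and the resulting groups are renamed so that G1 has the better
Kaplan-Meier survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score, silhouette_score

from .containers import ClinicalTable, RiskLabels
from .metrics import km_area, km_median_survival

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    """Per-feature univariable Cox screen output.

    ``table`` has one row per screened feature with columns ``coef``, ``se``,
    ``p`` (score test) and ``selected``; degenerate (zero-variance) features
    are listed in ``excluded``.
    """

    table: pd.DataFrame
    alpha: float
    excluded: list[str]

    @property
    def selected_features(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])

    @property
    def n_selected(self) -> int:
        return int(self.table["selected"].sum())

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature")


def cox_score_test(
    X: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized partial-likelihood score test at beta=0, Efron ties.

    Parameters: ``X`` (n x p covariates), ``time``, ``event``.  Returns
    (chi-square statistics, p-values), one per column.  For a binary
    covariate without tied event times the statistic equals the classical
    log-rank chi-square.
    """
    X = np.asarray(X, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    Xs, ts, es = X[order], time[order], event[order]

    # suffix sums: risk set at time t = samples with time >= t
    S0 = np.arange(n, 0, -1.0)                        # |risk set| at each sorted position
    S1 = np.cumsum(Xs[::-1], axis=0)[::-1]            # sum of x over risk set
    S2 = np.cumsum(Xs[::-1] ** 2, axis=0)[::-1]       # sum of x^2 over risk set

    U = np.zeros(p)
    V = np.zeros(p)
    i = 0
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        deaths = np.nonzero(es[i:j])[0] + i
        d = len(deaths)
        if d:
            s0, s1, s2 = S0[i], S1[i], S2[i]
            d0 = float(d)
            d1 = Xs[deaths].sum(axis=0)
            d2 = (Xs[deaths] ** 2).sum(axis=0)
            U += d1
            for ell in range(d):
                f = ell / d0
                e0 = s0 - f * d0
                e1 = s1 - f * d1
                e2 = s2 - f * d2
                U -= e1 / e0
                V += e2 / e0 - (e1 / e0) ** 2
        i = j

    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(V > 0, U**2 / V, 0.0)
    pvals = stats.chi2.sf(chi2, df=1)
    pvals = np.where(V > 0, pvals, 1.0)
    return chi2, pvals


def cox_screen(
    latent: pd.DataFrame,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    fit_coefficients: bool = True,
) -> ScreenResult:
    """Univariable Cox-PH screen: keep features with score-test p < alpha.

    ``latent`` is samples x features, aligned to the clinical table by
    sample ID.  Zero-variance features are excluded (logged).  With
    ``fit_coefficients=False`` only the score-test p-values are computed
    (coef/se reported as NaN), which is much faster for large screens.
    """
    common = clinical.sample_ids.intersection(latent.index)
    if len(common) == 0:
        raise ValueError("no common samples between latent matrix and clinical table")
    latent = latent.loc[common]
    clin = clinical.subset(common)
    if clin.n_events < 2:
        raise ValueError("need at least 2 events for the Cox screen")
    arr = latent.to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("latent features must be finite")

    variances = arr.var(axis=0)
    degenerate = variances == 0
    excluded = list(latent.columns[degenerate])
    if excluded:
        logger.info("cox_screen: excluded %d zero-variance features", len(excluded))
    keep = latent.columns[~degenerate]
    Xk = arr[:, ~degenerate]

    t = clin.time.to_numpy()
    e = clin.event.to_numpy()
    chi2, pvals = cox_score_test(Xk, t, e)

    coefs = np.full(len(keep), np.nan)
    ses = np.full(len(keep), np.nan)
    if fit_coefficients:
        df_base = pd.DataFrame({"os_time": t, "os_event": e})
        for idx, feat in enumerate(keep):
            df = df_base.copy()
            df["x"] = Xk[:, idx]
            cph = CoxPHFitter()
            try:
                cph.fit(df, duration_col="os_time", event_col="os_event")
                coefs[idx] = cph.params_["x"]
                ses[idx] = cph.standard_errors_["x"]
            except Exception as err:  # convergence failure on a pathological feature
                logger.warning("cox_screen: fit failed for %s (%s)", feat, err)

    table = pd.DataFrame(
        {"coef": coefs, "se": ses, "chi2": chi2, "p": pvals, "selected": pvals < alpha},
        index=pd.Index(keep, name="feature"),
    )
    if table["selected"].sum() == 0:
        logger.warning("cox_screen: no feature passed p < %g", alpha)
    return ScreenResult(table=table, alpha=alpha, excluded=excluded)


def choose_k(
    features: pd.DataFrame,
    k_range: range = range(2, 7),
    seed: int = 0,
    n_restarts: int = 20,
) -> tuple[int, pd.DataFrame]:
    """Pick the number of clusters by Silhouette and Calinski-Harabasz.

    K-means is run for each k in ``k_range`` with ``n_restarts`` seeded
    restarts; the returned k maximizes both indices, with the Silhouette
    winning when they disagree (logged).  Also returns the per-k index table.
    """
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    if n < max(k_range) + 1:
        logger.warning("choose_k: only %d samples; large k values will be skipped", n)
    if np.allclose(X, X[0]):
        raise ValueError("all samples identical: clustering is degenerate")
    rows = []
    for k in k_range:
        if n <= k:
            logger.info("choose_k: skipping k=%d (only %d samples)", k, n)
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(X)
        if len(np.unique(lab)) < 2:
            continue
        rows.append(
            {"k": k,
             "silhouette": silhouette_score(X, lab),
             "calinski_harabasz": calinski_harabasz_score(X, lab)}
        )
    if not rows:
        raise ValueError("no k in the range could be evaluated")
    table = pd.DataFrame(rows).set_index("k")
    k_sil = int(table["silhouette"].idxmax())
    k_ch = int(table["calinski_harabasz"].idxmax())
    if k_sil != k_ch:
        logger.info("choose_k: Silhouette picks k=%d, Calinski-Harabasz k=%d; "
                    "using Silhouette", k_sil, k_ch)
    return k_sil, table


def assign_risk_groups(
    features: pd.DataFrame,
    clinical: ClinicalTable,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
    max_retries: int = 5,
) -> RiskLabels:
    """K-means cluster the selected features and orient groups by survival.

    Groups are renamed G1..Gk in order of decreasing Kaplan-Meier median
    survival (ties broken by the area under the KM curve), so G1 is always
    the better-survival group and the last group the higher-risk one.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    common = clinical.sample_ids.intersection(features.index)
    feats = features.loc[common]
    clin = clinical.subset(common)
    X = feats.to_numpy(dtype=float)

    lab = None
    for attempt in range(max_retries):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed + attempt)
        candidate = km.fit_predict(X)
        if len(np.unique(candidate)) == k:
            lab = candidate
            break
        logger.warning("assign_risk_groups: empty cluster, retrying with a new seed")
    if lab is None:
        raise RuntimeError(f"K-means produced an empty cluster in {max_retries} attempts")

    raw = pd.Series(lab, index=feats.index)
    # order clusters by survival: better (longer median, then larger KM area) first
    keys = {}
    for c in np.unique(lab):
        sub = clin.subset(raw.index[raw == c])
        med = km_median_survival(sub)
        keys[c] = (med if np.isfinite(med) else np.inf, km_area(sub))
    ordered = sorted(keys, key=lambda c: keys[c], reverse=True)
    rename = {c: f"G{i + 1}" for i, c in enumerate(ordered)}
    labels = raw.map(rename)
    risk_order = [f"G{i + 1}" for i in range(k)]
    return RiskLabels(labels=labels, risk_order=risk_order)


def discover_subtypes(
    latent: pd.DataFrame,
    clinical: ClinicalTable,
    alpha: float = 0.05,
    k_range: range = range(2, 7),
    seed: int = 0,
) -> tuple[RiskLabels, ScreenResult, int]:
    """Screen -> choose k -> assign risk groups, returning all three results."""
    screen = cox_screen(latent, clinical, alpha=alpha)
    sel = screen.selected_features
    if not sel:
        raise ValueError("Cox screen selected no features; clustering refused")
    selected = latent[sel]
    k, _ = choose_k(selected, k_range=k_range, seed=seed)
    labels = assign_risk_groups(selected, clinical, k=k, seed=seed)
    return labels, screen, k
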