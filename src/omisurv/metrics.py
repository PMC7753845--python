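"""Survival evaluation: Kaplan-Meier, log-rank, Harrell's C, IPCW Brier score.

Kaplan-Meier estimation and the two-group log-rank test are delegated to
lifelines; Harrell's concordance index wraps lifelines' implementation with
the risk-score convention (higher score = higher risk = shorter expected
survival).  The Brier score at a horizon t* is the inverse-probability-of-
censoring-weighted mean squared error between the predicted event
probability and the event indicator 1{T <= t*, event}, with weights from the
Kaplan-Meier estimate of the censoring distribution G: an observed event
before t* is weighted by 1/G(T-), a subject still under observation at t* by
1/G(t*); subjects censored before t* contribute nothing.  Without censoring
this reduces exactly to the mean squared error of the binary outcome.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import concordance_index as _ll_cindex

from .containers import ClinicalTable, EvalReport, RiskLabels

logger = logging.getLogger(__name__)


def kaplan_meier(
    clinical: ClinicalTable, labels: RiskLabels | None = None
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate, overall or per group.

    Returns a dict mapping group tag (``"all"`` when no labels are given) to
    a DataFrame of step coordinates with columns ``time`` and ``survival``
    (right-continuous, starting at S(0)=1).
    """
    out: dict[str, pd.DataFrame] = {}
    if labels is None:
        members = {"all": clinical.sample_ids}
    else:
        aligned = labels.labels.loc[clinical.sample_ids]
        members = {g: aligned.index[aligned == g] for g in sorted(aligned.unique())}
    for g, ids in members.items():
        if len(ids) == 0:
            logger.warning("kaplan_meier: group %s is empty, skipped", g)
            continue
        sub = clinical.subset(ids)
        kmf = KaplanMeierFitter()
        kmf.fit(sub.time, event_observed=sub.event)
        sf = kmf.survival_function_
        out[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return out


def km_median_survival(clinical: ClinicalTable) -> float:
    """Kaplan-Meier median survival time (inf if S never reaches 0.5)."""
    kmf = KaplanMeierFitter()
    kmf.fit(clinical.time, event_observed=clinical.event)
    return float(kmf.median_survival_time_)


def km_area(clinical: ClinicalTable) -> float:
    """Area under the KM curve up to the last observed time (restricted mean)."""
    kmf = KaplanMeierFitter()
    kmf.fit(clinical.time, event_observed=clinical.event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    # right-continuous step function: integrate S over [0, t_max]
    widths = np.diff(times)
    return float(np.sum(surv[:-1] * widths))


def logrank_test(clinical: ClinicalTable, labels: RiskLabels) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic with 1 df, p-value)."""
    groups = labels.groups
    if len(groups) != 2:
        raise ValueError(f"log-rank test needs exactly two groups, got {len(groups)}")
    lab = labels.labels.loc[clinical.sample_ids]
    ids_a = lab.index[lab == groups[0]]
    ids_b = lab.index[lab == groups[1]]
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError("each group must contain at least one subject")
    a, b = clinical.subset(ids_a), clinical.subset(ids_b)
    res = _ll_logrank(a.time, b.time, event_observed_A=a.event, event_observed_B=b.event)
    return float(res.test_statistic), float(res.p_value)


def concordance_index(
    risk_score: pd.Series | np.ndarray, clinical: ClinicalTable
) -> float:
    """Harrell's C for a per-sample risk score (higher = earlier death).

    C = (concordant pairs + 0.5 * tied-score pairs) / comparable pairs,
    where a pair is comparable iff the shorter observed time ends in an
    event.  Tied event times between two deaths are not comparable.
    """
    if isinstance(risk_score, pd.Series):
        scores = risk_score.loc[clinical.sample_ids].to_numpy(dtype=float)
    else:
        scores = np.asarray(risk_score, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("risk scores must be finite")
    # lifelines expects higher score <-> longer survival, so negate the risk
    try:
        return float(_ll_cindex(clinical.time, -scores, clinical.event))
    except ZeroDivisionError:
        raise ValueError("concordance undefined: no comparable pairs") from None


def censoring_survival(clinical: ClinicalTable) -> KaplanMeierFitter:
    """KM estimate of the censoring distribution G (events and censorings swapped)."""
    kmf = KaplanMeierFitter()
    kmf.fit(clinical.time, event_observed=1 - clinical.event)
    return kmf


def brier_score(
    event_probability: pd.Series | np.ndarray,
    clinical: ClinicalTable,
    horizon: float | None = None,
) -> tuple[float, float]:
    """IPCW Brier score at ``horizon`` t*; returns (score, horizon used).

    ``event_probability`` is the predicted probability of death by t* per
    sample.  When ``horizon`` is None the median follow-up time of the
    cohort is used.  Subjects censored before t* are excluded; the rest are
    weighted by the inverse censoring-survival probability (1/G(T-) for
    events, 1/G(t*) for those still at risk at t*).
    """
    if isinstance(event_probability, pd.Series):
        p = event_probability.loc[clinical.sample_ids].to_numpy(dtype=float)
    else:
        p = np.asarray(event_probability, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("event probabilities must lie in [0, 1]")
    if horizon is None:
        horizon = float(np.median(clinical.time))
    if horizon <= 0:
        raise ValueError(f"Brier horizon must be > 0, got {horizon}")

    t = clinical.time.to_numpy(dtype=float)
    e = clinical.event.to_numpy(dtype=int)
    G = censoring_survival(clinical)

    def g_at(times: np.ndarray) -> np.ndarray:
        return G.survival_function_at_times(times).to_numpy(dtype=float)

    died_by = (t <= horizon) & (e == 1)
    at_risk = t > horizon
    usable = died_by | at_risk
    excluded = int((~usable).sum())
    if excluded:
        logger.info("brier_score: %d subjects censored before t*=%g excluded", excluded, horizon)

    w = np.zeros_like(p)
    # G(T-): left limit of the censoring survival just before the event time
    g_event = g_at(np.maximum(t[died_by] - 1e-12, 0.0))
    g_hor = g_at(np.array([horizon]))[0]
    bad = 0
    with np.errstate(divide="ignore"):
        w[died_by] = np.where(g_event > 0, 1.0 / g_event, 0.0)
        bad += int((g_event == 0).sum())
        if at_risk.any():
            if g_hor > 0:
                w[at_risk] = 1.0 / g_hor
            else:
                bad += int(at_risk.sum())
    if bad:
        logger.warning("brier_score: %d subjects dropped (zero censoring weight)", bad)
    outcome = died_by.astype(float)
    score = float(np.sum(w * (outcome - p) ** 2) / len(t))
    return score, float(horizon)


def evaluate_labels(
    clinical: ClinicalTable,
    labels: RiskLabels,
    brier_horizon: float | None = None,
) -> EvalReport:
    """Full evaluation of a two-group risk labeling: log-rank, C, Brier.

    The risk score fed to the C-index and the Brier event probability is the
    indicator of the higher-risk group per the recorded orientation.
    """
    stat, p = logrank_test(clinical, labels)
    score = labels.risk_score().loc[clinical.sample_ids]
    if score.max() > score.min():
        score = (score - score.min()) / (score.max() - score.min())
    c = concordance_index(score, clinical)
    b, horizon = brier_score(score, clinical, brier_horizon)
    return EvalReport(
        logrank_stat=stat,
        logrank_p=p,
        c_index=c,
        brier=min(b, 1.0),
        brier_horizon=horizon,
        n_samples=len(clinical.sample_ids),
        n_events=clinical.n_events,
    )
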