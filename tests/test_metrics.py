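"""Survival metrics against hand-computed and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

import omisurv as om
from omisurv.containers import ClinicalTable, RiskLabels
from omisurv.metrics import brier_score, concordance_index, kaplan_meier, logrank_test

from conftest import random_censored_clinical


def _clin(times, events):
    return ClinicalTable(
        pd.DataFrame(
            {"os_time": times, "os_event": events},
            index=pd.Index([f"s{i}" for i in range(len(times))], name="sample_id"),
        )
    )


def brute_force_cindex(scores, times, events):
    """Independent pairwise enumeration of Harrell's C."""
    conc = ties = comp = 0
    n = len(times)
    for i in range(n):
        for j in range(i + 1, n):
            if times[i] == times[j]:
                continue
            first, second = (i, j) if times[i] < times[j] else (j, i)
            if not events[first]:
                continue
            comp += 1
            if scores[first] > scores[second]:
                conc += 1
            elif scores[first] == scores[second]:
                ties += 1
    return (conc + 0.5 * ties) / comp if comp else np.nan


class TestKaplanMeier:
    def test_no_censoring_empirical(self):
        km = kaplan_meier(_clin([1.0, 2.0], [1, 1]))["all"]
        s = km.set_index("time")["survival"]
        assert s.loc[1.0] == pytest.approx(0.5)
        assert s.loc[2.0] == pytest.approx(0.0)

    def test_all_censored_flat(self):
        km = kaplan_meier(_clin([1.0, 2.0, 3.0], [0, 0, 0]))["all"]
        assert (km["survival"] == 1.0).all()

    def test_hand_product_limit(self):
        # death at 1, censor at 2, death at 3: S(1)=2/3, S(3)=0
        km = kaplan_meier(_clin([1.0, 2.0, 3.0], [1, 0, 1]))["all"]
        s = km.set_index("time")["survival"]
        assert s.loc[1.0] == pytest.approx(2 / 3)
        assert s.loc[3.0] == pytest.approx(0.0)

    def test_never_increases(self):
        rng = np.random.default_rng(0)
        clin = random_censored_clinical(rng, 50)
        km = kaplan_meier(clin)["all"]
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_per_group_curves(self, tiny_clinical):
        labels = RiskLabels(
            pd.Series(["G1", "G1", "G1", "G2", "G2", "G2"], index=tiny_clinical.sample_ids),
            risk_order=["G1", "G2"],
        )
        curves = kaplan_meier(tiny_clinical, labels)
        assert set(curves) == {"G1", "G2"}


class TestLogrank:
    def test_two_subject_hand_value(self):
        clin = _clin([1.0, 2.0], [1, 1])
        labels = RiskLabels(pd.Series(["A", "B"], index=clin.sample_ids), ["A", "B"])
        stat, p = logrank_test(clin, labels)
        assert stat == pytest.approx(1.0, abs=1e-9)
        assert p == pytest.approx(0.3173, abs=1e-4)

    def test_identical_groups_null(self):
        clin = _clin([1.0, 2.0, 1.0, 2.0], [1, 1, 1, 1])
        labels = RiskLabels(
            pd.Series(["A", "A", "B", "B"], index=clin.sample_ids), ["A", "B"]
        )
        stat, p = logrank_test(clin, labels)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_power_under_planted_hazard(self):
        cfg = om.SyntheticConfig(
            n_samples=300,
            n_features={"rna": 2, "mirna": 2, "methylation": 2},
            n_informative={"rna": 0, "mirna": 0, "methylation": 0},
            hazard_ratio=3.0,
            seed=5,
        )
        _, clin, truth = om.generate_cohort(cfg)
        labels = RiskLabels(truth.true_group.astype(str), ["1", "2"])
        _, p = logrank_test(clin, labels)
        assert p < 1e-3


class TestConcordance:
    def test_perfect_ordering(self):
        clin = _clin([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert concordance_index(np.array([4.0, 3.0, 2.0, 1.0]), clin) == pytest.approx(1.0)

    def test_three_subject_hand_case(self):
        clin = _clin([1.0, 2.0, 3.0], [1, 1, 1])
        assert concordance_index(np.array([3.0, 1.0, 2.0]), clin) == pytest.approx(2 / 3)

    def test_all_tied_scores(self):
        clin = _clin([1.0, 2.0, 3.0], [1, 1, 1])
        assert concordance_index(np.zeros(3), clin) == pytest.approx(0.5)

    def test_brute_force_oracle(self):
        """Implementation equals exhaustive pair enumeration on random data."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 31))
            clin = random_censored_clinical(rng, n)
            scores = rng.normal(size=n)
            expected = brute_force_cindex(
                scores, clin.time.to_numpy(), clin.event.to_numpy()
            )
            if np.isnan(expected):
                with pytest.raises(ValueError, match="comparable"):
                    concordance_index(scores, clin)
            else:
                assert concordance_index(scores, clin) == pytest.approx(expected)


class TestBrier:
    def test_perfect_prediction_zero(self):
        clin = _clin([1.0, 5.0], [1, 1])
        score, _ = brier_score(np.array([1.0, 0.0]), clin, horizon=2.0)
        assert score == pytest.approx(0.0)

    def test_constant_half_quarter(self):
        clin = _clin([1.0, 2.0, 5.0, 6.0], [1, 1, 1, 1])
        score, _ = brier_score(np.full(4, 0.5), clin, horizon=3.0)
        assert score == pytest.approx(0.25)

    def test_equals_mse_without_censoring(self):
        rng = np.random.default_rng(3)
        n = 40
        t = rng.exponential(1.0, n)
        clin = _clin(t, np.ones(n, dtype=int))
        p = rng.uniform(0, 1, n)
        horizon = float(np.median(t))
        score, _ = brier_score(p, clin, horizon=horizon)
        outcome = (t <= horizon).astype(float)
        assert score == pytest.approx(float(np.mean((outcome - p) ** 2)))

    def test_hand_weighted_censored_case(self):
        # subjects: death t=1, censored t=2, death t=3; horizon 2.5
        # censoring KM: G(t)=1 for t<2, G(t)=0.5 for t>=2
        # s0: weight 1/G(1-)=1, outcome 1; s1 censored pre-horizon: excluded;
        # s2: at risk at 2.5, weight 1/G(2.5)=2, outcome 0
        clin = _clin([1.0, 2.0, 3.0], [1, 0, 1])
        p = np.array([0.8, 0.5, 0.3])
        score, _ = brier_score(p, clin, horizon=2.5)
        expected = (1.0 * (1 - 0.8) ** 2 + 2.0 * (0 - 0.3) ** 2) / 3
        assert score == pytest.approx(expected)

    def test_matches_scikit_survival(self):
        """Cross-check the IPCW weighting against an independent implementation."""
        sksurv_metrics = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(11)
        clin = random_censored_clinical(rng, 60)
        p = rng.uniform(0, 1, 60)
        horizon = float(np.quantile(clin.time, 0.4))
        mine, _ = brier_score(p, clin, horizon=horizon)
        y = np.array(
            [(bool(e), t) for e, t in zip(clin.event, clin.time)],
            dtype=[("event", "?"), ("time", "<f8")],
        )
        _, theirs = sksurv_metrics.brier_score(y, y, 1 - p, [horizon])
        assert mine == pytest.approx(float(theirs[0]), abs=1e-6)

    def test_default_horizon_is_median_followup(self, tiny_clinical):
        _, horizon = brier_score(np.full(6, 0.5), tiny_clinical)
        assert horizon == pytest.approx(float(np.median(tiny_clinical.time)))


def test_logrank_equals_cox_score_test_binary():
    """Spec invariant: log-rank == Cox score test on ties-free binary data."""
    from omisurv.subtype import cox_score_test

    rng = np.random.default_rng(19)
    t = rng.exponential(1.0, 50) + rng.random(50) * 1e-9
    e = rng.integers(0, 2, 50)
    e[:4] = 1  # ensure events
    g = rng.integers(0, 2, 50)
    clin = _clin(t, e)
    labels = RiskLabels(pd.Series(np.where(g == 0, "A", "B"), index=clin.sample_ids), ["A", "B"])
    stat, _ = logrank_test(clin, labels)
    chi2, _ = cox_score_test(g[:, None].astype(float), t, e)
    assert chi2[0] == pytest.approx(stat, abs=1e-6)


def test_evaluate_labels_report_contract(tiny_clinical):
    labels = RiskLabels(
        pd.Series(["G1", "G2", "G1", "G2", "G1", "G2"], index=tiny_clinical.sample_ids),
        risk_order=["G1", "G2"],
    )
    report = om.evaluate_labels(tiny_clinical, labels)
    assert 0 <= report.logrank_p <= 1
    assert 0 <= report.c_index <= 1
    assert 0 <= report.brier <= 1
    assert report.n_samples == 6 and report.n_events == 4
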