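"""Baseline reductions and the shared benchmark path."""

import numpy as np
import pandas as pd
import pytest

import omisurv as om
from omisurv.comparators import ReductionSpec, reduce


def _stacked_from(X):
    cols = [f"rna:f{j}" for j in range(X.shape[1])]
    return om.StackedMatrix(
        values=pd.DataFrame(X, index=[f"s{i}" for i in range(X.shape[0])], columns=cols),
        block_of_origin=pd.Series("rna", index=cols),
    )


class TestReduce:
    def test_pca_exact_planar_data(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 10))
        coords = rng.normal(size=(30, 2))
        X = coords @ basis
        X = (X - X.min(0)) / (X.max(0) - X.min(0))
        scores = reduce(_stacked_from(X), ReductionSpec("pca", n_components=2))
        recon_err = np.linalg.norm(
            X - X.mean(0)
        ) ** 2 - np.linalg.norm(scores.to_numpy()) ** 2
        assert abs(recon_err) < 1e-18 or recon_err == pytest.approx(0.0, abs=1e-12)

    def test_pca_deterministic_sign_convention(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(0, 1, (20, 8))
        a = reduce(_stacked_from(X), ReductionSpec("pca", n_components=3))
        b = reduce(_stacked_from(X), ReductionSpec("pca", n_components=3))
        pd.testing.assert_frame_equal(a, b)

    def test_nmf_rank_one_exact(self):
        u = np.array([1.0, 2.0, 3.0, 4.0])[:, None]
        v = np.array([[0.5, 1.0, 1.5]])
        X = u @ v
        scores = reduce(_stacked_from(X), ReductionSpec("nmf", n_components=1, nmf_max_iter=2000))
        # rank-1 nonnegative matrix admits an exact 1-component factorization
        from sklearn.decomposition import NMF

        model = NMF(1, init="nndsvda", random_state=0, max_iter=2000).fit(X)
        recon = model.transform(X) @ model.components_
        rel = np.linalg.norm(X - recon) / np.linalg.norm(X)
        assert rel < 1e-6

    def test_nmf_seeded_determinism(self):
        rng = np.random.default_rng(2)
        X = rng.uniform(0, 1, (15, 10))
        a = reduce(_stacked_from(X), ReductionSpec("nmf", n_components=3, seed=5))
        b = reduce(_stacked_from(X), ReductionSpec("nmf", n_components=3, seed=5))
        pd.testing.assert_frame_equal(a, b)

    def test_tsne_exact_solver_beyond_three_dims(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 1, (40, 12))
        scores = reduce(
            _stacked_from(X),
            ReductionSpec("tsne", n_components=4, seed=0, tsne_n_iter=250),
        )
        assert scores.shape == (40, 4)

    def test_n_components_too_large_rejected(self):
        X = np.random.default_rng(0).uniform(0, 1, (10, 5))
        with pytest.raises(ValueError, match="n_components"):
            reduce(_stacked_from(X), ReductionSpec("pca", n_components=20))

    def test_nmf_negative_input_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 5))
        sm = om.StackedMatrix(
            values=pd.DataFrame(
                X - X.min() + 0.1,
                index=[f"s{i}" for i in range(10)],
                columns=[f"rna:f{j}" for j in range(5)],
            ),
            block_of_origin=pd.Series("rna", index=[f"rna:f{j}" for j in range(5)]),
        )
        sm.values.iloc[0, 0] = -1.0
        with pytest.raises(ValueError, match="non-negative"):
            reduce(sm, ReductionSpec("nmf", n_components=2))


class TestCoxBaseline:
    def test_signal_feature_outranks_noise(self):
        rng = np.random.default_rng(4)
        n = 200
        g = np.repeat([1, 2], n // 2)
        lam = 0.2 * 3.0 ** (g - 1)
        clin = om.ClinicalTable(
            pd.DataFrame(
                {"os_time": rng.exponential(1 / lam), "os_event": 1},
                index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
            )
        )
        rna = pd.DataFrame(
            {"signal": g.astype(float), **{f"noise{j}": rng.normal(size=n) for j in range(8)}},
            index=clin.sample_ids,
        )
        blocks = {"rna": om.OmicsMatrix(rna, "rna")}
        top = om.cox_baseline_features(blocks, clin, top_k=1)
        assert list(top.columns) == ["rna:signal"]

    def test_null_cindex_centered_at_half(self):
        rng = np.random.default_rng(6)
        n = 150
        clin = om.ClinicalTable(
            pd.DataFrame(
                {"os_time": rng.exponential(1.0, n), "os_event": 1},
                index=pd.Index([f"s{i}" for i in range(n)], name="sample_id"),
            )
        )
        rna = pd.DataFrame(
            {f"noise{j}": rng.normal(size=n) for j in range(20)}, index=clin.sample_ids
        )
        from omisurv.metrics import concordance_index
        from lifelines import CoxPHFitter

        cs = []
        for col in rna.columns:
            df = pd.DataFrame({"t": clin.time, "e": clin.event, "x": rna[col]})
            cph = CoxPHFitter().fit(df, "t", "e")
            cs.append(concordance_index(rna[col] * float(cph.params_["x"]), clin))
        assert abs(np.mean(cs) - 0.5) <= 0.05

    def test_top_k_one_single_column(self, stacked_small):
        _, clinical, _, clean = stacked_small
        blocks = {"mirna": clean["mirna"]}
        top = om.cox_baseline_features(blocks, clinical, top_k=1)
        assert top.shape[1] == 1


class TestRunBenchmark:
    def test_single_method_single_row(self, stacked_small):
        stacked, clinical, _, clean = stacked_small
        table = om.run_benchmark(
            stacked, clean, clinical, ["pca"], n_components=10, seed=0
        )
        assert len(table) == 1 and table.index[0] == "pca"

    def test_reports_within_contract_and_deterministic(self, stacked_small):
        stacked, clinical, _, clean = stacked_small
        methods = ["pca", "coxph"]
        t1 = om.run_benchmark(stacked, clean, clinical, methods, n_components=10, seed=1)
        t2 = om.run_benchmark(stacked, clean, clinical, methods, n_components=10, seed=1)
        pd.testing.assert_frame_equal(t1, t2)
        for _, row in t1.iterrows():
            if row["error"] is None:
                assert 0 <= row["logrank_p"] <= 1
                assert 0 <= row["c_index"] <= 1

    def test_failing_method_recorded_not_raised(self, stacked_small):
        stacked, clinical, _, clean = stacked_small
        table = om.run_benchmark(
            stacked, clean, clinical, ["nmf"], n_components=10_000, seed=0
        )
        assert table.loc["nmf", "error"] is not None
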