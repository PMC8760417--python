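"""PCA wheel, k-NN classification, CCS aggregation, Spearman assignment."""

import numpy as np
import pandas as pd
import pytest

from cyclesig import signature
from cyclesig.signature import (
    aggregate_ccs,
    build_signature,
    circular_rank_correlation,
    knn_classify,
    normalize_query,
    pca_wheel,
    spearman_assign,
)


class TestPcaWheel:
    def test_rank_one_matrix_pc1_explains_everything(self):
        rng = np.random.default_rng(0)
        u = rng.standard_normal(20)
        v = rng.standard_normal(8)
        X = pd.DataFrame(np.outer(u, v),
                         index=[f"P{i%4+1}_B1_T{i%2+1}x{i}" for i in range(20)])
        X.index = [f"s{i}" for i in range(20)]
        res = pca_wheel(X)
        assert res.var_explained[0] == pytest.approx(100.0)

    def test_variance_percentages_sum_to_100(self, signature_model):
        res = pca_wheel(signature_model.sample_matrix)
        assert res.var_explained.sum() == pytest.approx(100.0)
        assert (res.var_explained >= 0).all()

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.standard_normal((30, 6)),
                         index=[f"s{i}" for i in range(30)])
        res = pca_wheel(X)
        Xc = X.to_numpy() - X.to_numpy().mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1]
        for j in range(3):
            oracle = Xc @ evecs[:, order[j]]
            got = res.scores.iloc[:, j].to_numpy()
            assert min(
                np.abs(got - oracle).max(), np.abs(got + oracle).max()
            ) < 1e-8

    def test_pc1_sign_fixed_on_reference_samples(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.standard_normal((30, 6)),
                         index=[f"s{i}" for i in range(30)])
        ref = [f"s{i}" for i in range(5)]
        res = pca_wheel(X, interphase_samples=ref)
        assert res.scores.loc[ref, "PC1"].mean() >= 0

    def test_constant_feature_dropped_with_warning(self):
        X = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5], "c": [0.0, 1, 0]},
                         index=["s1", "s2", "s3"])
        with pytest.warns(UserWarning, match="constant"):
            res = pca_wheel(X)
        assert res.scores.shape[1] == 2

    def test_wheel_recovers_cyclic_population_order(self, signature_model):
        res = pca_wheel(
            signature_model.sample_matrix,
            interphase_samples=signature_model.sample_design.index[
                signature_model.sample_design["population"] <= 8
            ],
        )
        pops = signature_model.sample_design["population"].to_numpy()
        pop_scores = res.scores.groupby(pops).mean()
        angles = np.arctan2(pop_scores["PC2"], pop_scores["PC1"]).to_numpy()
        corr = circular_rank_correlation(angles, pop_scores.index.to_numpy())
        assert corr >= 0.9


class TestKnn:
    def test_duplicated_training_points_vote_their_label(self):
        train = np.tile([[1.0, 0.0]], (6, 1))
        test = np.array([[1.0, 0.0]])
        pred = knn_classify(train, np.full(6, 3), test, k=6)
        assert pred[0] == 3

    def test_k1_returns_nearest_label(self):
        train = np.array([[0.0], [10.0]])
        pred = knn_classify(train, np.array([1, 2]), np.array([[2.0]]), k=1)
        assert pred[0] == 1

    def test_tie_broken_by_mean_distance(self):
        # 1 neighbor of label 1 close, 1 neighbor of label 2 far
        train = np.array([[0.0], [3.0]])
        pred = knn_classify(train, np.array([2, 1]), np.array([[1.0]]), k=2)
        assert pred[0] == 2

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValueError):
            knn_classify(np.ones((6, 3)), np.arange(6), np.ones((1, 2)), k=2)

    def test_leave_one_biorep_out_beats_chance(self, signature_model):
        accs = []
        for b in (1, 2, 3, 4):
            true, pred = signature.leave_one_biorep_out(signature_model, b)
            accs.append((true == pred).mean())
        assert np.mean(accs) >= 0.5  # chance level is 1/16

    def test_robust_to_removing_two_signature_proteins(self, signature_model):
        # removing any 2 of ~100 signature proteins leaves >= 95% of
        # individual k-NN predictions unchanged (the classification does
        # not hinge on single proteins)
        rng = np.random.default_rng(7)
        design = signature_model.sample_design
        X = signature_model.sample_matrix
        test_mask = (design["biorep"] == 4).to_numpy()
        y = design["population"].to_numpy()
        base = knn_classify(X.to_numpy()[~test_mask], y[~test_mask],
                            X.to_numpy()[test_mask])
        agree = []
        for _ in range(20):
            drop = rng.choice(X.columns, 2, replace=False)
            Xs = X.drop(columns=list(drop)).to_numpy()
            pred = knn_classify(Xs[~test_mask], y[~test_mask], Xs[test_mask])
            agree.append((pred == base).mean())
        assert np.mean(agree) >= 0.95


class TestAggregateCcs:
    def test_surjective_onto_eight_labels(self, signature_model):
        assert set(signature_model.pop_to_ccs.values()) == set(range(1, 9))
        assert set(signature_model.pop_to_ccs.keys()) == set(range(1, 17))

    def test_profiles_are_member_means(self, signature_model):
        m = signature_model
        for ccs in m.ccs_profiles.index:
            members = [p for p, c in m.pop_to_ccs.items()
                       if f"CCS{c}" == ccs]
            np.testing.assert_allclose(
                m.ccs_profiles.loc[ccs].to_numpy(),
                m.pop_means.loc[members].mean(axis=0).to_numpy(),
            )

    def test_deterministic_under_seed(self, ppm_table, psp_ids):
        m1 = aggregate_ccs(build_signature(ppm_table, psp_ids), seed=5)
        m2 = aggregate_ccs(build_signature(ppm_table, psp_ids), seed=5)
        assert m1.pop_to_ccs == m2.pop_to_ccs

    def test_eight_well_separated_pairs(self):
        # 16 population vectors forming 8 tight pairs -> one CCS per pair
        rng = np.random.default_rng(8)
        centers = rng.standard_normal((8, 40)) * 10
        pop_means = pd.DataFrame(
            np.repeat(centers, 2, axis=0) + rng.standard_normal((16, 40)) * 0.01,
            index=pd.Index(range(1, 17), name="population"),
        )
        model = signature.SignatureModel(
            psp_ids=list(pop_means.columns),
            sample_matrix=pd.DataFrame(),
            sample_design=pd.DataFrame(),
            pop_means=pop_means,
        )
        model = aggregate_ccs(model, seed=9)
        for p in range(1, 16, 2):
            assert model.pop_to_ccs[p] == model.pop_to_ccs[p + 1]


class TestSpearmanAssign:
    def test_profile_restriction_gives_rho_one(self, signature_model):
        prof = signature_model.ccs_profiles.loc["CCS3"].iloc[:60]
        a = spearman_assign(prof, signature_model)
        assert a.best_ccs == "CCS3"
        assert a.rho["CCS3"] == pytest.approx(1.0)

    def test_negated_profile_gives_rho_minus_one(self, signature_model):
        prof = -signature_model.ccs_profiles.loc["CCS3"]
        a = spearman_assign(prof, signature_model)
        assert a.rho["CCS3"] == pytest.approx(-1.0)

    def test_small_overlap_unassigned(self, signature_model):
        prof = signature_model.ccs_profiles.loc["CCS1"].iloc[:10]
        a = spearman_assign(prof, signature_model)
        assert a.best_ccs is None
        assert "overlap" in a.reason

    def test_invariant_to_monotone_transform(self, signature_model):
        prof = signature_model.ccs_profiles.loc["CCS5"]
        noisy = prof + np.random.default_rng(10).normal(0, 0.3, len(prof))
        a1 = spearman_assign(noisy, signature_model)
        a2 = spearman_assign(np.exp(noisy * 2) + 7, signature_model)
        pd.testing.assert_series_equal(a1.rho, a2.rho)

    def test_batch_bh_control(self, signature_model):
        rng = np.random.default_rng(11)
        queries = {}
        for i, ccs in enumerate(signature_model.ccs_profiles.index):
            queries[f"good_{ccs}"] = signature_model.ccs_profiles.loc[ccs] \
                + rng.normal(0, 0.3, signature_model.ccs_profiles.shape[1])
        # pure-noise queries should mostly not be assigned
        for i in range(8):
            queries[f"noise{i}"] = pd.Series(
                rng.standard_normal(len(signature_model.psp_ids)),
                index=signature_model.psp_ids,
            )
        report, _ = signature.assign_batch(queries, signature_model)
        good = report[report["experiment_id"].str.startswith("good")]
        noise = report[report["experiment_id"].str.startswith("noise")]
        assert good["assigned"].all()
        assert noise["assigned"].mean() <= 0.25


class TestNormalizeQuery:
    def test_sample_equals_reference_gives_zeros(self):
        df = pd.DataFrame({"v": [2.0, 4.0, 8.0], "ref": [2.0, 4.0, 8.0]})
        out = normalize_query(df, mode="lfq_vs_reference", value_col="v",
                              reference_col="ref")
        np.testing.assert_allclose(out, 0.0)

    def test_log2_of_ratio_four_is_two_before_centering(self):
        df = pd.DataFrame({"v": [4.0, 1.0], "ref": [1.0, 1.0]})
        out = normalize_query(df, mode="lfq_vs_reference", value_col="v",
                              reference_col="ref")
        assert out.iloc[0] - out.iloc[1] == pytest.approx(2.0)

    def test_nonpositive_ratio_becomes_missing(self):
        df = pd.DataFrame({"v": [4.0, -1.0, 0.0], "ref": [1.0, 1.0, 1.0]})
        out = normalize_query(df, mode="lfq_vs_reference", value_col="v",
                              reference_col="ref")
        assert out.iloc[1:].isna().all()

    def test_silac_centering_median_zero(self):
        s = pd.Series([0.5, 1.0, 3.0, -2.0, np.nan])
        out = normalize_query(s, mode="silac_log_ratio")
        assert out.median() == pytest.approx(0.0)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            normalize_query(pd.Series([1.0]), mode="other")
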