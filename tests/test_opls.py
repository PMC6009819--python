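import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from tagdnl.opls import (
    OplsModel,
    cv_anova,
    oplsda_fit,
    opls_predict,
    pca_fit,
    permutation_test,
    plsda_vip,
    predict_and_roc,
    splot,
)
from tagdnl.preprocess import Scaler


def planted_discriminant(n=120, p=30, delta=2.0, ortho=0.0, seed=0):
    """Binary classes separated along one direction, optional strong
    class-orthogonal factor."""
    rng = np.random.default_rng(seed)
    y = (np.arange(n) % 2).astype(float)
    X = rng.normal(size=(n, p))
    X[:, 0] += delta * y
    if ortho:
        X += np.outer(rng.normal(size=n), rng.normal(size=p)) * ortho
    return X, y


class TestPca:
    def test_rank_one_matrix_single_component(self):
        t = np.random.default_rng(0).normal(size=12)
        p = np.random.default_rng(1).normal(size=5)
        X = np.outer(t, p)
        with pytest.warns(UserWarning, match="rank"):
            model = pca_fit(X, n_components=3, scaling="center")
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 10))
        model = pca_fit(X, n_components=3, scaling="center")
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        for a in range(3):
            ref = U[:, a] * S[a]
            got = model.scores[:, a]
            sign = np.sign(ref @ got)
            assert np.allclose(got, sign * ref, atol=1e-8)

    def test_explained_variance_non_increasing(self):
        X = np.random.default_rng(3).normal(size=(30, 8))
        model = pca_fit(X, n_components=5, scaling="unit_variance")
        evr = model.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-10)

    def test_qc_samples_inside_subject_ellipse(self, normed_small_cohort):
        """After QC normalization the pooled-QC scores sit inside the
        subjects' empirical 95% score ellipse."""
        normed, _, _ = normed_small_cohort
        model = pca_fit(normed.intensities.to_numpy(), n_components=2, scaling="pareto")
        qc_mask = normed.is_qc.to_numpy()
        subj = model.scores[~qc_mask]
        cov = np.linalg.inv(np.cov(subj, rowvar=False))
        ctr = subj.mean(axis=0)

        def maha2(pts):
            d = pts - ctr
            return np.einsum("ij,jk,ik->i", d, cov, d)

        lim = np.quantile(maha2(subj), 0.95)
        assert (maha2(model.scores[qc_mask]) <= lim).all()


class TestOplsFit:
    def test_noiseless_single_direction(self):
        """y carried exactly by one X direction: no orthogonal components,
        R2Y = 1."""
        rng = np.random.default_rng(4)
        y = (np.arange(40) % 2).astype(float)
        v = rng.normal(size=6)
        X = np.outer(y - y.mean(), v)
        model = oplsda_fit(X, y, scaling="center", seed=0)
        assert model.n_ortho == 0
        assert model.r2y == pytest.approx(1.0, abs=1e-10)

    def test_reconstruction_identity(self):
        X, y = planted_discriminant(ortho=1.0, seed=5)
        model = oplsda_fit(X, y, n_ortho=2, scaling="pareto", seed=0)
        Xs = model.scaler.transform(X)
        recon = np.outer(model.t, model.p)
        for k in range(model.W_o.shape[1]):
            recon += np.outer(model.T_o[:, k], model.P_o[:, k])
        assert np.allclose(Xs - recon, model.E, atol=1e-10)

    def test_orthogonal_filter_beats_raw_pls1_correlation(self):
        """With a planted orthogonal factor, the filtered predictive score
        correlates more strongly with y than the unfiltered PLS1 score."""
        X, y = planted_discriminant(n=200, delta=1.5, ortho=2.5, seed=6)
        model = oplsda_fit(X, y, n_ortho=1, scaling="center", seed=0)
        Xs = Scaler("center").fit_transform(X)
        yc = y - y.mean()
        w = Xs.T @ yc
        t_pls1 = Xs @ (w / np.linalg.norm(w))
        c_opls = abs(np.corrcoef(model.t, y)[0, 1])
        c_pls1 = abs(np.corrcoef(t_pls1, y)[0, 1])
        assert c_opls >= c_pls1

    def test_reduces_to_pls1_without_orthogonal_components(self):
        X, y = planted_discriminant(seed=7)
        model = oplsda_fit(X, y, n_ortho=0, scaling="center", seed=0)
        pls = PLSRegression(n_components=1, scale=False)
        Xs = Scaler("center").fit_transform(X)
        pls.fit(Xs, y - y.mean())
        t_ref = pls.x_scores_[:, 0]
        sign = np.sign(t_ref @ model.t)
        assert np.allclose(
            model.t / np.linalg.norm(model.t),
            sign * t_ref / np.linalg.norm(t_ref),
            atol=1e-8,
        )

    def test_single_class_rejected(self):
        X = np.random.default_rng(8).normal(size=(20, 4))
        with pytest.raises(ValueError, match="2 classes"):
            oplsda_fit(X, np.zeros(20), seed=0)

    def test_q2_deterministic_given_seed(self):
        X, y = planted_discriminant(seed=9)
        m1 = oplsda_fit(X, y, seed=3)
        m2 = oplsda_fit(X, y, seed=3)
        assert m1.q2 == m2.q2 and m1.n_ortho == m2.n_ortho

    def test_permuted_label_q2_mean_nonpositive(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(300, 15))
        y = (np.arange(300) % 2).astype(float)
        q2s = []
        for _ in range(100):
            yp = rng.permutation(y)
            q2s.append(oplsda_fit(X, yp, n_ortho=0, seed=0).q2)
        assert np.mean(q2s) <= 0.0


class TestSplot:
    def test_feature_equal_to_score(self):
        X, y = planted_discriminant(seed=11)
        model = oplsda_fit(X, y, n_ortho=0, scaling="center", seed=0)
        Xs = model.scaler.transform(X)
        Xs2 = np.column_stack([Xs, model.t])
        model.feature_names = [f"f{i}" for i in range(Xs.shape[1])] + ["score_copy"]
        out = splot(model, Xs2)
        assert out.loc["score_copy", "p_corr"] == pytest.approx(1.0, abs=1e-10)
        assert out.loc["score_copy", "p_cov"] == pytest.approx(
            np.var(model.t, ddof=1), abs=1e-10
        )

    def test_pure_noise_feature_low_correlation(self):
        rng = np.random.default_rng(12)
        X, y = planted_discriminant(n=2000, p=5, delta=3.0, seed=12)
        X = np.column_stack([X, rng.normal(size=2000)])
        model = oplsda_fit(X, y, n_ortho=0, scaling="center", seed=0)
        out = splot(model, model.scaler.transform(X))
        assert abs(out.loc[5, "p_corr"]) < 0.1

    def test_zero_variance_feature_excluded(self):
        X, y = planted_discriminant(seed=13)
        model = oplsda_fit(X, y, n_ortho=0, scaling="center", seed=0)
        Xs = np.column_stack([model.scaler.transform(X), np.zeros(len(y))])
        with pytest.warns(UserWarning, match="zero-variance"):
            out = splot(model, Xs)
        assert len(out) == X.shape[1]


class TestPermutation:
    def test_pure_noise_model_fails_validation(self):
        rng = np.random.default_rng(14)
        X = rng.normal(size=(60, 10))
        y = (np.arange(60) % 2).astype(float)
        rep = permutation_test(X, y, n_perm=25, seed=0, n_ortho=0)
        assert not rep.passed

    def test_strong_signal_passes(self):
        ok = 0
        for seed in range(10):
            X, y = planted_discriminant(n=100, delta=3.0, seed=seed)
            rep = permutation_test(X, y, n_perm=25, seed=seed, n_ortho=0)
            ok += rep.passed
        assert ok >= 9

    def test_identity_permutation_never_recorded(self):
        X, y = planted_discriminant(n=30, seed=15)
        rep = permutation_test(X, y, n_perm=25, seed=1, n_ortho=0)
        assert (rep.records["corr"] < 1.0 - 1e-12).all()


class TestCvAnova:
    def test_no_predictive_power_gives_p_one(self):
        X, y = planted_discriminant(seed=16)
        model = oplsda_fit(X, y, n_ortho=0, seed=0)
        model.cv_press = model.cv_ssy  # PRESS == SSY
        F, _, _, p = cv_anova(model)
        assert p == 1.0 and F <= 0.0

    def test_hand_computed_f_on_fixed_model(self):
        X, y = planted_discriminant(n=12, p=4, delta=3.0, seed=17)
        model = oplsda_fit(X, y, n_ortho=0, n_folds=4, seed=0)
        F, df1, df2, p = cv_anova(model)
        A = 1 + model.n_ortho
        f_ref = ((model.cv_ssy - model.cv_press) / A) / (
            model.cv_press / (model.n_samples - A - 1)
        )
        from scipy import stats

        assert F == pytest.approx(f_ref, abs=1e-12)
        assert (df1, df2) == (A, model.n_samples - A - 1)
        assert p == pytest.approx(stats.f.sf(f_ref, df1, df2), abs=1e-12)

    def test_planted_signal_significant(self):
        sig = 0
        for seed in range(10):
            X, y = planted_discriminant(n=80, delta=2.5, seed=seed)
            model = oplsda_fit(X, y, n_ortho=0, seed=seed)
            sig += cv_anova(model)[3] < 0.001
        assert sig >= 9


def auc_pair_counting(scores, labels):
    """Rank-pair oracle: P(score_pos > score_neg) with ties counting half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestPredictRoc:
    def _identity_model(self):
        """Model whose prediction equals the first feature of X_new."""
        X = np.array([[0.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        scaler = Scaler("center").fit(np.vstack([X, [[0, 0]]]))
        return OplsModel(
            scaler=scaler, y_mean=0.0, classes_=(0, 1),
            w=np.array([1.0, 0.0]), t=np.zeros(3), p=np.array([1.0, 0.0]), q=1.0,
            W_o=np.empty((2, 0)), T_o=np.empty((3, 0)), P_o=np.empty((2, 0)),
            E=np.zeros((3, 2)), r2x=0, r2y=0, q2=0, n_ortho=0, n_folds=2, seed=0,
            cv_press=1.0, cv_ssy=1.0, n_samples=3, threshold=0.5,
        )

    def test_auc_matches_pair_counting_oracle(self):
        model = self._identity_model()
        scores = [0.1, 0.4, 0.35, 0.8]
        X_new = np.column_stack([scores, np.zeros(4)])
        y = np.array([0, 0, 1, 1])
        yhat, calls, roc, auc = predict_and_roc(model, X_new, y)
        assert np.allclose(yhat, scores)
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(auc_pair_counting(scores, y))

    def test_random_scores_match_oracle(self):
        rng = np.random.default_rng(18)
        model = self._identity_model()
        scores = rng.normal(size=50)
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        _, _, _, auc = predict_and_roc(model, np.column_stack([scores, np.zeros(50)]), y)
        assert auc == pytest.approx(auc_pair_counting(scores, y), abs=1e-12)

    def test_training_set_of_separated_model_auc_one(self):
        X, y = planted_discriminant(n=60, delta=8.0, seed=19)
        model = oplsda_fit(X, y, n_ortho=0, seed=0)
        _, _, _, auc = predict_and_roc(model, X, y)
        assert auc == pytest.approx(1.0)

    def test_feature_mismatch_rejected(self):
        model = self._identity_model()
        with pytest.raises(ValueError, match="feature mismatch"):
            opls_predict(model, np.zeros((2, 5)))


class TestTransferPrediction:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_fli_trained_model_predicts_ultrasound_status(self, seed):
        """A model trained on FLI labels predicts held-out ultrasound labels
        with AUC >= 0.8 at the default planted effect sizes."""
        from tagdnl.clinical import steatosis_labels
        from tagdnl.preprocess import qc_normalize
        from tagdnl.synthetic import CohortSpec, generate_cohort

        table, subjects = generate_cohort(CohortSpec(seed=seed))
        normed, _ = qc_normalize(table)
        X = normed.subjects().intensities
        meta = subjects.loc[X.index]
        n_train = int(0.6 * len(X))
        train, test = X.index[:n_train], X.index[n_train:]
        model = oplsda_fit(
            X.loc[train], steatosis_labels(meta.loc[train], "fli60").to_numpy(), seed=seed
        )
        y_us = steatosis_labels(meta.loc[test], "ultrasound").to_numpy()
        _, _, _, auc = predict_and_roc(model, X.loc[test], y_us)
        assert auc >= 0.8


class TestVip:
    def test_informative_feature_has_max_vip(self):
        rng = np.random.default_rng(20)
        y = np.repeat([0, 1, 2], 20)
        X = rng.normal(size=(60, 10))
        X[:, 3] += y * 2.0
        vip, _ = plsda_vip(X, y, n_components=2)
        assert vip.idxmax() == 3 and vip.max() > 1.0

    def test_mean_squared_vip_is_one(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(40, 12))
        y = np.repeat([0, 1], 20)
        vip, _ = plsda_vip(X, y, n_components=3)
        assert (vip**2).mean() == pytest.approx(1.0, abs=1e-8)

    def test_mouse_diet_vip_enriched_for_planted_cluster(self):
        """VIP > 1 species are enriched for the diet-shifted saturated TAG
        cluster (hypergeometric p < 0.01)."""
        from scipy.stats import hypergeom

        from tagdnl.synthetic import TAG_CLUSTERS, generate_mouse_livers

        ok = 0
        for seed in range(5):
            table, dnl = generate_mouse_livers(seed=seed)
            vip, _ = plsda_vip(table.intensities, dnl["diet"].to_numpy())
            hits = vip[vip > 1].index
            k = sum(f in TAG_CLUSTERS["dnl"] for f in hits)
            M, n, N = len(vip), len(TAG_CLUSTERS["dnl"]), len(hits)
            p = hypergeom.sf(k - 1, M, n, N)
            ok += p < 0.01
        assert ok >= 4

    def test_needs_two_classes(self):
        with pytest.raises(ValueError):
            plsda_vip(np.zeros((10, 3)), np.zeros(10))
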