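import numpy as np
import pandas as pd
import pytest

from dmdgait.cml import (
    CLASSIFIERS,
    CMLConfig,
    CMLGaitClassifier,
    loso_evaluate,
    project_lda,
    project_pca,
    sweep_configs,
)
from dmdgait.gait_features import FEATURE_NAMES


def _table(n_per_class=8, separation=5.0, seed=0, activity="SC-L3",
           informative_only=False):
    """Feature table with a group shift of `separation` SD on sl.

    With ``informative_only`` the seven other features are constant, so
    sl is the single informative dimension.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n, shift in (("TD", n_per_class, 0.0), ("DMD", n_per_class, separation)):
        for i in range(n):
            feats = dict(zip(FEATURE_NAMES, rng.normal(0, 1, len(FEATURE_NAMES))))
            if informative_only:
                feats = {k: 0.0 for k in feats}
                feats["sl"] = rng.normal(0, 1)
            feats["sl"] += shift
            rows.append({"participant_id": f"{group}{i}", "activity": activity,
                         "group": group, "nsaa": 34, **feats})
    return pd.DataFrame(rows)


class TestEstimatorContract:
    def test_get_set_params_roundtrip(self):
        est = CMLGaitClassifier(classifier="SVM", projection="pca2")
        params = est.get_params()
        est2 = CMLGaitClassifier(**params)
        assert est2.get_params() == params

    def test_unfitted_predict_raises(self):
        from sklearn.exceptions import NotFittedError
        with pytest.raises(NotFittedError):
            CMLGaitClassifier().predict(np.zeros((2, 8)))

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 8))
        with pytest.raises(ValueError):
            CMLGaitClassifier().fit(X, np.array(["TD"] * 6))


class TestLOSO:
    @pytest.mark.parametrize("classifier", CLASSIFIERS)
    @pytest.mark.parametrize("projection", ["none", "lda1"])
    def test_perfectly_separable(self, classifier, projection):
        table = _table(separation=8.0, informative_only=True)
        run = loso_evaluate(table, CMLConfig(classifier=classifier,
                                             projection=projection,
                                             activity="SC-L3", seed=0))
        assert run.accuracy == 1.0

    def test_one_fold_per_participant(self, contrast_table):
        run = loso_evaluate(contrast_table,
                            CMLConfig(classifier="LR", projection="none",
                                      activity="SC-L3", seed=0))
        assert run.n_folds == 30
        assert len(run.fold_predictions) == 30

    def test_no_leakage(self, contrast_table):
        run = loso_evaluate(contrast_table,
                            CMLConfig(classifier="GNB", projection="lda1",
                                      activity="SC-L3", seed=0))
        for pid, train_ids in run.fold_train_ids.items():
            assert pid not in train_ids
            assert len(train_ids) == 29
        run.assert_no_leakage()

    def test_deterministic_given_seed(self, contrast_table):
        cfg = CMLConfig(classifier="RF", projection="pca2", activity="SC-L3", seed=3)
        r1 = loso_evaluate(contrast_table, cfg)
        r2 = loso_evaluate(contrast_table, cfg)
        assert r1.fold_predictions == r2.fold_predictions

    def test_null_features_near_chance(self):
        """Group-independent features: accuracy within the 95% binomial band."""
        accs = []
        for seed in range(20):
            table = _table(n_per_class=15, separation=0.0, seed=seed)
            run = loso_evaluate(table, CMLConfig(classifier="LR",
                                                 projection="lda1",
                                                 activity="SC-L3", seed=0))
            accs.append(run.accuracy)
        mean = np.mean(accs)
        half_width = 1.96 * np.sqrt(0.25 / (20 * 30))
        assert abs(mean - 0.5) < half_width + 1e-12

    def test_single_class_fold_rejected(self):
        table = _table(n_per_class=2)
        table = table[~((table["group"] == "DMD") & (table["participant_id"] == "DMD1"))]
        with pytest.raises(ValueError):
            loso_evaluate(table, CMLConfig(activity="SC-L3"))


class TestProjections:
    def test_pca_line_data(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=30)
        base = _table(n_per_class=15, separation=0.0)
        for i, f in enumerate(FEATURE_NAMES):
            # near-collinear columns: data lies on a line up to 1e-6 jitter
            base[f] = (i + 1) * u + 1e-6 * rng.normal(size=30)
        scores, loadings, evr = project_pca(base, activity="SC-L3")
        assert evr[0] > 0.999
        assert np.all(np.diff(evr) <= 1e-12)
        # orthonormal components
        np.testing.assert_allclose(loadings @ loadings.T, np.eye(2), atol=1e-9)

    def test_pca_reconstruction_error_matches_discarded_variance(self):
        table = _table(n_per_class=10, separation=1.0, seed=5)
        from sklearn.preprocessing import StandardScaler
        X = StandardScaler().fit_transform(table[FEATURE_NAMES].to_numpy())
        scores, loadings, evr = project_pca(table, activity="SC-L3")
        Z = scores[["PC1", "PC2"]].to_numpy()
        resid = X - Z @ loadings
        total_var = np.var(X, axis=0, ddof=1).sum()
        resid_var = np.var(resid, axis=0, ddof=1).sum()
        assert resid_var / total_var == pytest.approx(1 - evr.sum(), rel=1e-6)

    def test_lda_sign_convention_and_dimension(self):
        table = _table(separation=4.0)
        scores = project_lda(table, activity="SC-L3")
        assert scores.loc[scores["group"] == "DMD", "LDA1"].mean() > 0
        assert scores.loc[scores["group"] == "TD", "LDA1"].mean() < 0
        assert scores["LDA1"].ndim == 1

    def test_lda_recovers_separating_direction(self):
        # clouds separated along a known direction: scores track that axis
        rng = np.random.default_rng(2)
        direction = np.zeros(8)
        direction[2] = 1.0  # sl
        table = _table(n_per_class=40, separation=3.0, seed=2)
        scores = project_lda(table, activity="SC-L3")
        proj_true = table["sl"].to_numpy()
        r = np.corrcoef(scores["LDA1"], proj_true)[0, 1]
        assert abs(r) > 0.95

    def test_rank_deficient_pca_rejected(self):
        table = _table(n_per_class=2, separation=0.0)
        for f in FEATURE_NAMES:
            table[f] = 1.0
        with pytest.raises(ValueError):
            project_pca(table, activity="SC-L3")


class TestSweep:
    def test_grid_shape_and_best_marking(self):
        table = _table(n_per_class=4, separation=6.0)
        grid = sweep_configs(table, ["SC-L3"], classifiers=("RF", "LR"),
                             projections=("none", "lda1"))
        assert len(grid) == 4
        for (_, proj), block in grid.groupby(["activity", "projection"]):
            best = block.loc[block["best_in_column"]]
            assert (best["accuracy_pct"] == block["accuracy_pct"].max()).all()

    def test_grid_deterministic(self):
        table = _table(n_per_class=4, separation=2.0, seed=9)
        g1 = sweep_configs(table, ["SC-L3"], classifiers=("RF",), projections=("none",))
        g2 = sweep_configs(table, ["SC-L3"], classifiers=("RF",), projections=("none",))
        pd.testing.assert_frame_equal(g1, g2)
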