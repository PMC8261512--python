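"""Preprocessing hygiene, RFECV consensus, SVM platform models, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from noduleomics.models import (ModelSpec, RfecvSpec, apply_preprocessor,
                                bootstrap_auc, fit_preprocessor, rfecv_select,
                                train_platform_model)
from noduleomics.evaluation import rank_auc


class TestPreprocessor:
    def test_log_transform_and_median(self):
        df = pd.DataFrame({"f": [0.0, 7.0]})
        params = fit_preprocessor(df)
        assert params.medians["f"] == pytest.approx(1.5)  # log2{1,8} = {0,3}

    def test_discovery_table_standardized_to_zero_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.gamma(2, 3, size=(50, 4)), columns=list("abcd"))
        params = fit_preprocessor(df)
        z = apply_preprocessor(params, df)
        assert np.allclose(z.mean(), 0, atol=1e-9)
        assert np.allclose(z.std(ddof=0), 1, atol=1e-9)

    def test_constant_column_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="zero-variance"):
            params = fit_preprocessor(df)
        assert params.dropped == ("b",)
        assert apply_preprocessor(params, df).columns.tolist() == ["a"]

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            fit_preprocessor(pd.DataFrame({"a": [-1.0, 2.0]}))

    def test_validation_uses_discovery_params_not_refit(self):
        disc = pd.DataFrame({"a": [0.0, 1.0, 3.0, 15.0]})
        params = fit_preprocessor(disc)
        val = pd.DataFrame({"a": [2 ** params.medians["a"] - 1]})
        z = apply_preprocessor(params, val)
        # a validation value equal to the discovery median is z-scored with
        # the discovery mean/std, generally nonzero
        expected = (params.medians["a"] - params.means["a"]) / params.stds["a"]
        assert z["a"].iloc[0] == pytest.approx(expected)
        assert z["a"].iloc[0] != 0

    def test_fully_missing_row_becomes_median_row(self):
        disc = pd.DataFrame({"a": [1.0, 2.0, 4.0], "b": [3.0, 5.0, 9.0]})
        params = fit_preprocessor(disc)
        z = apply_preprocessor(params, pd.DataFrame({"a": [np.nan], "b": [np.nan]}))
        assert np.isfinite(z.to_numpy()).all()

    def test_double_transform_refused(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 4.0]})
        params = fit_preprocessor(df)
        z = apply_preprocessor(params, df)
        with pytest.raises(ValueError, match="already preprocessed"):
            apply_preprocessor(params, z)

    def test_no_leakage_from_validation_labels(self):
        # the validation transform is a pure function of discovery params
        rng = np.random.default_rng(1)
        disc = pd.DataFrame(rng.gamma(2, 2, size=(40, 3)), columns=list("abc"))
        val = pd.DataFrame(rng.gamma(2, 2, size=(20, 3)), columns=list("abc"))
        params = fit_preprocessor(disc)
        z1 = apply_preprocessor(params, val.copy())
        z2 = apply_preprocessor(params, val.copy())  # "shuffled labels" run
        pd.testing.assert_frame_equal(z1, z2)


class TestRfecv:
    def test_recovers_planted_strong_features(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        X = rng.normal(size=(100, 50))
        X[:, :5] += y[:, None] * 2.0
        df = pd.DataFrame(X, columns=[f"f{i}" for i in range(50)])
        sel = rfecv_select(df, y, RfecvSpec(seed=0))
        assert all(f"f{i}" in sel for i in range(5))
        assert len(sel) <= 50

    def test_single_informative_feature_found_and_deterministic(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        X = rng.normal(size=(60, 8))
        X[:, 0] += y * 2.0
        df = pd.DataFrame(X, columns=[f"g{i}" for i in range(8)])
        spec = RfecvSpec(seed=1, n_repeats=6, splits_per_repeat=5)
        sel = rfecv_select(df, y, spec)
        assert "g0" in sel and len(sel) >= 1
        assert sel == rfecv_select(df, y, spec)

    def test_needs_two_features(self):
        with pytest.raises(ValueError, match="2 features"):
            rfecv_select(pd.DataFrame({"a": [1.0, 2.0]}), np.array([0, 1]))


class TestPlatformModel:
    def test_separable_toy_reaches_perfect_oof_auc(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        X = rng.normal(size=(60, 2)) + y[:, None] * 8.0
        model = train_platform_model(pd.DataFrame(X, columns=["a", "b"]), y,
                                     ModelSpec(seed=0))
        assert model.oof_auc == 1.0
        assert ((model.oof_scores > 0) & (model.oof_scores < 1)).all()

    def test_permuted_labels_score_near_chance(self):
        rng = np.random.default_rng(5)
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        X = rng.normal(size=(60, 2)) + y[:, None] * 8.0
        yperm = rng.permutation(y)
        model = train_platform_model(pd.DataFrame(X, columns=["a", "b"]), yperm,
                                     ModelSpec(seed=0))
        assert 0.35 <= model.oof_auc <= 0.65

    def test_age_like_single_feature_model(self):
        # Gaussian age separation of the study's demographic scale
        from noduleomics.synthetic import CohortSpec, generate_clinical
        clin, lab = generate_clinical(CohortSpec.default(seed=0))
        from noduleomics.models import fit_preprocessor
        z = apply_preprocessor(fit_preprocessor(clin[["age"]]), clin[["age"]])
        model = train_platform_model(z, lab, ModelSpec(seed=0))
        assert 0.68 <= model.oof_auc <= 0.84

    def test_calibrated_probability_monotone_in_margin(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.zeros(30), np.ones(30)].astype(int)
        X = rng.normal(size=(60, 2)) + y[:, None] * 2.0
        df = pd.DataFrame(X, columns=["a", "b"])
        model = train_platform_model(df, y, ModelSpec(seed=0))
        margins = model.decision_function(df)
        probs = model.predict_proba(df).to_numpy()
        order = np.argsort(margins)
        assert (np.diff(probs[order]) >= 0).all()

    def test_model_json_round_trip(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        df = pd.DataFrame(rng.normal(size=(40, 2)) + y[:, None],
                          columns=["a", "b"])
        m = train_platform_model(df, y, ModelSpec(seed=0))
        from noduleomics.models import PlatformModel
        m2 = PlatformModel.from_json(m.to_json())
        assert np.allclose(m2.predict_proba(df), m.predict_proba(df))


class TestBootstrapAuc:
    def test_perfect_scores(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        y = np.r_[np.zeros(10), np.ones(10)].astype(int)
        mean, (lo, hi) = bootstrap_auc(scores, y, n_boot=200, seed=0)
        assert mean == 1.0 and (lo, hi) == (1.0, 1.0)

    def test_mean_close_to_plug_in(self):
        rng = np.random.default_rng(4)
        y = np.r_[np.zeros(50), np.ones(50)].astype(int)
        scores = rng.normal(size=100) + y
        mean, _ = bootstrap_auc(scores, y, n_boot=500, seed=0)
        assert abs(mean - rank_auc(scores, y)) < 0.03

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(6)
        y = np.r_[np.zeros(20), np.ones(20)].astype(int)
        scores = rng.normal(size=40) + y
        assert bootstrap_auc(scores, y, seed=7) == bootstrap_auc(scores, y, seed=7)
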