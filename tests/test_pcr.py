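"""Principal-component regression: oracle equivalence, CV selection, prediction."""

import numpy as np
import pandas as pd
import pytest

from phospec import preprocess, synthetic
from phospec.io import GridMismatchError, SpectrumSet
from phospec.pcr import (
    BootstrapConfig,
    RankError,
    bootstrap_train,
    fit_pcr,
    learning_curve,
    load_model,
    predict_available,
    resample_to_grid,
    save_model,
    select_components,
)


def _random_xy(rng, n=20, p=50, k_true=None):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(scale=0.1, size=n)
    return X, y


def _low_rank_xy(rng, n=60, p=30, k=3, noise=0.0):
    factors = rng.normal(size=(n, k))
    loadings = rng.normal(size=(k, p))
    X = factors @ loadings
    y = factors @ rng.normal(size=k)
    if noise:
        X = X + rng.normal(scale=noise, size=X.shape)
        y = y + rng.normal(scale=noise, size=n)
    return X, y


class TestFitPCR:
    def test_rank_one_latent_factor_fits_exactly(self, rng):
        latent = rng.normal(size=40)
        X = np.outer(latent, rng.normal(size=25))
        y = 2.0 + 3.0 * latent
        model = fit_pcr(X, y, n_components=1)
        resid = model.predict_matrix(X) - y
        assert np.max(np.abs(resid)) < 1e-10

    def test_full_rank_matches_pseudo_inverse_oracle(self, rng):
        """100 random 20x50 trials: PCR at full rank equals direct least squares."""
        for _ in range(100):
            X, y = _random_xy(rng)
            Xc = X - X.mean(axis=0)
            model = fit_pcr(X, y, n_components=19)  # rank of centered 20-row X
            # independent oracle: minimum-norm least squares on centered X
            beta = np.linalg.pinv(Xc) @ (y - y.mean())
            oracle = Xc @ beta + y.mean()
            np.testing.assert_allclose(model.predict_matrix(X), oracle, atol=1e-8)

    def test_row_permutation_invariance(self, rng):
        X, y = _random_xy(rng, n=30, p=12)
        perm = rng.permutation(30)
        m1 = fit_pcr(X, y, 5)
        m2 = fit_pcr(X[perm], y[perm], 5)
        # loadings may flip sign; compare predictions instead of coefficients
        np.testing.assert_allclose(
            m1.predict_matrix(X), m2.predict_matrix(X), atol=1e-10
        )

    def test_rank_deficiency_raises(self, rng):
        X, _ = _low_rank_xy(rng, n=20, p=10, k=2)
        with pytest.raises(RankError):
            fit_pcr(X, np.zeros(20), n_components=8)

    def test_missing_values_rejected(self, rng):
        X, y = _random_xy(rng, n=10, p=5)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_pcr(X, y, 2)

    def test_affine_equivariance_of_predictions(self, rng):
        X, y = _random_xy(rng, n=25, p=10)
        m1 = fit_pcr(X, y, 4)
        m2 = fit_pcr(X, y + 11.5, 4)
        np.testing.assert_allclose(
            m2.predict_matrix(X), m1.predict_matrix(X) + 11.5, atol=1e-10
        )


class TestSelectComponents:
    def test_recovers_true_rank_on_noiseless_three_factor_data(self, rng):
        X, y = _low_rank_xy(rng, n=60, p=30, k=3)
        cv = select_components(X, y, folds=10, max_components=10, seed=0)
        assert cv.selected_components == 3

    def test_fixed_seed_reproducible(self, rng):
        X, y = _random_xy(rng, n=40, p=15)
        cv1 = select_components(X, y, folds=5, max_components=8, seed=3)
        cv2 = select_components(X, y, folds=5, max_components=8, seed=3)
        assert cv1.selected_components == cv2.selected_components
        np.testing.assert_array_equal(cv1.msep_by_components, cv2.msep_by_components)

    def test_matches_brute_force_refit_per_fold(self, rng):
        """Independent oracle: explicit refit of fit_pcr per fold and count."""
        from phospec.pcr import _fold_assignment, TRANSFORMS

        X, y = _random_xy(rng, n=40, p=12)
        folds, kmax, seed = 5, 6, 11
        cv = select_components(X, y, folds=folds, max_components=kmax, seed=seed)
        fold_of_row = _fold_assignment(40, folds, seed, None)
        sq = np.zeros(kmax)
        cnt = np.zeros(kmax)
        for f in range(folds):
            te = fold_of_row == f
            for k in range(1, kmax + 1):
                m = fit_pcr(X[~te], y[~te], k)
                pred = m.predict_matrix(X[te])
                sq[k - 1] += np.sum((pred - y[te]) ** 2)
                cnt[k - 1] += te.sum()
        np.testing.assert_allclose(cv.msep_by_components, sq / cnt, atol=1e-10)

    def test_cv_never_trains_on_its_test_fold(self, rng):
        # canary: an outlier row predicted from other folds keeps a large error
        X, y = _low_rank_xy(rng, n=50, p=20, k=2, noise=0.01)
        y = y.copy()
        y[17] += 50.0  # canary target no other row supports
        cv = select_components(X, y, folds=10, max_components=5, seed=2)
        # if the canary leaked into training, MSEP could approach the noise floor
        assert cv.msep_by_components.min() > 1.0

    def test_groups_stay_whole_within_folds(self, rng):
        from phospec.pcr import _fold_assignment

        groups = np.repeat(np.arange(12), 3)
        fold_of_row = _fold_assignment(36, 4, 0, groups)
        df = pd.DataFrame({"g": groups, "f": fold_of_row})
        assert (df.groupby("g")["f"].nunique() == 1).all()

    def test_max_components_capped_at_rank(self, rng):
        X, y = _low_rank_xy(rng, n=30, p=10, k=3)
        cv = select_components(X, y, folds=5, max_components=9, seed=0)
        assert len(cv.msep_by_components) == 9
        assert cv.selected_components <= 3


class TestLearningCurve:
    def test_curve_equals_cv_msep(self, rng):
        X, y = _random_xy(rng, n=40, p=12)
        cv = select_components(X, y, folds=5, max_components=6, seed=4)
        curve = learning_curve(X, y, folds=5, max_components=6, seed=4)
        assert len(curve) == 6
        np.testing.assert_array_equal(curve["msep"].to_numpy(), cv.msep_by_components)
        assert curve.loc[curve["selected"], "n_components"].item() == cv.selected_components

    def test_non_increasing_up_to_true_rank_on_noiseless_data(self, rng):
        X, y = _low_rank_xy(rng, n=60, p=30, k=3)
        curve = learning_curve(X, y, folds=10, max_components=3, seed=0)
        msep = curve["msep"].to_numpy()
        assert np.all(np.diff(msep) <= 1e-12)


class TestBootstrapTrain:
    def test_degenerate_bootstrap_reduces_to_plain_fit(self, lab_training_matrix):
        processed = lab_training_matrix
        targets = processed.metadata["p_conc_uM"].astype(float)
        bcfg = BootstrapConfig(n_resamples=78, seed=5, with_replacement=False)
        model, cv = bootstrap_train(processed, targets, bcfg, max_components=20)
        cv_plain = select_components(
            processed.absorbance,
            np.log10(targets.to_numpy()),
            folds=10,
            max_components=20,
            seed=5,
        )
        np.testing.assert_allclose(
            cv.msep_by_components, cv_plain.msep_by_components, atol=1e-12
        )

    def test_default_dataset_msep_meets_selection_criterion(self, trained_model):
        _, cv = trained_model
        assert cv.msep <= 0.01  # log10-uM scale

    def test_selection_stable_across_bootstrap_seeds(self, lab_training_matrix, trained_model):
        processed = lab_training_matrix
        targets = processed.metadata["p_conc_uM"].astype(float)
        _, cv_a = trained_model  # seed 7
        _, cv_b = bootstrap_train(
            processed, targets, BootstrapConfig(n_resamples=6000, seed=13)
        )
        assert abs(cv_a.selected_components - cv_b.selected_components) <= 5

    def test_too_few_resamples_rejected(self, lab_training_matrix):
        processed = lab_training_matrix
        targets = processed.metadata["p_conc_uM"].astype(float)
        with pytest.raises(ValueError, match="folds"):
            bootstrap_train(processed, targets, BootstrapConfig(n_resamples=5))


class TestPredictAvailable:
    def test_full_rank_noiseless_interpolates_training_targets(self, rng):
        grid = np.arange(600.0, 660.0, 2.0)
        X = rng.normal(size=(12, grid.size))
        y = rng.uniform(1.0, 100.0, size=12)
        sset = SpectrumSet(grid, X, [f"s{i}" for i in range(12)])
        model = fit_pcr(X, y, n_components=11, training_grid=grid)
        pred = predict_available(model, sset)
        np.testing.assert_allclose(pred.to_numpy(), y, atol=1e-8)

    def test_mean_spectrum_predicts_intercept(self, rng):
        X, y = _random_xy(rng, n=25, p=10)
        model = fit_pcr(X, y, 4)
        pred = model.predict_matrix(X.mean(axis=0)[None, :])
        assert pred[0] == pytest.approx(y.mean(), abs=1e-10)

    def test_held_out_r2_at_default_snr(self, held_out_r2):
        assert held_out_r2 >= 0.95

    def test_prediction_bias_per_design_level(self):
        """Predicted log10 P bias at each design level < 0.1, pooled over 20
        seeded replicates (train on one dataset, predict a fresh one)."""
        errors: dict[float, list[float]] = {p: [] for p in synthetic.P_LEVELS_UM}
        cfg = preprocess.PreprocessConfig(normalization_scope="none")
        for seed in range(200, 220):
            sset, _ = synthetic.simulate_lab_dataset(seed)
            processed, _ = preprocess.run_preprocess(sset, cfg)
            targets = processed.metadata["p_conc_uM"].astype(float)
            model, _ = bootstrap_train(
                processed, targets, BootstrapConfig(n_resamples=1500, seed=seed)
            )
            eval_set, _ = synthetic.simulate_lab_dataset(seed + 5000)
            eval_proc, _ = preprocess.run_preprocess(eval_set, cfg)
            levels = eval_proc.metadata["p_conc_uM"].astype(float)
            pred = predict_available(model, eval_proc)
            for p in synthetic.P_LEVELS_UM:
                ids = levels.index[levels == p]
                errors[p].append(
                    float(np.mean(np.log10(pred.loc[ids]) - np.log10(p)))
                )
        for p, errs in errors.items():
            assert abs(np.mean(errs)) < 0.1, f"bias at {p} uM"

    def test_grid_mismatch_is_a_hard_error(self, lab_processed):
        processed, _ = lab_processed
        targets = processed.metadata["p_conc_uM"].astype(float)
        model, _ = bootstrap_train(
            processed, targets, BootstrapConfig(n_resamples=100, seed=1), max_components=5
        )
        shifted = SpectrumSet(
            processed.wavenumbers[:-1],
            processed.absorbance[:, :-1],
            processed.sample_ids,
            processed.metadata,
        )
        with pytest.raises(GridMismatchError):
            predict_available(model, shifted)

    def test_resample_to_grid_enables_prediction(self, lab_processed):
        processed, _ = lab_processed
        coarse = SpectrumSet(
            processed.wavenumbers[::2],
            processed.absorbance[:, ::2],
            processed.sample_ids,
            processed.metadata,
        )
        back = resample_to_grid(coarse, processed.wavenumbers[:-1])
        assert back.wavenumbers.size == processed.wavenumbers.size - 1


class TestSerialization:
    def test_model_round_trips_through_json(self, tmp_path, rng):
        X, _ = _random_xy(rng, n=25, p=10)
        y = rng.uniform(1.0, 500.0, size=25)  # positive: log10 target scale
        model = fit_pcr(X, y, 4, target_transform="log10", training_grid=np.arange(10.0))
        path = tmp_path / "model.json"
        save_model(model, str(path))
        back = load_model(str(path))
        np.testing.assert_array_equal(back.loadings, model.loadings)
        np.testing.assert_array_equal(back.coefficients, model.coefficients)
        assert back.target_transform == "log10"
        np.testing.assert_allclose(
            back.predict_matrix(X), model.predict_matrix(X), rtol=1e-12
        )


class TestSklearnOracle:
    def test_pcr_matches_sklearn_pca_regression(self, rng):
        """Dual-route check: PCA + linear regression from scikit-learn."""
        from sklearn.decomposition import PCA
        from sklearn.linear_model import LinearRegression

        X, y = _random_xy(rng, n=40, p=15)
        k = 6
        model = fit_pcr(X, y, k)
        pca = PCA(n_components=k).fit(X)
        scores = pca.transform(X)
        reg = LinearRegression().fit(scores, y)
        oracle = reg.predict(pca.transform(X))
        np.testing.assert_allclose(model.predict_matrix(X), oracle, atol=1e-8)
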