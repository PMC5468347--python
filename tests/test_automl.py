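import numpy as np
import pytest

import matsec as ms
from matsec.automl import (
    Configuration,
    SelectorSpec,
    bbc_correct,
    cross_validate,
    default_grid,
    make_config_grid,
    select_and_finalize,
    select_features,
    training_windows,
)
from matsec.metrics import auc
from .conftest import RIDGE_GRID_SPEC, rng_for


def _planted(rng, n=120, p=40, informative=2, beta=2.0):
    X = rng.normal(size=(n, p))
    z = X[:, :informative] @ np.full(informative, beta)
    y = rng.random(n) < 1 / (1 + np.exp(-z))
    y[:2] = [True, False]
    return X, y


class TestConfigGrid:
    def test_cartesian_product_arithmetic(self):
        grid = make_config_grid(
            {
                "alphas": [0.01, 0.05],
                "max_features": [25, 50],
                "classifiers": [
                    {"family": "ridge-logistic", "penalty": 1.0},
                    {"family": "ridge-logistic", "penalty": 10.0},
                ],
            }
        )
        assert len(grid) == 8

    def test_linear_only_drops_forests_and_kernels(self):
        grid = default_grid(linear_only=True)
        assert {c.family for c in grid} == {"ridge-logistic", "linear-svm"}

    def test_default_grid_size_and_determinism(self):
        a, b = default_grid(), default_grid()
        assert len(a) == 28
        assert [c.id for c in a] == [c.id for c in b]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            make_config_grid({"selectors": [{"alpha": 0.05}], "classifiers": []})


class TestSelectFeatures:
    def test_label_copy_column_selected_first(self):
        rng = rng_for("select-copy")
        X = rng.normal(size=(80, 30))
        y = rng.random(80) < 0.5
        X[:, 17] = y.astype(float)
        res = select_features(X, y, SelectorSpec(alpha=0.05, max_features=10))
        assert res.primary[0] == 17

    def test_duplicated_column_lands_in_alternate_signature(self):
        rng = rng_for("select-dup")
        X = rng.normal(size=(100, 20))
        y = X[:, 3] + 0.3 * rng.normal(size=100) > 0
        X[:, 11] = X[:, 3]  # exact duplicate of the informative column
        res = select_features(
            X, y, SelectorSpec(alpha=0.05, max_features=5), record_equivalents=True
        )
        assert (3 in res.primary) != (11 in res.primary)
        chosen, twin = (3, 11) if 3 in res.primary else (11, 3)
        assert twin in res.substitutes.get(chosen, [])
        assert any(twin in sig for sig in res.alternates)

    def test_pure_noise_keeps_signature_small(self):
        sizes = []
        for rep in range(10):
            rng = rng_for(f"select-noise-{rep}")
            X = rng.normal(size=(100, 100))
            y = rng.random(100) < 0.5
            y[:2] = [True, False]
            res = select_features(X, y, SelectorSpec(alpha=0.05, max_features=50))
            sizes.append(len(res.primary))
        assert np.mean(sizes) < 10

    def test_constant_labels_give_empty_signature(self):
        rng = rng_for("select-constant")
        X = rng.normal(size=(30, 5))
        assert select_features(X, np.ones(30, bool)).primary == []


class TestCrossValidate:
    def test_separable_data_scores_high(self, ridge_grid):
        rng = rng_for("cv-separable")
        X = rng.normal(size=(150, 30))
        # almost-noiseless linear rule: genuinely separable classes
        y = X[:, 0] + X[:, 1] + 0.05 * rng.normal(size=150) > 0
        cv = cross_validate(X, y, ridge_grid, K=5, seed=1)
        assert cv.mean_fold_auc.max() >= 0.95

    def test_permuted_labels_stay_near_chance(self, ridge_grid):
        rng = rng_for("cv-null")
        X = rng.normal(size=(200, 30))
        y = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        y = rng.permutation(y)
        cv = cross_validate(X, y, ridge_grid, K=5, seed=1)
        assert np.all(np.abs(cv.mean_fold_auc - 0.5) < 0.1)

    def test_fold_assignment_reproducible(self, ridge_grid):
        rng = rng_for("cv-folds")
        X, y = _planted(rng)
        a = cross_validate(X, y, ridge_grid, K=5, seed=3)
        b = cross_validate(X, y, ridge_grid, K=5, seed=3)
        assert np.array_equal(a.fold_of, b.fold_of)
        assert np.array_equal(a.oof, b.oof)

    def test_stratification_keeps_class_balance_per_fold(self, ridge_grid):
        rng = rng_for("cv-strat")
        X, y = _planted(rng, n=100)
        cv = cross_validate(X, y, ridge_grid, K=5, seed=0)
        global_rate = y.mean()
        for f in range(5):
            fold_rate = y[cv.fold_of == f].mean()
            assert abs(fold_rate - global_rate) <= 1.5 / (y.size / 5)

    def test_small_class_rejected_with_hint(self, ridge_grid):
        X = np.zeros((12, 3))
        y = np.r_[np.ones(3, bool), np.zeros(9, bool)]
        with pytest.raises(ValueError, match="smaller K"):
            cross_validate(X, y, ridge_grid, K=5)

    def test_fit_accounting_n_times_k(self, ridge_grid):
        rng = rng_for("cv-fits")
        X, y = _planted(rng)
        cv = cross_validate(X, y, ridge_grid, K=5, seed=0)
        assert cv.n_fits == len(ridge_grid) * 5

    def test_no_leak_from_held_out_rows(self, ridge_grid):
        """Selection fitted on training folds must not change when the
        held-out rows are corrupted."""
        rng = rng_for("cv-leak")
        X, y = _planted(rng, n=100, p=25)
        cv = cross_validate(X, y, ridge_grid, K=5, seed=2)
        fold0 = cv.fold_of == 0
        X_bad = X.copy()
        X_bad[fold0] = 1e6  # garbage in the held-out rows of fold 0
        sel_key = ridge_grid[0].selector
        redo = select_features(X_bad[~fold0], y[~fold0], sel_key)
        assert redo.primary == cv.selections[(0, sel_key.key())]


class TestFinalize:
    def test_single_configuration_wins_trivially(self):
        rng = rng_for("finalize-single")
        X, y = _planted(rng)
        grid = make_config_grid(
            {
                "selectors": [{"alpha": 0.05, "max_features": 10}],
                "classifiers": [{"family": "ridge-logistic", "penalty": 1.0}],
            }
        )
        cv = cross_validate(X, y, grid, K=5, seed=0)
        fit = select_and_finalize(X, y, cv, seed=0)
        assert fit.config is grid[0]
        assert fit.n_fits_total == 5 + 1

    def test_dominating_configuration_selected(self):
        rng = rng_for("finalize-dominate")
        X, y = _planted(rng, beta=3.0)
        grid = [
            Configuration(SelectorSpec(0.05, 10), "ridge-logistic", (("penalty", 1.0),)),
            # alpha so strict nothing is ever selected -> intercept fallback
            Configuration(SelectorSpec(1e-12, 10), "ridge-logistic", (("penalty", 1.0),)),
        ]
        cv = cross_validate(X, y, grid, K=5, seed=0)
        assert select_and_finalize(X, y, cv, seed=0).config is grid[0]

    def test_final_model_scores_are_probabilities(self, fixture_records, ridge_grid):
        model = ms.train_view(
            fixture_records, "mature", groups=["kmer1"], grid=ridge_grid, K=5,
            seed=0, bbc_B=0,
        )
        windows, _ = training_windows(fixture_records, "mature")
        from matsec.predict import score_window

        probs = [score_window(model, w) for w in windows[:10]]
        assert all(0.0 < p < 1.0 for p in probs)


class TestBbcCorrect:
    def test_single_configuration_matches_pooled_cv_auc(self):
        rng = rng_for("bbc-single")
        y = rng.random(150) < 0.5
        y[:2] = [True, False]
        scores = y + rng.normal(scale=0.8, size=150)
        corrected, (lo, hi), skipped = bbc_correct(scores[:, None], y, B=400, seed=0)
        assert skipped == 0
        assert corrected == pytest.approx(auc(scores, y), abs=0.03)
        assert lo <= corrected <= hi

    def test_deterministic_for_fixed_seed(self):
        rng = rng_for("bbc-seeded")
        S = rng.normal(size=(80, 5))
        y = np.r_[np.ones(40, bool), np.zeros(40, bool)]
        a = bbc_correct(S, y, B=200, seed=9)
        b = bbc_correct(S, y, B=200, seed=9)
        assert a == b

    def test_conservative_under_the_null(self):
        for rep in range(5):
            rng = rng_for(f"bbc-null-{rep}")
            S = rng.normal(size=(120, 10))
            y = np.r_[np.ones(60, bool), np.zeros(60, bool)]
            corrected, _, _ = bbc_correct(S, y, B=300, seed=rep)
            from matsec.metrics import auc_columns

            assert corrected <= auc_columns(S, y).max()


class TestTrainView:
    def test_model_json_roundtrip(self, fixture_records, ridge_grid, tmp_path):
        model = ms.train_view(
            fixture_records, "mature", groups=["kmer1"], grid=ridge_grid,
            K=5, seed=4, bbc_B=100,
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = ms.TrainedModel.from_json(path)
        assert back.selected_features == model.selected_features
        assert back.coefficients == pytest.approx(model.coefficients)
        assert back.threshold == model.threshold
        assert back.provenance["n_fits"] == len(ridge_grid) * 5 + 1

    def test_mature_view_requires_cleavage_for_secretory(self):
        recs = [
            ms.SequenceRecord("s", "M" * 100, "secretory"),  # no cleavage
            ms.SequenceRecord("c", "M" * 100, "cytoplasmic"),
        ]
        with pytest.raises(ValueError, match="cleavage"):
            training_windows(recs, "mature")
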