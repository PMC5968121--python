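import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from maxsdm import MaxEntSDM
from maxsdm.model import fit_maxent, penalized_objective


class TestSolver:
    def test_no_signal_gives_zero_weights_and_uniform_output(self):
        rng = np.random.default_rng(0)
        F_bg = rng.uniform(size=(200, 3))
        # presences drawn uniformly from the background: no signal
        F_pres = F_bg[rng.choice(200, 100, replace=False)]
        fit = fit_maxent(F_pres, F_bg, betas=np.full(3, 1.0), tol=1e-8)
        assert np.max(np.abs(fit.lambdas)) < 0.2
        q = np.exp(F_bg @ fit.lambdas - fit.log_z)
        assert q.max() / q.min() < 1.5

    def test_one_feature_matches_grid_search_oracle(self):
        # two-cell landscape, one binary feature, presences concentrated at
        # f=1; a positive penalty keeps the optimum finite
        F_bg = np.array([[0.0], [1.0]])
        F_pres = np.ones((8, 1))
        beta = np.array([0.5])

        def neg_obj(lam):
            return -penalized_objective(np.array([lam]), F_pres, F_bg, beta)

        # brute-force 1-D grid search refined by a scalar minimizer
        grid = np.linspace(-10, 10, 20001)
        coarse = grid[np.argmin([neg_obj(l) for l in grid])]
        res = minimize_scalar(neg_obj, bracket=(coarse - 0.1, coarse, coarse + 0.1))
        fit = fit_maxent(F_pres, F_bg, beta, tol=1e-12, max_iter=10000)
        assert fit.lambdas[0] == pytest.approx(res.x, abs=1e-4)

    def test_regularized_gain_trajectory_is_non_decreasing(self, signal_data):
        m = MaxEntSDM(
            feature_classes=("L", "Q"), reg_multiplier=2.0,
            categorical=("landcover",),
        ).fit(signal_data["X"], signal_data["y"])
        assert np.all(np.diff(m.gain_trajectory_) >= -1e-12)

    def test_unregularized_gain_is_non_decreasing_at_beta_zero(self, signal_data):
        m = MaxEntSDM(
            feature_classes=("L", "Q"), reg_multiplier=0.0,
            categorical=("landcover",),
        ).fit(signal_data["X"], signal_data["y"])
        assert np.all(np.diff(m.gain_trajectory_) >= -1e-12)

    def test_constraint_matching_at_beta_zero(self, signal_data):
        # at convergence with no penalty, model feature expectations over the
        # background match empirical presence feature means
        m = MaxEntSDM(
            feature_classes=("L", "Q"), reg_multiplier=0.0,
            categorical=("landcover",), tol=1e-10, max_iter=20000,
        ).fit(signal_data["X"], signal_data["y"])
        F = m.expander_.transform(signal_data["X"])
        y = signal_data["y"]
        F_pres, F_bg = F[y == 1], F[y == 0]
        s = F_bg @ m.lambdas_
        w = np.exp(s - s.max())
        w /= w.sum()
        assert np.max(np.abs(F_bg.T @ w - F_pres.mean(axis=0))) < 1e-3

    def test_monotone_sparsity_in_regularization(self, signal_data):
        counts = []
        for reg in (1.0, 300.0):
            m = MaxEntSDM(
                feature_classes=("L", "Q", "H"), reg_multiplier=reg,
                categorical=("landcover",),
            ).fit(signal_data["X"], signal_data["y"])
            counts.append(m.nonzero_count())
        assert counts[1] <= counts[0]

    def test_non_finite_features_rejected(self):
        F = np.array([[0.1], [np.inf]])
        with pytest.raises(ValueError, match="non-finite"):
            fit_maxent(F, F, np.zeros(1))


class TestPrediction:
    def test_zero_lambda_model_is_uniform(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame({"v": rng.uniform(size=50)})
        # presences = a uniform sample of background -> lambdas ~ 0
        Xall = pd.concat([X.iloc[:25], X], ignore_index=True)
        y = np.r_[np.ones(25), np.zeros(50)]
        m = MaxEntSDM(feature_classes=("L",), reg_multiplier=5.0).fit(Xall, y)
        if m.nonzero_count() == 0:
            q = m.predict_raw(X)
            assert np.allclose(q, 1.0 / 50)

    def test_raw_sums_to_one_over_training_background(self, fitted_model, signal_data):
        raw = fitted_model.predict_raw(signal_data["X_bg"])
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)

    def test_doubling_a_positive_weight_boosts_its_top_cell(self, signal_data):
        # brute-force recomputation on a 10-cell toy
        m = MaxEntSDM(feature_classes=("L", "Q"), categorical=("landcover",)).fit(
            signal_data["X"], signal_data["y"]
        )
        X10 = signal_data["X_bg"].iloc[:10]
        F = m.expander_.transform(X10)
        j = int(np.argmax(m.lambdas_))
        assert m.lambdas_[j] > 0
        top = int(np.argmax(F[:, j]))
        other = int(np.argmin(F[:, j]))
        lam2 = m.lambdas_.copy()
        lam2[j] *= 2
        q1 = np.exp(F @ m.lambdas_)
        q2 = np.exp(F @ lam2)
        assert q2[top] / q2[other] > q1[top] / q1[other]

    def test_logistic_typical_site_scores_half(self, fitted_model, signal_data):
        # a cell with raw probability exactly exp(-H) maps to 0.5
        q_typ = np.exp(-fitted_model.entropy_)
        c = np.exp(fitted_model.entropy_)
        assert c * q_typ / (1 + c * q_typ) == pytest.approx(0.5)

    def test_logistic_uniform_four_cell_toy(self):
        X = pd.DataFrame({"v": [0.0, 1.0, 2.0, 3.0]})
        Xall = pd.concat([X, X], ignore_index=True)
        y = np.r_[np.ones(4), np.zeros(4)]
        m = MaxEntSDM(feature_classes=("L",), tol=1e-10).fit(Xall, y)
        # presences mirror the background exactly: uniform raw output 1/4,
        # H = ln 4, so every logistic value is 0.5
        assert np.allclose(m.predict_logistic(X), 0.5, atol=1e-6)

    def test_logistic_monotone_and_vanishing(self, fitted_model, signal_data):
        q = fitted_model.predict_raw(signal_data["X_bg"])
        lg = fitted_model.predict_logistic(signal_data["X_bg"])
        order = np.argsort(q)
        assert np.all(np.diff(lg[order]) >= -1e-15)
        assert np.all(lg > 0) and np.all(lg < 1)


class TestResponseCurves:
    def test_strong_linear_signal_gives_increasing_curve(self):
        rng = np.random.default_rng(2)
        bg = pd.DataFrame({"v": rng.uniform(0, 1, 400), "w": rng.uniform(0, 1, 400)})
        p = np.exp(4 * bg["v"]) / np.exp(4 * bg["v"]).sum()
        pres = bg.iloc[rng.choice(400, 300, p=p)]
        X = pd.concat([pres, bg], ignore_index=True)
        y = np.r_[np.ones(len(pres)), np.zeros(len(bg))]
        m = MaxEntSDM(feature_classes=("L",)).fit(X, y)
        grid, suit = m.response_curve("v", n_points=25)
        assert np.all(np.diff(suit) > 0)

    def test_no_signal_curve_is_flat(self, signal_data):
        rng = np.random.default_rng(3)
        bg = pd.DataFrame({"v": rng.uniform(size=200), "w": rng.uniform(size=200)})
        pres = bg.iloc[rng.choice(200, 100)]
        X = pd.concat([pres, bg], ignore_index=True)
        y = np.r_[np.ones(100), np.zeros(200)]
        m = MaxEntSDM(feature_classes=("L",), reg_multiplier=10.0).fit(X, y)
        grid, suit = m.response_curve("v", n_points=10)
        assert np.ptp(suit) < 0.05

    def test_unknown_variable_rejected(self, fitted_model):
        with pytest.raises(KeyError, match="ghost"):
            fitted_model.response_curve("ghost")

    def test_categorical_curve_sweeps_levels(self, fitted_model):
        grid, suit = fitted_model.response_curve("landcover")
        assert list(grid) == [1, 2, 3]
        assert len(suit) == 3


class TestEstimatorContract:
    def test_requires_binary_target(self, signal_data):
        with pytest.raises(ValueError, match="binary"):
            MaxEntSDM().fit(signal_data["X"], np.full(len(signal_data["X"]), 2))

    def test_get_params_round_trip(self):
        m = MaxEntSDM(reg_multiplier=3.0, feature_classes=("L",))
        m2 = MaxEntSDM(**m.get_params())
        assert m2.reg_multiplier == 3.0 and m2.feature_classes == ("L",)

    def test_lambdas_text_serialization(self, fitted_model):
        text = fitted_model.to_lambdas_text()
        assert "logZ" in text and "entropy" in text
        assert len(text.strip().splitlines()) == 5 + len(fitted_model.lambdas_)
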