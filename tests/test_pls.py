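"""NIPALS PLS, LOO cross-validation, component selection, fit statistics."""

import numpy as np
import pytest

from qsarfield.fields import FieldBlock, GridSpec
from qsarfield.pls import (
    field_contributions,
    fit_pls,
    fit_statistics,
    loo_q2,
    predict,
    select_onc,
)


def _toy_block(matrix, kinds_per_col):
    kinds = tuple(dict.fromkeys(kinds_per_col))
    n_nodes = matrix.shape[1]
    grid = GridSpec((0.0, 0.0, 0.0), 1.0, (n_nodes, 1, 1))
    return FieldBlock(
        matrix=np.asarray(matrix, dtype=float),
        column_kinds=np.array(kinds_per_col, dtype=object),
        column_nodes=np.arange(n_nodes),
        kept_mask={k: np.array([c == k for c in kinds_per_col]) for k in kinds},
        scale_factors={k: 1.0 for k in kinds},
        grid=grid,
        kinds=kinds,
    )


class TestFit:
    def test_exact_linear_single_column(self):
        x = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = 2.0 * x[:, 0] + 1.0
        model = fit_pls(x, y, 1)
        r2, see, _ = fit_statistics(model, x, y)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert see == pytest.approx(0.0, abs=1e-10)

    def test_full_rank_equals_least_squares(self, rng):
        x = rng.normal(size=(9, 4))
        y = rng.normal(size=9)
        model = fit_pls(x, y, 4)
        # independent normal-equations oracle on centered data
        xc = x - x.mean(axis=0)
        beta, *_ = np.linalg.lstsq(xc, y - y.mean(), rcond=None)
        yhat_oracle = y.mean() + xc @ beta
        assert np.allclose(predict(model, x), yhat_oracle, atol=1e-8)

    def test_prediction_at_mean_point(self, rng):
        x = rng.normal(size=(10, 6))
        y = rng.normal(size=10)
        model = fit_pls(x, y, 3)
        assert predict(model, x.mean(axis=0)) == pytest.approx(y.mean(), abs=1e-10)

    def test_scores_orthogonal(self, rng):
        x = rng.normal(size=(15, 20))
        y = x[:, 0] + 0.5 * x[:, 3] + rng.normal(0, 0.2, 15)
        model = fit_pls(x, y, 5)
        t = model.scores
        gram = t.T @ t
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_dimension_mismatch(self, rng):
        model = fit_pls(rng.normal(size=(6, 3)), rng.normal(size=6), 2)
        with pytest.raises(ValueError, match="column count"):
            predict(model, np.zeros((2, 5)))

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            fit_pls(np.eye(4), np.ones(4), 1)


class TestLOO:
    def test_matches_bruteforce_refit_loop(self):
        x = np.array([[0.0, 0.3], [1.0, -0.2], [2.0, 0.1], [3.0, -0.4]])
        y = 2.0 * x[:, 0]
        report = loo_q2(x, y, 1)
        press = 0.0
        for i in range(4):
            mask = np.ones(4, dtype=bool)
            mask[i] = False
            m = fit_pls(x[mask], y[mask], 1)
            press += float((predict(m, x[i])[0] - y[i]) ** 2)
        assert report.press_by_component[0] == pytest.approx(press, abs=1e-10)
        tss = np.sum((y - y.mean()) ** 2)
        assert report.q2_by_component[0] == pytest.approx(1 - press / tss, abs=1e-12)

    def test_full_rank_matches_least_squares_loo(self, rng):
        # at full rank PLS is ordinary least squares, so an lstsq-based LOO
        # loop is a fully independent oracle
        x = rng.normal(size=(10, 3))
        y = x @ np.array([1.0, -2.0, 0.5]) + rng.normal(0, 0.3, 10)
        report = loo_q2(x, y, 3)
        press = 0.0
        for i in range(10):
            mask = np.ones(10, dtype=bool)
            mask[i] = False
            xc = x[mask] - x[mask].mean(axis=0)
            beta, *_ = np.linalg.lstsq(xc, y[mask] - y[mask].mean(), rcond=None)
            pred = y[mask].mean() + (x[i] - x[mask].mean(axis=0)) @ beta
            press += float((pred - y[i]) ** 2)
        assert report.press_by_component[2] == pytest.approx(press, abs=1e-10)

    def test_constant_response_rejected(self):
        with pytest.raises(ValueError):
            loo_q2(np.eye(5), np.ones(5), 1)

    def test_strong_signal_high_q2(self, rng):
        x = rng.normal(size=(30, 10))
        y = 2.0 * x[:, 0] + rng.normal(0, 0.1, 30)
        report = loo_q2(x, y, 3)
        assert report.q2 > 0.9

    def test_q2_not_above_r2(self, rng):
        for _ in range(3):
            x = rng.normal(size=(12, 8))
            y = x[:, 0] + rng.normal(0, 0.5, 12)
            report = loo_q2(x, y, 3)
            model = fit_pls(x, y, report.onc)
            r2, _, _ = fit_statistics(model, x, y)
            assert report.q2 <= r2 + 1e-12

    def test_noise_columns_never_help(self, rng):
        # appending pure-noise columns cannot raise cross-validated
        # predictivity beyond sampling tolerance
        diffs = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.normal(size=(20, 4))
            y = x[:, 0] - x[:, 1] + r.normal(0, 0.3, 20)
            base = loo_q2(x, y, 3).q2
            noisy = loo_q2(np.hstack([x, r.normal(size=(20, 30))]), y, 3).q2
            diffs.append(noisy - base)
        assert max(diffs) < 0.05


class TestONC:
    def test_parsimony_rule(self):
        assert select_onc([0.50, 0.778, 0.779], 0.05) == 2

    def test_monotone_decreasing(self):
        assert select_onc([0.8, 0.7, 0.6], 0.05) == 1

    def test_zero_tolerance_is_argmax(self):
        assert select_onc([0.3, 0.9, 0.9, 0.8], 0.0) == 2


class TestFitStatistics:
    def test_perfect_fit_sentinels(self):
        x = np.array([[0.0], [1.0], [2.0], [3.0], [4.0]])
        y = 3.0 * x[:, 0]
        model = fit_pls(x, y, 1)
        r2, see, f = fit_statistics(model, x, y)
        assert see == pytest.approx(0.0, abs=1e-10)
        assert np.isinf(f)

    def test_independent_residual_oracle(self, rng):
        x = rng.normal(size=(12, 5))
        y = x[:, 0] + rng.normal(0, 0.4, 12)
        model = fit_pls(x, y, 2)
        _, see, _ = fit_statistics(model, x, y)
        resid = y - (model.y_mean + (x - model.x_means) @ model.coefficients)
        see_oracle = np.sqrt(float(resid @ resid) / (12 - 2 - 1))
        assert see == pytest.approx(see_oracle, abs=1e-10)

    def test_cross_check_against_sklearn(self, rng):
        # external PLS used strictly as an oracle for the fitted values
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        x = rng.normal(size=(14, 25))
        y = x[:, 2] - 0.5 * x[:, 10] + rng.normal(0, 0.2, 14)
        model = fit_pls(x, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(x, y)
        assert np.allclose(predict(model, x), ref.predict(x).ravel(), atol=1e-6)


class TestContributions:
    def test_single_field_is_unity(self, rng):
        block = _toy_block(rng.normal(size=(8, 3)), ["steric"] * 3)
        model = fit_pls(block, rng.normal(size=8), 2)
        contrib = field_contributions(model, block)
        assert contrib == {"steric": pytest.approx(1.0)}

    def test_fractions_sum_to_one(self, rng):
        block = _toy_block(
            rng.normal(size=(10, 6)),
            ["steric", "steric", "hydrophobic", "hydrophobic", "donor", "donor"],
        )
        model = fit_pls(block, rng.normal(size=10), 3)
        contrib = field_contributions(model, block)
        assert sum(contrib.values()) == pytest.approx(1.0, abs=1e-6)
        assert all(v >= 0 for v in contrib.values())
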