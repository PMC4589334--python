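"""Quadratic discriminant: fitting, scoring, prediction, R correction,
serialization — each checked against an independent oracle where one exists."""

import io as stdio

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from cshairpin.exceptions import (
    ContractError,
    FormatError,
    MissingClassError,
    SingularCovarianceError,
    UndefinedRError,
)
from cshairpin.features import FeatureMatrix
from cshairpin.io import Label
from cshairpin.qda import (
    ClassModel,
    apply_r_correction,
    eta,
    fit,
    load_model,
    mahalanobis_sq,
    predict,
    predict_matrix,
    r_coefficient,
    save_model,
)

H, N = Label.HAIRPIN, Label.NOT_HAIRPIN


def matrix_from(rows_h, rows_n, names=None):
    rows_h, rows_n = np.atleast_2d(rows_h), np.atleast_2d(rows_n)
    d = rows_h.shape[1]
    names = names or tuple(f"f{i}" for i in range(d))
    X = np.vstack([rows_h, rows_n])
    labels = [H] * len(rows_h) + [N] * len(rows_n)
    ids = [f"s{i}" for i in range(len(X))]
    return FeatureMatrix(names, X, labels, ids)


def random_matrix(rng, d, n_h, n_n, spread=1.0, sep=1.0):
    a = rng.standard_normal((d, d))
    cov = a @ a.T + d * np.eye(d)
    mu_h = rng.standard_normal(d) * spread
    mu_n = mu_h + sep
    rows_h = rng.multivariate_normal(mu_h, cov, size=n_h)
    rows_n = rng.multivariate_normal(mu_n, cov, size=n_n)
    return matrix_from(rows_h, rows_n)


def spd(rng, d):
    a = rng.standard_normal((d, d))
    return a @ a.T + d * np.eye(d)


class TestFit:
    def test_hand_arithmetic_singular_case(self):
        X = matrix_from([[0.0, 0.0], [2.0, 2.0]], [[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(SingularCovarianceError, match="epsilon"):
            fit(X, epsilon=0.0)
        model = fit(X, epsilon=1e-6)
        cm = model.classes[H]
        assert np.allclose(cm.mu, [1.0, 1.0])
        assert np.allclose(cm.sigma, [[1.0 + 1e-6, 1.0], [1.0, 1.0 + 1e-6]])
        assert np.isfinite(cm.log_det)

    def test_mean_and_covariance_match_brute_force_double_loop(self):
        rng = np.random.default_rng(0)
        X = random_matrix(rng, 4, 30, 20)
        model = fit(X)
        for label in (H, N):
            rows = X.rows_for(label)
            p, d = rows.shape
            mu = np.array([sum(rows[:, j]) / p for j in range(d)])
            sigma = np.zeros((d, d))
            for i in range(d):
                for j in range(d):
                    s = 0.0
                    for n in range(p):
                        s += (rows[n, i] - mu[i]) * (rows[n, j] - mu[j])
                    sigma[i, j] = s / p
            cm = model.classes[label]
            assert np.allclose(cm.mu, mu, atol=1e-10)
            assert np.allclose(cm.sigma, sigma, atol=1e-10)

    def test_duplicating_samples_leaves_fit_unchanged(self):
        rng = np.random.default_rng(1)
        X = random_matrix(rng, 3, 10, 10)
        doubled = matrix_from(
            np.vstack([X.rows_for(H)] * 2), np.vstack([X.rows_for(N)] * 2)
        )
        m1, m2 = fit(X), fit(doubled)
        for label in (H, N):
            assert np.allclose(m1.classes[label].mu, m2.classes[label].mu)
            assert np.allclose(m1.classes[label].sigma, m2.classes[label].sigma)
            assert m2.classes[label].p == 2 * m1.classes[label].p

    def test_unbiased_divisor_flag(self):
        rng = np.random.default_rng(2)
        X = random_matrix(rng, 3, 12, 9)
        ml, ub = fit(X), fit(X, unbiased=True)
        for label in (H, N):
            p = ml.classes[label].p
            assert np.allclose(
                ub.classes[label].sigma, ml.classes[label].sigma * p / (p - 1)
            )

    def test_single_sample_class_rejected(self):
        X = matrix_from([[0.0, 0.0]], [[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(MissingClassError):
            fit(X)


class TestMahalanobisAndEta:
    def cm(self, mu, sigma, p=10):
        sigma = np.asarray(sigma, dtype=float)
        chol = np.linalg.cholesky(sigma)
        log_det = 2 * float(np.sum(np.log(np.diag(chol))))
        return ClassModel(H, p, np.asarray(mu, dtype=float), sigma, log_det)

    def test_distance_zero_at_mean(self):
        cm = self.cm([1.0, 2.0], np.eye(2))
        assert mahalanobis_sq(cm, np.array([1.0, 2.0])) == pytest.approx(0.0)

    def test_identity_covariance_gives_euclidean(self):
        cm = self.cm([0.0, 0.0, 0.0], np.eye(3))
        x = np.array([1.0, 2.0, 2.0])
        assert mahalanobis_sq(cm, x) == pytest.approx(9.0)

    def test_matches_explicit_inverse_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = rng.integers(2, 8)
            sigma = spd(rng, d)
            mu = rng.standard_normal(d)
            x = rng.standard_normal(d)
            cm = self.cm(mu, sigma)
            expected = (x - mu) @ np.linalg.inv(sigma) @ (x - mu)
            assert mahalanobis_sq(cm, x) == pytest.approx(expected, abs=1e-8)

    def test_dimension_mismatch_rejected(self):
        cm = self.cm([0.0, 0.0], np.eye(2))
        with pytest.raises(ContractError):
            mahalanobis_sq(cm, np.zeros(3))

    def test_eta_vanishes_in_trivial_configuration(self):
        cm = self.cm([0.0, 0.0], np.eye(2), p=1)
        assert eta(cm, np.zeros(2)) == pytest.approx(0.0)

    def test_eta_linear_in_distance(self):
        cm = self.cm([0.0], np.eye(1), p=5)
        e1 = eta(cm, np.array([1.0]))  # delta = 1
        e2 = eta(cm, np.array([np.sqrt(2.0)]))  # delta = 2
        assert e1 - e2 == pytest.approx(0.5, abs=1e-12)

    def test_eta_difference_equals_expanded_discriminant(self):
        """eta_i - eta_j must equal the independently expanded log-odds
        ln(p_i/p_j) - (delta_i - delta_j)/2 - (1/2) ln(|S_i|/|S_j|)."""
        rng = np.random.default_rng(4)
        for _ in range(25):
            d = int(rng.integers(2, 7))
            X = random_matrix(rng, d, int(rng.integers(5, 40)), int(rng.integers(5, 40)))
            model = fit(X)
            x = rng.standard_normal(d)
            ci, cj = model.classes[H], model.classes[N]
            di = (x - ci.mu) @ np.linalg.inv(ci.sigma) @ (x - ci.mu)
            dj = (x - cj.mu) @ np.linalg.inv(cj.sigma) @ (x - cj.mu)
            xi_expanded = (
                np.log(ci.p / cj.p)
                - (di - dj) / 2
                - 0.5 * np.log(np.linalg.det(ci.sigma) / np.linalg.det(cj.sigma))
            )
            assert eta(ci, x) - eta(cj, x) == pytest.approx(xi_expanded, abs=1e-10)


class TestPredict:
    def test_argmax_and_xi(self):
        rng = np.random.default_rng(5)
        X = random_matrix(rng, 2, 20, 20, sep=4.0)
        model = fit(X)
        x = X.rows_for(H).mean(axis=0)
        r = predict(model, x)
        assert r.predicted is H
        assert r.xi == pytest.approx(r.eta[H] - r.eta[N], abs=0)
        assert not r.corrected

    def test_symmetric_midpoint_tie_goes_to_hairpin(self):
        rows_h = np.array([[-2.0, 0.0], [-1.0, 1.0], [-1.0, -1.0], [0.0, 0.0]])
        rows_n = -rows_h  # mirror image: equal p, mirrored means, shared Sigma
        model = fit(matrix_from(rows_h, rows_n))
        r = predict(model, np.zeros(2))
        assert abs(r.xi) < 1e-12
        assert r.predicted is H

    def test_agrees_with_dense_log_posterior_oracle(self):
        rng = np.random.default_rng(6)
        X = random_matrix(rng, 3, 40, 25, sep=1.5)
        model = fit(X)
        pts = rng.multivariate_normal(np.zeros(3), 4 * np.eye(3), size=200)
        for x in pts:
            scores = {
                lab: np.log(cm.p)
                + multivariate_normal(cm.mu, cm.sigma).logpdf(x)
                for lab, cm in model.classes.items()
            }
            expected = max(scores, key=scores.get)
            assert predict(model, x).predicted is expected

    def test_equal_covariance_limit_is_linear_boundary(self):
        """With a shared covariance and equal class sizes the decision matches
        the closed-form linear discriminant sign."""
        rng = np.random.default_rng(7)
        d = 4
        sigma = spd(rng, d)
        mu_h, mu_n = rng.standard_normal(d), rng.standard_normal(d)
        model = fit(matrix_from(rng.standard_normal((10, d)), rng.standard_normal((10, d))))
        # overwrite with an exactly shared covariance / equal counts
        for lab, mu in ((H, mu_h), (N, mu_n)):
            chol = np.linalg.cholesky(sigma)
            model.classes[lab] = ClassModel(
                lab, 10, mu, sigma, 2 * float(np.sum(np.log(np.diag(chol))))
            )
        w = np.linalg.solve(sigma, mu_h - mu_n)
        b = -0.5 * (mu_h + mu_n) @ w
        for x in rng.standard_normal((1000, d)) * 3:
            lda = H if x @ w + b >= 0 else N
            assert predict(model, x).predicted is lda

    def test_matrix_prediction_requires_matching_names(self):
        rng = np.random.default_rng(8)
        X = random_matrix(rng, 2, 5, 5)
        model = fit(X)
        other = FeatureMatrix(("a", "b"), X.X, X.labels, X.fragment_ids)
        with pytest.raises(ContractError):
            predict_matrix(model, other)


class TestRCorrection:
    def test_r_arithmetic(self):
        assert r_coefficient(2.0, 2.0) == 0.0
        assert r_coefficient(2.0, 1.0) == 0.5
        # negative-eta regime: (-2 - (-1)) / -2 = +0.5
        assert r_coefficient(-2.0, -1.0) == 0.5

    def test_r_undefined_at_zero(self):
        with pytest.raises(UndefinedRError):
            r_coefficient(0.0, 1.0)

    @staticmethod
    def pred(fid, eta_h, eta_n):
        from cshairpin.qda import PredictionResult

        pred = H if eta_h >= eta_n else N
        return PredictionResult(fid, {H: eta_h, N: eta_n}, pred, eta_h - eta_n)

    def test_threshold_behavior(self):
        # misclassified hairpin in the negative-eta regime: R = (-2 - -1)/-2 = 0.5
        far = self.pred("far", -2.0, -1.0)
        # another with R = (-10 - -9.5)/-10 = 0.05 -> corrected at 0.2
        near = self.pred("near", -10.0, -9.5)
        ok = self.pred("ok", 3.0, 1.0)
        preds, log = apply_r_correction([far, near, ok], [H, H, H], r_max=0.2)
        assert [p.corrected for p in preds] == [False, True, False]
        assert log.corrected == [("near", 0.05)]
        assert preds[1].r_value == pytest.approx(0.05)
        assert preds[0].r_value == pytest.approx(0.5)

    def test_positive_eta_misclassification_always_in_scope(self):
        # eta_corr > 0 with eta_wro > eta_corr gives R < 0 < r_max for any
        # r_max >= 0: the formula corrects every such miss
        miss = self.pred("m", 1.0, 2.0)
        preds, _ = apply_r_correction([miss], [H], r_max=0.0)
        assert preds[0].corrected

    def test_undefined_eta_corr_logged_not_corrected(self):
        miss = self.pred("m", 0.0, 1.0)
        preds, log = apply_r_correction([miss], [H], r_max=0.2)
        assert not preds[0].corrected
        assert log.undefined == ["m"]

    def test_monotone_in_r_max(self):
        rng = np.random.default_rng(9)
        preds = [
            self.pred(f"s{i}", float(rng.normal(-3)), float(rng.normal(-3)))
            for i in range(50)
        ]
        truth = [H if rng.random() < 0.5 else N for _ in range(50)]
        counts = []
        for r_max in (0.0, 0.1, 0.2, 0.5, 1.0):
            corrected, _ = apply_r_correction(preds, truth, r_max=r_max)
            counts.append(sum(p.corrected for p in corrected))
        assert counts == sorted(counts)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            apply_r_correction([self.pred("a", 1, 2)], [H, N])


class TestSerialization:
    def test_round_trip_preserves_eta(self):
        rng = np.random.default_rng(10)
        X = random_matrix(rng, 6, 30, 30)
        model = fit(X, epsilon=1e-8)
        buf = stdio.StringIO()
        save_model(model, buf)
        buf.seek(0)
        back = load_model(buf)
        assert back.feature_names == model.feature_names
        assert back.epsilon == model.epsilon
        for x in rng.standard_normal((100, 6)):
            for lab in (H, N):
                assert eta(back.classes[lab], x) == eta(model.classes[lab], x)

    def test_truncated_file_is_format_error(self):
        rng = np.random.default_rng(11)
        model = fit(random_matrix(rng, 2, 5, 5))
        buf = stdio.StringIO()
        save_model(model, buf)
        truncated = stdio.StringIO(buf.getvalue()[: len(buf.getvalue()) // 2])
        with pytest.raises(FormatError):
            load_model(truncated)

    def test_version_mismatch_rejected(self):
        with pytest.raises(FormatError, match="version"):
            load_model(stdio.StringIO('{"version": 99}'))

    def test_file_round_trip(self, tmp_path):
        rng = np.random.default_rng(12)
        model = fit(random_matrix(rng, 3, 8, 8), epsilon=1e-6)
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.classes[H].epsilon == 1e-6
        assert np.array_equal(back.classes[H].mu, model.classes[H].mu)
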