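"""k-means init, EM fitting, mixture scoring and model-bank serialization."""

import json
import math

import numpy as np
import pytest
from sklearn.mixture import GaussianMixture

from bittern.gmm import (
    GMMComponent,
    GMMSpeciesClassifier,
    ModelBank,
    ModelFileError,
    SpeciesGMM,
    classify_frame,
    component_logpdf,
    fit_gmm,
    kmeans_init,
    load_model,
    model_loglik,
    save_model,
)


def make_component(mean, cov, weight=1.0):
    return GMMComponent(weight=weight, mean=np.asarray(mean, dtype=float),
                        cov=np.asarray(cov, dtype=float)).build_cache()


def single_gaussian_model(label, mean, cov):
    m = SpeciesGMM(label=label, weights=np.array([1.0]),
                   means=np.asarray([mean], dtype=float),
                   covs=np.asarray([cov], dtype=float))
    return m.build_cache()


class TestKMeansInit:
    def test_single_cluster_is_global_mean(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((200, 3))
        means, assign = kmeans_init(X, M=1, seed=0)
        assert np.allclose(means[0], X.mean(axis=0))
        assert np.all(assign == 0)

    def test_two_separated_clouds_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((300, 2)) + [10, 0]
        b = rng.standard_normal((300, 2)) - [10, 0]
        X = np.vstack([a, b])
        means, assign = kmeans_init(X, M=2, seed=0)
        centers = sorted(means[:, 0])
        assert centers[0] == pytest.approx(-10, abs=0.5)
        assert centers[1] == pytest.approx(10, abs=0.5)
        # each cloud maps to a single cluster
        assert len(set(assign[:300])) == 1 and len(set(assign[300:])) == 1

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((100, 4))
        m1, a1 = kmeans_init(X, M=5, seed=3)
        m2, a2 = kmeans_init(X, M=5, seed=3)
        assert np.array_equal(m1, m2) and np.array_equal(a1, a2)

    def test_too_few_points_rejected_with_species_name(self):
        with pytest.raises(ValueError, match="Sterna"):
            kmeans_init(np.zeros((3, 2)), M=5, label="Sterna")


class TestComponentLogpdf:
    def test_standard_normal_mode_density(self):
        comp = make_component([0.0], [[1.0]])
        assert math.exp(component_logpdf(np.array([0.0]), comp)) == \
            pytest.approx(1 / math.sqrt(2 * math.pi))

    def test_mean_of_identity_13d(self):
        comp = make_component(np.zeros(13), np.eye(13))
        assert component_logpdf(np.zeros(13), comp) == \
            pytest.approx(-13 / 2 * math.log(2 * math.pi))

    def test_matches_naive_inversion_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.standard_normal((3, 3))
            cov = a @ a.T + 3 * np.eye(3)
            mean = rng.standard_normal(3)
            x = rng.standard_normal(3)
            comp = make_component(mean, cov)
            diff = x - mean
            naive = (-1.5 * math.log(2 * math.pi)
                     - 0.5 * math.log(np.linalg.det(cov))
                     - 0.5 * diff @ np.linalg.inv(cov) @ diff)
            assert component_logpdf(x, comp) == pytest.approx(naive, abs=1e-10)

    def test_missing_cache_is_an_error_not_a_recompute(self):
        comp = GMMComponent(weight=1.0, mean=np.zeros(2), cov=np.eye(2))
        with pytest.raises(ValueError, match="cache"):
            component_logpdf(np.zeros(2), comp)


class TestModelLoglik:
    def test_single_component_equals_component_logpdf(self):
        model = single_gaussian_model("a", [1.0, 2.0], np.eye(2))
        x = np.array([0.3, -0.7])
        assert model_loglik(x, model) == pytest.approx(
            component_logpdf(x, model.components[0]), abs=1e-12)

    def test_duplicated_component_with_half_weights_is_identity(self):
        m = SpeciesGMM(label="a", weights=np.array([0.5, 0.5]),
                       means=np.zeros((2, 3)),
                       covs=np.stack([np.eye(3), np.eye(3)])).build_cache()
        single = single_gaussian_model("b", np.zeros(3), np.eye(3))
        x = np.array([0.1, 0.2, 0.3])
        assert model_loglik(x, m) == pytest.approx(
            model_loglik(x, single), abs=1e-12)

    def test_matches_direct_summation_oracle(self):
        m = SpeciesGMM(label="toy", weights=np.array([0.3, 0.7]),
                       means=np.array([[-1.0], [2.0]]),
                       covs=np.array([[[0.5]], [[2.0]]])).build_cache()
        for xv in [-2.0, 0.0, 1.5, 3.0]:
            direct = 0.0
            for k in range(2):
                w = m.weights[k]
                mu, var = m.means[k, 0], m.covs[k, 0, 0]
                direct += w * math.exp(-0.5 * (xv - mu) ** 2 / var) / \
                    math.sqrt(2 * math.pi * var)
            assert model_loglik(np.array([xv]), m) == \
                pytest.approx(math.log(direct), abs=1e-12)

    def test_all_zero_weights_rejected(self):
        m = SpeciesGMM(label="z", weights=np.array([0.0, 0.0]),
                       means=np.zeros((2, 1)),
                       covs=np.ones((2, 1, 1))).build_cache()
        with pytest.raises(ValueError, match="zero"):
            model_loglik(np.array([0.0]), m)

    def test_monte_carlo_normalization(self):
        """The mixture density integrates to 1 (importance sampling, d=2)."""
        m = SpeciesGMM(label="toy", weights=np.array([0.6, 0.4]),
                       means=np.array([[1.0, 0.0], [-1.0, 0.5]]),
                       covs=np.stack([np.eye(2), 0.5 * np.eye(2)])).build_cache()
        rng = np.random.default_rng(12)
        n = 200_000
        q_cov = 4.0
        x = rng.normal(0.0, math.sqrt(q_cov), size=(n, 2))
        log_q = (-np.sum(x ** 2, axis=1) / (2 * q_cov)
                 - math.log(2 * math.pi * q_cov))
        est = np.mean(np.exp(m.log_likelihood(x) - log_q))
        assert est == pytest.approx(1.0, abs=0.01)


class TestFitGmm:
    def test_single_gaussian_parameter_recovery(self):
        rng = np.random.default_rng(21)
        true_mean = np.array([1.0, -2.0])
        true_cov = np.array([[2.0, 0.6], [0.6, 1.0]])
        X = rng.multivariate_normal(true_mean, true_cov, size=5000)
        model = fit_gmm(X, M=1, seed=0)
        se = np.sqrt(np.diag(true_cov) / 5000)
        assert np.all(np.abs(model.means[0] - true_mean) < 3 * se)
        frob = np.linalg.norm(model.covs[0] - true_cov)
        assert frob / np.linalg.norm(true_cov) < 0.10

    def test_two_component_weight_recovery(self):
        rng = np.random.default_rng(22)
        n = 5000
        n1 = int(0.7 * n)
        X = np.vstack([
            rng.multivariate_normal([5, 0], np.eye(2), size=n1),
            rng.multivariate_normal([-5, 0], np.eye(2), size=n - n1)])
        model = fit_gmm(X, M=2, seed=0)
        weights = np.sort(model.weights)
        assert weights[0] == pytest.approx(0.3, abs=0.05)
        assert weights[1] == pytest.approx(0.7, abs=0.05)

    def test_em_loglikelihood_monotone(self):
        rng = np.random.default_rng(23)
        X = rng.standard_normal((600, 3)) + rng.integers(0, 2, (600, 1)) * 4
        model = fit_gmm(X, M=4, seed=1)
        h = np.array(model.metadata["log_likelihood_history"])
        assert h.size >= 2
        assert np.all(np.diff(h) >= -1e-9 * np.abs(h[:-1]))

    def test_weights_sum_to_one_exactly(self):
        rng = np.random.default_rng(24)
        X = rng.standard_normal((500, 2))
        model = fit_gmm(X, M=3, seed=0)
        assert np.sum(model.weights) == pytest.approx(1.0, abs=1e-12)

    def test_warns_when_data_thin_for_mixture_size(self):
        rng = np.random.default_rng(25)
        with pytest.warns(UserWarning, match="recommend"):
            fit_gmm(rng.standard_normal((40, 5)), M=8, seed=0)

    def test_matches_sklearn_density_on_same_parameters(self):
        """Independent oracle: sklearn evaluates our fitted mixture's density
        identically once given the same parameters."""
        rng = np.random.default_rng(26)
        X = np.vstack([rng.standard_normal((400, 3)) + 3,
                       rng.standard_normal((400, 3)) - 3])
        model = fit_gmm(X, M=2, seed=0)
        sk = GaussianMixture(n_components=2, covariance_type="full")
        sk.weights_ = model.weights
        sk.means_ = model.means
        sk.covariances_ = model.covs
        sk.precisions_cholesky_ = np.array([
            np.linalg.cholesky(np.linalg.inv(c)) for c in model.covs])
        ours = model.log_likelihood(X[:50])
        theirs = sk.score_samples(X[:50])
        assert np.allclose(ours, theirs, atol=1e-8)


class TestClassifyFrame:
    def _bank(self):
        return ModelBank(models=[
            single_gaussian_model("left", [-10.0], [[1.0]]),
            single_gaussian_model("right", [10.0], [[1.0]])])

    def test_frame_near_mean_takes_that_label(self):
        label, scores = classify_frame(np.array([10.0]), self._bank())
        assert label == "right"
        assert scores.shape == (2,)
        assert scores[1] > scores[0]

    def test_equidistant_tie_breaks_to_first_model(self):
        bank = ModelBank(models=[
            single_gaussian_model("first", [0.0], [[1.0]]),
            single_gaussian_model("second", [0.0], [[1.0]])])
        label, _ = classify_frame(np.array([0.7]), bank)
        assert label == "first"

    def test_common_weight_rescaling_leaves_argmax_unchanged(self):
        bank = self._bank()
        x = np.array([2.5])
        before, scores_before = classify_frame(x, bank)
        for m in bank.models:
            m.weights = m.weights * 0.25  # common affine rescale, no renorm
        after, scores_after = classify_frame(x, bank)
        assert before == after
        assert np.allclose(scores_after - scores_before, math.log(0.25))

    def test_empty_bank_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_frame(np.array([0.0]), ModelBank(models=[]))


class TestSerialization:
    def _fitted_bank(self):
        rng = np.random.default_rng(31)
        X = rng.standard_normal((300, 2))
        return ModelBank(models=[fit_gmm(X + 4, M=2, seed=0, label="a"),
                                 fit_gmm(X - 4, M=2, seed=0, label="b")])

    def test_roundtrip_scores_bit_identical(self, tmp_path):
        bank = self._fitted_bank()
        path = tmp_path / "bank.json"
        save_model(bank, path)
        loaded = load_model(path)
        x = np.array([[0.5, -0.5], [3.0, 3.0]])
        assert np.array_equal(bank.log_likelihoods(x),
                              loaded.log_likelihoods(x))

    def test_tampered_weight_sum_rejected(self, tmp_path):
        bank = self._fitted_bank()
        path = tmp_path / "bank.json"
        save_model(bank, path)
        payload = json.loads(path.read_text())
        payload["models"][0]["weights"] = [1.0, 0.5]
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelFileError, match="sum"):
            load_model(path)

    def test_missing_cache_rebuilt_with_warning(self, tmp_path, caplog):
        bank = self._fitted_bank()
        path = tmp_path / "bank.json"
        save_model(bank, path)
        payload = json.loads(path.read_text())
        for entry in payload["models"]:
            entry["log_dets"] = None
            entry["cov_invs"] = None
        path.write_text(json.dumps(payload))
        with caplog.at_level("WARNING", logger="bittern.gmm"):
            loaded = load_model(path)
        assert "rebuilding" in caplog.text
        x = np.array([[0.1, 0.2]])
        assert np.allclose(loaded.log_likelihoods(x),
                           bank.log_likelihoods(x), atol=1e-12)

    def test_corrupt_file_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ModelFileError):
            load_model(path)

    def test_non_spd_covariance_rejected(self, tmp_path):
        bank = self._fitted_bank()
        path = tmp_path / "bank.json"
        save_model(bank, path)
        payload = json.loads(path.read_text())
        payload["models"][0]["covs"][0] = [[1.0, 2.0], [2.0, 1.0]]
        path.write_text(json.dumps(payload))
        with pytest.raises(ModelFileError):
            load_model(path)


class TestClassifierEstimator:
    def test_fit_predict_on_separable_blobs(self):
        rng = np.random.default_rng(41)
        X = np.vstack([rng.standard_normal((150, 2)) + c for c in (-6, 0, 6)])
        y = np.repeat(["a", "b", "c"], 150)
        clf = GMMSpeciesClassifier(n_mixtures=2, random_state=0).fit(X, y)
        assert (clf.predict(X) == y).mean() > 0.99
        assert clf.decision_function(X).shape == (450, 3)

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(42)
        X = rng.standard_normal((100, 3))
        y = np.repeat(["a", "b"], 50)
        clf = GMMSpeciesClassifier(n_mixtures=1).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            clf.predict(rng.standard_normal((5, 4)))

    def test_sklearn_params_protocol(self):
        clf = GMMSpeciesClassifier(n_mixtures=8, random_state=7)
        params = clf.get_params()
        assert params["n_mixtures"] == 8
        clf.set_params(n_mixtures=4)
        assert clf.n_mixtures == 4
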