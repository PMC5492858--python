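"""Per-species Gaussian mixture classification.

One full-covariance GMM is trained per species (k-means initialisation
followed by EM); a frame x with 13-dimensional MFCC features is assigned
to the species whose model gives the highest likelihood

    P_i(x; theta_i) = sum_k w_k p_k(x; mu_k, Sigma_k),   sum_k w_k = 1,

with p_k the multivariate normal density. |Sigma_k| and Sigma_k^-1 are
precomputed once per component so that per-frame scoring costs only the
Mahalanobis products; all scoring is done in the log domain with
log-sum-exp, which leaves the argmax unchanged while avoiding the
underflow a 13-dimensional density suffers in linear arithmetic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1
_LOG_2PI = float(np.log(2.0 * np.pi))


class CovarianceCollapseError(RuntimeError):
    """A mixture component's covariance lost positive definiteness."""


def _first_non_spd(covs: np.ndarray) -> int:
    """Index of the first stacked covariance that fails Cholesky."""
    for k in range(covs.shape[0]):
        try:
            np.linalg.cholesky(covs[k])
        except np.linalg.LinAlgError:
            return k
    return -1


class ModelFileError(ValueError):
    """A serialized model bank failed validation on load."""


@dataclass
class GMMComponent:
    """One weighted multivariate Gaussian with cached |Sigma| and Sigma^-1."""

    weight: float
    mean: np.ndarray
    cov: np.ndarray
    log_det: float | None = None
    cov_inv: np.ndarray | None = None

    @property
    def has_cache(self) -> bool:
        return self.log_det is not None and self.cov_inv is not None

    def build_cache(self) -> "GMMComponent":
        """Precompute log|Sigma| and Sigma^-1 (Cholesky route)."""
        chol = np.linalg.cholesky(self.cov)  # raises LinAlgError if not SPD
        self.log_det = float(2.0 * np.sum(np.log(np.diag(chol))))
        self.cov_inv = np.linalg.inv(self.cov)
        return self


def component_logpdf(x: np.ndarray, comp: GMMComponent) -> float:
    """Log multivariate normal density using the component's cache.

    A missing cache is an error rather than a silent recompute: scoring
    cost is part of the deployment contract.
    """
    if not comp.has_cache:
        raise ValueError("component cache (log_det, cov_inv) not built")
    x = np.asarray(x, dtype=np.float64)
    d = comp.mean.size
    if x.shape[-1] != d:
        raise ValueError(f"x has dimension {x.shape[-1]}, component has {d}")
    diff = x - comp.mean
    maha = diff @ comp.cov_inv @ diff
    return float(-0.5 * (d * _LOG_2PI + comp.log_det + maha))


@dataclass
class SpeciesGMM:
    """Mixture model for one species, stored as stacked arrays.

    ``weights`` (M,), ``means`` (M, d), ``covs`` (M, d, d); caches
    ``log_dets`` (M,) and ``cov_invs`` (M, d, d) are built by
    :meth:`build_cache`. ``metadata`` records the training seed,
    iteration count and the per-iteration log-likelihood history.
    """

    label: str
    weights: np.ndarray
    means: np.ndarray
    covs: np.ndarray
    log_dets: np.ndarray | None = None
    cov_invs: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return self.weights.size

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def components(self) -> list[GMMComponent]:
        cached = self.log_dets is not None
        return [GMMComponent(
            weight=float(self.weights[k]), mean=self.means[k], cov=self.covs[k],
            log_det=float(self.log_dets[k]) if cached else None,
            cov_inv=self.cov_invs[k] if cached else None)
            for k in range(self.M)]

    def validate(self, atol: float = 1e-8) -> None:
        if np.any(self.weights < 0):
            raise ValueError(f"{self.label}: negative mixture weight")
        total = float(np.sum(self.weights))
        if abs(total - 1.0) > atol:
            raise ValueError(
                f"{self.label}: mixture weights sum to {total!r}, expected 1")
        for k in range(self.M):
            if not np.allclose(self.covs[k], self.covs[k].T, atol=1e-10):
                raise ValueError(f"{self.label}: covariance {k} not symmetric")

    def build_cache(self) -> "SpeciesGMM":
        try:
            chols = np.linalg.cholesky(self.covs)  # batched over components
        except np.linalg.LinAlgError as exc:
            bad = _first_non_spd(self.covs)
            raise CovarianceCollapseError(
                f"{self.label}: component {bad} covariance is not positive "
                f"definite") from exc
        diag = np.diagonal(chols, axis1=1, axis2=2)
        self.log_dets = 2.0 * np.sum(np.log(diag), axis=1)
        self.cov_invs = np.linalg.inv(self.covs)
        return self

    def _component_log_terms(self, X: np.ndarray) -> np.ndarray:
        """R x M matrix of ln(w_k) + ln p_k(x) (batched over components)."""
        with np.errstate(divide="ignore"):  # zero weights drop out as -inf
            log_w = np.log(self.weights)
        if np.all(np.isneginf(log_w)):
            raise ValueError(f"{self.label}: all mixture weights are zero")
        diff = X[None, :, :] - self.means[:, None, :]          # (M, R, d)
        maha = np.sum((diff @ self.cov_invs) * diff, axis=2)   # batched BLAS
        return (log_w[:, None] - 0.5 * (
            self.d * _LOG_2PI + self.log_dets[:, None] + maha)).T

    def log_likelihood(self, X: np.ndarray) -> np.ndarray:
        """log P(x; theta) for each row of X via log-sum-exp over components."""
        if self.log_dets is None:
            raise ValueError(f"{self.label}: model cache not built")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.d:
            raise ValueError(
                f"features have dimension {X.shape[1]}, model {self.label} "
                f"has d={self.d}")
        return logsumexp(self._component_log_terms(X), axis=1)


def model_loglik(x: np.ndarray, model: SpeciesGMM) -> float | np.ndarray:
    """Mixture log-likelihood of one frame (or an array of frames)."""
    x = np.asarray(x, dtype=np.float64)
    out = model.log_likelihood(x)
    return float(out[0]) if x.ndim == 1 else out


# ---------------------------------------------------------------------------
# k-means initialisation (Lloyd's algorithm with k-means++ seeding)
# ---------------------------------------------------------------------------

def _kmeanspp_seeds(X: np.ndarray, M: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((M, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for k in range(1, M):
        total = d2.sum()
        if total <= 0:
            centers[k] = X[rng.integers(n)]
            continue
        centers[k] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, np.sum((X - centers[k]) ** 2, axis=1))
    return centers


def kmeans_init(X: np.ndarray, M: int, seed: int = 0, max_iter: int = 100,
                label: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Cluster means and assignments for mixture initialisation.

    Lloyd's algorithm with k-means++ seeding; an emptied cluster is
    re-seeded from the point farthest from its current center.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n = X.shape[0]
    if n < M:
        who = f" for {label}" if label else ""
        raise ValueError(
            f"cannot initialise M={M} clusters from {n} feature vectors{who}")
    rng = np.random.default_rng(seed)
    centers = _kmeanspp_seeds(X, M, rng)
    assign = np.full(n, -1)
    for _ in range(max_iter):
        d2 = np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        new_assign = np.argmin(d2, axis=1)
        for k in range(M):
            members = new_assign == k
            if not np.any(members):
                far = int(np.argmax(d2[np.arange(n), new_assign]))
                centers[k] = X[far]
                new_assign[far] = k
                members = new_assign == k
            centers[k] = X[members].mean(axis=0)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
    return centers, assign


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def fit_gmm(X: np.ndarray, M: int = 32, seed: int = 0, tol: float = 1e-6,
            max_iter: int = 200, reg: float = 1e-6,
            label: str = "") -> SpeciesGMM:
    """Fit a full-covariance M-component mixture by EM.

    Initialisation from k-means (means = cluster means, covariances =
    cluster scatter + ``reg * I``, weights = cluster fractions); EM stops
    when the relative total log-likelihood gain falls below ``tol`` or
    after ``max_iter`` iterations. ``reg * I`` is added to every
    covariance each M-step to keep the components positive definite.
    """
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    n, d = X.shape
    if n < M:
        raise ValueError(
            f"{label or 'model'}: {n} vectors cannot support M={M} components")
    if n < M * (d + 1):
        warnings.warn(
            f"{label or 'model'}: only {n} vectors for M={M}, d={d}; "
            f"recommend at least M*(d+1)={M * (d + 1)}", stacklevel=2)

    means, assign = kmeans_init(X, M, seed=seed, label=label or None)
    weights = np.bincount(assign, minlength=M).astype(np.float64) / n
    covs = np.empty((M, d, d))
    eye = np.eye(d)
    for k in range(M):
        members = X[assign == k]
        diff = members - means[k]
        covs[k] = diff.T @ diff / max(members.shape[0], 1) + reg * eye

    model = SpeciesGMM(label=label, weights=weights, means=means, covs=covs)
    model.build_cache()

    history: list[float] = []
    prev_ll = -np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # E-step: responsibilities in the log domain
        log_terms = model._component_log_terms(X)
        log_norm = logsumexp(log_terms, axis=1)
        ll = float(np.sum(log_norm))
        history.append(ll)
        resp = np.exp(log_terms - log_norm[:, None])

        if np.isfinite(prev_ll):
            gain = abs(ll - prev_ll) / max(abs(prev_ll), 1.0)
            if gain < tol:
                break
        prev_ll = ll

        # M-step
        nk = resp.sum(axis=0)
        model.weights = nk / n
        model.means = (resp.T @ X) / nk[:, None]
        diff = X[None, :, :] - model.means[:, None, :]        # (M, n, d)
        covs = (diff * resp.T[:, :, None]).transpose(0, 2, 1) @ diff
        covs /= nk[:, None, None]
        covs += reg * eye
        model.covs = covs
        model.build_cache()
    model.weights = model.weights / model.weights.sum()  # exact renormalise
    model.metadata = {"seed": seed, "n_iter": n_iter,
                      "final_log_likelihood": history[-1] if history else None,
                      "log_likelihood_history": history}
    model.validate(atol=1e-12)
    return model


# ---------------------------------------------------------------------------
# Model bank
# ---------------------------------------------------------------------------

@dataclass
class ModelBank:
    """The collection of per-species mixtures used for argmax labelling."""

    models: list[SpeciesGMM]

    def __post_init__(self) -> None:
        labels = [m.label for m in self.models]
        if len(set(labels)) != len(labels):
            raise ValueError("model labels must be unique")
        dims = {m.d for m in self.models}
        if len(dims) > 1:
            raise ValueError(f"models disagree on feature dimension: {dims}")

    @property
    def labels(self) -> list[str]:
        return [m.label for m in self.models]

    @property
    def d(self) -> int:
        return self.models[0].d

    def log_likelihoods(self, X: np.ndarray) -> np.ndarray:
        """R x n matrix of per-model log-likelihoods."""
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        return np.column_stack([m.log_likelihood(X) for m in self.models])


def classify_frame(x: np.ndarray, bank: ModelBank) -> tuple[str, np.ndarray]:
    """Label of the most likely species for one frame, plus all log-likelihoods.

    Ties are broken toward the lowest species index (argmax convention).
    """
    if not bank.models:
        raise ValueError("empty model bank")
    scores = bank.log_likelihoods(np.asarray(x, dtype=np.float64))[0]
    return bank.labels[int(np.argmax(scores))], scores


def save_model(bank: ModelBank, path: str | Path) -> None:
    """Serialize a bank to JSON at full float precision, caches included."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "d": bank.d,
        "models": [{
            "label": m.label,
            "weights": m.weights.tolist(),
            "means": m.means.tolist(),
            "covs": m.covs.tolist(),
            "log_dets": None if m.log_dets is None else m.log_dets.tolist(),
            "cov_invs": None if m.cov_invs is None else m.cov_invs.tolist(),
            "metadata": {k: v for k, v in m.metadata.items()
                         if k != "log_likelihood_history"},
        } for m in bank.models],
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ModelBank:
    """Load and re-validate a bank; missing caches are rebuilt (logged)."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelFileError(f"cannot read model bank {path}: {exc}") from exc
    if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise ModelFileError(
            f"unsupported model schema {payload.get('schema_version')!r}")
    d = payload["d"]
    models = []
    for entry in payload["models"]:
        m = SpeciesGMM(
            label=entry["label"],
            weights=np.asarray(entry["weights"], dtype=np.float64),
            means=np.asarray(entry["means"], dtype=np.float64),
            covs=np.asarray(entry["covs"], dtype=np.float64),
            metadata=entry.get("metadata", {}))
        if m.d != d:
            raise ModelFileError(
                f"model {m.label} has d={m.d}, bank header says {d}")
        try:
            m.validate()
        except ValueError as exc:
            raise ModelFileError(str(exc)) from exc
        if entry.get("log_dets") is None or entry.get("cov_invs") is None:
            logger.warning("model %s: cache missing from file, rebuilding", m.label)
            m.build_cache()
        else:
            m.log_dets = np.asarray(entry["log_dets"], dtype=np.float64)
            m.cov_invs = np.asarray(entry["cov_invs"], dtype=np.float64)
        # loading must fail on a covariance that is not SPD
        try:
            np.linalg.cholesky(m.covs)
        except np.linalg.LinAlgError as exc:
            raise ModelFileError(
                f"model {m.label}: covariance not positive definite") from exc
        models.append(m)
    return ModelBank(models=models)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

class GMMSpeciesClassifier(ClassifierMixin, BaseEstimator):
    """Multi-class classifier: one full-covariance GMM per class.

    Parameters
    ----------
    n_mixtures : int, default 32
        Components per class mixture (M).
    tol, max_iter, reg_covar : EM stopping tolerance (relative
        log-likelihood gain), iteration cap, and the ridge added to every
        covariance each M-step.
    random_state : int, default 0
        Seeds the per-class k-means initialisation.
    """

    def __init__(self, n_mixtures: int = 32, tol: float = 1e-6,
                 max_iter: int = 200, reg_covar: float = 1e-6,
                 random_state: int = 0):
        self.n_mixtures = n_mixtures
        self.tol = tol
        self.max_iter = max_iter
        self.reg_covar = reg_covar
        self.random_state = random_state

    def fit(self, X, y) -> "GMMSpeciesClassifier":
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y lengths differ")
        self.classes_ = np.unique(y)
        models = []
        for idx, cls in enumerate(self.classes_):
            seed = (int(self.random_state) + 9973 * idx) % (2 ** 31)
            models.append(fit_gmm(
                X[y == cls], M=self.n_mixtures, seed=seed, tol=self.tol,
                max_iter=self.max_iter, reg=self.reg_covar, label=str(cls)))
        self.models_ = models
        self.bank_ = ModelBank(models=models)
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        """Per-class mixture log-likelihood for every row of X."""
        check_is_fitted(self, "bank_")
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, classifier was fitted with "
                f"{self.n_features_in_}")
        return self.bank_.log_likelihoods(X)

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.decision_function(X), axis=1)]

    def em_histories(self) -> dict[str, list[float]]:
        """Per-class EM log-likelihood trajectories from the last fit."""
        check_is_fitted(self, "models_")
        return {m.label: m.metadata.get("log_likelihood_history", [])
                for m in self.models_}
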