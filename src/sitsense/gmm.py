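"""Gaussian-mixture behavioral clustering fitted by expectation-maximization.

The mixture density is

    p(x) = sum_i  w_i · N(x | mu_i, Sigma_i),      w_i >= 0, sum_i w_i = 1

and the E-step responsibilities are the Bayes posteriors

    r_ji = w_i N(x_j | mu_i, Sigma_i) / sum_l w_l N(x_j | mu_l, Sigma_l).

The M-step re-estimates the parameters from responsibility-weighted
moments:

    mu_i    = sum_j r_ji x_j / sum_j r_ji
    Sigma_i = sum_j r_ji (x_j - mu_i)(x_j - mu_i)^T / sum_j r_ji  +  eps·I
    w_i     = (1/m) sum_j r_ji

EM alternates the two steps until the total log-likelihood
LL = sum_j ln p(x_j) changes by less than ``tol``; LL is non-decreasing
across iterations and the trace records it. All densities are evaluated in
log-space through a Cholesky factorization (never an explicit inverse),
with max-subtraction (log-sum-exp) in the E-step; a ridge ``eps·I`` keeps
covariances SPD even when feature columns are nearly constant. Hard
cluster assignment is the row-wise argmax of the responsibilities, ties
resolved to the lowest component index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .errors import InsufficientDataError, NumericalDegeneracyError

__all__ = [
    "GMMModel",
    "Responsibilities",
    "EMTrace",
    "GaussianMixtureEM",
    "gaussian_density",
    "responsibilities",
    "m_step",
    "log_likelihood",
    "em_fit",
    "assign_clusters",
    "model_to_dict",
    "model_from_dict",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class GMMModel:
    """A k-component Gaussian mixture: weights, means, covariances."""

    weights: np.ndarray      # (k,)
    means: np.ndarray        # (k, d)
    covariances: np.ndarray  # (k, d, d)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        mu = np.atleast_2d(np.asarray(self.means, dtype=float))
        cov = np.asarray(self.covariances, dtype=float)
        if cov.ndim == 2:
            cov = cov[None, :, :]
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "means", mu)
        object.__setattr__(self, "covariances", cov)
        if w.ndim != 1 or len(w) < 1:
            raise ValueError("weights must be a non-empty 1-d vector")
        if np.any(w < -1e-12) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1 (1e-12)")
        k, d = mu.shape
        if cov.shape != (k, d, d):
            raise ValueError(f"covariances shape {cov.shape} != ({k},{d},{d})")
        for i in range(k):
            if not np.allclose(cov[i], cov[i].T, atol=1e-9):
                raise ValueError(f"covariance {i} not symmetric")

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def d(self) -> int:
        return self.means.shape[1]


@dataclass(frozen=True)
class Responsibilities:
    """m x k posterior membership matrix; rows sum to 1."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        r = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        object.__setattr__(self, "matrix", r)
        if np.any(r < -1e-12) or np.any(r > 1 + 1e-12):
            raise ValueError("responsibilities must lie in [0, 1]")
        if not np.allclose(r.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("responsibility rows must sum to 1 (1e-12)")


@dataclass
class EMTrace:
    """Per-iteration log-likelihood record of one EM fit."""

    log_likelihoods: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    seed: int | None = None


def _chol_factor(cov: np.ndarray, reg: float):
    """Cholesky of a covariance, retrying with an added ridge once."""
    cov = np.asarray(cov, dtype=float)
    try:
        return linalg.cholesky(cov, lower=True)
    except linalg.LinAlgError:
        try:
            return linalg.cholesky(cov + reg * np.eye(cov.shape[0]), lower=True)
        except linalg.LinAlgError as exc:
            raise NumericalDegeneracyError(
                "covariance is not positive definite after regularization") from exc


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray,
                  reg: float = 1e-6) -> np.ndarray:
    """Row-wise log N(x | mean, cov) via Cholesky; X is (m, d)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mean = np.asarray(mean, dtype=float)
    d = X.shape[1]
    L = _chol_factor(np.asarray(cov, dtype=float), reg)
    z = linalg.solve_triangular(L, (X - mean).T, lower=True)
    log_det = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * _LOG2PI + log_det + np.sum(z * z, axis=0))


def gaussian_density(x, mean, cov, reg: float = 1e-6) -> float:
    """Multivariate normal density at a single point (factorized, no inverse)."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    cov = np.atleast_2d(np.asarray(cov, dtype=float))
    return float(np.exp(_log_gaussian(x[None, :], mean, cov, reg))[0])


def _log_resp(X: np.ndarray, model: GMMModel, reg: float = 1e-6):
    """Log responsibilities and per-row log mixture density."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    logp = np.empty((X.shape[0], model.k))
    with np.errstate(divide="ignore"):
        logw = np.log(model.weights)
    for i in range(model.k):
        logp[:, i] = logw[i] + _log_gaussian(X, model.means[i],
                                             model.covariances[i], reg)
    norm = logsumexp(logp, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        row = int(np.nonzero(bad)[0][0])
        raise NumericalDegeneracyError(
            f"all component densities underflowed for row {row}")
    return logp - norm[:, None], norm


def responsibilities(X, model: GMMModel, reg: float = 1e-6) -> Responsibilities:
    """E-step: Bayes posterior membership per row, computed in log-space."""
    log_r, _ = _log_resp(X, model, reg)
    r = np.exp(log_r)
    r /= r.sum(axis=1, keepdims=True)  # renormalize away exp round-off
    return Responsibilities(r)


def log_likelihood(X, model: GMMModel, reg: float = 1e-6) -> float:
    """Total data log-likelihood sum_j ln p(x_j) (log-sum-exp evaluation)."""
    _, norm = _log_resp(X, model, reg)
    return float(norm.sum())


def m_step(X, resp: Responsibilities, reg: float = 1e-6,
           on_collapse: str = "error",
           rng: np.random.Generator | None = None) -> GMMModel:
    """M-step: responsibility-weighted means, covariances (+ ridge), weights.

    A component whose responsibility mass vanishes is either re-seeded from
    the point farthest from all current means (``on_collapse='reseed'``) or
    reported as a degeneracy (``'error'``).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    R = resp.matrix
    m, d = X.shape
    k = R.shape[1]
    mass = R.sum(axis=0)

    collapsed = np.nonzero(mass < 1e-10 * m)[0]
    if len(collapsed) and on_collapse == "error":
        raise NumericalDegeneracyError(
            f"component(s) {collapsed.tolist()} collapsed (zero responsibility mass)")

    means = np.empty((k, d))
    covs = np.empty((k, d, d))
    safe_mass = np.where(mass < 1e-300, 1.0, mass)
    for i in range(k):
        means[i] = (R[:, i] @ X) / safe_mass[i]
        diff = X - means[i]
        covs[i] = (R[:, i][:, None] * diff).T @ diff / safe_mass[i]
        covs[i] += reg * np.eye(d)
    weights = mass / m

    if len(collapsed):
        global_cov = np.cov(X, rowvar=False).reshape(d, d) + reg * np.eye(d)
        alive = np.setdiff1d(np.arange(k), collapsed)
        for i in collapsed:
            ref = means[alive] if len(alive) else X.mean(axis=0)[None, :]
            dist = np.min(np.linalg.norm(X[:, None, :] - ref[None, :, :],
                                         axis=2), axis=1)
            means[i] = X[int(np.argmax(dist))]
            covs[i] = global_cov
            weights[i] = 1.0 / m
        weights /= weights.sum()

    weights = np.clip(weights, 0.0, None)
    weights /= weights.sum()
    covs = 0.5 * (covs + np.transpose(covs, (0, 2, 1)))  # enforce symmetry
    return GMMModel(weights=weights, means=means, covariances=covs)


def assign_clusters(resp: Responsibilities) -> np.ndarray:
    """Hard assignment: row-wise argmax, ties to the lowest component index."""
    return np.argmax(resp.matrix, axis=1)


def _init_model(X: np.ndarray, k: int, init: str, reg: float,
                rng: np.random.Generator) -> GMMModel:
    m, d = X.shape
    global_cov = np.cov(X, rowvar=False).reshape(d, d) + reg * np.eye(d)
    if init == "kmeans++":
        # k-means++ seeding of the means (D^2-weighted), no Lloyd iterations
        means = [X[int(rng.integers(m))]]
        for _ in range(1, k):
            d2 = np.min(np.linalg.norm(X[:, None, :] - np.array(means)[None, :, :],
                                       axis=2) ** 2, axis=1)
            tot = d2.sum()
            if tot <= 0:
                means.append(X[int(rng.integers(m))])
            else:
                means.append(X[int(rng.choice(m, p=d2 / tot))])
        means = np.array(means)
    elif init == "random":
        means = X[rng.choice(m, size=k, replace=False)]
    else:
        raise ValueError(f"unknown init strategy {init!r}")
    covs = np.repeat(global_cov[None, :, :], k, axis=0)
    weights = np.full(k, 1.0 / k)
    return GMMModel(weights=weights, means=means, covariances=covs)


def em_fit(X, k: int, init: str = "kmeans++", seed: int | None = 0,
           tol: float = 1e-7, max_iter: int = 500, reg: float = 1e-6,
           on_collapse: str = "reseed",
           ) -> tuple[GMMModel, Responsibilities, EMTrace]:
    """Fit a k-component mixture by EM; deterministic given the seed.

    Stops when the absolute change in total log-likelihood falls below
    ``tol`` or after ``max_iter`` iterations. Requires m > k samples.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m, d = X.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if m <= k:
        raise InsufficientDataError(f"need more samples ({m}) than components ({k})")
    rng = np.random.default_rng(seed)
    model = _init_model(X, k, init, reg, rng)
    trace = EMTrace(seed=seed)

    prev_ll = -np.inf
    resp = responsibilities(X, model, reg)
    for it in range(1, max_iter + 1):
        model = m_step(X, resp, reg=reg, on_collapse=on_collapse, rng=rng)
        resp = responsibilities(X, model, reg)
        ll = log_likelihood(X, model, reg)
        trace.log_likelihoods.append(ll)
        trace.n_iter = it
        if np.isfinite(prev_ll) and abs(ll - prev_ll) < tol:
            trace.converged = True
            break
        prev_ll = ll
    return model, resp, trace


class GaussianMixtureEM(BaseEstimator):
    """Gaussian-mixture clustering estimator fitted by EM.

    Parameters
    ----------
    n_components : number of mixture components (default 2 — the healthy and
        unhealthy behavioral regions).
    init : 'kmeans++' (D^2-weighted seeding of the means) or 'random'.
    random_state : seed controlling initialization; fits are deterministic
        given the seed.
    tol : absolute change in total log-likelihood declaring convergence.
    max_iter : EM iteration cap.
    reg_covar : ridge added to every covariance diagonal.
    on_collapse : 'reseed' (re-seed an emptied component from the farthest
        point) or 'error'.

    Attributes (after fit)
    ----------------------
    weights_, means_, covariances_ : mixture parameters.
    responsibilities_ : posterior membership of the training rows.
    labels_ : hard training assignment.
    trace_ : per-iteration log-likelihood record.
    converged_, n_iter_, lower_bound_ : convergence diagnostics.
    """

    def __init__(self, n_components: int = 2, init: str = "kmeans++",
                 random_state: int | None = 0, tol: float = 1e-7,
                 max_iter: int = 500, reg_covar: float = 1e-6,
                 on_collapse: str = "reseed"):
        self.n_components = n_components
        self.init = init
        self.random_state = random_state
        self.tol = tol
        self.max_iter = max_iter
        self.reg_covar = reg_covar
        self.on_collapse = on_collapse

    def fit(self, X, y=None):
        model, resp, trace = em_fit(
            X, k=self.n_components, init=self.init, seed=self.random_state,
            tol=self.tol, max_iter=self.max_iter, reg=self.reg_covar,
            on_collapse=self.on_collapse)
        self.model_ = model
        self.weights_ = model.weights
        self.means_ = model.means
        self.covariances_ = model.covariances
        self.responsibilities_ = resp
        self.labels_ = assign_clusters(resp)
        self.trace_ = trace
        self.converged_ = trace.converged
        self.n_iter_ = trace.n_iter
        self.lower_bound_ = trace.log_likelihoods[-1] if trace.log_likelihoods else np.nan
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_

    def predict_proba(self, X):
        return responsibilities(X, self.model_, self.reg_covar).matrix

    def predict(self, X):
        return assign_clusters(responsibilities(X, self.model_, self.reg_covar))

    def score(self, X, y=None):
        """Mean per-sample log-likelihood (sklearn convention)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return log_likelihood(X, self.model_, self.reg_covar) / X.shape[0]

    def score_total(self, X):
        """Total data log-likelihood LL = sum_j ln p(x_j)."""
        return log_likelihood(X, self.model_, self.reg_covar)

    def sample(self, n: int, random_state: int | None = None):
        """Ancestral sampling: component by weight, then the Gaussian."""
        from .synthetic import generate_gmm_samples
        return generate_gmm_samples(self.model_, n,
                                    seed=self.random_state if random_state is None
                                    else random_state)


def model_to_dict(model: GMMModel, scaler_state: dict | None = None,
                  trace: EMTrace | None = None, seed: int | None = None) -> dict:
    """JSON-ready mixture document (row-major covariances)."""
    doc = {
        "k": model.k,
        "d": model.d,
        "weights": model.weights.tolist(),
        "means": model.means.tolist(),
        "covariances": model.covariances.tolist(),
    }
    if scaler_state is not None:
        doc["scaler"] = scaler_state
    if trace is not None:
        doc["trace"] = {"log_likelihoods": trace.log_likelihoods,
                        "n_iter": trace.n_iter, "converged": trace.converged,
                        "seed": trace.seed}
    if seed is not None:
        doc["seed"] = seed
    return doc


def model_from_dict(doc: dict) -> GMMModel:
    return GMMModel(weights=np.array(doc["weights"], dtype=float),
                    means=np.array(doc["means"], dtype=float),
                    covariances=np.array(doc["covariances"], dtype=float))
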