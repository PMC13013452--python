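"""Data-driven classification of distribution components.

Instead of drawing manual bin limits, the pooled per-voxel components (100
bootstraps x 10 components) are clustered in the space of their evaluated
parameters.  Weights enter by replication: each component contributes
``round(100 * w_i / sum_voxel w)`` identical rows to the design matrix, so a
voxel contributes ~100 rows regardless of its brightness.  Each feature
column is then standardized by its standard deviation, and the rows are
modeled as a K-component Gaussian mixture

    p(x) = sum_k pi_k N(x | mu_k, Sigma_k),      sum_k pi_k = 1,

fitted by expectation maximization with full covariances.  Schwarz's
Bayesian information criterion, BIC = -2 loglik + p ln(n), guides (but does
not dictate) the choice of K.

Cluster-resolved maps mirror the bin-resolved ones: per-voxel signal
fractions f_clus, weighted parameter means E_clus[X], and the normalized
component-count frequency F_clus.

Variable presets
----------------
``bins3``       {D_iso, D_delta_sq}              — 3-bin comparison
``full_rat``    {D_iso, D_delta, R1, R2, delta_diso}
``full_human``  {D_iso, D_delta, R1, R2}
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .binning import group_maps

VARIABLE_PRESETS = {
    "bins3": ["D_iso", "D_delta_sq"],
    "full_rat": ["D_iso", "D_delta", "R1", "R2", "delta_diso"],
    "full_human": ["D_iso", "D_delta", "R1", "R2"],
}

_ALLOWED_VARIABLES = {"D_iso", "D_delta", "D_delta_sq", "R1", "R2",
                      "delta_diso"}

REPLICATION_BASE = 100  # weights discretized between 0 and 100


# --------------------------------------------------------------------------
# feature matrix


@dataclass
class FeatureMatrix:
    """Weight-replicated, standardized component rows ready for the GMM."""

    X: np.ndarray               # (n_rows, n_variables), standardized
    variables: list[str]
    scale: np.ndarray           # per-column std divided out
    counts: np.ndarray          # replication count per surviving component
    provenance: pd.DataFrame    # one row per surviving component

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]


def replication_counts(df: pd.DataFrame) -> np.ndarray:
    """round(100 * w / sum of w in the component's voxel) per table row."""
    if {"i", "j", "k"}.issubset(df.columns):
        totals = df.groupby(["i", "j", "k"])["w"].transform("sum")
    else:
        totals = df["w"].sum()
    return np.rint(REPLICATION_BASE * df["w"] / totals).to_numpy().astype(int)


def build_feature_matrix(df: pd.DataFrame, variables=None) -> FeatureMatrix:
    """Replicate, stack and standardize the requested variables.

    ``df`` is an evaluated-component table (:mod:`mdrc.metrics`); components
    whose replication count rounds to zero are omitted.  Standardization
    divides each column by the population standard deviation of the
    replicated rows; the scale is stored so unreplicated components can be
    projected into the same space later.
    """
    if len(df) == 0:
        raise ValueError("empty component table")
    if variables is None:
        variables = VARIABLE_PRESETS["full_rat"]
    if isinstance(variables, str):
        variables = VARIABLE_PRESETS[variables]
    unknown = set(variables) - _ALLOWED_VARIABLES
    if unknown:
        raise ValueError(f"unknown clustering variable(s): {sorted(unknown)}")

    counts = replication_counts(df)
    keep = counts > 0
    sub = df.loc[keep]
    counts = counts[keep]
    raw = sub[list(variables)].to_numpy(dtype=float)
    X = np.repeat(raw, counts, axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0          # constant columns stay unscaled
    return FeatureMatrix(X=X / scale, variables=list(variables), scale=scale,
                         counts=np.asarray(counts),
                         provenance=sub.reset_index(drop=True))


# --------------------------------------------------------------------------
# Gaussian mixture by expectation maximization


class WeightedGaussianMixture(BaseEstimator):
    """Full-covariance Gaussian mixture fitted by EM.

    Initialization draws k-means++-style seed points and hard-assigns
    responsibilities to the nearest seed; the best of ``n_init`` seeded runs
    (by log-likelihood) is kept.  Covariances are regularized by adding
    ``reg_covar`` to their diagonals each M-step.

    Attributes (after ``fit``)
    --------------------------
    weights_ : (K,) mixing proportions pi_k
    means_ : (K, d)
    covariances_ : (K, d, d)
    lower_bound_ : final total log-likelihood
    converged_ : bool
    n_iter_ : iterations of the winning run
    """

    def __init__(self, n_components=2, n_init=5, tol=1e-6, max_iter=500,
                 reg_covar=1e-6, random_state=0):
        self.n_components = n_components
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter
        self.reg_covar = reg_covar
        self.random_state = random_state

    # ---------------------------------------------------------------- fit

    def fit(self, X, y=None):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, d = X.shape
        k = self.n_components
        if k < 1:
            raise ValueError("n_components must be >= 1")
        if len(np.unique(X, axis=0)) < k:
            raise ValueError(f"k={k} exceeds the number of distinct rows")
        if n < k * (d + 1):
            raise ValueError(f"need at least k*(d+1)={k * (d + 1)} rows, "
                             f"got {n}")
        rng = np.random.default_rng(self.random_state)
        best = None
        for _ in range(self.n_init):
            result = self._em_once(X, rng)
            if best is None or result["loglik"] > best["loglik"]:
                best = result
        self.weights_ = best["pi"]
        self.means_ = best["mu"]
        self.covariances_ = best["sigma"]
        self.lower_bound_ = best["loglik"]
        self.converged_ = best["converged"]
        self.n_iter_ = best["n_iter"]
        self.loglik_path_ = best["path"]
        self.n_features_in_ = d
        self.n_obs_ = n
        return self

    def _em_once(self, X, rng):
        n, d = X.shape
        k = self.n_components
        resp = self._init_resp(X, rng)
        pi, mu, sigma = _m_step(X, resp, self.reg_covar)
        prev = -np.inf
        path = []
        converged = False
        for it in range(1, self.max_iter + 1):
            log_resp, loglik = _e_step(X, pi, mu, sigma)
            pi, mu, sigma = _m_step(X, np.exp(log_resp), self.reg_covar)
            path.append(loglik)
            if np.isfinite(prev) and abs(loglik - prev) <= \
                    self.tol * abs(loglik):
                converged = True
                break
            prev = loglik
        _, loglik = _e_step(X, pi, mu, sigma)
        path.append(loglik)
        return {"pi": pi, "mu": mu, "sigma": sigma, "loglik": loglik,
                "converged": converged, "n_iter": it, "path": np.array(path)}

    def _init_resp(self, X, rng):
        """k-means++-style seeding, hard assignment to nearest seed."""
        n = X.shape[0]
        k = self.n_components
        centers = [X[rng.integers(n)]]
        for _ in range(1, k):
            d2 = np.min([np.sum((X - c) ** 2, axis=1) for c in centers],
                        axis=0)
            total = d2.sum()
            probs = d2 / total if total > 0 else np.full(n, 1.0 / n)
            centers.append(X[rng.choice(n, p=probs)])
        centers = np.array(centers)
        labels = np.argmin(((X[:, None, :] - centers[None]) ** 2).sum(-1),
                           axis=1)
        resp = np.zeros((n, k))
        resp[np.arange(n), labels] = 1.0
        # guard: every cluster keeps at least a trace of responsibility
        resp += 1e-10
        resp /= resp.sum(axis=1, keepdims=True)
        return resp

    # ---------------------------------------------------------- inference

    def _check_fitted(self):
        if not hasattr(self, "means_"):
            raise AttributeError("WeightedGaussianMixture is not fitted yet")

    def predict_proba(self, X):
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        log_resp, _ = _e_step(X, self.weights_, self.means_,
                              self.covariances_)
        return np.exp(log_resp)

    def predict(self, X):
        return np.argmax(self.predict_proba(X), axis=1)

    def fit_predict(self, X, y=None):
        return self.fit(X).predict(X)

    def score_samples(self, X):
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return logsumexp(_weighted_log_prob(X, self.weights_, self.means_,
                                            self.covariances_), axis=1)

    def score(self, X, y=None):
        return float(np.mean(self.score_samples(X)))

    @property
    def n_parameters_(self) -> int:
        """Free parameters of the full-covariance mixture."""
        k, d = self.means_.shape
        return int(k - 1 + k * d + k * d * (d + 1) // 2)

    def bic(self, X) -> float:
        """-2 loglik + p ln(n) on the given data."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        loglik = float(np.sum(self.score_samples(X)))
        return -2.0 * loglik + self.n_parameters_ * np.log(X.shape[0])


def _weighted_log_prob(X, pi, mu, sigma):
    return np.column_stack([np.log(pi[j]) + _log_gaussian(X, mu[j], sigma[j])
                            for j in range(len(pi))])


def _log_gaussian(X, mu, sigma):
    """Row-wise log N(x | mu, sigma) via Cholesky factorization."""
    d = X.shape[1]
    chol = np.linalg.cholesky(sigma)
    z = np.linalg.solve(chol, (X - mu).T).T
    maha = np.sum(z ** 2, axis=1)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _e_step(X, pi, mu, sigma):
    wlp = np.column_stack([np.log(pi[j]) + _log_gaussian(X, mu[j], sigma[j])
                           for j in range(len(pi))])
    norm = logsumexp(wlp, axis=1)
    return wlp - norm[:, None], float(norm.sum())


def _m_step(X, resp, reg_covar):
    n, d = X.shape
    nk = resp.sum(axis=0) + 10 * np.finfo(float).tiny
    pi = nk / n
    mu = (resp.T @ X) / nk[:, None]
    k = resp.shape[1]
    sigma = np.empty((k, d, d))
    for j in range(k):
        diff = X - mu[j]
        sigma[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j]
        sigma[j].flat[:: d + 1] += reg_covar
    return pi, mu, sigma


# --------------------------------------------------------------------------
# model selection and assignment


def fit_gmm(fm: FeatureMatrix | np.ndarray, k: int, n_init: int = 5,
            tol: float = 1e-6, max_iter: int = 500, reg_covar: float = 1e-6,
            seed: int = 0) -> WeightedGaussianMixture:
    X = fm.X if isinstance(fm, FeatureMatrix) else np.asarray(fm)
    return WeightedGaussianMixture(n_components=k, n_init=n_init, tol=tol,
                                   max_iter=max_iter, reg_covar=reg_covar,
                                   random_state=seed).fit(X)


def bic_scan(fm: FeatureMatrix | np.ndarray, k_range=range(2, 16),
             **gmm_kwargs) -> tuple[pd.DataFrame, int]:
    """Fit the mixture for every k and tabulate (k, loglik, bic, converged).

    Returns the table and the BIC-minimizing k.  The selection is advisory;
    the table is what a user should inspect.
    """
    X = fm.X if isinstance(fm, FeatureMatrix) else np.asarray(fm)
    k_range = list(k_range)
    if not k_range:
        raise ValueError("k_range must be non-empty")
    rows = []
    for k in k_range:
        model = fit_gmm(X, k, **gmm_kwargs)
        rows.append({"k": k, "loglik": model.lower_bound_,
                     "bic": model.bic(X), "converged": model.converged_})
    table = pd.DataFrame(rows)
    selected = int(table.loc[table["bic"].idxmin(), "k"])
    return table, selected


def assign_components(model: WeightedGaussianMixture, df: pd.DataFrame,
                      variables: list[str], scale: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Hard-assign each original (unreplicated) component to a cluster.

    Components are standardized with the stored ``scale`` and labeled by the
    maximum posterior responsibility (first index wins ties).  Returns
    (labels, responsibilities).
    """
    scale = np.asarray(scale, dtype=float)
    if len(scale) != len(variables) or model.n_features_in_ != len(variables):
        raise ValueError("scale / variables / model dimension mismatch")
    X = df[list(variables)].to_numpy(dtype=float) / scale
    resp = model.predict_proba(X)
    return np.argmax(resp, axis=1), resp


def cluster_maps(df: pd.DataFrame, labels: np.ndarray, n_clusters: int,
                 shape: tuple[int, int, int],
                 statistics: tuple = ("D_iso", "D_delta_sq", "R1", "R2",
                                      "delta_diso")) -> dict:
    """Cluster-resolved maps: f_clus (signal fractions), E_clus (weighted
    means), F_clus (normalized component-count frequency), and the
    per-cluster share of replicated rows (percent_data)."""
    labels = np.asarray(labels)
    groups = list(range(n_clusters))
    maps = group_maps(df, labels, groups, shape, statistics=statistics)

    f_count = {g: np.zeros(shape) for g in groups}
    vox = df[["i", "j", "k"]].to_numpy()
    keys = pd.MultiIndex.from_arrays(vox.T)
    counts = pd.Series(1, index=keys).groupby(level=[0, 1, 2]).sum()
    for g in groups:
        in_g = labels == g
        if in_g.any():
            per_vox = pd.Series(1, index=keys[in_g]).groupby(
                level=[0, 1, 2]).sum()
            for ix, c in per_vox.items():
                f_count[g][ix] = c / counts[ix]

    rep = replication_counts(df)
    total_rep = rep.sum()
    percent = {g: 100.0 * rep[labels == g].sum() / total_rep for g in groups}
    return {"f_clus": maps["fractions"], "E_clus": maps["means"],
            "F_clus": f_count, "percent_data": percent,
            "group_labels": groups}


def order_by_percent_data(maps: dict) -> list:
    """Cluster indices ordered from highest to lowest share of the data,
    matching the reporting convention (clusters A, B, C, ...)."""
    pd_ = maps["percent_data"]
    return sorted(pd_, key=lambda g: -pd_[g])


def compare_subjects(models: list[WeightedGaussianMixture]) -> dict:
    """Match clusters across independently fitted models and report
    centroid agreement.

    Clusters of each model are matched to the first model's by minimizing
    the summed centroid distance (optimal assignment).  Returns matched
    means (n_models, K, d), matched covariances, the per-model permutations
    and the per-cluster centroid spread (std across models).
    """
    if len({m.n_components for m in models}) != 1:
        raise ValueError("all models must share the same K")
    if len({m.n_features_in_ for m in models}) != 1:
        raise ValueError("all models must share the same feature set")
    ref = models[0]
    perms, means, covs = [], [], []
    for m in models:
        cost = np.linalg.norm(ref.means_[:, None, :] - m.means_[None, :, :],
                              axis=2)
        _, col = linear_sum_assignment(cost)
        perms.append(col)
        means.append(m.means_[col])
        covs.append(m.covariances_[col])
    means = np.array(means)
    return {"means": means, "covariances": np.array(covs),
            "permutations": perms,
            "centroid_spread": means.std(axis=0, ddof=0)}
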