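"""Elastic-net logistic regression with a regularization path and inner CV.

The classifier minimizes the penalized mean binomial deviance

    (1/n) * sum_i  -[y_i log p_i + (1-y_i) log(1-p_i)]
        + lambda * ( alpha * ||beta||_1 + (1-alpha)/2 * ||beta||_2^2 )

over a decreasing lambda path, with features standardized to zero mean and
unit (population) variance inside the solver and coefficients reported back
on the original feature scale.  ``lambda`` is chosen as the minimizer of the
mean out-of-fold binomial deviance in a k-fold inner cross-validation that
can be grouped (here: by epitope, so no peptide informs its own validation
fold).  ``alpha`` mixes the lasso (1) and ridge (0) penalties and is treated
as an outer hyperparameter (see :mod:`mhcload.training`).

The solver is the classical iteratively-reweighted-least-squares /
cyclic-coordinate-descent scheme for penalized GLMs: per lambda, the
log-likelihood is replaced by its weighted quadratic approximation at the
current coefficients and the penalized weighted least-squares problem is
solved by soft-thresholded coordinate updates with active-set sweeps,
warm-starting along the path from large to small lambda.  Lasso zeros are
exact (produced by the soft threshold, not by rounding).
"""

from __future__ import annotations

import numpy as np
from numba import njit
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GroupKFold, KFold
from sklearn.utils.validation import check_X_y, check_array

#: Ridge guard: alpha in the lambda_max formula is floored at this value.
_ALPHA_FLOOR = 1e-3
_PROB_EPS = 1e-12
#: Floor on IRLS weights p(1-p), as in the reference GLM-net implementation.
_WEIGHT_FLOOR = 1e-5


def binomial_deviance(y_true: np.ndarray, prob: np.ndarray) -> float:
    """Mean binomial deviance, -2/n * log-likelihood, clipped for stability."""
    p = np.clip(prob, _PROB_EPS, 1.0 - _PROB_EPS)
    y = np.asarray(y_true, dtype=float)
    return float(-2.0 * np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def lambda_path(
    X_std: np.ndarray,
    y: np.ndarray,
    alpha: float,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
) -> np.ndarray:
    """Log-spaced lambda path for standardized features.

    ``lambda_max`` is the smallest penalty that zeroes every coefficient at
    the given alpha: max_j |x_j . (y - ybar)| / (n * max(alpha, 1e-3)).
    """
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(X_std.T @ resid).max() / (n * max(alpha, _ALPHA_FLOOR))
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # population (1/n) variance, matching the lambda scale
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd_safe


@njit(cache=True)
def _cd_path_kernel(XT, y, alpha, lambdas, tol, max_irls, max_sweeps):  # pragma: no cover - jitted
    """Warm-started IRLS/coordinate-descent path on standardized features.

    ``XT`` is the (p, n) transposed design for cache-friendly column access.
    Returns per-lambda coefficients and intercepts on the standardized scale.
    """
    p, n = XT.shape
    n_lam = lambdas.shape[0]
    coefs = np.zeros((n_lam, p))
    icpts = np.zeros(n_lam)
    beta = np.zeros(p)
    ybar = y.mean()
    if ybar < 1e-6:
        ybar = 1e-6
    if ybar > 1.0 - 1e-6:
        ybar = 1.0 - 1e-6
    icpt = np.log(ybar / (1.0 - ybar))
    w = np.empty(n)
    we = np.empty(n)
    v = np.empty(p)
    active = np.zeros(p, np.bool_)
    for li in range(n_lam):
        lam = lambdas[li]
        l1 = lam * alpha
        l2 = lam * (1.0 - alpha)
        for _ in range(max_irls):
            # quadratic approximation at the current linear predictor
            wsum = 0.0
            for i in range(n):
                s = icpt
                for j in range(p):
                    if beta[j] != 0.0:
                        s += beta[j] * XT[j, i]
                pr = 1.0 / (1.0 + np.exp(-s))
                wi = pr * (1.0 - pr)
                if wi < _WEIGHT_FLOOR:
                    wi = _WEIGHT_FLOOR
                w[i] = wi
                wsum += wi
                we[i] = y[i] - pr  # weighted working residual
            for j in range(p):
                s = 0.0
                for i in range(n):
                    s += w[i] * XT[j, i] * XT[j, i]
                v[j] = s / n
            max_step = 0.0
            full = True
            for _sweep in range(max_sweeps):
                maxd = 0.0
                s = 0.0
                for i in range(n):
                    s += we[i]
                db = s / wsum
                if db != 0.0:
                    icpt += db
                    for i in range(n):
                        we[i] -= db * w[i]
                    ad = abs(db)
                    if ad > maxd:
                        maxd = ad
                for j in range(p):
                    if not full and not active[j]:
                        continue
                    s = 0.0
                    for i in range(n):
                        s += XT[j, i] * we[i]
                    num = s / n + v[j] * beta[j]
                    if num > l1:
                        nb = (num - l1) / (v[j] + l2)
                    elif num < -l1:
                        nb = (num + l1) / (v[j] + l2)
                    else:
                        nb = 0.0
                    d = nb - beta[j]
                    if d != 0.0:
                        for i in range(n):
                            we[i] -= d * w[i] * XT[j, i]
                        beta[j] = nb
                        md = abs(d) * np.sqrt(v[j])
                        if md > maxd:
                            maxd = md
                    active[j] = beta[j] != 0.0
                if maxd > max_step:
                    max_step = maxd
                if maxd < tol:
                    if full:
                        break
                    full = True  # converged on the active set; verify fully
                else:
                    full = False
            if max_step < 10.0 * tol:  # IRLS fixed point reached
                break
        coefs[li] = beta
        icpts[li] = icpt
    return coefs, icpts


def _fit_path(
    X_std: np.ndarray,
    y: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    tol: float = 1e-7,
    max_irls: int = 30,
    max_sweeps: int = 1000,
) -> list[tuple[np.ndarray, float]]:
    """Python-facing wrapper over the jitted path solver."""
    XT = np.ascontiguousarray(X_std.T)
    coefs, icpts = _cd_path_kernel(
        XT,
        np.ascontiguousarray(y, dtype=np.float64),
        float(alpha),
        np.ascontiguousarray(lambdas, dtype=np.float64),
        float(tol),
        max_irls,
        max_sweeps,
    )
    return [(coefs[i], float(icpts[i])) for i in range(len(lambdas))]


class ElasticNetLogisticCV(ClassifierMixin, BaseEstimator):
    """Binary elastic-net logistic regression with inner-CV lambda selection.

    Parameters
    ----------
    alpha : float in [0, 1]
        Lasso/ridge mixing parameter (1 = lasso, 0 = ridge).
    n_lambda, lambda_min_ratio : int, float
        Length and depth of the log-spaced lambda path from lambda_max.
    inner_folds : int
        Folds of the inner cross-validation that selects lambda ("min" rule).
    tol : float
        Coordinate-descent convergence tolerance.
    random_state : int or None
        Seeds fold shuffling for ungrouped CV (the solver itself is
        deterministic).

    Attributes
    ----------
    coef_ : (n_features,) coefficients on the original feature scale
    intercept_ : float
    lambda_ : the selected penalty strength
    lambda_path_, cv_deviance_path_ : the searched path and its CV curve
    """

    def __init__(
        self,
        alpha: float = 0.5,
        n_lambda: int = 100,
        lambda_min_ratio: float = 1e-4,
        inner_folds: int = 6,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.alpha = alpha
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.inner_folds = inner_folds
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y, groups=None) -> "ElasticNetLogisticCV":
        """Fit, selecting lambda by grouped inner CV.

        ``groups`` (e.g. epitope sequences) keeps all records of one group in
        a single inner fold, preventing leakage between fit and validation.
        """
        X, y = check_X_y(X, y, dtype=np.float64)
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
        self.classes_ = classes
        y01 = (y == classes[1]).astype(np.float64)
        rs = 0 if self.random_state is None else int(self.random_state) % (2**31 - 1)

        X_std, mu, sd = _standardize(X)
        lambdas = lambda_path(
            X_std, y01, self.alpha, self.n_lambda, self.lambda_min_ratio
        )

        if groups is not None:
            splitter = GroupKFold(n_splits=self.inner_folds)
            splits = splitter.split(X_std, y01, np.asarray(groups))
        else:
            splitter = KFold(n_splits=self.inner_folds, shuffle=True, random_state=rs)
            splits = splitter.split(X_std, y01)

        dev = np.zeros((self.inner_folds, len(lambdas)))
        for f, (tr, va) in enumerate(splits):
            Xtr, mtr, sdtr = _standardize(X[tr])
            Xva = (X[va] - mtr) / sdtr
            path = _fit_path(Xtr, y01[tr], self.alpha, lambdas, self.tol)
            for j, (coef, icept) in enumerate(path):
                prob = expit(Xva @ coef + icept)
                dev[f, j] = binomial_deviance(y01[va], prob)

        mean_dev = dev.mean(axis=0)
        # ties toward the larger (sparser) lambda: argmin takes the first,
        # and the path is ordered from large to small
        best = int(np.argmin(mean_dev))
        self.lambda_path_ = lambdas
        self.cv_deviance_path_ = mean_dev
        self.lambda_ = float(lambdas[best])

        final_path = _fit_path(X_std, y01, self.alpha, lambdas[: best + 1], self.tol)
        coef_std, icept_std = final_path[-1]
        self.coef_ = coef_std / sd
        self.coef_[coef_std == 0.0] = 0.0
        self.intercept_ = float(icept_std - np.dot(coef_std, mu / sd))
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X) -> np.ndarray:
        X = check_array(X, dtype=np.float64)
        return X @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X) -> np.ndarray:
        p1 = expit(self.decision_function(X))
        return self.classes_[(p1 > 0.5).astype(int)]

    @property
    def n_nonzero_(self) -> int:
        return int(np.count_nonzero(self.coef_))


def fit_elastic_net(
    X,
    y,
    alpha: float,
    groups=None,
    inner_folds: int = 6,
    seed: int | None = None,
    **kwargs,
) -> ElasticNetLogisticCV:
    """Functional wrapper over :class:`ElasticNetLogisticCV`."""
    est = ElasticNetLogisticCV(
        alpha=alpha, inner_folds=inner_folds, random_state=seed, **kwargs
    )
    return est.fit(X, y, groups=groups)
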