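"""NIPALS partial least squares regression (PLS1) with cross-validation.

The spectral matrix X and response y are mean-centered and decomposed as

    X = T P' + E,      y = T q + f,

extracting one latent component at a time: the weight vector w maximises
covariance with the (deflated) response, the score t = X w, the X-loading
p = X't / t't and y-loading q = y't / t't, after which X is deflated by
t p'.  Predictions for new spectra run either through the score space
(project with weights, deflate, accumulate t_a q_a) or through the compact
regression vector b = W (P'W)^-1 q with yhat = y_mean + (x - x_mean) b; the
two routes agree to numerical precision and both are exposed.

Component count is chosen by leave-one-out cross-validation, taking the
smallest count attaining the minimal RMSECV.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLSModel",
    "CvResult",
    "RegressionMetrics",
    "fit_pls",
    "predict",
    "predict_via_scores",
    "loo_cv",
    "split_calibration_validation",
    "regression_metrics",
]


@dataclass
class PLSModel:
    """Fitted PLS1 model in both factorised and compact form."""

    x_mean: np.ndarray          # length p
    y_mean: float
    weights: np.ndarray         # p x A  (W)
    x_loadings: np.ndarray      # p x A  (P)
    y_loadings: np.ndarray      # length A  (q)
    coef: np.ndarray            # length p, yhat = y_mean + (x - x_mean) @ coef
    n_components: int

    def coef_for(self, a: int) -> np.ndarray:
        """Compact regression vector using only the leading ``a`` components."""
        W = self.weights[:, :a]
        P = self.x_loadings[:, :a]
        q = self.y_loadings[:a]
        return W @ np.linalg.solve(P.T @ W, q)

    def to_json(self, path) -> None:
        payload = {
            "x_mean": self.x_mean.tolist(),
            "y_mean": self.y_mean,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "n_components": self.n_components,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PLSModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            x_mean=np.array(d["x_mean"]),
            y_mean=float(d["y_mean"]),
            weights=np.array(d["weights"]),
            x_loadings=np.array(d["x_loadings"]),
            y_loadings=np.array(d["y_loadings"]),
            coef=np.array(d["coef"]),
            n_components=int(d["n_components"]),
        )


@dataclass
class CvResult:
    """RMSECV per candidate component count and the chosen count."""

    rmsecv: np.ndarray          # index a-1 -> RMSECV with a components
    n_components: int           # smallest count attaining the minimum

    def __post_init__(self):
        self.rmsecv = np.asarray(self.rmsecv, dtype=float)


@dataclass(frozen=True)
class RegressionMetrics:
    """Coefficient of determination and root mean square error."""

    r2: float
    rmse: float
    n: int


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, a_max: int, tol: float = 1e-12):
    """Core NIPALS loop on centered data; returns (W, P, q, a_used)."""
    n, p = Xc.shape
    W = np.zeros((p, a_max))
    P = np.zeros((p, a_max))
    q = np.zeros(a_max)
    X = Xc.copy()
    y = yc.copy()
    a_used = 0
    for a in range(a_max):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw < tol:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt < tol:
            break
        p_a = X.T @ t / tt
        q_a = float(y @ t) / tt
        X = X - np.outer(t, p_a)
        y = y - q_a * t
        W[:, a], P[:, a], q[a] = w, p_a, q_a
        a_used = a + 1
    return W[:, :a_used], P[:, :a_used], q[:a_used], a_used


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS1 by NIPALS on mean-centered data.

    ``X`` may be a SpectraMatrix or an (n, p) array; ``y`` a length-n
    response.  Requesting more components than the data can support
    truncates with a warning.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 2:
        raise ValueError("PLS needs at least 2 samples")
    if y.size != n or not np.all(np.isfinite(y)):
        raise ValueError("response must be finite and match the sample count")
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    cap = min(n - 1, p)
    if n_components > cap:
        warnings.warn(
            f"n_components={n_components} exceeds min(n-1, p)={cap}; truncating"
        )
        n_components = cap

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, a_used = _nipals_pls1(X - x_mean, y - y_mean, n_components)
    if a_used < n_components:
        warnings.warn(
            f"NIPALS stopped after {a_used} components (rank exhausted)"
        )
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSModel(
        x_mean=x_mean,
        y_mean=y_mean,
        weights=W,
        x_loadings=P,
        y_loadings=q,
        coef=coef,
        n_components=a_used,
    )


def predict(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict responses via the compact regression vector."""
    X = _as_matrix(X)
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"feature count {X.shape[1]} does not match training {model.x_mean.size}"
        )
    return model.y_mean + (X - model.x_mean) @ model.coef


def predict_via_scores(model: PLSModel, X: np.ndarray) -> np.ndarray:
    """Predict through the score space: project, deflate, accumulate t_a q_a.

    Numerically equivalent to :func:`predict`; kept as the second route of
    the factorisation for consistency checks.
    """
    X = _as_matrix(X)
    E = X - model.x_mean
    yhat = np.full(X.shape[0], model.y_mean)
    for a in range(model.n_components):
        t = E @ model.weights[:, a]
        yhat = yhat + t * model.y_loadings[a]
        E = E - np.outer(t, model.x_loadings[:, a])
    return yhat


def loo_cv(X: np.ndarray, y: np.ndarray, max_components: int = 10) -> CvResult:
    """Leave-one-out cross-validation over candidate component counts.

    Each left-out sample is predicted from a model refit on the rest; one
    NIPALS pass at ``max_components`` per held-out sample yields predictions
    for every smaller count via nested coefficient vectors.  Ties in RMSECV
    are broken toward fewer components.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("LOO cross-validation needs at least 3 samples")
    cap = min(n - 2, p)
    if max_components > cap:
        warnings.warn(f"max_components capped at {cap}")
        max_components = cap

    press = np.zeros(max_components)       # squared-error accumulators per a
    counts = np.zeros(max_components)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xi, yi = X[keep], y[keep]
        x_mean = Xi.mean(axis=0)
        y_mean = yi.mean()
        W, P, q, a_used = _nipals_pls1(Xi - x_mean, yi - y_mean, max_components)
        if a_used == 0:
            continue
        # nested predictions: b_a from leading a columns
        M = P.T @ W
        xc = X[i] - x_mean
        for a in range(1, a_used + 1):
            b = W[:, :a] @ np.linalg.solve(M[:a, :a], q[:a])
            err = y[i] - (y_mean + xc @ b)
            press[a - 1] += err * err
            counts[a - 1] += 1
        for a in range(a_used + 1, max_components + 1):
            # rank exhausted: best available model stands in
            b = W @ np.linalg.solve(M, q)
            err = y[i] - (y_mean + xc @ b)
            press[a - 1] += err * err
            counts[a - 1] += 1
    rmsecv = np.sqrt(press / counts)
    best = int(np.argmin(rmsecv)) + 1      # argmin takes the first minimum
    return CvResult(rmsecv=rmsecv, n_components=best)


def split_calibration_validation(
    n_or_indices, ratio: float = 3 / 5, seed: int | np.random.Generator = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint split into calibration and validation index sets.

    ``|calibration| = round(ratio * n)`` via a uniform permutation under the
    given seed; deterministic per seed.
    """
    if np.isscalar(n_or_indices):
        indices = np.arange(int(n_or_indices))
    else:
        indices = np.asarray(n_or_indices)
    n = indices.size
    if n == 0:
        raise ValueError("cannot split an empty group")
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    n_cal = int(round(ratio * n))
    if n_cal == 0 or n_cal == n:
        raise ValueError(f"split leaves an empty side (n={n}, ratio={ratio})")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    perm = rng.permutation(n)
    return np.sort(indices[perm[:n_cal]]), np.sort(indices[perm[n_cal:]])


def regression_metrics(y_true, y_pred) -> RegressionMetrics:
    """R^2 (about the mean of y_true) and RMSE in the response's units.

    R^2 may be negative when predictions are worse than the evaluation-set
    mean — the convention used for held-out validation sets.
    """
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("need equal-length vectors with at least 2 values")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R^2 undefined: y_true has zero variance")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return RegressionMetrics(
        r2=1.0 - ss_res / ss_tot,
        rmse=float(np.sqrt(np.mean((y_true - y_pred) ** 2))),
        n=int(y_true.size),
    )


def _as_matrix(X) -> np.ndarray:
    values = getattr(X, "values", X)
    return np.atleast_2d(np.asarray(values, dtype=float))
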