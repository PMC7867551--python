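"""L1-regularized squared-hinge linear SVM (scikit-learn style estimator).

The model minimizes

    ||w||_1 + C * sum_i max(0, 1 - y_i * w^T x_i)**2

— the sparse linear classifier used to separate treatment conditions from
the 28 pairwise-coherence features. The L1 penalty drives most weights to
exact zero at moderate cost C, so the surviving connections are directly
interpretable as the functional connections the classifier relies on.

Conventions
-----------
* The bias is handled by appending a constant-1 feature that is penalized
  like any other (augmented-bias convention); ``fit_intercept=False``
  turns it off.
* Features are z-scored with training-set statistics before fitting
  (L1 penalties are scale-sensitive); ``standardize=False`` turns it off.
  Frozen standardization parameters travel with the model so it can be
  applied to new sessions without retraining.
* A score of exactly 0 classifies as the negative class (conservative
  toward sham/untreated).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._solver import fit_path, objective_value, solve_cd


class DegenerateLabelsError(ValueError):
    """Training data contains fewer than two classes."""


def zero_cost_threshold(X: np.ndarray, y: np.ndarray) -> float:
    """Largest C at which the all-zero weight vector is optimal.

    At w = 0 every margin is 1 and the smooth-part gradient is
    -2C * sum_i y_i x_ij; w = 0 satisfies the L1 subgradient optimality
    condition iff |2C * sum_i y_i x_ij| <= 1 for every feature j, i.e.
    C <= 1 / (2 * max_j |sum_i y_i x_ij|).

    ``X`` and ``y`` are taken as the solver sees them (after any
    standardization / bias augmentation).
    """
    corr = np.abs(np.asarray(X).T @ np.asarray(y))
    mx = corr.max() if corr.size else 0.0
    return float(np.inf) if mx == 0 else float(1.0 / (2.0 * mx))


class SparseHingeSVM(BaseEstimator, ClassifierMixin):
    """Sparse linear classifier with L1 penalty and squared-hinge loss.

    Parameters
    ----------
    C : float
        Misclassification cost weighting the squared hinge; small C
        yields sparser, more regularized models.
    standardize : bool
        Z-score features with training statistics before fitting.
    fit_intercept : bool
        Append a penalized constant-1 feature (augmented bias).
    tol : float
        Stop when the maximum coordinate-wise optimality violation falls
        below this value.
    max_sweeps : int
        Cap on full coordinate sweeps.

    Attributes
    ----------
    coef_ : ndarray, shape (n_features,)
        Weights on the original (unstandardized) feature order.
    intercept_ : float
    classes_ : ndarray, shape (2,)
        ``classes_[1]`` is the positive (+1) class.
    scale_mean_, scale_std_ : ndarray
        Frozen standardization parameters (zeros/ones if disabled).
    n_iter_ : int
        Coordinate sweeps used.
    """

    def __init__(
        self,
        C: float = 1.0,
        standardize: bool = True,
        fit_intercept: bool = True,
        tol: float = 1e-8,
        max_sweeps: int = 10_000,
    ) -> None:
        self.C = C
        self.standardize = standardize
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_sweeps = max_sweeps

    def _encode(self, y: np.ndarray) -> np.ndarray:
        classes = np.unique(y)
        if len(classes) != 2:
            raise DegenerateLabelsError(
                f"need exactly 2 classes, got {list(classes)}"
            )
        self.classes_ = classes
        return np.where(y == classes[1], 1.0, -1.0)

    def fit(self, X, y, feature_names=None) -> "SparseHingeSVM":
        if self.C <= 0:
            raise ValueError("C must be positive")
        X, y = check_X_y(X, y, dtype=np.float64)
        ypm = self._encode(y)
        n, p = X.shape

        if self.standardize:
            self.scale_mean_ = X.mean(axis=0)
            sd = X.std(axis=0)
            self.scale_std_ = np.where(sd > 0, sd, 1.0)
        else:
            self.scale_mean_ = np.zeros(p)
            self.scale_std_ = np.ones(p)
        Xs = (X - self.scale_mean_) / self.scale_std_
        if self.fit_intercept:
            Xs = np.hstack([Xs, np.ones((n, 1))])

        w = np.zeros(Xs.shape[1])
        self.n_iter_ = int(
            solve_cd(Xs, ypm, float(self.C), w, int(self.max_sweeps),
                     float(self.tol))
        )
        self.coef_ = w[:p].copy()
        self.intercept_ = float(w[p]) if self.fit_intercept else 0.0
        self.n_features_in_ = p
        self.feature_names_ = (
            tuple(feature_names) if feature_names is not None else None
        )
        return self

    def _check_X(self, X) -> np.ndarray:
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=np.float64)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features; model was trained with "
                f"{self.n_features_in_}"
            )
        return X

    def decision_function(self, X) -> np.ndarray:
        """Classification score w^T x (+ bias) before thresholding."""
        X = self._check_X(X)
        Xs = (X - self.scale_mean_) / self.scale_std_
        return Xs @ self.coef_ + self.intercept_

    def predict(self, X) -> np.ndarray:
        """Sign rule: positive score -> positive class; ties -> negative."""
        scores = self.decision_function(X)
        return self.classes_[(scores > 0).astype(int)]

    def objective(self, X, y) -> float:
        """Value of the trained objective on (X, y) in solver coordinates."""
        X = self._check_X(X)
        ypm = np.where(np.asarray(y) == self.classes_[1], 1.0, -1.0)
        Xs = (X - self.scale_mean_) / self.scale_std_
        if self.fit_intercept:
            Xs = np.hstack([Xs, np.ones((len(Xs), 1))])
            w = np.append(self.coef_, self.intercept_)
        else:
            w = self.coef_
        return objective_value(Xs, ypm, w, self.C)

    def nonzero_connections(self) -> list[tuple[str, float, str]]:
        """Connections carrying nonzero weight, largest |weight| first.

        Returns (name, weight, direction) triples where direction reports
        whether coherence on that connection is increased or decreased in
        the positive class.
        """
        check_is_fitted(self, "coef_")
        names = self.feature_names_ or tuple(
            f"f{j}" for j in range(self.n_features_in_)
        )
        nz = [
            (names[j], float(self.coef_[j]),
             "increase" if self.coef_[j] > 0 else "decrease")
            for j in np.flatnonzero(self.coef_)
        ]
        return sorted(nz, key=lambda t: abs(t[1]), reverse=True)


def train(
    X,
    y,
    C: float,
    feature_names=None,
    standardize: bool = True,
    fit_intercept: bool = True,
    tol: float = 1e-8,
    max_sweeps: int = 10_000,
) -> SparseHingeSVM:
    """Functional wrapper over :class:`SparseHingeSVM`."""
    model = SparseHingeSVM(
        C=C, standardize=standardize, fit_intercept=fit_intercept,
        tol=tol, max_sweeps=max_sweeps,
    )
    return model.fit(X, y, feature_names=feature_names)


def score(model: SparseHingeSVM, x) -> float:
    """Classification score of a single feature vector."""
    return float(model.decision_function(np.atleast_2d(x))[0])


def weight_path(
    X, y, C_grid, standardize: bool = True, fit_intercept: bool = True,
    max_sweeps: int = 10_000, tol: float = 1e-8, scale_tol: bool = False,
) -> np.ndarray:
    """Warm-started weight path over an ascending C grid (solver space).

    ``scale_tol`` multiplies the stopping tolerance by max(1, C), the
    convention of the capped cross-validation inner loop.
    """
    X = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    if set(np.unique(yv)) - {-1.0, 1.0}:
        raise DegenerateLabelsError("y must be coded -1/+1 for weight_path")
    n, p = X.shape
    if standardize:
        mu, sd = X.mean(0), X.std(0)
        X = (X - mu) / np.where(sd > 0, sd, 1.0)
    if fit_intercept:
        X = np.hstack([X, np.ones((n, 1))])
    return fit_path(X, yv, np.asarray(C_grid, dtype=float), max_sweeps, tol,
                    scale_tol=scale_tol)
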