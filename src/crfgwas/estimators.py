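"""Scikit-learn style estimators wrapping the random-field model.

``PairwiseCRF`` is the core conditional model: a logistic-family classifier
whose linear predictor carries, besides the covariates, a neighbour field
summarizing the phenotypes of genetically similar individuals.  With
``similarity=None`` it reduces exactly to (a factor-2 reparameterization
of) ordinary logistic regression with a robust sandwich covariance.

``CRFGenomeScan`` runs the per-SNP association scan as a fit-once object
holding the tidy results table.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted
from scipy.special import expit

from .crf import fit_pseudolikelihood
from .datatypes import CovariateMatrix, GenotypeMatrix, PhenotypeVector, SimilarityMatrix
from .scan import precompute_offsets, run_scan
from .similarity import center_couplings

__all__ = ["PairwiseCRF", "CRFGenomeScan"]


class PairwiseCRF(ClassifierMixin, BaseEstimator):
    """Pairwise conditional random field fitted by pseudo-likelihood.

    Parameters
    ----------
    similarity : ndarray of shape (n, n) or None
        Pairwise genetic similarities between the *training* individuals.
        ``None`` disables the pairwise term (independent logistic model).
    coupling : {"centered", "raw"}
        Transform applied to the similarities before use as edge weights.
    coupling_scale : {"learned", "fixed"}
        "learned" estimates a scalar coefficient on the neighbour field,
        "fixed" uses it as a unit-coefficient offset.
    fit_intercept : bool
        Prepend a constant column.
    optimizer : {"newton", "gd"}
        Damped Newton (default) or plain gradient descent with rate ``eta``.
    eta, tol, max_iter
        Gradient-descent learning rate, gradient max-norm convergence
        tolerance, and iteration cap.

    Attributes
    ----------
    coef_ : weights of the covariate columns (model parameterization; the
        comparable logistic-regression coefficient is twice this)
    intercept_ : fitted intercept (0 when fit_intercept=False)
    coupling_coef_ : learned neighbour-field coefficient (1.0 when fixed)
    sandwich_ : robust covariance of the fitted weight vector
    offsets_ : neighbour field used during fitting
    n_iter_, converged_ : optimization record
    """

    def __init__(
        self,
        similarity: np.ndarray | None = None,
        *,
        coupling: str = "centered",
        coupling_scale: str = "learned",
        fit_intercept: bool = True,
        optimizer: str = "newton",
        eta: float = 0.01,
        tol: float = 1e-8,
        max_iter: int = 500,
    ) -> None:
        self.similarity = similarity
        self.coupling = coupling
        self.coupling_scale = coupling_scale
        self.fit_intercept = fit_intercept
        self.optimizer = optimizer
        self.eta = eta
        self.tol = tol
        self.max_iter = max_iter

    def _design(self, X: np.ndarray, offsets: np.ndarray | None):
        cols = []
        if self.fit_intercept:
            cols.append(np.ones((X.shape[0], 1)))
        cols.append(X)
        if offsets is not None and self.coupling_scale == "learned":
            cols.append(offsets[:, None])
        return np.column_stack(cols)

    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y have different numbers of rows")
        yv = y.labels if isinstance(y, PhenotypeVector) else y
        if not np.isin(yv, (0, 1)).all():
            raise ValueError("y must be binary 0/1")
        n = X.shape[0]

        r = None
        if self.similarity is not None:
            a = (
                self.similarity.values
                if isinstance(self.similarity, SimilarityMatrix)
                else np.asarray(self.similarity, dtype=float)
            )
            if a.shape != (n, n):
                raise ValueError("similarity must be n x n for the training rows")
            if self.coupling == "centered":
                a = center_couplings(a)
            elif self.coupling == "raw":
                a = a - np.diag(np.diag(a))
            else:
                raise ValueError(f"unknown coupling {self.coupling!r}")
            r = precompute_offsets(a, yv)

        design = self._design(X, r)
        fixed = r if (r is not None and self.coupling_scale == "fixed") else np.zeros(n)
        fit = fit_pseudolikelihood(
            yv, design, fixed,
            optimizer=self.optimizer, eta=self.eta,
            tol=self.tol, max_iter=self.max_iter,
        )

        w = fit.weights
        k = 0
        if self.fit_intercept:
            self.intercept_ = float(w[0])
            k = 1
        else:
            self.intercept_ = 0.0
        p = X.shape[1]
        self.coef_ = np.asarray(w[k : k + p])
        if r is not None and self.coupling_scale == "learned":
            self.coupling_coef_ = float(w[-1])
        else:
            self.coupling_coef_ = 1.0 if r is not None else 0.0
        self.offsets_ = np.zeros(n) if r is None else r
        self.sandwich_ = fit.sandwich
        self.hessian_ = fit.hessian
        self.score_outer_ = fit.score_outer
        self.neg_log_pl_ = fit.neg_log_pl
        self.n_iter_ = fit.iterations
        self.converged_ = fit.converged
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = p
        return self

    def decision_function(self, X, offsets: np.ndarray | None = None):
        """Linear predictor 2(w.x + gamma * r); offsets default to zero for
        individuals outside the training graph."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        r = np.zeros(X.shape[0]) if offsets is None else np.asarray(offsets, dtype=float)
        return 2.0 * (self.intercept_ + X @ self.coef_ + self.coupling_coef_ * r)

    def predict_proba(self, X, offsets: np.ndarray | None = None):
        p1 = expit(self.decision_function(X, offsets))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X, offsets: np.ndarray | None = None):
        return (self.decision_function(X, offsets) > 0).astype(int)


class CRFGenomeScan(BaseEstimator):
    """Per-SNP Wald scan as a reusable configured object.

    ``fit(geno, y, covariates=..., similarity=...)`` runs the scan; the
    tidy per-SNP table lands in ``results_`` and calibration quantities can
    be computed from ``results_["chi2"]`` / ``results_["p"]``.
    """

    def __init__(
        self,
        *,
        coupling: str = "centered",
        coupling_scale: str = "prefit",
        optimizer: str = "newton",
        eta: float = 0.01,
        tol: float = 1e-8,
        max_iter: int = 500,
    ) -> None:
        self.coupling = coupling
        self.coupling_scale = coupling_scale
        self.optimizer = optimizer
        self.eta = eta
        self.tol = tol
        self.max_iter = max_iter

    def fit(
        self,
        geno: GenotypeMatrix,
        y: PhenotypeVector,
        *,
        covariates: CovariateMatrix | None = None,
        similarity: SimilarityMatrix | np.ndarray | None = None,
    ):
        scan = run_scan(
            geno, covariates, y, similarity,
            coupling=self.coupling, coupling_scale=self.coupling_scale,
            optimizer=self.optimizer, eta=self.eta,
            tol=self.tol, max_iter=self.max_iter,
        )
        self.results_ = scan.table
        self.metadata_ = scan.metadata
        return self
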