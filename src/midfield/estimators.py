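"""Scikit-learn style estimators for receptive-field dimension recovery.

``MaximallyInformativeDimensions`` is a transformer: ``fit(X, y)`` on an
embedded-stimulus design matrix and per-row spike counts estimates the K
maximally informative dimensions; ``transform`` projects stimuli onto them and
``score`` reports the captured information in bits per spike.

``ProjectionPursuitRegressor`` is the additive-ridge least-squares baseline
with the usual ``fit`` / ``predict`` regressor surface.

Both follow scikit-learn conventions (``get_params`` / ``set_params``, fitted
attributes with trailing underscores, input validation), so they compose with
pipelines and model-selection utilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .info import bin_distributions, mutual_information
from .optim import AnnealConfig, fit_dimensions, fit_jackknifed
from .ppr import PPRConfig, fit_ppr

__all__ = ["MaximallyInformativeDimensions", "ProjectionPursuitRegressor"]


def _check_Xy(X, y):
    X = np.asarray(X)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be a 2D design matrix of embedded stimuli")
    if y.ndim != 1 or y.shape[0] != X.shape[0]:
        raise ValueError("y must be a 1D spike-count vector aligned with X")
    if np.any(y < 0):
        raise ValueError("spike counts must be nonnegative")
    return X, y


class MaximallyInformativeDimensions(TransformerMixin, BaseEstimator):
    """Estimate K maximally informative stimulus dimensions.

    Parameters
    ----------
    n_dims : int
        Number of relevant dimensions K to estimate (1-3 with the histogram
        estimator).
    mode : {"joint", "sequential"}
        Joint K-dimensional information maximization, or one-dimensional
        searches restricted to orthogonal complements.
    jackknife : bool
        Fit on ``n_folds`` training sets each omitting a contiguous block, and
        average the aligned estimates (the protocol used for error bars).
        With ``False`` a single fit on all data is performed.
    n_iterations, bins_start, bins_stop, cooling, refresh_period, line_evals,
    convergence_tol, convergence_patience, reheat_factor, perturb_scale :
        Annealing-optimizer settings; see :class:`midfield.optim.AnnealConfig`.
    eval_bins : int
        Bin count used for the reported information values.
    random_state : int or None
        Seeds every stochastic element (starting frames, acceptance draws).

    Attributes
    ----------
    dimensions_ : ndarray of shape (n_dims, n_features)
        Aligned (fold-averaged) unit-norm dimension estimates.
    dimensions_per_fold_ : ndarray of shape (n_folds, n_dims, n_features)
    info_per_fold_ : ndarray of shape (n_folds,)
        Training information (bits/spike) of the final set per fold.
    info_traces_ : per-fold, per-dimension iteration traces.
    """

    def __init__(
        self,
        n_dims: int = 1,
        mode: str = "joint",
        jackknife: bool = True,
        n_folds: int = 4,
        n_iterations: int = 1200,
        bins_start: int = 6,
        bins_stop: int = 11,
        cooling: float = 0.95,
        initial_temperature: float | None = None,
        refresh_period: int = 100,
        line_evals: int = 12,
        convergence_tol: float = 1e-5,
        convergence_patience: int = 10,
        reheat_factor: float = 100.0,
        perturb_scale: float = 0.5,
        eval_bins: int = 11,
        max_k: int = 3,
        random_state: int | None = None,
    ):
        self.n_dims = n_dims
        self.mode = mode
        self.jackknife = jackknife
        self.n_folds = n_folds
        self.n_iterations = n_iterations
        self.bins_start = bins_start
        self.bins_stop = bins_stop
        self.cooling = cooling
        self.initial_temperature = initial_temperature
        self.refresh_period = refresh_period
        self.line_evals = line_evals
        self.convergence_tol = convergence_tol
        self.convergence_patience = convergence_patience
        self.reheat_factor = reheat_factor
        self.perturb_scale = perturb_scale
        self.eval_bins = eval_bins
        self.max_k = max_k
        self.random_state = random_state

    def _config(self) -> AnnealConfig:
        return AnnealConfig(
            iterations_per_dim=self.n_iterations,
            bins_start=self.bins_start,
            bins_stop=self.bins_stop,
            cooling=self.cooling,
            initial_temperature=self.initial_temperature,
            refresh_period=self.refresh_period,
            line_evals=self.line_evals,
            convergence_tol=self.convergence_tol,
            convergence_patience=self.convergence_patience,
            reheat_factor=self.reheat_factor,
            perturb_scale=self.perturb_scale,
            eval_bins=self.eval_bins,
            fold_count=self.n_folds,
            seed=self.random_state,
            max_k=self.max_k,
        )

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        if self.mode not in ("joint", "sequential"):
            raise ValueError("mode must be 'joint' or 'sequential'")
        config = self._config()
        if self.jackknife:
            result = fit_jackknifed(X, y, mode=self.mode, K=self.n_dims, config=config)
            self.dimensions_ = result.dimensions
            self.dimensions_per_fold_ = result.dims_per_fold
            self.info_per_fold_ = result.info_per_fold
            self.info_traces_ = result.info_traces
            self.fit_result_ = result
        else:
            V, traces, info = fit_dimensions(
                X, y, K=self.n_dims, mode=self.mode, config=config
            )
            self.dimensions_ = V
            self.dimensions_per_fold_ = V[None]
            self.info_per_fold_ = np.asarray([info])
            self.info_traces_ = [traces]
            self.fit_result_ = None
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "dimensions_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different dimensionality than at fit time")
        return X @ self.dimensions_.T

    def score(self, X, y) -> float:
        """Information (bits/spike) captured by the fitted dimensions on (X, y)."""
        check_is_fitted(self, "dimensions_")
        X, y = _check_Xy(X, y)
        return mutual_information(bin_distributions(self.transform(X), y, self.eval_bins))


class ProjectionPursuitRegressor(RegressorMixin, BaseEstimator):
    """Additive-ridge least-squares baseline (projection pursuit regression).

    Fits ``rate ~ intercept + sum_k f_k(X @ v_k)`` with piecewise-constant (or
    polynomial) ridge functions, terms added sequentially on residuals with an
    optional back-fitting pass.

    Attributes
    ----------
    dimensions_ : ndarray (n_terms, n_features) -- unit-norm directions.
    ridge_functions_ : list of fitted scalar functions.
    intercept_ : float -- mean training rate.
    chi2_trace_ : chi-squared values across the fitting alternations.
    """

    def __init__(
        self,
        n_terms: int = 1,
        n_bins: int = 15,
        ridge_kind: str = "bins",
        poly_degree: int = 5,
        max_alternations: int = 30,
        tol: float = 1e-9,
        line_evals: int = 12,
        backfit: bool = True,
        init: str = "auto",
        random_state: int | None = None,
    ):
        self.n_terms = n_terms
        self.n_bins = n_bins
        self.ridge_kind = ridge_kind
        self.poly_degree = poly_degree
        self.max_alternations = max_alternations
        self.tol = tol
        self.line_evals = line_evals
        self.backfit = backfit
        self.init = init
        self.random_state = random_state

    def _config(self) -> PPRConfig:
        return PPRConfig(
            n_bins=self.n_bins,
            ridge_kind=self.ridge_kind,
            poly_degree=self.poly_degree,
            max_alternations=self.max_alternations,
            tol=self.tol,
            line_evals=self.line_evals,
            backfit=self.backfit,
            init=self.init,
            seed=self.random_state,
        )

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        model = fit_ppr(X, y, K=self.n_terms, config=self._config())
        self.model_ = model
        self.dimensions_ = model.dimensions
        self.ridge_functions_ = model.ridges
        self.intercept_ = model.intercept
        self.chi2_trace_ = model.chi2_trace
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("X has a different dimensionality than at fit time")
        return self.model_.predict(X)
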