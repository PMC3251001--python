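"""Minimal projection pursuit regression (PPR) baseline.

PPR approximates the firing rate as an additive sum of one-dimensional ridge
functions of projections, ``r(s) ~ rbar + sum_k f_k(s . v_k)``, fitted by
least squares.  Terms are added sequentially: each new (dimension, ridge)
pair is fitted to the residual left by all previous terms, alternating

  (a) ridge update -- ``f`` re-estimated as the bin-averaged (or polynomial
      least-squares) residual versus the current projection, and
  (b) dimension update -- a gradient step on ``v`` of the squared error
      ``chi^2 = sum_n (residual_n - f(x_n))^2`` followed by a line search,

until the decrease in chi-squared stalls.  An optional back-fitting pass
revisits each term against the residual of the others.

The additive (separable) form is the method's defining assumption -- and its
weakness: with correlated non-Gaussian stimuli and a non-separable gain the
recovered subspace is systematically biased, which is what the comparison
against joint information maximization exercises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RidgeFunction", "PPRModel", "fit_ppr_term", "fit_ppr", "chi_squared"]


@dataclass
class RidgeFunction:
    """Piecewise-constant (or polynomial) scalar function of a projection."""

    kind: str  # "bins" | "poly"
    edges: np.ndarray | None = None  # (B+1,) for bins
    values: np.ndarray | None = None  # (B,) for bins
    coeffs: np.ndarray | None = None  # polynomial coefficients (poly)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.kind == "poly":
            return np.polyval(self.coeffs, x)
        B = len(self.values)
        lo, hi = self.edges[0], self.edges[-1]
        idx = np.clip(((x - lo) * (B / (hi - lo))).astype(np.int64), 0, B - 1)
        return self.values[idx]

    def slope(self, x: np.ndarray) -> np.ndarray:
        """Derivative of f at x; finite differences across bins for the binned form."""
        if self.kind == "poly":
            return np.polyval(np.polyder(self.coeffs), np.asarray(x, dtype=float))
        B = len(self.values)
        lo, hi = self.edges[0], self.edges[-1]
        width = (hi - lo) / B
        idx = np.clip(((np.asarray(x) - lo) * (B / (hi - lo))).astype(np.int64), 0, B - 1)
        dv = np.gradient(self.values, width)
        return dv[idx]


@dataclass
class PPRModel:
    """Fitted additive model: intercept (mean rate) plus K ridge terms."""

    dimensions: np.ndarray  # (K, D) unit rows
    ridges: list  # K RidgeFunction, mean-centred on the training data
    intercept: float
    chi2_trace: list

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        out = np.full(matrix.shape[0], self.intercept)
        for v, f in zip(self.dimensions, self.ridges):
            out = out + f(matrix @ v)
        return out


def chi_squared(residual: np.ndarray, prediction: np.ndarray) -> float:
    return float(np.sum((residual - prediction) ** 2))


def _fit_ridge(
    x: np.ndarray, residual: np.ndarray, n_bins: int, kind: str, poly_degree: int
) -> RidgeFunction:
    if kind == "poly":
        coeffs = np.polyfit(x, residual, poly_degree)
        f = RidgeFunction(kind="poly", coeffs=coeffs)
    else:
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.clip(((x - lo) * (n_bins / (hi - lo))).astype(np.int64), 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        sums = np.bincount(idx, weights=residual, minlength=n_bins)
        values = np.where(counts > 0, sums / np.maximum(counts, 1.0), 0.0)
        f = RidgeFunction(kind="bins", edges=edges, values=values)
    # centre the ridge so the intercept keeps the mean rate
    offset = float(np.mean(f(x)))
    if kind == "poly":
        f.coeffs = f.coeffs.copy()
        f.coeffs[-1] -= offset
    else:
        f.values = f.values - offset
    return f


@dataclass
class PPRConfig:
    n_bins: int = 15
    ridge_kind: str = "bins"  # "bins" | "poly"
    poly_degree: int = 5
    max_alternations: int = 30
    tol: float = 1e-9  # relative chi^2 change
    line_evals: int = 12
    backfit: bool = True
    init: str = "auto"  # "auto" | "linear" | "stc"
    seed: int | None = None


def _golden_max(f, lo, hi, n_evals):
    from .optim import _golden_max as g

    return g(f, lo, hi, n_evals)


def _initial_dimension(X: np.ndarray, residual: np.ndarray, config: PPRConfig) -> np.ndarray:
    """Starting dimension: residual-weighted average and/or top eigenvector of the
    residual-weighted covariance (which captures symmetric, energy-like gains)."""
    rng = np.random.default_rng(config.seed)
    cands = []
    lin = X.T @ residual
    n = np.linalg.norm(lin)
    if n > 1e-12 and config.init in ("auto", "linear"):
        cands.append(lin / n)
    if config.init in ("auto", "stc"):
        r = residual - residual.mean()
        C = X.T @ (r[:, None] * X)
        C = 0.5 * (C + C.T)
        w, vecs = np.linalg.eigh(C)
        for pick in (np.argmax(np.abs(w)),):
            v = vecs[:, pick]
            cands.append(v / np.linalg.norm(v))
    if not cands:
        v = rng.standard_normal(X.shape[1])
        cands.append(v / np.linalg.norm(v))
    if len(cands) == 1:
        return cands[0]
    # pick the candidate whose ridge fit explains more of the residual
    best, best_chi = None, np.inf
    for v in cands:
        x = X @ v
        f = _fit_ridge(x, residual, config.n_bins, config.ridge_kind, config.poly_degree)
        chi = chi_squared(residual, f(x))
        if chi < best_chi:
            best, best_chi = v, chi
    return best


def fit_ppr_term(
    X: np.ndarray,
    residual: np.ndarray,
    config: PPRConfig | None = None,
    v0: np.ndarray | None = None,
):
    """Fit one (dimension, ridge function) pair to a residual rate by least squares.

    Alternates ridge re-estimation with an annealing-free gradient/line step on
    the dimension; chi-squared is non-increasing across alternations.  Returns
    ``(unit dimension, RidgeFunction, chi2 trace)``.
    """
    if config is None:
        config = PPRConfig()
    residual = np.asarray(residual, dtype=float)
    if not np.all(np.isfinite(residual)):
        raise ValueError("residual contains non-finite values")
    if np.allclose(residual, residual[0]):
        raise ValueError("constant residual: nothing to fit")
    X = np.asarray(X, dtype=float)
    v = _initial_dimension(X, residual, config) if v0 is None else np.asarray(v0, float)
    v = v / np.linalg.norm(v)

    x = X @ v
    f = _fit_ridge(x, residual, config.n_bins, config.ridge_kind, config.poly_degree)
    chi = chi_squared(residual, f(x))
    trace = [chi]
    step_scale = 1.0
    for _ in range(config.max_alternations):
        # (b) gradient step on the dimension: d(chi^2)/dv = -2 sum (res - f) f'(x) s
        err = residual - f(x)
        grad = -2.0 * (X.T @ (err * f.slope(x)))
        grad = grad - (grad @ v) * v
        gn = np.linalg.norm(grad)
        if gn > 1e-14:
            d = -grad / gn  # descend chi^2

            def line_chi(step: float) -> float:
                if step == 0.0:
                    return -chi
                w = v + step * d
                w = w / np.linalg.norm(w)
                xw = X @ w
                fw = _fit_ridge(xw, residual, config.n_bins, config.ridge_kind, config.poly_degree)
                return -chi_squared(residual, fw(xw))

            step_best, neg_chi_best = _golden_max(line_chi, 0.0, 2.0 * step_scale, config.line_evals)
            if -neg_chi_best < chi:
                v = v + step_best * d
                v = v / np.linalg.norm(v)
                step_scale = max(step_best, 1e-3)
        # (a) ridge refit on the updated projection
        x = X @ v
        f = _fit_ridge(x, residual, config.n_bins, config.ridge_kind, config.poly_degree)
        new_chi = chi_squared(residual, f(x))
        trace.append(new_chi)
        if chi - new_chi < config.tol * max(chi, 1e-30):
            chi = new_chi
            break
        chi = new_chi
    return v, f, trace


def fit_ppr(
    X: np.ndarray,
    spikes: np.ndarray,
    K: int,
    config: PPRConfig | None = None,
) -> PPRModel:
    """Sequential PPR fit of K additive terms to spike counts.

    Terms are fitted one at a time on the residual of the previous ones; with
    ``config.backfit`` a final pass revisits each term against the residual of
    the others.  ``K = 0`` returns the constant mean-rate model.
    """
    if config is None:
        config = PPRConfig()
    if K > 3:
        raise ValueError("K > 3 not supported by default")
    spikes = np.asarray(spikes, dtype=float)
    X = np.asarray(X, dtype=float)
    intercept = float(spikes.mean())
    residual = spikes - intercept
    dims: list[np.ndarray] = []
    ridges: list[RidgeFunction] = []
    chi_trace: list[float] = [chi_squared(residual, np.zeros_like(residual))]
    for _ in range(K):
        v, f, tr = fit_ppr_term(X, residual, config)
        dims.append(v)
        ridges.append(f)
        residual = residual - f(X @ v)
        chi_trace.extend(tr)
    if config.backfit and K > 1:
        for k in range(K):
            partial = residual + ridges[k](X @ dims[k])
            v, f, tr = fit_ppr_term(X, partial, config, v0=dims[k])
            dims[k], ridges[k] = v, f
            residual = partial - f(X @ v)
            chi_trace.extend(tr)
    model = PPRModel(
        dimensions=np.vstack(dims) if dims else np.empty((0, X.shape[1])),
        ridges=ridges,
        intercept=intercept,
        chi2_trace=chi_trace,
    )
    return model
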