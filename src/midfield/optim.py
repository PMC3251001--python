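"""Information maximization over stimulus dimensions by annealed gradient ascent.

The search for each dimension alternates gradient computation with a
golden-section line optimization along the (projected) gradient.  Uphill moves
are always accepted; downhill moves are accepted with probability
``exp(dI / T)`` where the effective temperature ``T`` cools by a fixed factor
every iteration.  When progress stalls, the temperature is reheated and the
current point is perturbed by a large random step, letting the search escape
local maxima of the non-convex objective.  The histogram resolution follows a
coarse-to-fine schedule (bin count stepping up across the run), which first
shapes large-scale structure in the dimensions and then refines it.

Two search strategies are provided:

* ``sequential`` -- each new dimension maximizes the one-dimensional
  information, restricted to the orthogonal complement of all previously
  found dimensions, which are never revised.
* ``joint`` -- each new dimension maximizes the full K-dimensional
  information; periodically (every ``refresh_period`` iterations) the earlier
  dimensions also receive a gradient/line step, so the whole set is optimized
  against the joint objective.

For the first dimension the two strategies coincide.  Fitting is repeated on
four jackknife training sets (each omitting a contiguous quarter of the data)
and the per-fold estimates are aligned and averaged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .info import (
    BinningScheme,
    _flux_sample_weights,
    _flux_sample_weights_renyi2,
    _info_from_hist,
    _renyi2_from_hist,
)
from .stimuli import jackknife_partitions

__all__ = [
    "AnnealConfig",
    "FitResult",
    "fit_first_dimension",
    "fit_sequential",
    "fit_joint",
    "fit_dimensions",
    "fit_jackknifed",
]

_LN2 = math.log(2.0)
_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass
class AnnealConfig:
    """Tunables of the annealing optimizer.

    Defaults follow the reference protocol: 1200 iterations per dimension with
    the bin count stepping from 6 to 11 in equal segments, temperature cooling
    by 0.95 per iteration, earlier dimensions refreshed every 100th iteration
    during a joint search, and a 4-fold jackknife.
    """

    iterations_per_dim: int = 1200
    bins_start: int = 6
    bins_stop: int = 11
    cooling: float = 0.95
    initial_temperature: float | None = None  # None: set from early-step |dI|
    reheat_factor: float = 100.0
    convergence_tol: float = 1e-5  # bits
    convergence_patience: int = 10
    refresh_period: int = 100
    line_evals: int = 12
    perturb_scale: float = 0.5
    eval_bins: int = 11
    fold_count: int = 4
    seed: int | None = None
    max_k: int = 3
    whiten: bool = True
    whiten_reg: float = 1e-3  # eigenvalue floor, fraction of the mean eigenvalue
    objective: str = "kl"  # "kl" (information) or "renyi2" (least-squares-equivalent)

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling < 1.0:
            raise ValueError("cooling must be in (0, 1)")
        if self.refresh_period < 1 or self.convergence_patience < 1:
            raise ValueError("periods must be >= 1")
        if self.bins_stop < self.bins_start or self.bins_start < 2:
            raise ValueError("invalid bin schedule")
        if self.objective not in ("kl", "renyi2"):
            raise ValueError("objective must be 'kl' or 'renyi2'")

    def bin_schedule(self, iteration: int) -> int:
        levels = self.bins_stop - self.bins_start + 1
        seg = max(1, math.ceil(self.iterations_per_dim / levels))
        return self.bins_start + min(iteration // seg, levels - 1)


@dataclass
class FitResult:
    """Dimensions estimated on one or more jackknife training folds."""

    mode: str
    n_dims: int
    dimensions: np.ndarray  # (K, D) aligned fold average, unit rows
    dims_per_fold: np.ndarray  # (F, K, D) aligned
    info_per_fold: np.ndarray  # (F,) training information at eval_bins
    info_traces: list  # per fold: list of per-dimension iteration traces
    config: AnnealConfig
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_folds(self) -> int:
        return self.dims_per_fold.shape[0]


# ---------------------------------------------------------------------------
# Fast binned objective over a candidate dimension with cached fixed axes


class _DimObjective:
    """Joint (or 1D) binned information as a function of one moving dimension.

    Projections onto the fixed dimensions are cached, as are their bin
    assignments at the current bin count, so each objective evaluation costs
    one matrix-vector product plus one histogram.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        fixed: list[np.ndarray],
        objective: str = "kl",
    ):
        self.objective = objective
        self.X = X
        self.y = np.asarray(y, dtype=np.float64)
        self.n = X.shape[0]
        self.nspk = float(self.y.sum())
        if self.nspk <= 0:
            raise ValueError("no spikes in training data")
        self.fixed = [np.asarray(v, dtype=X.dtype) for v in fixed]
        self.pfix = [self.X @ v for v in self.fixed]
        self.B = None
        self._fixed_edges: list[np.ndarray] = []
        self._base: np.ndarray | None = None  # flat index over fixed axes

    @property
    def n_axes(self) -> int:
        return len(self.fixed) + 1

    def set_bins(self, B: int) -> None:
        self.B = int(B)
        self._fixed_edges = []
        base = None
        for p in self.pfix:
            edges, idx = self._axis_bins(p)
            self._fixed_edges.append(edges)
            base = idx if base is None else base * self.B + idx
        self._base = base

    def refresh_fixed(self, j: int, v: np.ndarray) -> None:
        self.fixed[j] = np.asarray(v, dtype=self.X.dtype)
        self.pfix[j] = self.X @ self.fixed[j]
        self.set_bins(self.B)

    def _axis_bins(self, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = float(p.min())
        hi = float(p.max())
        if hi <= lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, self.B + 1)
        idx = ((p - lo) * (self.B / (hi - lo))).astype(np.int64)
        np.clip(idx, 0, self.B - 1, out=idx)
        return edges, idx

    def project(self, v: np.ndarray) -> np.ndarray:
        return self.X @ np.asarray(v, dtype=self.X.dtype)

    def value_at(self, x_new: np.ndarray) -> float:
        """Information (bits) with the candidate axis projections ``x_new``."""
        _, idx = self._axis_bins(x_new)
        flat = idx if self._base is None else self._base * self.B + idx
        size = self.B**self.n_axes
        counts = np.bincount(flat, minlength=size)
        spike_counts = np.bincount(flat, weights=self.y, minlength=size)
        if self.objective == "renyi2":
            return _renyi2_from_hist(counts, spike_counts)
        return _info_from_hist(counts, spike_counts)

    def value(self, v: np.ndarray) -> float:
        return self.value_at(self.project(v))

    def gradient(self, x_new: np.ndarray, axis: int | None = None) -> np.ndarray:
        """Gradient of the joint information w.r.t. the dimension on ``axis``.

        ``axis=None`` means the moving (last) axis.
        """
        K = self.n_axes
        if axis is None:
            axis = K - 1
        edges_new, idx_new = self._axis_bins(x_new)
        idx = np.empty((self.n, K), dtype=np.int64)
        for k, p in enumerate(self.pfix):
            _, idx[:, k] = self._axis_bins(p)
        idx[:, K - 1] = idx_new
        scheme = BinningScheme(edges=self._fixed_edges + [edges_new])
        x_axis = x_new if axis == K - 1 else self.pfix[axis]
        weight_fn = (
            _flux_sample_weights_renyi2 if self.objective == "renyi2" else _flux_sample_weights
        )
        c = weight_fn(idx, np.asarray(x_axis, dtype=np.float64), self.y, scheme, axis=axis)
        return self.X.T @ c.astype(self.X.dtype, copy=False)


def _golden_max(f, lo: float, hi: float, n_evals: int):
    """Golden-section maximization on [lo, hi]; returns the best point evaluated."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    fc, fd = f(c), f(d)
    best_x, best_f = (c, fc) if fc >= fd else (d, fd)
    evals = 2
    while evals < n_evals:
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
            x, fx = c, fc
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
            x, fx = d, fd
        evals += 1
        if fx > best_f:
            best_x, best_f = x, fx
    return best_x, best_f


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-30:
        raise ValueError("zero vector cannot be normalized")
    return v / n


def _orthogonalize(v: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    for b in basis:
        v = v - (v @ b) * b
    return v


def _anneal_dimension(
    X: np.ndarray,
    y: np.ndarray,
    fixed: list[np.ndarray],
    v0: np.ndarray,
    config: AnnealConfig,
    rng: np.random.Generator,
    mode: str,
    refresh: bool,
    restart_candidates: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, list[np.ndarray], np.ndarray]:
    """Optimize one dimension; returns (dimension, updated fixed list, info trace).

    ``mode='sequential'``: 1D objective, search restricted orthogonal to ``fixed``.
    ``mode='joint'``: joint objective over ``fixed + [candidate]``; if ``refresh``
    the fixed dimensions get a gradient/line step every ``refresh_period``
    iterations.
    """
    sequential = mode == "sequential"
    obj = _DimObjective(X, y, fixed=[] if sequential else fixed,
                        objective=config.objective)
    ortho_basis = [np.asarray(f, dtype=X.dtype) for f in fixed] if sequential else []

    def clean(v: np.ndarray) -> np.ndarray:
        if sequential and ortho_basis:
            v = _orthogonalize(v, ortho_basis)
        return _unit(v)

    v = clean(np.asarray(v0, dtype=X.dtype))
    B = config.bin_schedule(0)
    obj.set_bins(B)
    x_cur = obj.project(v)
    I_cur = obj.value_at(x_cur)

    T = config.initial_temperature
    warmup: list[float] = []
    warmup_n = 10 if T is None else 0
    temperature = T if T is not None else math.inf

    step_scale = 1.0
    stall = 0
    best_v, best_I = v.copy(), I_cur
    trace = np.empty(config.iterations_per_dim)

    for i in range(config.iterations_per_dim):
        newB = config.bin_schedule(i)
        if newB != B:
            B = newB
            obj.set_bins(B)
            I_cur = obj.value_at(x_cur)
            best_I = obj.value(best_v)  # re-reference the incumbent at the new resolution

        g = obj.gradient(x_cur)
        g = g - (g @ v) * v
        if sequential and ortho_basis:
            g = _orthogonalize(g, ortho_basis)
        gn = np.linalg.norm(g)
        if gn < 1e-14:
            d = rng.standard_normal(v.shape).astype(X.dtype)
            d = d - (d @ v) * v
            if sequential and ortho_basis:
                d = _orthogonalize(d, ortho_basis)
            d = (d / np.linalg.norm(d)).astype(X.dtype)
        else:
            d = (g / gn).astype(X.dtype)

        def line_value(step: float) -> float:
            if step == 0.0:
                return I_cur
            return obj.value(clean(v + X.dtype.type(step) * d))

        step_best, I_best_line = _golden_max(
            line_value, 0.0, 2.0 * step_scale, config.line_evals
        )
        dI = I_best_line - I_cur

        if warmup_n and i < warmup_n:
            accept = True
            warmup.append(abs(dI))
            if i == warmup_n - 1:
                med = float(np.median(warmup))
                temperature = med / _LN2 if med > 0 else 1e-3
        else:
            accept = dI >= 0 or (
                temperature > 0 and rng.random() < math.exp(dI / temperature)
            )

        if dI <= 0:
            # no uphill point on the line: bracket too wide, tighten it
            step_scale = max(step_scale * 0.5, 1e-4)
        if accept and step_best > 0.0:
            v = clean(v + X.dtype.type(step_best) * d)
            x_cur = obj.project(v)
            I_cur = I_best_line
            if dI > 0:
                step_scale = max(step_best, 1e-3)
            if I_cur > best_I:
                best_I = I_cur
                best_v = v.copy()
            stall = stall + 1 if abs(dI) < config.convergence_tol else 0
        elif accept:
            stall += 1
        else:
            stall = 0

        if math.isfinite(temperature):
            temperature *= config.cooling
        if not np.isfinite(I_cur):
            raise FloatingPointError("information objective became non-finite")

        if stall >= config.convergence_patience:
            # converged locally: reheat and take a large random step
            temperature = (
                temperature * config.reheat_factor
                if math.isfinite(temperature)
                else config.reheat_factor * 1e-3
            )
            v = clean(
                v + config.perturb_scale * _unit(rng.standard_normal(v.shape)).astype(X.dtype)
            )
            x_cur = obj.project(v)
            I_cur = obj.value_at(x_cur)
            stall = 0

        if (
            refresh
            and not sequential
            and obj.fixed
            and (i + 1) % config.refresh_period == 0
        ):
            for j in range(len(obj.fixed)):
                I_cur = _refresh_step(
                    obj, j, x_cur, I_cur, step_scale, temperature, rng, config,
                    restart_candidates,
                )

        trace[i] = I_cur

    final_I = obj.value(best_v)
    if I_cur > final_I:
        best_v = v
    out = np.asarray(best_v, dtype=np.float64)
    out /= np.linalg.norm(out)
    return out, [np.asarray(f, dtype=np.float64) for f in obj.fixed] if not sequential else [
        np.asarray(f, dtype=np.float64) for f in fixed
    ], trace


def _refresh_step(
    obj: _DimObjective,
    j: int,
    x_cur: np.ndarray,
    I_cur: float,
    step_scale: float,
    temperature: float,
    rng: np.random.Generator,
    config: AnnealConfig,
    restart_candidates: list[np.ndarray] | None = None,
) -> float:
    """One annealed gradient/line step on a previously found dimension.

    After the local step, wholesale replacement of the dimension by each
    restart candidate is also tested under the joint objective (a
    basin-hopping move: an earlier dimension captured by a spurious
    information maximum cannot be rescued by local steps alone); a
    replacement is kept only if it strictly improves the objective.
    """
    w = obj.fixed[j]
    saved_p = obj.pfix[j].copy()
    saved_w = w.copy()
    g = obj.gradient(x_cur, axis=j)
    g = g - (g @ w) * w
    gn = np.linalg.norm(g)
    if gn > 1e-14:
        d = (g / gn).astype(obj.X.dtype)

        def line_value(step: float) -> float:
            if step == 0.0:
                return I_cur
            trial = _unit(w + obj.X.dtype.type(step) * d)
            obj.refresh_fixed(j, trial)
            return obj.value_at(x_cur)

        step_best, I_best = _golden_max(line_value, 0.0, 2.0 * step_scale, config.line_evals)
        dI = I_best - I_cur
        accept = step_best > 0 and (
            dI >= 0
            or (
                math.isfinite(temperature)
                and temperature > 0
                and rng.random() < math.exp(dI / temperature)
            )
        )
        if accept:
            obj.refresh_fixed(j, _unit(w + obj.X.dtype.type(step_best) * d))
            I_cur = I_best
        else:
            obj.fixed[j] = saved_w
            obj.pfix[j] = saved_p
            obj.set_bins(obj.B)

    if restart_candidates:
        best_w, best_val = None, I_cur
        cur_w = obj.fixed[j].copy()
        cur_p = obj.pfix[j].copy()
        for cand in restart_candidates:
            c = _unit(np.asarray(cand, dtype=obj.X.dtype))
            if abs(float(c @ cur_w)) > 0.99:
                continue
            c, val = _refine_replacement(obj, j, c, x_cur, config)
            if val > best_val:
                best_w, best_val = c, val
        if best_w is not None:
            obj.refresh_fixed(j, best_w)
            I_cur = best_val
        else:
            obj.fixed[j] = cur_w
            obj.pfix[j] = cur_p
            obj.set_bins(obj.B)
    return I_cur


def _refine_replacement(
    obj: _DimObjective,
    j: int,
    w: np.ndarray,
    x_cur: np.ndarray,
    config: AnnealConfig,
    n_steps: int = 3,
) -> tuple[np.ndarray, float]:
    """Polish a restart candidate with a few strict-ascent gradient/line steps.

    A raw candidate is compared against an already-refined incumbent; without
    this polish a basin with a higher ceiling but unrefined entry point would
    always lose the comparison.
    """
    obj.refresh_fixed(j, w)
    val = obj.value_at(x_cur)
    step_scale = 1.0
    for _ in range(n_steps):
        g = obj.gradient(x_cur, axis=j)
        w_cur = obj.fixed[j]
        g = g - (g @ w_cur) * w_cur
        gn = np.linalg.norm(g)
        if gn < 1e-14:
            break
        d = (g / gn).astype(obj.X.dtype)

        def line_value(step: float) -> float:
            if step == 0.0:
                return val
            obj.refresh_fixed(j, _unit(w_cur + obj.X.dtype.type(step) * d))
            return obj.value_at(x_cur)

        step_best, v_best = _golden_max(line_value, 0.0, 2.0 * step_scale, config.line_evals)
        if v_best > val and step_best > 0:
            obj.refresh_fixed(j, _unit(w_cur + obj.X.dtype.type(step_best) * d))
            val = v_best
            step_scale = max(step_best, 1e-3)
        else:
            obj.refresh_fixed(j, w_cur)
            step_scale = max(step_scale * 0.5, 1e-4)
    return obj.fixed[j].copy(), val


# ---------------------------------------------------------------------------
# Whole-model fits


def _spike_triggered_average(X: np.ndarray, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    sta = (X.T @ y.astype(X.dtype)) / float(y.sum()) - X.mean(axis=0)
    norm = np.linalg.norm(sta)
    if norm < 1e-10:
        return _unit(rng.standard_normal(X.shape[1]).astype(X.dtype))
    return (sta / norm).astype(X.dtype)


def _stc_delta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spike-triggered covariance difference ``C_spike - C_all``.

    For gain functions that are symmetric in a projection (energy- or
    threshold-like cells) the spike-triggered average vanishes, but the
    covariance of spike-eliciting stimuli still differs from the prior along
    the relevant dimensions, so this matrix's extreme eigenvectors (most
    positive = excitatory, most negative = suppressive) are informative
    starting points for the information search.
    """
    w = y.astype(np.float64) / float(y.sum())
    mu = X.mean(axis=0)
    Xc = X - mu.astype(X.dtype)
    spk = np.nonzero(y > 0)[0]
    Xs = Xc[spk]
    ws = w[spk].astype(X.dtype)
    C_spike = (Xs.T * ws) @ Xs
    C_all = (Xc.T @ Xc) / X.shape[0]
    delta = (C_spike - C_all).astype(np.float64)
    return 0.5 * (delta + delta.T)


def _eig_candidates(delta: np.ndarray, n_each: int = 2) -> np.ndarray:
    vals, vecs = np.linalg.eigh(delta)
    picks = list(range(len(vals) - 1, len(vals) - 1 - n_each, -1)) + list(range(n_each))
    return vecs[:, picks].T.copy()


def _deflated_candidates(
    delta: np.ndarray, keep_out: list[np.ndarray], n_each: int = 2
) -> list[np.ndarray]:
    """Extreme eigenvectors of the covariance difference restricted to the
    orthogonal complement of ``keep_out`` (deflation): exposes relevant
    structure masked by already-fitted dimensions."""
    if not keep_out:
        return list(_eig_candidates(delta, n_each))
    D = delta.shape[0]
    B = np.zeros((D, len(keep_out)))
    for i, v in enumerate(keep_out):
        B[:, i] = np.asarray(v, dtype=np.float64)
    Q, _ = np.linalg.qr(B)
    P = np.eye(D) - Q @ Q.T
    return list(_eig_candidates(P @ delta @ P, n_each))


def _stc_eigendimensions(X: np.ndarray, y: np.ndarray, n_each: int = 2) -> np.ndarray:
    """Extreme eigenvectors of the spike-triggered covariance difference."""
    return _eig_candidates(_stc_delta(X, y), n_each)


def _zca_transforms(X: np.ndarray, reg: float) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric (ZCA) whitening transform W and its inverse for the stimulus rows.

    The information objective is invariant under a consistent invertible map of
    stimulus space, but optimizing in whitened coordinates preconditions the
    gradient when the ensemble is strongly correlated (e.g. 1/f spectra), where
    raw-space ascent crawls along high-variance directions.  Eigenvalues are
    floored at ``reg`` times their mean to bound noise amplification.
    """
    Xc = X - X.mean(axis=0)
    C = (Xc.T @ Xc).astype(np.float64) / X.shape[0]
    vals, vecs = np.linalg.eigh(0.5 * (C + C.T))
    floor = reg * float(vals.mean())
    vals = np.maximum(vals, floor)
    W = (vecs * (1.0 / np.sqrt(vals))) @ vecs.T
    W_inv = (vecs * np.sqrt(vals)) @ vecs.T
    return W.astype(X.dtype), W_inv.astype(X.dtype)


def _best_start(
    X: np.ndarray,
    y: np.ndarray,
    fixed_for_obj: list[np.ndarray],
    forbid: list[np.ndarray],
    candidates: list[np.ndarray],
    config: AnnealConfig,
) -> np.ndarray:
    """Pick the candidate starting vector with the highest refined objective.

    Candidates are orthogonalized against ``forbid`` (the restricted-search
    basis), polished with a few strict-ascent gradient/line steps, and scored
    with the coarsest bin count of the schedule -- on the 1D objective when
    ``fixed_for_obj`` is empty, otherwise the joint objective.  Refining
    before comparing matters: a suppressive dimension contributes little
    information until its gain structure sharpens, so an unrefined comparison
    systematically discards it.
    """
    obj = _DimObjective(X, y, fixed_for_obj, objective=config.objective)
    obj.set_bins(config.bins_start)
    best_v, best_val = None, -np.inf
    for cand in candidates:
        v = np.asarray(cand, dtype=X.dtype)
        if forbid:
            v = _orthogonalize(v, forbid)
        norm = np.linalg.norm(v)
        if norm < 1e-8:
            continue
        v = v / norm
        v, val = _strict_ascent_moving(obj, v, forbid, config, n_steps=3)
        if val > best_val:
            best_v, best_val = v, val
    if best_v is None:
        raise ValueError("no valid starting point (all candidates degenerate)")
    return best_v


def _strict_ascent_moving(
    obj: _DimObjective,
    v: np.ndarray,
    forbid: list[np.ndarray],
    config: AnnealConfig,
    n_steps: int = 3,
) -> tuple[np.ndarray, float]:
    """A few uphill-only gradient/line steps on the moving axis."""
    x = obj.project(v)
    val = obj.value_at(x)
    step_scale = 1.0
    for _ in range(n_steps):
        g = obj.gradient(x)
        g = g - (g @ v) * v
        if forbid:
            g = _orthogonalize(g, forbid)
        gn = np.linalg.norm(g)
        if gn < 1e-14:
            break
        d = (g / gn).astype(obj.X.dtype)

        def line_value(step: float) -> float:
            if step == 0.0:
                return val
            w = v + obj.X.dtype.type(step) * d
            if forbid:
                w = _orthogonalize(w, forbid)
            return obj.value(_unit(w))

        step_best, v_best = _golden_max(line_value, 0.0, 2.0 * step_scale, config.line_evals)
        if v_best > val and step_best > 0:
            w = v + obj.X.dtype.type(step_best) * d
            if forbid:
                w = _orthogonalize(w, forbid)
            v = _unit(w)
            x = obj.project(v)
            val = v_best
            step_scale = max(step_best, 1e-3)
        else:
            step_scale = max(step_scale * 0.5, 1e-4)
    return v, val


def _orthonormal_basis(vectors: list[np.ndarray], dtype) -> list[np.ndarray]:
    basis: list[np.ndarray] = []
    for v in vectors:
        v = np.asarray(v, dtype=dtype)
        v = _orthogonalize(v, basis)
        n = np.linalg.norm(v)
        if n > 1e-10:
            basis.append(v / n)
    return basis


def _dim_rng(config: AnnealConfig, fold: int, dim: int) -> np.random.Generator:
    base = 0 if config.seed is None else int(config.seed)
    return np.random.default_rng(np.random.SeedSequence([base, fold, dim]))


def fit_dimensions(
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    mode: str,
    config: AnnealConfig | None = None,
    fold: int = 0,
    precomputed_first: np.ndarray | None = None,
) -> tuple[np.ndarray, list[np.ndarray], float]:
    """Single (non-jackknifed) fit of K dimensions on one training set.

    Returns ``(dimensions (K, D), per-dimension info traces, final joint
    information at eval_bins)``.  ``fold`` only seeds the per-dimension random
    streams, so that jackknife folds explore different starting frames.
    """
    if config is None:
        config = AnnealConfig()
    if mode not in ("sequential", "joint"):
        raise ValueError("mode must be 'sequential' or 'joint'")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > config.max_k:
        raise ValueError(
            f"K={K} exceeds the histogram estimator limit max_k={config.max_k}; "
            "raise AnnealConfig.max_k to override"
        )
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    y = np.asarray(y)
    if y.shape[0] != X32.shape[0]:
        raise ValueError("X and y are misaligned")
    if y.sum() <= 0:
        raise ValueError("no spikes in training data")

    if config.whiten:
        W, W_inv = _zca_transforms(X32, config.whiten_reg)
        Xw = X32 @ W
    else:
        W = W_inv = None
        Xw = X32

    def from_w(vw: np.ndarray) -> np.ndarray:
        v = W @ vw if W is not None else vw
        v = np.asarray(v, dtype=np.float64)
        return v / np.linalg.norm(v)

    def to_w_proj(v: np.ndarray) -> np.ndarray:
        # original dimension -> whitened coordinates preserving projections
        if W_inv is None:
            return np.asarray(v, dtype=X32.dtype)
        return (W_inv @ np.asarray(v, dtype=X32.dtype)).astype(X32.dtype)

    def forbid_basis(found: list[np.ndarray]) -> list[np.ndarray]:
        # original-space orthogonality v_new . v_j = 0 becomes, in whitened
        # coordinates, orthogonality to W @ v_j
        if W is None:
            return _orthonormal_basis(found, X32.dtype)
        return _orthonormal_basis([W @ np.asarray(d, dtype=X32.dtype) for d in found], X32.dtype)

    delta_w = _stc_delta(Xw, y)
    stc_starts = _eig_candidates(delta_w)
    dims: list[np.ndarray] = []  # original stimulus space
    traces: list[np.ndarray] = []
    for k in range(K):
        rng = _dim_rng(config, fold, k)
        if k == 0 and precomputed_first is not None:
            dims.append(np.asarray(precomputed_first, dtype=np.float64))
            traces.append(np.empty(0))
            continue
        candidates = [Xw[int(rng.integers(Xw.shape[0]))].copy()]  # a stimulus frame
        if k == 0:
            candidates.append(_spike_triggered_average(Xw, y, rng))
        candidates.extend(np.asarray(s, dtype=Xw.dtype) for s in stc_starts)
        sequential_step = k == 0 or mode == "sequential"
        if sequential_step:
            forbid = forbid_basis(dims)
            v0 = _best_start(Xw, y, [], forbid, candidates, config)
            vw, _, trace = _anneal_dimension(
                Xw, y, forbid, v0, config, rng, mode="sequential", refresh=False
            )
            dims.append(from_w(vw))
        else:
            fixed_w = [to_w_proj(d) for d in dims]
            v0 = _best_start(Xw, y, fixed_w, [], candidates, config)
            vw, updated_w, trace = _anneal_dimension(
                Xw, y, fixed_w, v0, config, rng, mode="joint", refresh=True,
                restart_candidates=[np.asarray(s, dtype=Xw.dtype) for s in stc_starts],
            )
            dims = [from_w(np.asarray(u, dtype=Xw.dtype)) for u in updated_w]
            dims.append(from_w(vw))
        traces.append(trace)

    if mode == "joint" and K >= 2:
        dims_w = [to_w_proj(d) for d in dims]
        polished = _joint_polish(
            Xw, y, dims_w,
            [np.asarray(s, dtype=Xw.dtype) for s in stc_starts],
            config, _dim_rng(config, fold, K), delta=delta_w,
        )
        dims = [from_w(np.asarray(u, dtype=Xw.dtype)) for u in polished]

    V = np.vstack(dims)
    final_info = _joint_info(X32, y, V, config.eval_bins)
    return V, traces, final_info


def _joint_polish(
    Xw: np.ndarray,
    y: np.ndarray,
    dims_w: list[np.ndarray],
    stc_starts: list[np.ndarray],
    config: AnnealConfig,
    rng: np.random.Generator,
    delta: np.ndarray | None = None,
    rounds: int = 3,
) -> list[np.ndarray]:
    """Strict-ascent polish of a fitted joint dimension set.

    Cycles refresh (gradient/line) and restart-rescue moves over every
    dimension at the final bin count with zero temperature, accepting only
    improvements of the joint objective.  Rescue candidates combine the
    global STC eigenvectors with *deflated* ones -- eigenvectors of the
    covariance difference restricted to the complement of the other fitted
    dimensions -- which expose a relevant direction masked by the rest of the
    set.  This recovers configurations where one dimension locked onto a
    spurious maximum during the annealed phase.
    """
    obj = _DimObjective(Xw, y, [np.asarray(d, dtype=Xw.dtype) for d in dims_w[:-1]],
                        objective=config.objective)
    obj.set_bins(config.eval_bins)
    v = _unit(np.asarray(dims_w[-1], dtype=Xw.dtype))
    x_cur = obj.project(v)
    I_cur = obj.value_at(x_cur)

    def rescue_candidates(slot: int | None) -> list[np.ndarray]:
        others = [obj.fixed[j] for j in range(len(obj.fixed)) if j != slot]
        if slot is not None:
            others.append(v)
        cands = list(stc_starts)
        if delta is not None:
            cands.extend(
                np.asarray(c, dtype=Xw.dtype)
                for c in _deflated_candidates(delta, others)
            )
        return cands

    for _ in range(rounds):
        for j in range(len(obj.fixed)):
            I_cur = _refresh_step(
                obj, j, x_cur, I_cur, 1.0, 0.0, rng, config, rescue_candidates(j)
            )
        # moving (last) dimension: strict ascent, then candidate replacement
        v2, val = _strict_ascent_moving(obj, v, [], config, n_steps=5)
        if val > I_cur:
            v, I_cur = v2, val
            x_cur = obj.project(v)
        for cand in rescue_candidates(None):
            c = _unit(np.asarray(cand, dtype=Xw.dtype))
            if abs(float(c @ v)) > 0.99:
                continue
            c2, val = _strict_ascent_moving(obj, c, [], config, n_steps=5)
            if val > I_cur:
                v, I_cur = c2, val
                x_cur = obj.project(v)
    return [f.copy() for f in obj.fixed] + [v]


def _joint_info(X: np.ndarray, y: np.ndarray, V: np.ndarray, n_bins: int) -> float:
    from .info import bin_distributions, mutual_information

    P = X @ np.asarray(V, dtype=X.dtype).T
    return mutual_information(bin_distributions(P, y, n_bins))


def _procrustes_align(V: np.ndarray, V_ref: np.ndarray) -> np.ndarray:
    """Rotate/reflect the set V (rows) within its span to best match V_ref."""
    C = V_ref @ V.T
    U, _, Vt = np.linalg.svd(C)
    return (U @ Vt) @ V


def _align_folds(dims_per_fold: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    aligned = dims_per_fold.copy()
    ref = aligned[0]
    for f in range(1, aligned.shape[0]):
        aligned[f] = _procrustes_align(aligned[f], ref)
    mean = aligned.mean(axis=0)
    norms = np.linalg.norm(mean, axis=1, keepdims=True)
    mean = mean / np.where(norms > 1e-30, norms, 1.0)
    return aligned, mean


def fit_jackknifed(
    X: np.ndarray,
    y: np.ndarray,
    mode: str,
    K: int,
    config: AnnealConfig | None = None,
) -> FitResult:
    """Fit on each of ``fold_count`` jackknife training sets and combine.

    Each fold omits a contiguous 1/fold_count block.  Per-fold estimates are
    sign/rotation aligned to the first fold (orthogonal Procrustes within the
    spanned subspace) before averaging; the averaged rows are renormalized.
    """
    if config is None:
        config = AnnealConfig()
    y = np.asarray(y)
    part = jackknife_partitions(X.shape[0], config.fold_count)
    dims, infos, traces = [], [], []
    for f in range(part.fold_count):
        mask = part.train_mask(f)
        try:
            V, tr, info = fit_dimensions(X[mask], y[mask], K, mode, config, fold=f)
        except Exception as err:  # noqa: BLE001 - annotate with fold index
            raise RuntimeError(f"fit failed on jackknife fold {f}") from err
        dims.append(V)
        infos.append(info)
        traces.append(tr)
    dims_per_fold = np.stack(dims)
    aligned, mean = _align_folds(dims_per_fold)
    return FitResult(
        mode=mode,
        n_dims=K,
        dimensions=mean,
        dims_per_fold=aligned,
        info_per_fold=np.asarray(infos),
        info_traces=traces,
        config=config,
        seed=config.seed,
    )


def fit_first_dimension(X: np.ndarray, y: np.ndarray, config: AnnealConfig | None = None) -> FitResult:
    """Single-fold fit of the first (maximally informative) dimension."""
    if config is None:
        config = AnnealConfig()
    V, traces, info = fit_dimensions(X, y, K=1, mode="sequential", config=config)
    return FitResult(
        mode="first",
        n_dims=1,
        dimensions=V,
        dims_per_fold=V[None],
        info_per_fold=np.asarray([info]),
        info_traces=[traces],
        config=config,
        seed=config.seed,
    )


def fit_sequential(X: np.ndarray, y: np.ndarray, K: int, config: AnnealConfig | None = None) -> FitResult:
    """Single-fold sequential fit of K dimensions (orthogonal 1D searches)."""
    if config is None:
        config = AnnealConfig()
    V, traces, info = fit_dimensions(X, y, K=K, mode="sequential", config=config)
    return FitResult(
        mode="sequential",
        n_dims=K,
        dimensions=V,
        dims_per_fold=V[None],
        info_per_fold=np.asarray([info]),
        info_traces=[traces],
        config=config,
        seed=config.seed,
    )


def fit_joint(X: np.ndarray, y: np.ndarray, K: int, config: AnnealConfig | None = None) -> FitResult:
    """Single-fold joint fit of K dimensions (full K-dimensional information)."""
    if config is None:
        config = AnnealConfig()
    V, traces, info = fit_dimensions(X, y, K=K, mode="joint", config=config)
    return FitResult(
        mode="joint",
        n_dims=K,
        dimensions=V,
        dims_per_fold=V[None],
        info_per_fold=np.asarray([info]),
        info_traces=[traces],
        config=config,
        seed=config.seed,
    )


def config_to_dict(config: AnnealConfig) -> dict:
    return asdict(config)
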