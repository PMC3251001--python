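"""Linear-nonlinear (LN) model cells with Gabor spatiotemporal filters.

An LN cell projects the embedded stimulus onto ``K`` unit-norm relevant
dimensions and maps the projections through a static gain function ``g`` to a
per-frame expected spike count (or spike probability).  Three gain families
are provided:

``or_threshold``
    Binary OR of two threshold units: a spike is emitted if ``|s_i + n_i| > theta``
    for either projection, with additive Gaussian noise ``n_i ~ N(0, sigma^2)``.
    The noise-averaged spike probability has a closed form in Gaussian tails.

``divisive``
    Energy-style numerator with divisive suppression,
    ``r = gamma * [(s.e1)^2 + (s.e2)^2] / [1 + omega * (s.e3)^2]``,
    a simplified divisive gain control with two excitatory dimensions and one
    suppressive dimension.

``quadratic_1d``
    ``r = gamma * (s.e1)^2``, the one-dimensional energy cell.

Spikes are Bernoulli for ``or_threshold`` (the rule is binary) and Poisson for
the rate-valued families.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
from scipy.special import ndtr
from scipy.optimize import brentq

__all__ = [
    "GaborFilterSpec",
    "LNCellSpec",
    "make_gabor_dimension",
    "make_or_cell",
    "make_divisive_cell",
    "make_quadratic_cell",
    "expected_rate",
    "calibrate_gain",
    "simulate_spikes",
    "save_cell",
    "load_cell",
]

#: biphasic temporal profile (oldest lag first): sensitivity to feature onset
DEFAULT_TEMPORAL_WEIGHTS = (-0.4, 0.3, 1.0)


@dataclass
class GaborFilterSpec:
    """Parameters of a spatial Gabor carried by a temporal weight profile."""

    center: tuple[float, float]  # (row, col) in pixels
    orientation: float  # radians
    spatial_frequency: float  # cycles / pixel
    phase: float  # radians
    envelope_sd: float  # pixels
    temporal_weights: tuple[float, ...] = DEFAULT_TEMPORAL_WEIGHTS

    def __post_init__(self) -> None:
        if self.envelope_sd <= 0:
            raise ValueError("envelope_sd must be positive")
        if not np.any(np.asarray(self.temporal_weights)):
            raise ValueError("temporal_weights must not be all zero")


def make_gabor_dimension(spec: GaborFilterSpec, H: int, W: int, n_lags: int) -> np.ndarray:
    """Build a unit-norm spatiotemporal dimension from a Gabor spec.

    The result is separable: ``dim[lag, y, x] = w[lag] * gabor[y, x]``, flattened
    in the same (lag-major, most recent last) order as the stimulus embedding.
    """
    w = np.asarray(spec.temporal_weights, dtype=float)
    if w.shape[0] != n_lags:
        raise ValueError(f"temporal_weights must have length n_lags={n_lags}")
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    dy = yy - spec.center[0]
    dx = xx - spec.center[1]
    # coordinates along / across the carrier
    u = dx * np.cos(spec.orientation) + dy * np.sin(spec.orientation)
    v = -dx * np.sin(spec.orientation) + dy * np.cos(spec.orientation)
    envelope = np.exp(-(u**2 + v**2) / (2.0 * spec.envelope_sd**2))
    carrier = np.cos(2.0 * np.pi * spec.spatial_frequency * u + spec.phase)
    gabor = envelope * carrier
    dim = (w[:, None, None] * gabor[None]).ravel()
    norm = np.linalg.norm(dim)
    if norm < 1e-12:
        raise ValueError("degenerate Gabor parameters give a zero filter")
    return dim / norm


@dataclass
class LNCellSpec:
    """An LN model cell: K unit-norm dimensions plus a gain family."""

    dimensions: np.ndarray  # (K, D)
    gain_family: str  # or_threshold | divisive | quadratic_1d
    theta: float = 2.0  # threshold (or_threshold)
    sigma: float = 0.5  # additive noise SD (or_threshold)
    gamma: float = 1.0  # overall scale (divisive / quadratic_1d)
    suppression: float = 0.0  # divisive suppression strength (omega)
    meta: dict = field(default_factory=dict)

    _ARITY = {"or_threshold": 2, "divisive": 3, "quadratic_1d": 1}

    def __post_init__(self) -> None:
        self.dimensions = np.atleast_2d(np.asarray(self.dimensions, dtype=float))
        if self.gain_family not in self._ARITY:
            raise ValueError(f"unknown gain family {self.gain_family!r}")
        K = self.dimensions.shape[0]
        if K != self._ARITY[self.gain_family]:
            raise ValueError(
                f"{self.gain_family} needs {self._ARITY[self.gain_family]} dimensions, got {K}"
            )
        norms = np.linalg.norm(self.dimensions, axis=1)
        if np.any(norms < 1e-12):
            raise ValueError("dimensions must be nonzero")
        self.dimensions = self.dimensions / norms[:, None]
        if K > 1 and np.linalg.matrix_rank(self.dimensions) < K:
            raise ValueError("dimensions must be linearly independent")
        if self.gain_family == "or_threshold" and (self.theta <= 0 or self.sigma <= 0):
            raise ValueError("theta and sigma must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.suppression < 0:
            raise ValueError("suppression must be nonnegative")

    @property
    def n_dims(self) -> int:
        return self.dimensions.shape[0]


def _or_threshold_probability(
    projections: np.ndarray, theta: float, sigma: float
) -> np.ndarray:
    """Noise-averaged P(spike) for the binary OR-of-thresholds rule.

    Per unit, P(|s + n| > theta) with n ~ N(0, sigma^2) is the sum of the two
    Gaussian tails Q((theta - s)/sigma) + Q((theta + s)/sigma); the OR combines
    the independent units as 1 - prod(1 - p_i).
    """
    s = projections
    q_hi = 1.0 - ndtr((theta - s) / sigma)
    q_lo = 1.0 - ndtr((theta + s) / sigma)
    p_unit = q_hi + q_lo
    return 1.0 - np.prod(1.0 - p_unit, axis=1)


def expected_rate(cell: LNCellSpec, projections: np.ndarray) -> np.ndarray:
    """Expected spike count (or probability) per frame from the K projections."""
    projections = np.atleast_2d(np.asarray(projections, dtype=float))
    K = cell.n_dims
    if projections.shape[1] != K:
        raise ValueError(f"expected {K} projection columns, got {projections.shape[1]}")
    if cell.gain_family == "or_threshold":
        return _or_threshold_probability(projections, cell.theta, cell.sigma)
    if cell.gain_family == "quadratic_1d":
        return cell.gamma * projections[:, 0] ** 2
    # divisive
    numer = projections[:, 0] ** 2 + projections[:, 1] ** 2
    denom = 1.0 + cell.suppression * projections[:, 2] ** 2
    return cell.gamma * numer / denom


def rates_on(cell: LNCellSpec, matrix: np.ndarray) -> np.ndarray:
    """Expected rate for every row of an embedded-stimulus matrix."""
    projections = matrix @ cell.dimensions.T
    return expected_rate(cell, projections)


def calibrate_gain(
    cell: LNCellSpec,
    matrix: np.ndarray,
    target_mean_rate: float = 0.56,
    target_suppression_mean: float = 4.26,
) -> LNCellSpec:
    """Calibrate gain parameters against a stimulus ensemble.

    divisive: solve ``omega`` from ``<1 + omega*(s.e3)^2> = target_suppression_mean``
    (linear in omega), then scale ``gamma`` so the mean rate is ``target_mean_rate``.

    quadratic_1d: scale ``gamma`` to the target mean rate.

    or_threshold: bisect ``theta`` so the mean spike probability equals
    ``target_mean_rate`` (``sigma`` is kept fixed).
    """
    if matrix.shape[0] == 0:
        raise ValueError("calibration ensemble is empty")
    if target_mean_rate <= 0:
        raise ValueError("target mean rate must be positive")
    projections = matrix @ cell.dimensions.T

    if cell.gain_family == "divisive":
        if target_suppression_mean < 1.0:
            raise ValueError("target <1 + omega*(s.e3)^2> cannot be below 1")
        msq = float(np.mean(projections[:, 2] ** 2))
        if msq <= 0:
            raise ValueError("suppressive projection has zero power")
        omega = (target_suppression_mean - 1.0) / msq
        trial = replace(cell, suppression=omega, gamma=1.0)
        base = float(np.mean(expected_rate(trial, projections)))
        return replace(cell, suppression=omega, gamma=target_mean_rate / base)

    if cell.gain_family == "quadratic_1d":
        base = float(np.mean(projections[:, 0] ** 2))
        return replace(cell, gamma=target_mean_rate / base)

    # or_threshold: mean probability decreases monotonically in theta
    def gap(theta: float) -> float:
        return (
            float(np.mean(_or_threshold_probability(projections, theta, cell.sigma)))
            - target_mean_rate
        )

    scale = float(np.std(projections)) + cell.sigma
    lo, hi = 1e-6 * scale, 20.0 * scale
    if gap(lo) < 0 or gap(hi) > 0:
        raise ValueError("target mean spike probability is unattainable")
    theta = brentq(gap, lo, hi, xtol=1e-12)
    return replace(cell, theta=theta)


def simulate_spikes(
    rates: np.ndarray, seed: int | None = None, family: str = "poisson"
) -> np.ndarray:
    """Draw spike counts: Poisson for rate cells, Bernoulli for the binary OR cell."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    rng = np.random.default_rng(seed)
    if family in ("bernoulli", "or_threshold"):
        if np.any(rates > 1):
            raise ValueError("Bernoulli probabilities must be <= 1")
        return (rng.random(rates.shape) < rates).astype(np.int64)
    if family in ("poisson", "divisive", "quadratic_1d"):
        return rng.poisson(rates).astype(np.int64)
    raise ValueError(f"unknown spiking family {family!r}")


# ---------------------------------------------------------------------------
# Standard model geometries


def _default_gabor(H: int, W: int, phase: float, orientation: float) -> GaborFilterSpec:
    return GaborFilterSpec(
        center=((H - 1) / 2.0, (W - 1) / 2.0),
        orientation=orientation,
        spatial_frequency=2.0 / min(H, W),
        phase=phase,
        envelope_sd=min(H, W) / 4.0,
    )


def quadrature_pair(H: int, W: int, n_lags: int, orientation: float = 0.0) -> np.ndarray:
    """Two Gabor dimensions with identical orientation/frequency, phases 0 and pi/2."""
    w = DEFAULT_TEMPORAL_WEIGHTS[-n_lags:] if n_lags <= 3 else None
    if w is None:
        raise ValueError("default temporal profile supports n_lags <= 3")
    specs = [
        replace(_default_gabor(H, W, phase, orientation), temporal_weights=w)
        for phase in (0.0, np.pi / 2.0)
    ]
    return np.stack([make_gabor_dimension(s, H, W, n_lags) for s in specs])


def make_or_cell(
    H: int = 16,
    W: int = 16,
    n_lags: int = 3,
    theta_sd_units: float = 2.0,
    sigma_sd_units: float = 0.5,
    projection_sd: float = 1.0,
) -> LNCellSpec:
    """OR-of-thresholds cell on a quadrature Gabor pair.

    ``theta`` and ``sigma`` are expressed in units of the projection standard
    deviation (defaults 2.0 and 0.5): pass the measured SD of the ensemble's
    projections for correlated stimuli, or leave 1.0 for z-scored white noise
    with unit-norm filters.
    """
    dims = quadrature_pair(H, W, n_lags)
    return LNCellSpec(
        dimensions=dims,
        gain_family="or_threshold",
        theta=theta_sd_units * projection_sd,
        sigma=sigma_sd_units * projection_sd,
        meta={"H": H, "W": W, "n_lags": n_lags},
    )


def make_divisive_cell(
    H: int = 16,
    W: int = 16,
    n_lags: int = 3,
    gamma: float = 1.0,
    suppression: float = 1.0,
) -> LNCellSpec:
    """Divisive gain-control cell: quadrature pair + orthogonal-orientation suppressor."""
    dims = quadrature_pair(H, W, n_lags)
    w = DEFAULT_TEMPORAL_WEIGHTS[-n_lags:]
    supp_spec = replace(
        _default_gabor(H, W, phase=0.0, orientation=np.pi / 2.0), temporal_weights=w
    )
    supp = make_gabor_dimension(supp_spec, H, W, n_lags)
    return LNCellSpec(
        dimensions=np.vstack([dims, supp]),
        gain_family="divisive",
        gamma=gamma,
        suppression=suppression,
        meta={"H": H, "W": W, "n_lags": n_lags},
    )


def make_quadratic_cell(
    H: int = 16, W: int = 16, n_lags: int = 3, gamma: float = 1.0
) -> LNCellSpec:
    """One-dimensional energy cell on a single Gabor."""
    dims = quadrature_pair(H, W, n_lags)[:1]
    return LNCellSpec(
        dimensions=dims,
        gain_family="quadratic_1d",
        gamma=gamma,
        meta={"H": H, "W": W, "n_lags": n_lags},
    )


# ---------------------------------------------------------------------------
# Serialization: JSON spec + HDF5 dimensions


def save_cell(path: str | Path, cell: LNCellSpec) -> None:
    path = Path(path)
    obj = {
        "gain_family": cell.gain_family,
        "theta": cell.theta,
        "sigma": cell.sigma,
        "gamma": cell.gamma,
        "suppression": cell.suppression,
        "meta": cell.meta,
        "dimensions_file": path.with_suffix(".h5").name,
    }
    path.write_text(json.dumps(obj, indent=2))
    with h5py.File(path.with_suffix(".h5"), "w") as f:
        f.create_dataset("dimensions", data=cell.dimensions)


def load_cell(path: str | Path) -> LNCellSpec:
    path = Path(path)
    obj = json.loads(path.read_text())
    with h5py.File(path.parent / obj["dimensions_file"], "r") as f:
        dims = f["dimensions"][...]
    return LNCellSpec(
        dimensions=dims,
        gain_family=obj["gain_family"],
        theta=obj["theta"],
        sigma=obj["sigma"],
        gamma=obj["gamma"],
        suppression=obj["suppression"],
        meta=obj.get("meta", {}),
    )
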