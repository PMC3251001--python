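"""Scoring reconstructed dimensions: subspace overlap, information explained, SNR.

The central metric is the subspace projection ``O``: project the unit cube of
the reconstructed subspace onto the model subspace, measure the remaining
volume (a Gram-determinant ratio), and take the K-th root to get a linear
measure in [0, 1].  ``O`` is invariant to any invertible recombination of the
dimensions within either set, so it compares subspaces, not bases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cells as _cells
from .info import bin_distributions, mutual_information, project_stimuli
from .stimuli import jackknife_partitions

__all__ = [
    "SubspaceOverlap",
    "subspace_projection",
    "percent_info_explained",
    "snr_map",
    "convergence_experiment",
]


@dataclass
class SubspaceOverlap:
    """Result of comparing two K-dimensional subspaces."""

    overlap: float  # O in [0, 1]
    projected_volume: float  # |det P| / sqrt(det G_model det G_recon)
    n_dims: int


def subspace_projection(model_dims: np.ndarray, recon_dims: np.ndarray) -> SubspaceOverlap:
    """Subspace projection O between model and reconstructed dimension sets.

    ``O = (|det P| / sqrt(det G_model * det G_recon)) ** (1/K)`` with
    ``P[i, j] = model_i . recon_j`` and G the Gram matrices of each set.
    For K = 1 this is the absolute cosine similarity.
    """
    A = np.atleast_2d(np.asarray(model_dims, dtype=float))
    B = np.atleast_2d(np.asarray(recon_dims, dtype=float))
    if A.shape[0] != B.shape[0]:
        raise ValueError("model and reconstruction must have the same number of dimensions")
    if A.shape[1] != B.shape[1]:
        raise ValueError("dimension lengths differ")
    K = A.shape[0]
    G_a = A @ A.T
    G_b = B @ B.T
    det_a = np.linalg.det(G_a)
    det_b = np.linalg.det(G_b)
    scale = float(np.mean(np.diag(G_a)) * np.mean(np.diag(G_b))) or 1.0
    if det_a <= 1e-12 * scale**K or det_b <= 1e-12 * scale**K:
        raise ValueError("rank-deficient dimension set")
    P = A @ B.T
    volume = abs(np.linalg.det(P)) / np.sqrt(det_a * det_b)
    volume = min(volume, 1.0)  # clip rounding excursions above the bound
    return SubspaceOverlap(overlap=float(volume ** (1.0 / K)), projected_volume=float(volume), n_dims=K)


def percent_info_explained(
    fit_dims: np.ndarray,
    heldout_matrix: np.ndarray,
    heldout_spikes: np.ndarray,
    i_spike: float,
    n_bins: int = 11,
) -> float:
    """Percent of the cell's information per spike captured on held-out data.

    The binned information of the fitted dimensions is recomputed on the
    held-out rows (edges refit to the held-out projections) and divided by the
    rate-based information per spike ``i_spike``.  Values can exceed 100 by
    estimator noise; they are reported as-is, not clamped.
    """
    heldout_spikes = np.asarray(heldout_spikes)
    if i_spike <= 0:
        raise ValueError("i_spike must be positive")
    if heldout_spikes.sum() <= 0:
        raise ValueError("no spikes in held-out data")
    P = project_stimuli(heldout_matrix, fit_dims)
    info = mutual_information(bin_distributions(P, heldout_spikes, n_bins))
    return 100.0 * info / i_spike


def snr_map(fold_estimates: np.ndarray) -> np.ndarray:
    """Per-coefficient signal-to-noise ratio across aligned fold estimates.

    ``SNR[k, d] = |mean_f V[f, k, d]| / SD_f V[f, k, d]``.  Coefficients whose
    across-fold SD is zero (identical folds) are flagged as saturated with
    ``inf``.
    """
    V = np.asarray(fold_estimates, dtype=float)
    if V.ndim == 2:
        V = V[:, None, :]
    if V.shape[0] < 2:
        raise ValueError("need at least two fold estimates")
    mean = V.mean(axis=0)
    sd = V.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.abs(mean) / sd
    snr[(sd == 0) & (np.abs(mean) > 0)] = np.inf
    snr[(sd == 0) & (np.abs(mean) == 0)] = 0.0
    return snr


def _scaled_cell(cell, matrix: np.ndarray, n_spikes_target: float):
    """Scale the cell's rate (via gamma or the Bernoulli probability) to a spike budget."""
    rates = _cells.rates_on(cell, matrix)
    current = rates.sum()
    factor = n_spikes_target / current
    if cell.gain_family == "or_threshold":
        return None, np.clip(rates * factor, 0.0, 1.0)
    from dataclasses import replace

    scaled = replace(cell, gamma=cell.gamma * factor)
    return scaled, rates * factor


def convergence_experiment(
    cells_by_k: dict,
    matrix: np.ndarray,
    budget_factors,
    config,
    modes=("joint", "sequential"),
    n_seeds: int = 8,
    base_seed: int = 0,
    with_info: bool = False,
) -> pd.DataFrame:
    """Reconstruction quality versus spike budget for model cells of K = 1..3.

    ``budget_factors`` are spike budgets in units of ``K * D`` (the number of
    parameters defining the dimensions), so the abscissa ``K*D/N_spikes`` is
    sampled at the same target points for every K.  For each cell, budget,
    mode and seed: scale the firing rate to the budget, draw Poisson (or
    Bernoulli) spikes, run a single (non-jackknifed) fit, and score the
    subspace projection against the cell's first K dimensions.  Returns a
    tidy table with columns ``K, D, n_spikes, target_ratio, kd_ratio, mode,
    seed, O`` (plus ``pct_info`` when ``with_info``).
    """
    from dataclasses import replace as _replace

    from .info import info_per_spike
    from .optim import fit_dimensions

    rows = []
    D = matrix.shape[1]
    for K, cell in sorted(cells_by_k.items()):
        # the cell's first K dimensions are the relevant ones being estimated
        true_dims = cell.dimensions[:K]
        for factor in budget_factors:
            budget = factor * K * D
            if budget < 1:
                raise ValueError("spike budget must be at least 1 spike")
            scaled, rates = _scaled_cell(cell, matrix, budget)
            for seed in range(n_seeds):
                y = _cells.simulate_spikes(
                    rates, seed=base_seed + 7919 * seed + 13 * K, family=cell.gain_family
                )
                if y.sum() < 1:
                    continue
                for mode in modes:
                    if K == 1 and mode == "sequential" and "joint" in modes:
                        continue  # identical to joint by construction
                    cfg = _replace(config, seed=(base_seed + 101 * seed + K))
                    V, _, _ = fit_dimensions(matrix, y, K=K, mode=mode, config=cfg)
                    O = subspace_projection(true_dims, V).overlap
                    row = {
                        "K": K,
                        "D": D,
                        "n_spikes": int(y.sum()),
                        "target_ratio": 1.0 / factor,
                        "kd_ratio": K * D / float(y.sum()),
                        "mode": mode,
                        "seed": seed,
                        "O": O,
                    }
                    if with_info:
                        part = jackknife_partitions(matrix.shape[0], 4)
                        hold = part.holdout_indices(0)
                        row["pct_info"] = percent_info_explained(
                            V, matrix[hold], y[hold], info_per_spike(rates[hold])
                        )
                    rows.append(row)
    df = pd.DataFrame(rows)
    if "joint" in modes and len(df):
        # K=1 sequential is identical to joint; duplicate for a complete table
        k1 = df[(df["K"] == 1) & (df["mode"] == "joint")].copy()
        if len(k1) and "sequential" in modes:
            k1["mode"] = "sequential"
            df = pd.concat([df, k1], ignore_index=True)
    return df
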