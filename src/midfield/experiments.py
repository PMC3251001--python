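"""End-to-end experiment drivers: model-cell simulations and method comparisons.

Each driver generates a stimulus ensemble, builds a model cell, simulates
spikes, runs the designated fits under the 4-fold jackknife protocol, and
reports subspace projections, percent information explained and SNR maps with
jackknife errors.  Drivers are deterministic given a seed, and every run can
be captured in a :class:`RunManifest`.

Named experiments
-----------------
``fig1_noise``        2D OR-threshold cell on Gaussian white noise; sequential
                      vs joint 2D information maximization.
``fig1_natural``      same cell on a natural movie (or, when no movie file is
                      supplied, on the naturalistic surrogate ensemble): the
                      non-Gaussian correlations bias the sequential search and
                      joint optimization repairs it.
``fig2_joint3d``      3D divisive gain-control cell, joint 3D fit.
``fig3_ppr``          same data analyzed with projection pursuit regression.
``fig4_convergence``  reconstruction quality vs spike budget for K = 1, 2, 3.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import cells as mc
from .evaluation import (
    convergence_experiment,
    percent_info_explained,
    snr_map,
    subspace_projection,
)
from .info import info_per_spike
from .optim import AnnealConfig, _align_folds, fit_dimensions
from .ppr import PPRConfig, fit_ppr
from .stimuli import (
    embed_spatiotemporal,
    generate_naturalistic,
    generate_white_noise,
    jackknife_partitions,
    load_stimuli,
)

logger = logging.getLogger("midfield")

EXPERIMENT_NAMES = (
    "fig1_noise",
    "fig1_natural",
    "fig2_joint3d",
    "fig3_ppr",
    "fig4_convergence",
)


@dataclass
class RunManifest:
    """Traceability record for one experiment run."""

    command: str
    config: dict
    seed: int | None
    input_hashes: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    def to_json(self) -> str:
        return json.dumps(
            {
                "command": self.command,
                "config": self.config,
                "seed": self.seed,
                "input_hashes": self.input_hashes,
                "outputs": self.outputs,
                "timestamp": self.timestamp,
            },
            indent=2,
            sort_keys=True,
        )


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _mean_se(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    se = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
    return float(v.mean()), se


def _make_ensemble(kind: str, T: int, H: int, W: int, seed: int, movie_path=None):
    if kind == "white_noise":
        return generate_white_noise(T, H, W, seed=seed)
    if kind == "naturalistic":
        return generate_naturalistic(T, H, W, seed=seed)
    if kind == "external":
        return load_stimuli(movie_path)
    raise ValueError(f"unknown ensemble kind {kind!r}")


def or_cell_experiment(
    ensemble_kind: str = "white_noise",
    T: int = 50000,
    H: int = 16,
    W: int = 16,
    n_lags: int = 3,
    seed: int = 0,
    config: AnnealConfig | None = None,
    movie_path=None,
    modes=("sequential", "joint"),
) -> dict:
    """2D OR-threshold cell: simulate, fit both search modes, score.

    The first dimension is optimized once per jackknife fold and shared by the
    sequential and joint fits (for the first dimension the two are identical).
    Returns a report dict with per-mode subspace projections and percent
    information explained (jackknife mean +/- SE), SNR maps and the fitted
    dimensions.
    """
    if config is None:
        config = AnnealConfig(seed=seed)
    stim = _make_ensemble(ensemble_kind, T, H, W, seed=seed, movie_path=movie_path)
    T, H, W = stim.shape
    emb = embed_spatiotemporal(stim, n_lags)
    X = emb.matrix
    dims_true = mc.quadrature_pair(H, W, n_lags)
    proj_sd = float((X @ dims_true.T).std())
    cell = mc.LNCellSpec(
        dimensions=dims_true,
        gain_family="or_threshold",
        theta=2.0 * proj_sd,
        sigma=0.5 * proj_sd,
        meta={"H": H, "W": W, "n_lags": n_lags},
    )
    rates = mc.rates_on(cell, X)
    y = mc.simulate_spikes(rates, seed=seed + 1, family="or_threshold")
    part = jackknife_partitions(X.shape[0], config.fold_count)

    per_mode: dict[str, dict] = {m: {"O": [], "pct": [], "dims": []} for m in modes}
    for f in range(part.fold_count):
        tr = part.train_mask(f)
        hold = part.holdout_indices(f)
        first, _, _ = fit_dimensions(X[tr], y[tr], K=1, mode="sequential", config=config, fold=f)
        i_spk = info_per_spike(rates[hold])
        for mode in modes:
            V, _, _ = fit_dimensions(
                X[tr], y[tr], K=2, mode=mode, config=config, fold=f,
                precomputed_first=first[0],
            )
            per_mode[mode]["dims"].append(V)
            per_mode[mode]["O"].append(subspace_projection(cell.dimensions, V).overlap)
            per_mode[mode]["pct"].append(
                percent_info_explained(V, X[hold], y[hold], i_spk, n_bins=config.eval_bins)
            )

    report = {
        "ensemble": stim.ensemble_kind,
        "T": int(T),
        "D": int(X.shape[1]),
        "n_spikes": int(y.sum()),
        "i_spike_bits": info_per_spike(rates),
        "seed": seed,
        "modes": {},
    }
    for mode in modes:
        dims_per_fold = np.stack(per_mode[mode]["dims"])
        aligned, mean_dims = _align_folds(dims_per_fold)
        o_mean, o_se = _mean_se(per_mode[mode]["O"])
        p_mean, p_se = _mean_se(per_mode[mode]["pct"])
        report["modes"][mode] = {
            "O": o_mean,
            "O_se": o_se,
            "O_per_fold": list(map(float, per_mode[mode]["O"])),
            "pct_info": p_mean,
            "pct_info_se": p_se,
            "pct_per_fold": list(map(float, per_mode[mode]["pct"])),
            "dimensions": mean_dims,
            "snr": snr_map(aligned),
        }
    return report


def divisive_cell_experiment(
    T: int = 49152,
    H: int = 16,
    W: int = 16,
    n_lags: int = 3,
    seed: int = 0,
    config: AnnealConfig | None = None,
    method: str = "joint_mid",  # "joint_mid" | "ppr"
    ppr_config: PPRConfig | None = None,
    ensemble_kind: str = "naturalistic",
    movie_path=None,
) -> dict:
    """3D divisive gain-control cell on the naturalistic surrogate.

    The cell is calibrated so that the mean rate is 0.56 spikes/frame and the
    mean suppressive factor <1 + omega (s.e3)^2> is 4.26, then analyzed with
    either joint 3D information maximization or projection pursuit regression.
    """
    if config is None:
        config = AnnealConfig(seed=seed)
    stim = _make_ensemble(ensemble_kind, T, H, W, seed=seed, movie_path=movie_path)
    T, H, W = stim.shape
    emb = embed_spatiotemporal(stim, n_lags)
    X = emb.matrix
    cell = mc.calibrate_gain(mc.make_divisive_cell(H, W, n_lags), X)
    rates = mc.rates_on(cell, X)
    y = mc.simulate_spikes(rates, seed=seed + 1, family="divisive")
    part = jackknife_partitions(X.shape[0], config.fold_count)

    O_folds, pct_folds, dims_folds = [], [], []
    for f in range(part.fold_count):
        tr = part.train_mask(f)
        hold = part.holdout_indices(f)
        if method == "joint_mid":
            V, _, _ = fit_dimensions(X[tr], y[tr], K=3, mode="joint", config=config, fold=f)
        elif method == "ppr":
            cfg = ppr_config or PPRConfig(seed=seed + f)
            V = fit_ppr(X[tr], y[tr], K=3, config=cfg).dimensions
        else:
            raise ValueError(f"unknown method {method!r}")
        dims_folds.append(V)
        O_folds.append(subspace_projection(cell.dimensions, V).overlap)
        pct_folds.append(
            percent_info_explained(
                V, X[hold], y[hold], info_per_spike(rates[hold]), n_bins=config.eval_bins
            )
        )
    aligned, mean_dims = _align_folds(np.stack(dims_folds))
    o_mean, o_se = _mean_se(O_folds)
    p_mean, p_se = _mean_se(pct_folds)
    return {
        "ensemble": stim.ensemble_kind,
        "method": method,
        "T": int(T),
        "D": int(X.shape[1]),
        "n_spikes": int(y.sum()),
        "seed": seed,
        "O": o_mean,
        "O_se": o_se,
        "O_per_fold": list(map(float, O_folds)),
        "pct_info": p_mean,
        "pct_info_se": p_se,
        "dimensions": mean_dims,
        "snr": snr_map(aligned),
        "cell": cell,
    }


def convergence_driver(
    T: int = 20000,
    H: int = 10,
    W: int = 10,
    n_lags: int = 3,
    spike_budget_factors=(0.5, 1.0, 2.0, 4.0),
    n_seeds: int = 8,
    seed: int = 0,
    config: AnnealConfig | None = None,
    ensemble_kind: str = "naturalistic",
) -> pd.DataFrame:
    """Reconstruction quality vs spike budget for K = 1, 2, 3 model cells.

    Spike budgets are expressed as multiples of ``K * D`` (the number of
    parameters defining the K dimensions); the mean firing rate is scaled to
    hit each budget, mimicking shorter recordings.
    """
    if config is None:
        config = AnnealConfig(seed=seed)
    stim = _make_ensemble(ensemble_kind, T, H, W, seed=seed)
    emb = embed_spatiotemporal(stim, n_lags)
    X = emb.matrix
    cells_by_k = {
        1: mc.calibrate_gain(mc.make_quadratic_cell(H, W, n_lags), X, target_mean_rate=0.56),
        2: mc.calibrate_gain(
            mc.make_divisive_cell(H, W, n_lags), X, target_suppression_mean=1.0
        ),
        3: mc.calibrate_gain(mc.make_divisive_cell(H, W, n_lags), X),
    }
    return convergence_experiment(
        cells_by_k,
        X,
        spike_budget_factors,
        config,
        n_seeds=n_seeds,
        base_seed=seed,
    )


def run_figure_experiment(name: str, config: dict | None = None) -> dict:
    """Dispatch a named end-to-end experiment; see module docstring for names.

    ``config`` overrides driver keyword arguments (``T``, ``H``, ``W``,
    ``seed``, ``anneal`` sub-dict for optimizer settings, ``movie_path`` ...).
    Returns a JSON-serializable report (arrays reduced to summaries) plus
    tables for the convergence experiment.
    """
    config = dict(config or {})
    seed = int(config.pop("seed", 0))
    anneal_kwargs = config.pop("anneal", {})
    anneal = AnnealConfig(seed=seed, **anneal_kwargs)
    movie_path = config.pop("movie_path", None)

    if name == "fig1_noise":
        rep = or_cell_experiment(
            ensemble_kind="white_noise", seed=seed, config=anneal, **config
        )
    elif name == "fig1_natural":
        if movie_path is None:
            logger.warning(
                "NOTICE: no natural movie supplied; falling back to the "
                "naturalistic surrogate ensemble"
            )
            rep = or_cell_experiment(
                ensemble_kind="naturalistic", seed=seed, config=anneal, **config
            )
        else:
            rep = or_cell_experiment(
                ensemble_kind="external", seed=seed, config=anneal,
                movie_path=movie_path, **config
            )
    elif name == "fig2_joint3d":
        kind = "naturalistic" if movie_path is None else "external"
        rep = divisive_cell_experiment(
            method="joint_mid", seed=seed, config=anneal, ensemble_kind=kind,
            movie_path=movie_path, **config
        )
    elif name == "fig3_ppr":
        kind = "naturalistic" if movie_path is None else "external"
        rep = divisive_cell_experiment(
            method="ppr", seed=seed, config=anneal, ensemble_kind=kind,
            movie_path=movie_path, **config
        )
    elif name == "fig4_convergence":
        df = convergence_driver(seed=seed, config=anneal, **config)
        return {"name": name, "seed": seed, "table": df}
    else:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENT_NAMES}")
    rep["name"] = name
    return rep


def save_dimension_figure(dimensions, frame_shape, n_lags, path, snr=None) -> None:
    """Plot fitted spatiotemporal dimensions (one row per dimension, one
    column per time lag), optionally alongside their SNR maps.

    Requires matplotlib (optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dims = np.atleast_2d(np.asarray(dimensions))
    H, W = frame_shape
    K = dims.shape[0]
    ncols = n_lags * (2 if snr is not None else 1)
    fig, axes = plt.subplots(K, ncols, figsize=(2 * ncols, 2 * K), squeeze=False)
    for k in range(K):
        filt = dims[k].reshape(n_lags, H, W)
        vmax = np.abs(filt).max() or 1.0
        for lag in range(n_lags):
            ax = axes[k][lag]
            ax.imshow(filt[lag], cmap="RdBu_r", vmin=-vmax, vmax=vmax)
            ax.set_xticks([]); ax.set_yticks([])
            if k == 0:
                ax.set_title(f"lag {lag}")
        if snr is not None:
            smap = np.asarray(snr)[k].reshape(n_lags, H, W)
            for lag in range(n_lags):
                ax = axes[k][n_lags + lag]
                ax.imshow(np.nan_to_num(smap[lag], posinf=10.0), cmap="viridis")
                ax.set_xticks([]); ax.set_yticks([])
                if k == 0:
                    ax.set_title(f"SNR lag {lag}")
        axes[k][0].set_ylabel(f"dim {k + 1}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def report_to_json(report: dict) -> str:
    """Serialize a report, dropping arrays down to summary statistics."""

    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items() if k not in ("dimensions", "snr", "cell")}
        if isinstance(obj, pd.DataFrame):
            return obj.to_dict(orient="records")
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return json.dumps(clean(report), indent=2, sort_keys=True)
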