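"""Measurement apparatus: support-restricted errors, greedy component
matching, method-comparison sweeps, and Gaussian-mixture AIC scoring."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.special import logsumexp
from scipy.stats import multivariate_normal

from .config import SMSSVDConfig
from .decomposition import smssvd
from .exceptions import DataError, ShapeError
from .synthetic import SyntheticConfig, SyntheticSignal, generate_dataset
from .types import DataMatrix

__all__ = [
    "ComponentAssignment",
    "GMMScore",
    "reconstruction_error",
    "greedy_match",
    "benchmark_sweep",
    "gmm_aic",
]

logger = logging.getLogger(__name__)


def reconstruction_error(Y: SyntheticSignal, Y_hat: np.ndarray) -> float:
    """Frobenius error of the reconstruction, restricted to the support rows."""
    y_hat = np.asarray(Y_hat, dtype=float)
    if y_hat.shape != Y.Y.shape:
        raise ShapeError(f"shape {y_hat.shape} != {Y.Y.shape}")
    diff = Y.Y[Y.support] - y_hat[Y.support]
    return float(np.linalg.norm(diff))


@dataclass
class ComponentAssignment:
    """Result of matching rank-1 components to planted signals.

    ``assignment[c]`` is the signal index the c-th component was matched
    to, or ``None`` if it stayed unassigned.  Exactly ``rank(Y_k)``
    components are matched to each signal k.
    """

    assignment: list[int | None]
    per_signal_error: np.ndarray
    total_error: float


def greedy_match(
    components: list[tuple[np.ndarray, float, np.ndarray]],
    signals: list[SyntheticSignal],
) -> ComponentAssignment:
    """Greedily match rank-1 components to signals, minimizing total error.

    At each step, the (component, signal) pair whose addition to that
    signal's running reconstruction lowers the total support-restricted
    error the most is committed, until every signal has received
    ``rank(Y_k)`` components.  Ties prefer the lowest component index,
    then the lowest signal index.
    """
    n_comp = len(components)
    capacity = [s.rank for s in signals]
    if n_comp < sum(capacity):
        raise DataError(
            f"{n_comp} components cannot fill a total capacity of {sum(capacity)}"
        )
    # per-signal running reconstruction, restricted to the support rows
    recon = [np.zeros((s.support.size, s.Y.shape[1])) for s in signals]
    target = [s.Y[s.support] for s in signals]
    errors = np.array([float(np.linalg.norm(t)) for t in target])
    # component matrices restricted to each signal's support
    comp_on_support = [
        [sigma * np.outer(u[s.support], v) for s in signals]
        for (u, sigma, v) in components
    ]

    assignment: list[int | None] = [None] * n_comp
    remaining = list(capacity)
    while any(r > 0 for r in remaining):
        best = None  # (delta, comp_idx, sig_idx)
        for c in range(n_comp):
            if assignment[c] is not None:
                continue
            for k in range(len(signals)):
                if remaining[k] <= 0:
                    continue
                cand = float(
                    np.linalg.norm(target[k] - recon[k] - comp_on_support[c][k])
                )
                delta = cand - errors[k]
                if best is None or delta < best[0] - 1e-15:
                    best = (delta, c, k)
        _, c, k = best
        assignment[c] = k
        recon[k] += comp_on_support[c][k]
        errors[k] = float(np.linalg.norm(target[k] - recon[k]))
        remaining[k] -= 1
    return ComponentAssignment(
        assignment=assignment,
        per_signal_error=errors,
        total_error=float(errors.sum()),
    )


def _truncated_svd_components(values: np.ndarray, dim: int):
    u, s, vt = scipy.linalg.svd(values, full_matrices=False)
    return [(u[:, j], float(s[j]), vt[j]) for j in range(dim)]


def benchmark_sweep(
    param_grid: dict,
    methods: tuple[str, ...] = ("truncated_svd", "smssvd"),
    n_replicates: int = 1,
    seed: int = 0,
    N: int = 100,
    K: int = 8,
    smssvd_config: SMSSVDConfig | None = None,
):
    """Run the method comparison over a parameter grid.

    ``param_grid`` maps any of ``P``, ``L``, ``d``, ``sigma``, ``regime``
    to lists of values (missing axes get a single default).  For each
    cell and replicate a dataset is generated, each method is run to the
    total planted dimension, the output is split into rank-1 components
    and greedily matched to the planted signals.  Errors larger than the
    signal strength are flagged (the component found a different signal).

    Returns a tidy long-format :class:`pandas.DataFrame`.
    """
    import pandas as pd

    unknown = set(methods) - {"truncated_svd", "smssvd"}
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    axes = {
        "P": param_grid.get("P", [1000]),
        "L": param_grid.get("L", [64]),
        "d": param_grid.get("d", [1]),
        "sigma": param_grid.get("sigma", [0.1]),
        "regime": param_grid.get("regime", ["all"]),
    }
    rows = []
    cells = list(itertools.product(*axes.values()))
    for cell_idx, (p, l, d, sigma, regime) in enumerate(cells):
        for rep in range(n_replicates):
            ds_seed = int(
                np.random.SeedSequence(
                    entropy=seed, spawn_key=(cell_idx, rep)
                ).generate_state(1)[0]
            )
            base = dict(
                replicate=rep, P=p, L=l, d=d, sigma=sigma, regime=regime
            )
            try:
                ds = generate_dataset(
                    SyntheticConfig(
                        P=p, N=N, L=l, K=K, d=d,
                        noise_sigma=sigma, noise_support=regime, seed=ds_seed,
                    )
                )
            except Exception as exc:  # infeasible cell: record and continue
                logger.warning("cell %s failed to generate: %s", base, exc)
                for method in methods:
                    rows.append(
                        dict(base, method=method, signal_index=np.nan,
                             err=np.nan, signal_strength=np.nan,
                             flagged=False, note=f"generation failed: {exc}")
                    )
                continue
            total_dim = sum(s.rank for s in ds.signals)
            for method in methods:
                try:
                    if method == "truncated_svd":
                        comps = _truncated_svd_components(ds.X, total_dim)
                    else:
                        cfg = smssvd_config if smssvd_config is not None else SMSSVDConfig()
                        cfg = SMSSVDConfig(
                            target_dim=total_dim,
                            n_randomizations=cfg.n_randomizations,
                            seed=ds_seed,
                            disable_selection=cfg.disable_selection,
                            center_variables=cfg.center_variables,
                            threshold_grid_size=cfg.threshold_grid_size,
                            d_max=cfg.d_max,
                        )
                        result = smssvd(DataMatrix(ds.X), total_dim, cfg)
                        comps = result.components()
                    match = greedy_match(comps, ds.signals)
                except Exception as exc:
                    logger.warning("cell %s method %s failed: %s", base, method, exc)
                    rows.append(
                        dict(base, method=method, signal_index=np.nan,
                             err=np.nan, signal_strength=np.nan,
                             flagged=False, note=str(exc))
                    )
                    continue
                for k, signal in enumerate(ds.signals):
                    err = float(match.per_signal_error[k])
                    strength = signal.strength
                    rows.append(
                        dict(base, method=method, signal_index=k + 1,
                             err=err, signal_strength=strength,
                             flagged=bool(err > strength), note="")
                    )
    return pd.DataFrame(rows)


@dataclass
class GMMScore:
    """Classification log-likelihood and AIC of a per-class Gaussian model."""

    loglik: float
    n_params: int
    aic: float
    per_class: list[tuple[np.ndarray, np.ndarray, float]]


def gmm_aic(coords: np.ndarray, labels, ridge: float = 0.0) -> GMMScore:
    """Score how well a sample representation explains class labels.

    One multivariate Gaussian is fit per class (maximum-likelihood mean
    and covariance); class priors are proportional to class sizes.  The
    log-likelihood is the conditional likelihood of the labels given the
    coordinates, obtained through Bayes' rule, and
    ``AIC = 2 * n_params - 2 * loglik`` with
    ``n_params = C * (D + D * (D + 1) / 2)`` (priors are determined by
    counts, not fitted).

    ``ridge`` optionally adds ``ridge * trace(cov) / D`` to the diagonal
    of each class covariance (off by default).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n, dim = coords.shape
    labels = np.asarray(labels)
    if labels.shape != (n,):
        raise ShapeError(f"expected {n} labels, got {labels.shape}")
    classes, class_idx = np.unique(labels, return_inverse=True)
    c = classes.size
    per_class = []
    log_joint = np.empty((n, c))
    for j, cls in enumerate(classes):
        rows = coords[class_idx == j]
        if rows.shape[0] < dim + 1:
            raise DataError(
                f"class {cls!r} has {rows.shape[0]} samples; need at least "
                f"{dim + 1} to estimate a {dim}-dimensional covariance"
            )
        mean = rows.mean(axis=0)
        centered = rows - mean
        cov = centered.T @ centered / rows.shape[0]
        if ridge > 0:
            cov = cov + np.eye(dim) * (ridge * np.trace(cov) / dim)
        prior = rows.shape[0] / n
        try:
            dist = multivariate_normal(mean=mean, cov=cov)
        except (np.linalg.LinAlgError, ValueError) as exc:
            raise DataError(f"singular covariance for class {cls!r}: {exc}") from exc
        log_joint[:, j] = dist.logpdf(coords) + np.log(prior)
        per_class.append((mean, cov, prior))
    log_post = log_joint - logsumexp(log_joint, axis=1, keepdims=True)
    loglik = float(log_post[np.arange(n), class_idx].sum())
    n_params = int(c * (dim + dim * (dim + 1) // 2))
    return GMMScore(
        loglik=loglik,
        n_params=n_params,
        aic=float(2 * n_params - 2 * loglik),
        per_class=per_class,
    )
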