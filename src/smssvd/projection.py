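"""Variance-filtering variable selection scored against a permutation null.

The informativeness of a variable subset for a rank-d representation is
the root fraction of squared singular mass carried by the top d singular
values of the selected submatrix.  The projection score subtracts the
mean informativeness of randomized copies of the same submatrix (entries
permuted independently within each variable), so a positive score means
the subset carries more low-rank structure than chance.

The optimizer sweeps a quantile grid of standard-deviation thresholds
jointly with the candidate dimension and returns the arg-max.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .config import SMSSVDConfig
from .decomposition import RANK_RTOL
from .exceptions import DimensionError, EmptySelectionError, RankError
from .types import DataMatrix, SelectionMap

__all__ = [
    "ScoreGrid",
    "variance_filter",
    "informativeness",
    "null_informativeness",
    "projection_score",
    "optimize_projection_score",
]

logger = logging.getLogger(__name__)


def variance_filter(X: DataMatrix, threshold: float) -> SelectionMap:
    """Select variables whose sample standard deviation exceeds ``threshold``.

    The inequality is strict and the standard deviation uses denominator
    N - 1.  Raises :class:`EmptySelectionError` when nothing survives.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    stds = values.std(axis=1, ddof=1)
    idx = np.flatnonzero(stds > threshold)
    if idx.size == 0:
        raise EmptySelectionError(
            f"no variable has standard deviation above {threshold!r}"
        )
    return SelectionMap.subset(idx, n_variables=values.shape[0])


def informativeness(sigma, d: int) -> float:
    """Root fraction of squared singular mass in the top ``d`` values.

    ``tau_d = sqrt((sigma_1^2 + .. + sigma_d^2) / (sigma_1^2 + .. + sigma_r^2))``
    """
    sigma = np.asarray(sigma, dtype=float)
    if d < 1 or d > sigma.size:
        raise DimensionError(f"d must be in [1, {sigma.size}]")
    sq = sigma**2
    total = float(sq.sum())
    if total == 0.0:
        raise ValueError("all singular values are zero")
    return float(np.sqrt(sq[:d].sum() / total))


def _randomization_rng(seed: int, stream_key: tuple, r: int) -> np.random.Generator:
    """Dedicated, evaluation-order-independent stream for randomization r."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(*stream_key, r))
    return np.random.Generator(np.random.PCG64(ss))


def _null_sq_spectra(
    values: np.ndarray, n_randomizations: int, seed: int, stream_key: tuple = ()
) -> np.ndarray:
    """Squared singular values (descending) of permuted copies of ``values``.

    Each copy permutes the entries within every row independently,
    destroying inter-variable correlation while preserving marginals.
    Returns an array of shape (n_randomizations, min(L, N)).
    """
    l, n = values.shape
    k = min(l, n)
    out = np.empty((n_randomizations, k))
    for r in range(n_randomizations):
        rng = _randomization_rng(seed, stream_key, r)
        permuted = rng.permuted(values, axis=1)
        if l >= n:
            gram = permuted.T @ permuted
        else:
            gram = permuted @ permuted.T
        eig = np.linalg.eigvalsh(gram)[::-1]
        out[r] = np.clip(eig, 0.0, None)
    return out


def null_informativeness(
    Xs, d: int, n_randomizations: int, seed: int
) -> float:
    """Mean informativeness of randomized copies of the submatrix ``Xs``.

    Rows are processed in the order given; callers wanting invariance to
    variable reordering should pass rows in a canonical (id-sorted) order,
    as :func:`projection_score` does.
    """
    values = Xs.values if isinstance(Xs, DataMatrix) else np.asarray(Xs, dtype=float)
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    sq = _null_sq_spectra(values, n_randomizations, seed)
    if d < 1 or d > sq.shape[1]:
        raise DimensionError(f"d must be in [1, {sq.shape[1]}]")
    totals = sq.sum(axis=1)
    if np.any(totals == 0.0):
        raise ValueError("randomized submatrix has all-zero singular values")
    taus = np.sqrt(sq[:, :d].sum(axis=1) / totals)
    return float(taus.mean())


def _id_sorted_submatrix(X, S: SelectionMap) -> np.ndarray:
    """``S^T X`` with rows sorted by variable id (canonical null order)."""
    if isinstance(X, DataMatrix) and S.mode == "subset":
        ids = X.variable_ids[S.indices].astype(str)
        order = np.argsort(ids, kind="stable")
        return X.values[S.indices[order]]
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    return S.apply(values)


def projection_score(
    X: DataMatrix, S: SelectionMap, d: int, n_randomizations: int, seed: int
) -> float:
    """Observed minus null informativeness of the selected submatrix."""
    sub = _id_sorted_submatrix(X, S)
    s = scipy.linalg.svdvals(sub)
    rank = int(np.count_nonzero(s > RANK_RTOL * s[0])) if s.size and s[0] > 0 else 0
    if rank < d:
        raise RankError(f"rank(S^T X) = {rank} < d = {d}")
    tau = informativeness(s, d)
    null = null_informativeness(sub, d, n_randomizations, seed)
    return float(tau - null)


@dataclass
class ScoreGrid:
    """Projection scores over the (threshold, dimension) grid.

    ``scores[t, j]`` is the score at ``thresholds[t]`` and dimension
    ``dims[j]``; cells where too few variables survive (or the submatrix
    rank is below the dimension) are NaN, i.e. invalid rather than zero.
    """

    thresholds: np.ndarray
    dims: np.ndarray
    scores: np.ndarray
    n_selected: np.ndarray
    n_randomizations: int
    seed: int
    best_threshold_index: int | None = None
    best_d: int | None = None
    fallback: bool = False

    @property
    def best_threshold(self) -> float | None:
        if self.best_threshold_index is None:
            return None
        return float(self.thresholds[self.best_threshold_index])

    @property
    def best_score(self) -> float | None:
        if self.best_threshold_index is None or self.best_d is None:
            return None
        j = int(np.flatnonzero(self.dims == self.best_d)[0])
        return float(self.scores[self.best_threshold_index, j])

    def to_frame(self):
        """Long-to-wide table: threshold, n_selected, one column per d."""
        import pandas as pd

        data = {"threshold": self.thresholds, "n_selected": self.n_selected}
        for j, d in enumerate(self.dims):
            data[f"score_d{int(d)}"] = self.scores[:, j]
        return pd.DataFrame(data)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, na_rep="", float_format="%.17g")


def _threshold_grid(stds: np.ndarray, grid_size: int) -> np.ndarray:
    qs = np.quantile(stds, np.arange(grid_size) / grid_size)
    qs[0] = 0.0
    return np.unique(qs)


def optimize_projection_score(
    X: DataMatrix,
    config: SMSSVDConfig | None = None,
    d_cap: int | None = None,
    seed: int | None = None,
    stream_key: tuple = (),
) -> tuple[SelectionMap, int, ScoreGrid]:
    """Joint arg-max of the projection score over threshold and dimension.

    Evaluates the full grid (quantile thresholds x dimensions 1..d_max),
    skipping cells where fewer than d + 1 variables survive or the
    submatrix rank is below d.  Ties prefer smaller d, then larger
    threshold.  If every cell is invalid, falls back to all variables
    with d = 1 and logs a warning.

    Returns ``(selection, d, grid)``.
    """
    config = config if config is not None else SMSSVDConfig()
    if seed is None:
        seed = config.seed
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    if not np.any(values):
        raise ValueError("input matrix is zero")
    p, n = values.shape
    var_ids = (
        X.variable_ids.astype(str)
        if isinstance(X, DataMatrix)
        else np.array([f"v{i + 1}" for i in range(p)])
    )

    stds = values.std(axis=1, ddof=1)
    thresholds = _threshold_grid(stds, config.threshold_grid_size)
    d_max = min(config.d_max, max(n - 1, 1))
    if d_cap is not None:
        d_max = min(d_max, d_cap)
    d_max = max(d_max, 1)
    dims = np.arange(1, d_max + 1)

    # rows sorted by decreasing std (ties by index): every threshold's
    # selection is a prefix, so observed Grams accumulate as suffix sums.
    order = np.lexsort((np.arange(p), -stds))
    sorted_vals = np.ascontiguousarray(values[order])
    counts = np.array([np.count_nonzero(stds > t) for t in thresholds])

    n_thresh = thresholds.size
    scores = np.full((n_thresh, d_max), np.nan)

    gram = np.zeros((n, n))
    filled = 0  # rows already accumulated into gram (from the top)
    for t in range(n_thresh - 1, -1, -1):
        c = int(counts[t])
        if c == 0:
            continue
        if c > filled:
            block = sorted_vals[filled:c]
            gram += block.T @ block
            filled = c
        eig = np.clip(np.linalg.eigvalsh(gram)[::-1], 0.0, None)
        total = float(eig.sum())
        if total == 0.0:
            continue
        # rank from the squared spectrum; the Gram route has a noise floor
        # of ~eps * eig_max, so use the standard eigenvalue tolerance
        rank = int(np.count_nonzero(eig > eig[0] * max(c, n) * np.finfo(float).eps))
        max_d = min(d_max, c - 1, rank)
        if max_d < 1:
            continue
        tau_obs = np.sqrt(np.cumsum(eig[:max_d]) / total)

        # canonical (variable-id-sorted) row order for the null streams so
        # the score is invariant under reordering of the input rows
        sel_rows = order[:c]
        id_order = np.argsort(var_ids[sel_rows], kind="stable")
        sub = sorted_vals[:c][id_order]
        null_sq = _null_sq_spectra(
            sub, config.n_randomizations, seed, stream_key=(*stream_key, t)
        )
        null_totals = null_sq.sum(axis=1)
        null_tau = np.sqrt(
            np.cumsum(null_sq[:, :max_d], axis=1) / null_totals[:, None]
        ).mean(axis=0)
        scores[t, :max_d] = tau_obs - null_tau

    best = None  # (score, d, threshold_index)
    for t in range(n_thresh):
        for j in range(d_max):
            s = scores[t, j]
            if np.isnan(s):
                continue
            d = int(dims[j])
            if best is None:
                best = (s, d, t)
                continue
            b_s, b_d, b_t = best
            if s > b_s:
                best = (s, d, t)
            elif s == b_s and (d < b_d or (d == b_d and t > b_t)):
                best = (s, d, t)

    grid = ScoreGrid(
        thresholds=thresholds,
        dims=dims,
        scores=scores,
        n_selected=counts,
        n_randomizations=config.n_randomizations,
        seed=seed,
    )
    if best is None:
        logger.warning(
            "no valid (threshold, d) cell; falling back to all variables, d = 1"
        )
        grid.fallback = True
        return SelectionMap.all_variables(p), 1, grid

    _, best_d, best_t = best
    grid.best_threshold_index = best_t
    grid.best_d = best_d
    selection = SelectionMap.subset(
        np.sort(order[: counts[best_t]]), n_variables=p
    )
    return selection, best_d, grid
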