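"""Restricted SVD, selection-expansion, deflation and the main iteration.

The pipeline extracts one low-rank "signal" per iteration:

1. choose a variable selection ``S_k`` and a dimension ``d_k`` by
   optimizing the projection score of the current residual matrix;
2. take the rank-``d_k`` truncated SVD of the selected submatrix
   ``S_k^T X_k`` and keep its right-singular subspace ``Pi_k``;
3. expand back to all variables by computing the SVD of ``X_k``
   restricted to ``Pi_k``;
4. deflate: ``X_{k+1} = (I - U_k U_k^T) X_k``.

Deflation makes the concatenated factors orthonormal across signals, so
the result behaves like an SVD (and coincides with the truncated SVD when
selection is disabled).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .config import SMSSVDConfig
from .exceptions import (
    DimensionError,
    OrthogonalityError,
    RankError,
    ShapeError,
)
from .types import DataMatrix, SelectionMap, SubspaceBasis

__all__ = [
    "SignalFactors",
    "SMSSVDResult",
    "restricted_svd",
    "select_expand",
    "remove_signal",
    "smssvd",
    "concatenate_signals",
    "reconstruct",
]

logger = logging.getLogger(__name__)

#: relative cutoff below which singular values do not count toward rank
RANK_RTOL = 1e-12

_FACTOR_TOL = 1e-8


def numerical_rank(values: np.ndarray, rtol: float = RANK_RTOL) -> int:
    """Number of singular values above ``rtol`` times the largest one."""
    s = scipy.linalg.svdvals(values)
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.count_nonzero(s > rtol * s[0]))


def _fix_signs(u: np.ndarray, v: np.ndarray) -> None:
    """Deterministic sign convention, in place.

    The entry of largest magnitude in each U column is made positive
    (ties broken by lowest row index), with the matching V column flipped
    to preserve the product.
    """
    for j in range(u.shape[1]):
        i = int(np.argmax(np.abs(u[:, j])))
        if u[i, j] < 0:
            u[:, j] = -u[:, j]
            v[:, j] = -v[:, j]


@dataclass
class SignalFactors:
    """One extracted signal: an SVD-like triple plus selection metadata.

    ``U`` (P x d) and ``V`` (N x d) have orthonormal columns; ``sigma``
    holds the d singular values in nonincreasing order.  For signals
    produced through variable selection, ``submatrix_sigma`` carries the
    singular values of the selected submatrix and ``selection`` /
    ``threshold`` / ``score`` record how the variables were chosen.
    """

    U: np.ndarray
    sigma: np.ndarray
    V: np.ndarray
    d: int
    selection: SelectionMap | None = None
    threshold: float | None = None
    score: float | None = None
    submatrix_sigma: np.ndarray | None = None
    grid: "object | None" = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.U.shape[1] != self.d or self.V.shape[1] != self.d:
            raise ShapeError("factor column counts do not match d")
        if self.sigma.shape != (self.d,):
            raise ShapeError("sigma length does not match d")
        if self.d > 0:
            if np.any(self.sigma <= 0):
                raise ValueError("singular values must be positive")
            if np.any(np.diff(self.sigma) > 0):
                raise ValueError("singular values must be nonincreasing")
            for name, m in (("U", self.U), ("V", self.V)):
                gram = m.T @ m
                if not np.allclose(gram, np.eye(self.d), atol=_FACTOR_TOL):
                    raise OrthogonalityError(f"{name} columns are not orthonormal")
        if (
            self.submatrix_sigma is not None
            and self.selection is not None
            and self.selection.is_orthonormal
        ):
            # expansion can only grow the Frobenius mass when S^T S = I
            full = float(np.linalg.norm(self.sigma))
            sub = float(np.linalg.norm(self.submatrix_sigma))
            if full < sub * (1.0 - 1e-8):
                raise ValueError(
                    "expanded singular values smaller than submatrix ones "
                    f"({full} < {sub})"
                )

    @property
    def n_variables(self) -> int:
        return self.U.shape[0]

    @property
    def n_samples(self) -> int:
        return self.V.shape[0]

    def matrix(self) -> np.ndarray:
        """The rank-d signal matrix ``U diag(sigma) V^T``."""
        return (self.U * self.sigma) @ self.V.T

    @classmethod
    def empty(cls, n_variables: int, n_samples: int) -> "SignalFactors":
        return cls(
            U=np.zeros((n_variables, 0)),
            sigma=np.zeros(0),
            V=np.zeros((n_samples, 0)),
            d=0,
        )


@dataclass
class SMSSVDResult:
    """Ordered signals plus their concatenation and the final residual."""

    signals: list[SignalFactors]
    U: np.ndarray
    sigma: np.ndarray
    V: np.ndarray
    residual: DataMatrix
    total_dim: int

    @property
    def n_variables(self) -> int:
        return self.U.shape[0]

    @property
    def n_samples(self) -> int:
        return self.V.shape[0]

    def components(self) -> list[tuple[np.ndarray, float, np.ndarray]]:
        """All rank-1 triplets ``(u, sigma, v)`` in concatenation order."""
        return [
            (self.U[:, j], float(self.sigma[j]), self.V[:, j])
            for j in range(self.total_dim)
        ]


def restricted_svd(X: DataMatrix, pi: SubspaceBasis) -> SignalFactors:
    """SVD of the data matrix restricted to a subspace of sample space.

    Computed as the thin SVD of the P x d matrix ``X @ basis`` with the
    right factor rotated back through the basis, so no N x N or P x P
    projection is ever formed.  Requires the subspace to be orthogonal to
    the null space of X (checked numerically).
    """
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    if pi.ambient_dim != values.shape[1]:
        raise ShapeError(
            f"basis ambient dimension {pi.ambient_dim} != number of samples "
            f"{values.shape[1]}"
        )
    return _restricted_svd(values, pi.basis)


def _restricted_svd(values: np.ndarray, basis: np.ndarray) -> SignalFactors:
    d = basis.shape[1]
    if d > values.shape[1]:
        raise DimensionError("subspace dimension exceeds the number of samples")
    b = values @ basis
    u, s, wt = scipy.linalg.svd(b, full_matrices=False)
    if s[0] == 0.0 or s[-1] <= RANK_RTOL * s[0]:
        raise RankError(
            "subspace intersects the null space of the data matrix "
            f"(singular values of X@basis: max={s[0]:.3e}, min={s[-1]:.3e})"
        )
    v = basis @ wt.T
    _fix_signs(u, v)
    return SignalFactors(U=u, sigma=s, V=v, d=d)


def select_expand(X: DataMatrix, S: SelectionMap, d: int) -> SignalFactors:
    """Truncated SVD of the selected submatrix, expanded to all variables.

    Takes the rank-``d`` truncated SVD of ``S^T X``, uses its right
    singular vectors as the subspace, and returns the restricted SVD of
    the full matrix on that subspace.  The submatrix singular values are
    attached as ``submatrix_sigma``.
    """
    values = X.values if isinstance(X, DataMatrix) else np.asarray(X, dtype=float)
    if d < 1:
        raise DimensionError("d must be >= 1")
    sub = S.apply(values)
    _, st, vt = scipy.linalg.svd(sub, full_matrices=False)
    r = int(np.count_nonzero(st > RANK_RTOL * st[0])) if st.size and st[0] > 0 else 0
    if r < d:
        raise RankError(
            f"insufficient submatrix rank: rank(S^T X) = {r} < d = {d}"
        )
    vtilde = vt[:d].T
    factors = _restricted_svd(values, vtilde)
    factors.selection = S
    factors.submatrix_sigma = st[:d].copy()
    return factors


def remove_signal(X_k: DataMatrix, factors: SignalFactors) -> DataMatrix:
    """Deflate: project the data onto the orthogonal complement of U.

    Returns ``(I - U U^T) X_k``, which removes the extracted signal and
    lowers the rank by ``d``.  A ``d = 0`` signal leaves X unchanged.
    """
    is_dm = isinstance(X_k, DataMatrix)
    values = X_k.values if is_dm else np.asarray(X_k, dtype=float)
    if factors.U.shape[0] != values.shape[0]:
        raise ShapeError(
            f"signal has {factors.U.shape[0]} variables, matrix has {values.shape[0]}"
        )
    if factors.d == 0:
        out = values.copy()
    else:
        out = values - factors.U @ (factors.U.T @ values)
    return X_k.with_values(out) if is_dm else out


def concatenate_signals(
    signals: list[SignalFactors], residual: DataMatrix
) -> SMSSVDResult:
    """Block-concatenate signals into a single SVD-like factorization.

    Signal order is preserved; singular values are descending within each
    signal but not necessarily across signals.  Cross-signal column
    orthogonality (guaranteed by proper deflation) is verified to 1e-6.
    """
    p, n = residual.shape
    for f in signals:
        if f.n_variables != p or f.n_samples != n:
            raise ShapeError("signals and residual have inconsistent shapes")
    for i in range(len(signals)):
        for j in range(i + 1, len(signals)):
            if signals[i].d == 0 or signals[j].d == 0:
                continue
            cross_u = np.max(np.abs(signals[i].U.T @ signals[j].U))
            cross_v = np.max(np.abs(signals[i].V.T @ signals[j].V))
            if max(cross_u, cross_v) > 1e-6:
                raise OrthogonalityError(
                    f"signals {i + 1} and {j + 1} are not orthogonal "
                    f"(max inner product {max(cross_u, cross_v):.3e}); "
                    "were they produced by proper deflation?"
                )
    if signals:
        u = np.hstack([f.U for f in signals])
        sigma = np.concatenate([f.sigma for f in signals])
        v = np.hstack([f.V for f in signals])
    else:
        u = np.zeros((p, 0))
        sigma = np.zeros(0)
        v = np.zeros((n, 0))
    return SMSSVDResult(
        signals=list(signals),
        U=u,
        sigma=sigma,
        V=v,
        residual=residual,
        total_dim=int(sigma.size),
    )


def reconstruct(result: SMSSVDResult) -> DataMatrix:
    """The denoised low-rank matrix ``U diag(sigma) V^T``.

    In general this does not equal the original matrix: the part of the
    data orthogonal to the extracted signals (noise) has been dropped.
    """
    values = (result.U * result.sigma) @ result.V.T
    return result.residual.with_values(values)


def _residual_is_zero(values: np.ndarray, scale: float) -> bool:
    return bool(np.max(np.abs(values)) <= RANK_RTOL * max(scale, 1e-300))


def smssvd(
    X: DataMatrix,
    target_dim: int | None = None,
    config: SMSSVDConfig | None = None,
) -> SMSSVDResult:
    """Run the full iterative decomposition.

    Parameters
    ----------
    X
        The P x N data matrix (variables x samples).
    target_dim
        Total number of dimensions to extract; overrides
        ``config.target_dim``.  If it exceeds the numerical rank, all
        rank dimensions are returned and a warning is logged.  ``None``
        (and ``config.target_dim`` None) selects open-ended mode: stop
        when no variable subset beats the randomization null.
    config
        See :class:`~smssvd.config.SMSSVDConfig`.

    Returns
    -------
    SMSSVDResult
        Ordered signals, their concatenated factors and the residual.
    """
    from .projection import optimize_projection_score  # local: avoid cycle

    config = config if config is not None else SMSSVDConfig()
    if target_dim is None:
        target_dim = config.target_dim

    work = X.values.copy()
    if config.center_variables:
        work = work - work.mean(axis=1, keepdims=True)
    p, n = work.shape
    if not np.any(work):
        raise ValueError("input matrix is zero; nothing to decompose")

    rank = numerical_rank(work)
    scale = float(np.max(np.abs(work)))
    if target_dim is not None:
        if target_dim < 1 or target_dim > min(p, n):
            raise DimensionError(
                f"target_dim must be in [1, min(P, N)] = [1, {min(p, n)}]"
            )
        budget = target_dim
        if target_dim > rank:
            logger.warning(
                "target_dim %d exceeds numerical rank %d; returning %d dimensions",
                target_dim,
                rank,
                rank,
            )
            budget = rank
    else:
        budget = None

    signals: list[SignalFactors] = []
    used = 0
    k = 0
    while True:
        k += 1
        remaining = None if budget is None else budget - used
        if remaining is not None and remaining <= 0:
            break
        if _residual_is_zero(work, scale):
            break
        current = X.with_values(work)
        if config.disable_selection:
            sel = SelectionMap.all_variables(p)
            d_k = remaining if remaining is not None else numerical_rank(work)
            d_k = min(d_k, numerical_rank(work))
            threshold = None
            score = None
            grid = None
        else:
            d_cap = min(config.d_max, n - 1) if n > 1 else 1
            if remaining is not None:
                d_cap = min(d_cap, remaining)
            sel, d_k, grid = optimize_projection_score(
                current, config, d_cap=d_cap, seed=config.seed, stream_key=(k,)
            )
            threshold = grid.best_threshold
            score = grid.best_score
            if budget is None and (grid.fallback or score is None or score <= 0):
                logger.info(
                    "iteration %d: best projection score %s not positive; stopping",
                    k,
                    score,
                )
                break
            if remaining is not None and d_k > remaining:
                d_k = remaining  # truncate the final signal to the budget
        factors = select_expand(current, sel, d_k)
        factors.threshold = threshold
        factors.score = score
        factors.grid = grid
        signals.append(factors)
        logger.info(
            "iteration %d: d=%d threshold=%s n_selected=%d score=%s",
            k,
            d_k,
            "None" if threshold is None else f"{threshold:.6g}",
            sel.n_selected,
            "None" if score is None else f"{score:.6g}",
        )
        work = remove_signal(work, factors)
        used += d_k

    return concatenate_signals(signals, X.with_values(work))
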