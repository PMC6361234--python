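"""Synthetic benchmark generator: orthogonal sparse-support low-rank signals.

Each dataset is a sum of K mutually orthogonal rank-d signals
``Y_k = U_k diag(sigma_k) V_k^T`` plus Gaussian noise.  Signal power
decays geometrically both between signals and within the components of a
signal: the i-th singular value of signal k is ``0.6**(k-1) * 0.9**(i-1)``.
Variable-side factors are supported on L randomly chosen variables per
signal; sample-side factors live in the full sample space.  New factor
columns are drawn as i.i.d. Gaussian vectors projected onto the orthogonal
complement of all previously generated columns (across signals), which
enforces ``Y_i^T Y_j = 0`` and ``Y_i Y_j^T = 0`` for i != j exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import CapacityError, DataError
from .types import DataMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticSignal",
    "SyntheticDataset",
    "sigma_schedule",
    "orthonormal_column",
    "generate_dataset",
    "figure4_fixture",
]

NOISE_SUPPORTS = ("all", "non_signal_only", "none")

# spawn-key domains so each (signal, side, column) has its own substream
_DOM_SUPPORT, _DOM_U, _DOM_V, _DOM_NOISE = 0, 1, 2, 3


@dataclass
class SyntheticConfig:
    """Generation parameters for one synthetic dataset."""

    P: int
    N: int = 100
    L: int = 64
    K: int = 8
    d: int = 1
    noise_sigma: float | np.ndarray = 0.1
    noise_support: str = "all"
    seed: int = 0
    disjoint_supports: bool = False

    def __post_init__(self) -> None:
        if self.P < 1 or self.N < 1:
            raise DataError("P and N must be >= 1")
        if self.K < 1 or self.d < 1:
            raise DataError("K and d must be >= 1")
        if self.K * self.d > min(self.N, self.P):
            raise CapacityError(
                f"K*d = {self.K * self.d} exceeds min(N, P) = {min(self.N, self.P)}: "
                "cannot build that many mutually orthogonal components"
            )
        if self.L < self.d:
            raise DataError(f"support size L = {self.L} must be >= d = {self.d}")
        if self.L > self.P:
            raise DataError(f"support size L = {self.L} exceeds P = {self.P}")
        if self.noise_support not in NOISE_SUPPORTS:
            raise DataError(
                f"noise_support must be one of {NOISE_SUPPORTS}, got {self.noise_support!r}"
            )
        sig = np.asarray(self.noise_sigma, dtype=float)
        if np.any(sig < 0):
            raise DataError("noise_sigma must be nonnegative")
        if sig.ndim not in (0, 1, 2):
            raise DataError("noise_sigma must be a scalar, P-vector or P x N matrix")
        if self.disjoint_supports and self.K * self.L > self.P:
            raise CapacityError(
                f"disjoint supports need K*L = {self.K * self.L} <= P = {self.P}"
            )


@dataclass
class SyntheticSignal:
    """One planted rank-d signal with its variable support."""

    Y: np.ndarray
    U: np.ndarray
    sigma: np.ndarray
    V: np.ndarray
    support: np.ndarray

    @property
    def rank(self) -> int:
        return int(self.sigma.size)

    @property
    def strength(self) -> float:
        """Frobenius norm of the signal, ``||sigma||_2``."""
        return float(np.linalg.norm(self.sigma))


@dataclass
class SyntheticDataset:
    """Planted signals, the noise matrix and the observed sum."""

    signals: list[SyntheticSignal]
    noise: np.ndarray
    X: np.ndarray
    config: SyntheticConfig

    def data_matrix(self) -> DataMatrix:
        return DataMatrix(self.X)

    @property
    def support_union(self) -> np.ndarray:
        return np.unique(np.concatenate([s.support for s in self.signals]))


def sigma_schedule(k: int, d: int) -> np.ndarray:
    """Singular values of signal ``k``: ``0.6**(k-1) * 0.9**(i-1)``, i = 1..d."""
    if k < 1 or d < 1:
        raise ValueError("k and d must be >= 1")
    return 0.6 ** (k - 1) * 0.9 ** np.arange(d)


def _rng(seed: int, *key: int) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=key)
    return np.random.Generator(np.random.PCG64(ss))


def orthonormal_column(
    rng: np.random.Generator,
    forbidden: np.ndarray,
    support: np.ndarray | None = None,
) -> np.ndarray:
    """Draw a unit vector orthogonal to all ``forbidden`` columns.

    An i.i.d. Gaussian vector is projected onto the orthogonal complement
    of the forbidden columns and normalized.  When ``support`` is given,
    the draw and projection happen within the support coordinates (using
    the forbidden columns restricted to the support) and the result is
    zero-padded to the full dimension.
    """
    forbidden = np.asarray(forbidden, dtype=float)
    if forbidden.ndim != 2:
        raise DataError("forbidden must be a 2-d array (dim x m, m may be 0)")
    dim = forbidden.shape[0]
    if support is not None:
        support = np.asarray(support, dtype=np.intp)
        restricted = forbidden[support]
        free_dim = support.size
    else:
        restricted = forbidden
        free_dim = dim
    q = scipy.linalg.orth(restricted) if restricted.size else np.zeros((free_dim, 0))
    if q.shape[1] >= free_dim:
        raise CapacityError(
            "orthogonal complement exhausted: forbidden columns span the "
            f"whole {free_dim}-dimensional space"
        )
    for _ in range(64):
        g = rng.standard_normal(free_dim)
        if q.shape[1]:
            g = g - q @ (q.T @ g)
        nrm = np.linalg.norm(g)
        if nrm > 1e-8:
            g = g / nrm
            break
    else:  # pragma: no cover - probability ~0
        raise CapacityError("failed to draw a vector in the orthogonal complement")
    if support is None:
        return g
    out = np.zeros(dim)
    out[support] = g
    return out


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate signals and noise according to ``config``.

    Every (signal, side, column) draw uses its own named substream of the
    master seed, so e.g. increasing K leaves earlier signals unchanged.
    """
    p, n, k_sig, d = config.P, config.N, config.K, config.d
    seed = config.seed

    if config.disjoint_supports:
        pool = _rng(seed, _DOM_SUPPORT).choice(p, size=k_sig * config.L, replace=False)
        supports = [np.sort(pool[i * config.L : (i + 1) * config.L]) for i in range(k_sig)]
    else:
        supports = [
            np.sort(_rng(seed, _DOM_SUPPORT, k).choice(p, size=config.L, replace=False))
            for k in range(1, k_sig + 1)
        ]

    u_all = np.zeros((p, 0))
    v_all = np.zeros((n, 0))
    signals: list[SyntheticSignal] = []
    for k in range(1, k_sig + 1):
        support = supports[k - 1]
        u_cols = []
        v_cols = []
        for i in range(1, d + 1):
            try:
                u_col = orthonormal_column(
                    _rng(seed, _DOM_U, k, i), u_all, support=support
                )
            except CapacityError as exc:
                raise CapacityError(
                    f"signal {k}, column {i}: cannot draw a variable-side "
                    f"direction orthogonal to the {u_all.shape[1]} previous "
                    f"columns within a support of size {support.size}"
                ) from exc
            u_all = np.hstack([u_all, u_col[:, None]])
            u_cols.append(u_col)
            v_col = orthonormal_column(_rng(seed, _DOM_V, k, i), v_all)
            v_all = np.hstack([v_all, v_col[:, None]])
            v_cols.append(v_col)
        u = np.column_stack(u_cols)
        v = np.column_stack(v_cols)
        sig = sigma_schedule(k, d)
        y = (u * sig) @ v.T
        signals.append(SyntheticSignal(Y=y, U=u, sigma=sig, V=v, support=support))

    sigma_arr = np.asarray(config.noise_sigma, dtype=float)
    if config.noise_support == "none":
        noise = np.zeros((p, n))
    else:
        noise = _rng(seed, _DOM_NOISE).standard_normal((p, n))
        if sigma_arr.ndim == 1:
            noise *= sigma_arr[:, None]
        else:
            noise *= sigma_arr
        if config.noise_support == "non_signal_only":
            union = np.unique(np.concatenate(supports))
            noise[union] = 0.0

    x = noise.copy()
    for s in signals:
        x += s.Y
    return SyntheticDataset(signals=signals, noise=noise, X=x, config=config)


def figure4_fixture(
    regime: str = "none", seed: int = 0, noise_sigma: float = 0.1
) -> SyntheticDataset:
    """Two 2-d signals with disjoint 64-variable supports in a 5000 x 32 matrix.

    ``regime`` selects where noise is added: ``"none"``,
    ``"non_signal_only"`` (supports stay noise-free) or ``"all"``.
    """
    config = SyntheticConfig(
        P=5000,
        N=32,
        L=64,
        K=2,
        d=2,
        noise_sigma=noise_sigma,
        noise_support=regime,
        seed=seed,
        disjoint_supports=True,
    )
    return generate_dataset(config)
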