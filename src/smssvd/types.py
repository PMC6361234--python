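"""Core value types: labelled data matrices, variable selections, subspaces."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, DimensionError, EmptySelectionError, ShapeError

__all__ = ["DataMatrix", "SelectionMap", "SubspaceBasis"]

_ORTHO_TOL = 1e-10


def _as_id_array(ids, n: int, prefix: str) -> np.ndarray:
    if ids is None:
        return np.array([f"{prefix}{i + 1}" for i in range(n)], dtype=object)
    out = np.array([str(x) for x in ids], dtype=object)
    if out.shape != (n,):
        raise ShapeError(f"expected {n} {prefix!r}-labels, got {out.shape}")
    return out


@dataclass
class DataMatrix:
    """A labelled P x N matrix with variables in rows and samples in columns.

    Parameters
    ----------
    values
        Real P x N array; all entries must be finite.
    variable_ids, sample_ids
        Unique row / column labels.  Generated (``v1..vP`` / ``s1..sN``)
        when omitted.
    """

    values: np.ndarray
    variable_ids: np.ndarray = None
    sample_ids: np.ndarray = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ShapeError(f"values must be 2-dimensional, got {self.values.ndim}")
        p, n = self.values.shape
        if p < 1 or n < 1:
            raise DataError("matrix must have at least one variable and one sample")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise DataError(
                f"non-finite entry at variable {bad[0]}, sample {bad[1]}"
            )
        self.variable_ids = _as_id_array(self.variable_ids, p, "v")
        self.sample_ids = _as_id_array(self.sample_ids, n, "s")
        for name, ids in (("variable", self.variable_ids), ("sample", self.sample_ids)):
            uniq, counts = np.unique(ids.astype(str), return_counts=True)
            if np.any(counts > 1):
                raise DataError(f"duplicate {name} id: {uniq[counts > 1][0]!r}")

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "DataMatrix":
        """Same labels, new values (shape-checked)."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.values.shape:
            raise ShapeError(f"shape {values.shape} != {self.values.shape}")
        return DataMatrix(values, self.variable_ids.copy(), self.sample_ids.copy())


@dataclass
class SelectionMap:
    """The linear map S used to select (or weight) variables.

    Two modes:

    * ``subset`` -- S has distinct standard basis vectors as columns, so
      that ``S^T X`` keeps the rows listed in ``indices`` (S^T S = I).
    * ``weights`` -- S is a diagonal matrix of nonnegative per-variable
      weights; zero weight excludes a variable.
    """

    mode: str
    indices: np.ndarray = None
    weights: np.ndarray = None
    n_variables: int = None

    def __post_init__(self) -> None:
        if self.mode == "subset":
            idx = np.asarray(self.indices, dtype=np.intp)
            if idx.ndim != 1 or idx.size < 1:
                raise EmptySelectionError("subset selection needs at least one index")
            if np.any(np.diff(idx) <= 0):
                raise DataError("subset indices must be strictly increasing")
            if self.n_variables is not None and (idx[0] < 0 or idx[-1] >= self.n_variables):
                raise DimensionError("selection index out of range")
            self.indices = idx
        elif self.mode == "weights":
            w = np.asarray(self.weights, dtype=float)
            if w.ndim != 1:
                raise ShapeError("weights must be a vector")
            if np.any(w < 0):
                raise DataError("weights must be nonnegative")
            if not np.any(w > 0):
                raise EmptySelectionError("at least one weight must be positive")
            self.weights = w
            self.n_variables = w.size
        else:
            raise ValueError(f"unknown selection mode {self.mode!r}")

    @classmethod
    def subset(cls, indices, n_variables: int | None = None) -> "SelectionMap":
        return cls("subset", indices=np.sort(np.asarray(indices, dtype=np.intp)),
                   n_variables=n_variables)

    @classmethod
    def all_variables(cls, n_variables: int) -> "SelectionMap":
        return cls("subset", indices=np.arange(n_variables), n_variables=n_variables)

    @classmethod
    def from_weights(cls, weights) -> "SelectionMap":
        return cls("weights", weights=np.asarray(weights, dtype=float))

    @property
    def n_selected(self) -> int:
        if self.mode == "subset":
            return int(self.indices.size)
        return int(np.count_nonzero(self.weights))

    @property
    def is_orthonormal(self) -> bool:
        """True iff S^T S = I (always true in subset mode)."""
        return self.mode == "subset"

    def apply(self, values: np.ndarray) -> np.ndarray:
        """Compute ``S^T @ values`` without materializing S."""
        if self.mode == "subset":
            if self.n_variables is not None and values.shape[0] != self.n_variables:
                raise ShapeError("selection built for a different number of variables")
            return values[self.indices]
        if values.shape[0] != self.weights.size:
            raise ShapeError("weight vector length does not match matrix")
        return self.weights[:, None] * values

    def matrix(self, n_variables: int | None = None) -> np.ndarray:
        """Dense S (P x L in subset mode, P x P diagonal in weights mode)."""
        if self.mode == "subset":
            p = n_variables if n_variables is not None else self.n_variables
            if p is None:
                raise ShapeError("n_variables unknown for dense selection matrix")
            s = np.zeros((p, self.indices.size))
            s[self.indices, np.arange(self.indices.size)] = 1.0
            return s
        return np.diag(self.weights)


@dataclass
class SubspaceBasis:
    """An orthonormal basis of a d-dimensional subspace of sample space."""

    basis: np.ndarray

    def __post_init__(self) -> None:
        self.basis = np.asarray(self.basis, dtype=float)
        if self.basis.ndim != 2:
            raise ShapeError("basis must be a 2-d array")
        n, d = self.basis.shape
        if d < 1:
            raise DimensionError("subspace dimension must be >= 1")
        if d > n:
            raise DimensionError(f"subspace dimension {d} exceeds ambient dimension {n}")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(d), atol=_ORTHO_TOL):
            raise DataError("basis columns are not orthonormal")

    @property
    def d(self) -> int:
        return self.basis.shape[1]

    @property
    def ambient_dim(self) -> int:
        return self.basis.shape[0]
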