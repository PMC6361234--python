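"""Reading and writing data matrices, decomposition results and datasets.

Supported matrix formats: TSV/CSV (variable ids in the first column,
sample ids in the header) and MatrixMarket (``<stem>.mtx`` with
``<stem>.rownames`` / ``<stem>.colnames`` sidecars, one label per line).
All numeric output uses 17 significant digits so files round-trip to
bit-identical doubles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .decomposition import SMSSVDResult
from .exceptions import DataError
from .synthetic import SyntheticDataset
from .types import DataMatrix

__all__ = ["read_matrix", "write_matrix", "write_result", "write_dataset"]

FLOAT_FMT = "%.17g"

_SUFFIX_FORMATS = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv", ".mtx": "mtx"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("tsv", "csv", "mtx"):
            raise DataError(f"unknown format {fmt!r}")
        return fmt
    guess = _SUFFIX_FORMATS.get(path.suffix.lower())
    if guess is None:
        raise DataError(
            f"cannot infer format from suffix {path.suffix!r}; pass format explicitly"
        )
    return guess


def _read_sidecar(path: Path) -> list[str]:
    if not path.exists():
        raise DataError(f"missing sidecar file: {path}")
    with open(path) as fh:
        return [line.rstrip("\n") for line in fh if line.rstrip("\n") != ""]


def read_matrix(path, format: str | None = None, transpose: bool = False) -> DataMatrix:
    """Read a variables-x-samples matrix from TSV, CSV or MatrixMarket.

    ``transpose`` flips a samples-in-rows file into the canonical
    orientation after reading.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
        if df.shape[0] == 0 or df.shape[1] == 0:
            raise DataError(f"empty matrix in {path}")
        non_numeric = df.columns[
            [not np.issubdtype(t, np.number) for t in df.dtypes]
        ]
        if len(non_numeric):
            col = non_numeric[0]
            coerced = pd.to_numeric(df[col], errors="coerce")
            row = df.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise DataError(
                f"non-numeric cell at variable {row!r}, sample {col!r} in {path}"
            )
        values = df.to_numpy(dtype=float)
        var_ids = [str(x) for x in df.index]
        sample_ids = [str(x) for x in df.columns]
    else:
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        stem = path.with_suffix("")
        var_ids = _read_sidecar(Path(str(stem) + ".rownames"))
        sample_ids = _read_sidecar(Path(str(stem) + ".colnames"))
        if len(var_ids) != values.shape[0]:
            raise DataError(
                f"{len(var_ids)} row names for {values.shape[0]} rows in {path}"
            )
        if len(sample_ids) != values.shape[1]:
            raise DataError(
                f"{len(sample_ids)} column names for {values.shape[1]} columns in {path}"
            )
    if transpose:
        values = values.T
        var_ids, sample_ids = sample_ids, var_ids
    return DataMatrix(values, var_ids, sample_ids)


def write_matrix(X: DataMatrix, path, format: str | None = None) -> None:
    """Write a matrix in TSV, CSV or MatrixMarket (+ sidecars) form."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt in ("tsv", "csv"):
        sep = "\t" if fmt == "tsv" else ","
        df = pd.DataFrame(X.values, index=X.variable_ids, columns=X.sample_ids)
        df.to_csv(path, sep=sep, float_format=FLOAT_FMT)
    else:
        scipy.io.mmwrite(path, X.values)
        stem = path.with_suffix("")
        for suffix, ids in ((".rownames", X.variable_ids), (".colnames", X.sample_ids)):
            with open(str(stem) + suffix, "w") as fh:
                for label in ids:
                    fh.write(f"{label}\n")


def component_names(result: SMSSVDResult) -> list[str]:
    """Column labels ``s<k>c<i>`` in concatenation order."""
    names = []
    for k, factors in enumerate(result.signals, start=1):
        names.extend(f"s{k}c{i}" for i in range(1, factors.d + 1))
    return names


def write_result(result: SMSSVDResult, prefix) -> list[Path]:
    """Write a decomposition as a set of text files under ``prefix``.

    Produces ``<prefix>.U.tsv``, ``<prefix>.V.tsv``, ``<prefix>.sigma.tsv``,
    ``<prefix>.signals.json`` and one ``<prefix>.scoregrid.<k>.tsv`` per
    iteration that recorded a score grid.
    """
    prefix = str(prefix)
    names = component_names(result)
    var_ids = result.residual.variable_ids
    sample_ids = result.residual.sample_ids
    written = []

    u_path = Path(prefix + ".U.tsv")
    pd.DataFrame(result.U, index=var_ids, columns=names).to_csv(
        u_path, sep="\t", float_format=FLOAT_FMT
    )
    written.append(u_path)

    v_path = Path(prefix + ".V.tsv")
    pd.DataFrame(result.V, index=sample_ids, columns=names).to_csv(
        v_path, sep="\t", float_format=FLOAT_FMT
    )
    written.append(v_path)

    sigma_path = Path(prefix + ".sigma.tsv")
    pd.DataFrame({"component": names, "sigma": result.sigma}).to_csv(
        sigma_path, sep="\t", index=False, float_format=FLOAT_FMT
    )
    written.append(sigma_path)

    signals_meta = []
    for k, f in enumerate(result.signals, start=1):
        selected = (
            [str(var_ids[i]) for i in f.selection.indices]
            if f.selection is not None and f.selection.mode == "subset"
            else None
        )
        signals_meta.append(
            {
                "signal": k,
                "d": f.d,
                "threshold": f.threshold,
                "projection_score": f.score,
                "selected_variables": selected,
                "sigma_frobenius": float(np.linalg.norm(f.sigma)),
                "submatrix_sigma_frobenius": (
                    float(np.linalg.norm(f.submatrix_sigma))
                    if f.submatrix_sigma is not None
                    else None
                ),
            }
        )
    json_path = Path(prefix + ".signals.json")
    with open(json_path, "w") as fh:
        json.dump({"total_dim": result.total_dim, "signals": signals_meta}, fh, indent=2)
        fh.write("\n")
    written.append(json_path)

    for k, f in enumerate(result.signals, start=1):
        if f.grid is not None:
            grid_path = Path(f"{prefix}.scoregrid.{k}.tsv")
            f.grid.to_tsv(grid_path)
            written.append(grid_path)
    return written


def write_dataset(dataset: SyntheticDataset, prefix, format: str = "tsv") -> list[Path]:
    """Write a synthetic dataset matrix plus a JSON sidecar of its makeup."""
    prefix = str(prefix)
    x_path = Path(f"{prefix}.X.{format if format != 'mtx' else 'mtx'}")
    write_matrix(dataset.data_matrix(), x_path, format=format)
    cfg = dataset.config
    sigma = np.asarray(cfg.noise_sigma, dtype=float)
    meta = {
        "config": {
            "P": cfg.P,
            "N": cfg.N,
            "L": cfg.L,
            "K": cfg.K,
            "d": cfg.d,
            "noise_sigma": sigma.tolist() if sigma.ndim else float(sigma),
            "noise_support": cfg.noise_support,
            "seed": cfg.seed,
            "disjoint_supports": cfg.disjoint_supports,
        },
        "signals": [
            {
                "signal": k + 1,
                "support": [int(i) for i in s.support],
                "strength": s.strength,
            }
            for k, s in enumerate(dataset.signals)
        ],
    }
    json_path = Path(prefix + ".dataset.json")
    with open(json_path, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")
    return [x_path, json_path]
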