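"""Design-matrix construction shared by the regression modules."""

from __future__ import annotations

import numpy as np
import pandas as pd


class CollinearDesignError(ValueError):
    """Raised when a design matrix is rank deficient; names the offending columns."""


def encode_covariates(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Indicator-code categorical covariates (first level is the reference).

    Numeric columns pass through unchanged; object/categorical/boolean columns
    are expanded with :func:`pandas.get_dummies` using ``drop_first=True``.
    """
    pieces = []
    for name in covariates:
        if name not in df.columns:
            raise KeyError(f"covariate column not found: {name!r}")
        col = df[name]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            pieces.append(col.astype(float).to_frame(name))
        else:
            dummies = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            pieces.append(dummies)
    if not pieces:
        return pd.DataFrame(index=df.index)
    return pd.concat(pieces, axis=1)


def build_design(
    df: pd.DataFrame,
    covariates: list[str],
    *,
    lead_columns: dict[str, np.ndarray] | None = None,
    add_intercept: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Assemble a float design matrix: intercept, lead columns, covariates.

    ``lead_columns`` are named numeric regressors (exposure, product terms)
    placed right after the intercept so their indices are predictable.
    """
    blocks: list[np.ndarray] = []
    names: list[str] = []
    n = len(df)
    if add_intercept:
        blocks.append(np.ones((n, 1)))
        names.append("intercept")
    for name, values in (lead_columns or {}).items():
        arr = np.asarray(values, dtype=float).reshape(n, 1)
        blocks.append(arr)
        names.append(name)
    enc = encode_covariates(df, covariates)
    if enc.shape[1]:
        blocks.append(enc.to_numpy(dtype=float))
        names.extend(enc.columns.tolist())
    X = np.hstack(blocks)
    check_full_rank(X, names)
    return X, names


def check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise :class:`CollinearDesignError` naming (nearly) collinear columns."""
    if not np.all(np.isfinite(X)):
        raise ValueError("design matrix contains non-finite values")
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # QR with column pivoting: columns pivoted past the numerical rank are
    # the ones that add no new direction.
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    bad = [names[j] for j in piv[np.sum(diag > tol):]]
    raise CollinearDesignError(
        f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
        f"collinear columns: {bad}"
    )
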