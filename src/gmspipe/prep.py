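"""Species filtering and the centered log-ratio (CLR) transform.

A taxa count matrix is represented as a :class:`pandas.DataFrame` with
species on the rows (unique index) and samples on the columns (unique
columns), holding non-negative integer counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_PREVALENCE_MIN = 0.20
DEFAULT_MEAN_COUNT_MIN = 50.0
DEFAULT_PSEUDOCOUNT = 0.5


def validate_counts(counts: pd.DataFrame) -> None:
    """Check the taxa-count-matrix contract (ids unique, entries >= 0)."""
    if counts.index.has_duplicates:
        raise ValueError("species ids are not unique")
    if counts.columns.has_duplicates:
        raise ValueError("sample ids are not unique")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise TypeError("counts must be numeric")
    if np.any(values < 0):
        raise ValueError("counts contain negative entries")


@dataclass
class ClrMatrix:
    """CLR-transformed abundances (species x samples) plus provenance.

    ``values`` columns each sum to zero over the retained species.
    """

    values: pd.DataFrame
    pseudocount: float
    provenance: dict = field(default_factory=dict)

    @property
    def species_ids(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.values.columns.tolist()


def filter_species(
    counts: pd.DataFrame,
    prevalence_min: float = DEFAULT_PREVALENCE_MIN,
    mean_count_min: float = DEFAULT_MEAN_COUNT_MIN,
) -> pd.DataFrame:
    """Retain species present in more than ``prevalence_min`` of samples
    with mean raw count greater than ``mean_count_min``.

    Both conditions are strict inequalities; a species is "present" in a
    sample when its raw count is > 0. Species order is preserved. An empty
    result is allowed but warned about.
    """
    validate_counts(counts)
    if counts.shape[1] < 1:
        raise ValueError("at least one sample is required")
    values = counts.to_numpy()
    prevalence = (values > 0).mean(axis=1)
    mean_count = values.mean(axis=1)
    keep = (prevalence > prevalence_min) & (mean_count > mean_count_min)
    out = counts.loc[keep]
    if out.shape[0] == 0:
        warnings.warn("no species passed the abundance/prevalence filters",
                      stacklevel=2)
    return out


def clr_transform(
    counts: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> ClrMatrix:
    """Centered log-ratio transform of a (filtered) count matrix.

    Per sample j and species k: ``x_kj = ln(c_kj + pc) - mean_k ln(c_kj + pc)``,
    so every sample column of the result sums to zero. A pseudocount of zero
    is permitted only on strictly positive counts.
    """
    validate_counts(counts)
    if counts.shape[0] < 2:
        raise ValueError("CLR requires at least two species")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    values = counts.to_numpy(dtype=float)
    if pseudocount == 0 and np.any(values <= 0):
        raise ValueError("pseudocount 0 requires strictly positive counts")
    logs = np.log(values + pseudocount)
    clr = logs - logs.mean(axis=0, keepdims=True)
    frame = pd.DataFrame(clr, index=counts.index, columns=counts.columns)
    return ClrMatrix(values=frame, pseudocount=float(pseudocount),
                     provenance={"n_species": int(counts.shape[0]),
                                 "n_samples": int(counts.shape[1])})


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a species-by-sample TSV (first column = species id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    validate_counts(df)
    return df


def write_counts_tsv(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="species_id")


def read_counts_biom(path) -> pd.DataFrame:
    """Read a BIOM table if the optional ``biom`` package is installed."""
    try:
        import biom  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading BIOM files requires the optional 'biom-format' package; "
            "use the TSV layout instead"
        ) from exc
    table = biom.load_table(str(path))  # pragma: no cover
    df = table.to_dataframe(dense=True)  # pragma: no cover
    validate_counts(df)  # pragma: no cover
    return df  # pragma: no cover
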