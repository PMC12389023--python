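"""Weighted microbiome score: log-fold-change weights applied to
correlation-whitened CLR abundances, with tertile assignment and a
trend-based validation regression.

The score for sample j is ``beta @ W @ x_j`` where ``beta`` holds the
per-species log-fold changes estimated within a genotype stratum, ``W`` is
the symmetric inverse square root of the selected species' CLR correlation
matrix, and ``x_j`` is the sample's CLR column restricted to those species.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._design import build_design
from .prep import ClrMatrix

logger = logging.getLogger(__name__)

DEFAULT_EIG_FLOOR = 1e-6
TERTILE_LABELS = {1: "low", 2: "middle", 3: "high"}


def inverse_sqrt_correlation(sigma: np.ndarray,
                             eig_floor: float = DEFAULT_EIG_FLOOR) -> np.ndarray:
    """Symmetric inverse square root of a correlation matrix.

    Eigenvalues are floored at ``eig_floor`` before inversion, which keeps
    near-duplicate species from blowing up the whitening matrix; flooring is
    logged because ``W @ sigma @ W = I`` no longer holds exactly then.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise ValueError("sigma must be a square matrix")
    if not np.allclose(sigma, sigma.T, atol=1e-8):
        raise ValueError("sigma must be symmetric")
    if not np.allclose(np.diag(sigma), 1.0, atol=1e-8):
        raise ValueError("sigma must have a unit diagonal")
    vals, vecs = np.linalg.eigh(sigma)
    if np.any(vals < eig_floor):
        logger.warning(
            "flooring %d eigenvalue(s) below %.1e during whitening; "
            "W @ sigma @ W will deviate from identity",
            int(np.sum(vals < eig_floor)), eig_floor,
        )
    floored = np.maximum(vals, eig_floor)
    W = (vecs * (1.0 / np.sqrt(floored))) @ vecs.T
    return (W + W.T) / 2.0


@dataclass
class GmsModel:
    """Fitted score model: species, weights, correlation and whitening matrix."""

    stratum: str
    species_ids: list[str]
    beta: np.ndarray
    sigma: np.ndarray
    whitening: np.ndarray
    eig_floor: float = DEFAULT_EIG_FLOOR
    regularized: bool = False
    settings: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.species_ids)

    def to_json(self, path=None) -> str:
        payload = {
            "stratum": self.stratum,
            "species_ids": list(self.species_ids),
            "beta": np.asarray(self.beta).tolist(),
            "sigma": np.asarray(self.sigma).tolist(),
            "whitening": np.asarray(self.whitening).tolist(),
            "eig_floor": self.eig_floor,
            "regularized": self.regularized,
            "settings": self.settings,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GmsModel":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            try:
                payload = json.loads(source)
            except (ValueError, TypeError):
                with open(source) as fh:
                    payload = json.load(fh)
        return cls(
            stratum=payload["stratum"],
            species_ids=list(payload["species_ids"]),
            beta=np.asarray(payload["beta"], dtype=float),
            sigma=np.asarray(payload["sigma"], dtype=float),
            whitening=np.asarray(payload["whitening"], dtype=float),
            eig_floor=float(payload.get("eig_floor", DEFAULT_EIG_FLOOR)),
            regularized=bool(payload.get("regularized", False)),
            settings=payload.get("settings", {}),
        )


@dataclass
class GmsScores:
    """Per-sample scores and tertile levels under a fitted model."""

    scores: pd.Series
    tertile: np.ndarray | None
    model_stratum: str

    def frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"gms": self.scores})
        if self.tertile is not None:
            out["gms_tertile"] = self.tertile
            out["gms_tertile_label"] = [TERTILE_LABELS[t] for t in self.tertile]
        return out


def build_gms_model(
    diff_results: pd.DataFrame,
    clr: ClrMatrix,
    sample_ids: list[str] | None = None,
    p_cutoff: float = 0.05,
    method: str = "pearson",
    eig_floor: float = DEFAULT_EIG_FLOOR,
    stratum: str | None = None,
) -> GmsModel:
    """Select species at ``p < p_cutoff``, assemble weights, and whiten.

    The correlation matrix of the selected species' CLR rows is computed on
    ``sample_ids`` (defaults to every sample in ``clr``), normally the same
    stratum used to estimate the log-fold changes.
    """
    selected = diff_results.loc[diff_results["p_value"] < p_cutoff]
    if len(selected) < 2:
        raise ValueError(
            f"need at least 2 species with p < {p_cutoff}; got {len(selected)}"
        )
    species = selected["species_id"].tolist()
    missing = [s for s in species if s not in clr.values.index]
    if missing:
        raise KeyError(f"selected species missing from CLR matrix: {missing}")
    cols = list(sample_ids) if sample_ids is not None else clr.values.columns
    sub = clr.values.loc[species, cols].to_numpy()
    if np.any(sub.std(axis=1) == 0):
        flat = [s for s, sd in zip(species, sub.std(axis=1)) if sd == 0]
        raise ValueError(f"constant CLR rows (correlation undefined): {flat}")
    if method == "pearson":
        sigma = np.corrcoef(sub)
    elif method == "spearman":
        sigma, _ = stats.spearmanr(sub, axis=1)
        sigma = np.atleast_2d(sigma)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    np.fill_diagonal(sigma, 1.0)
    regularized = bool(np.min(np.linalg.eigvalsh(sigma)) < eig_floor)
    W = inverse_sqrt_correlation(sigma, eig_floor=eig_floor)
    label = stratum if stratum is not None else str(selected["stratum"].iloc[0])
    return GmsModel(
        stratum=label,
        species_ids=species,
        beta=selected["lfc"].to_numpy(dtype=float),
        sigma=sigma,
        whitening=W,
        eig_floor=eig_floor,
        regularized=regularized,
        settings={"p_cutoff": p_cutoff, "method": method,
                  "n_samples_sigma": len(cols)},
    )


def compute_gms(model: GmsModel, clr: ClrMatrix,
                assign_tertiles: bool = True) -> GmsScores:
    """Score every sample in ``clr`` under ``model``.

    The score vector is ``beta @ W @ X`` over the model's species (in model
    order, so input ordering is irrelevant). Tertiles are assigned within the
    scored population unless ``assign_tertiles`` is False.
    """
    missing = [s for s in model.species_ids if s not in clr.values.index]
    if missing:
        raise KeyError(f"model species missing from CLR matrix: {missing}")
    X = clr.values.loc[model.species_ids].to_numpy()
    raw = np.asarray(model.beta) @ model.whitening @ X
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite scores produced")
    scores = pd.Series(raw, index=clr.values.columns, name="gms")
    tert = tertile_assign(scores.to_numpy()) if assign_tertiles else None
    return GmsScores(scores=scores, tertile=tert, model_stratum=model.stratum)


def tertile_assign(scores) -> np.ndarray:
    """Assign tertile levels 1 (low), 2 (middle), 3 (high).

    Cutpoints are the empirical 1/3 and 2/3 quantiles (linear interpolation);
    intervals are ``(-inf, q1], (q1, q2], (q2, inf)``, so boundary ties fall
    into the lower group.
    """
    x = np.asarray(scores, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need at least 3 scores")
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct score values for tertiles")
    q1, q2 = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
    out = np.where(x <= q1, 1, np.where(x <= q2, 2, 3))
    return out.astype(int)


def validate_gms(
    scores: pd.Series,
    cohort: pd.DataFrame,
    stratum: str,
    covariates: list[str] | None = None,
    alcohol_col: str = "alcohol_level",
) -> dict:
    """Linear trend of the score on alcohol level within a genotype stratum.

    Returns the alcohol coefficient, its SE, two-sided p-value and n. Used to
    check that a stratum-specific model tracks alcohol only in its own
    stratum.
    """
    covariates = list(covariates or [])
    if "sample_id" in cohort.columns:
        cohort = cohort.set_index("sample_id")
    if stratum == "pooled":
        sub = cohort
    else:
        sub = cohort.loc[cohort["genotype_group"] == stratum]
    sub = sub.loc[[s for s in sub.index if s in scores.index]]
    needed = [alcohol_col] + covariates
    sub = sub.dropna(subset=[c for c in needed if c in sub.columns])
    if len(sub) == 0:
        raise ValueError(f"stratum {stratum!r} is empty")
    alcohol = sub[alcohol_col].to_numpy(dtype=float)
    if np.ptp(alcohol) == 0:
        raise ValueError(f"alcohol level is constant in stratum {stratum!r}")
    X, names = build_design(sub, covariates,
                            lead_columns={"alcohol_level": alcohol})
    y = scores.loc[sub.index].to_numpy(dtype=float)
    xtx_inv = np.linalg.inv(X.T @ X)
    b = xtx_inv @ (X.T @ y)
    resid = y - X @ b
    dof = len(sub) - X.shape[1]
    sigma2 = resid @ resid / dof
    idx = names.index("alcohol_level")
    se = float(np.sqrt(xtx_inv[idx, idx] * sigma2))
    coef = float(b[idx])
    tval = coef / se if se > 0 else np.inf
    p = float(2.0 * stats.t.sf(abs(tval), dof))
    return {"stratum": stratum, "coef": coef, "se": se, "p_value": p,
            "n": len(sub), "direction": "positive" if coef > 0 else "negative"}
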