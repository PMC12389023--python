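"""Association and effect-modification models.

Implements logistic trend models for a binary outcome against ordinal alcohol
level, category contrasts versus non-drinkers, tertile-stratified effects with
a product-term interaction test, and rank-based robust regression (rank
inverse-normal transform + OLS with HC3 standard errors) for continuous
traits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from ._design import build_design
from .score import tertile_assign

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)


class SeparationError(RuntimeError):
    """Raised when a logistic model is (quasi-)perfectly separated."""


@dataclass
class AssocResult:
    outcome: str
    stratum: str
    estimate: float        # odds ratio (binary outcome) or coefficient
    ci_low: float
    ci_high: float
    p_trend: float
    n: int
    scale: str = "odds_ratio"

    def as_dict(self) -> dict:
        return {
            "outcome": self.outcome, "stratum": self.stratum,
            "estimate": self.estimate, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p_trend": self.p_trend,
            "n": self.n, "scale": self.scale,
        }


@dataclass
class InteractionResult:
    modifier: str
    outcome: str
    strata: list[AssocResult]
    p_interaction: float
    interaction_coef: float = np.nan
    notes: dict = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = [r.as_dict() for r in self.strata]
        frame = pd.DataFrame(rows)
        frame["modifier"] = self.modifier
        frame["p_interaction"] = self.p_interaction
        return frame


def _complete_cases(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    present = [c for c in columns if c in df.columns]
    out = df.dropna(subset=present)
    dropped = len(df) - len(out)
    if dropped:
        logger.info("dropped %d incomplete rows from model", dropped)
    return out


def _fit_logit(y: np.ndarray, X: np.ndarray, names: list[str]):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except PerfectSeparationError as exc:
        raise SeparationError(f"perfect separation in logistic model: {exc}") from exc
    except (np.linalg.LinAlgError, RuntimeWarning) as exc:
        raise SeparationError(
            f"logistic model failed to converge ({exc}); "
            "check for separation or a singular design"
        ) from exc
    if np.any(np.abs(res.params) > 30):
        big = [names[i] for i in np.flatnonzero(np.abs(res.params) > 30)]
        raise SeparationError(
            f"diverging logistic coefficients (likely separation): {big}"
        )
    return res


def logistic_trend(
    cohort: pd.DataFrame,
    outcome_col: str = "insulin_resistant",
    alcohol_col: str = "alcohol_level",
    covariates: list[str] | None = None,
    stratum_label: str = "all",
) -> AssocResult:
    """Logistic trend of a binary outcome on alcohol level (continuous 0-3).

    Returns the per-level odds ratio with a Wald 95% CI and two-sided p.
    """
    covariates = list(covariates or [])
    df = _complete_cases(cohort, [outcome_col, alcohol_col] + covariates)
    y = df[outcome_col].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    n = len(df)
    if n <= 10 * (len(covariates) + 2):
        raise ValueError(
            f"n={n} too small for logistic model with {len(covariates)} covariates"
        )
    alcohol = df[alcohol_col].to_numpy(dtype=float)
    if np.ptp(alcohol) == 0:
        raise ValueError("alcohol level is constant")
    X, names = build_design(df, covariates,
                            lead_columns={"alcohol_level": alcohol})
    res = _fit_logit(y, X, names)
    i = names.index("alcohol_level")
    coef, se = res.params[i], res.bse[i]
    return AssocResult(
        outcome=outcome_col, stratum=stratum_label,
        estimate=float(np.exp(coef)),
        ci_low=float(np.exp(coef - Z95 * se)),
        ci_high=float(np.exp(coef + Z95 * se)),
        p_trend=float(res.pvalues[i]), n=n,
    )


def category_contrasts(
    cohort: pd.DataFrame,
    outcome_col: str = "insulin_resistant",
    alcohol_col: str = "alcohol_level",
    covariates: list[str] | None = None,
) -> list[AssocResult]:
    """Odds ratios for alcohol levels 1-3 versus non-drinkers (level 0)."""
    covariates = list(covariates or [])
    df = _complete_cases(cohort, [outcome_col, alcohol_col] + covariates)
    y = df[outcome_col].astype(float).to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    levels = np.sort(df[alcohol_col].unique())
    if levels.size < 2:
        raise ValueError("alcohol level must take at least two values")
    lead = {
        f"alcohol_{int(lv)}": (df[alcohol_col] == lv).to_numpy(dtype=float)
        for lv in levels[1:]
    }
    X, names = build_design(df, covariates, lead_columns=lead)
    res = _fit_logit(y, X, names)
    out = []
    for lv in levels[1:]:
        i = names.index(f"alcohol_{int(lv)}")
        coef, se = res.params[i], res.bse[i]
        out.append(AssocResult(
            outcome=outcome_col, stratum=f"level_{int(lv)}_vs_0",
            estimate=float(np.exp(coef)),
            ci_low=float(np.exp(coef - Z95 * se)),
            ci_high=float(np.exp(coef + Z95 * se)),
            p_trend=float(res.pvalues[i]), n=len(df),
        ))
    return out


def stratified_interaction(
    cohort: pd.DataFrame,
    modifier_tertile,
    outcome_col: str = "insulin_resistant",
    alcohol_col: str = "alcohol_level",
    covariates: list[str] | None = None,
    modifier_label: str = "gms",
) -> InteractionResult:
    """Tertile-stratified logistic trends plus a pooled product-term test.

    ``modifier_tertile`` holds levels 1-3 aligned with ``cohort`` rows. The
    interaction p-value comes from the product of the two continuous codes
    (tertile 1-3 times alcohol 0-3) in a pooled model that keeps both main
    effects and all covariates.
    """
    covariates = list(covariates or [])
    tert = np.asarray(modifier_tertile, dtype=float)
    if tert.shape[0] != len(cohort):
        raise ValueError("modifier_tertile must align with cohort rows")
    if np.unique(tert).size < 2:
        raise ValueError("modifier is constant; interaction inestimable")
    work = cohort.copy()
    work["_tertile"] = tert

    strata = []
    for level in (1, 2, 3):
        sub = work.loc[work["_tertile"] == level]
        if len(sub) == 0:
            raise ValueError(f"empty modifier tertile {level}")
        strata.append(logistic_trend(
            sub, outcome_col=outcome_col, alcohol_col=alcohol_col,
            covariates=covariates,
            stratum_label=f"{modifier_label}_tertile_{level}",
        ))

    df = _complete_cases(work, [outcome_col, alcohol_col] + covariates)
    y = df[outcome_col].astype(float).to_numpy()
    alcohol = df[alcohol_col].to_numpy(dtype=float)
    t = df["_tertile"].to_numpy(dtype=float)
    X, names = build_design(
        df, covariates,
        lead_columns={
            "alcohol_level": alcohol,
            "tertile": t,
            "tertile_x_alcohol": t * alcohol,
        },
    )
    res = _fit_logit(y, X, names)
    i = names.index("tertile_x_alcohol")
    return InteractionResult(
        modifier=modifier_label, outcome=outcome_col, strata=strata,
        p_interaction=float(res.pvalues[i]),
        interaction_coef=float(res.params[i]),
        notes={"n_pooled": len(df)},
    )


def rank_inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom rank-based inverse normal transform (average ranks for ties)."""
    x = np.asarray(values, dtype=float)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (x.size - 2.0 * offset + 1.0))


def rank_robust_regression(
    cohort: pd.DataFrame,
    trait_col: str,
    alcohol_col: str = "alcohol_level",
    covariates: list[str] | None = None,
    stratum_label: str = "all",
) -> AssocResult:
    """Rank-based robust trend of a continuous trait on alcohol level.

    The trait is replaced by normal scores (Blom offset 3/8) and regressed on
    alcohol level plus covariates by OLS with HC3 heteroskedasticity-
    consistent standard errors. The coefficient is in normal-score SD units.
    """
    covariates = list(covariates or [])
    df = _complete_cases(cohort, [trait_col, alcohol_col] + covariates)
    trait = df[trait_col].to_numpy(dtype=float)
    if np.unique(trait).size < 10:
        raise ValueError(
            f"trait {trait_col!r} has fewer than 10 distinct values"
        )
    alcohol = df[alcohol_col].to_numpy(dtype=float)
    if np.ptp(alcohol) == 0:
        raise ValueError("alcohol level is constant")
    y = rank_inverse_normal(trait)
    X, names = build_design(df, covariates,
                            lead_columns={"alcohol_level": alcohol})
    res = sm.OLS(y, X).fit(cov_type="HC3")
    i = names.index("alcohol_level")
    coef, se = res.params[i], res.bse[i]
    return AssocResult(
        outcome=trait_col, stratum=stratum_label,
        estimate=float(coef),
        ci_low=float(coef - Z95 * se),
        ci_high=float(coef + Z95 * se),
        p_trend=float(res.pvalues[i]), n=len(df),
        scale="normal_score_sd",
    )


def species_modifier_analysis(
    cohort: pd.DataFrame,
    species_clr: pd.Series,
    outcome_col: str = "insulin_resistant",
    alcohol_col: str = "alcohol_level",
    covariates: list[str] | None = None,
    species_label: str | None = None,
) -> InteractionResult:
    """Effect modification by one species' CLR abundance tertiles.

    ``species_clr`` must be indexed by sample id; only samples present in
    both inputs are used.
    """
    if "sample_id" in cohort.columns:
        cohort = cohort.set_index("sample_id")
    common = [s for s in cohort.index if s in species_clr.index]
    sub = cohort.loc[common]
    vals = species_clr.loc[common].to_numpy(dtype=float)
    if np.unique(vals).size < 3:
        raise ValueError("species CLR has fewer than 3 distinct values")
    tert = tertile_assign(vals)
    label = species_label or (species_clr.name or "species")
    return stratified_interaction(
        sub, tert, outcome_col=outcome_col, alcohol_col=alcohol_col,
        covariates=covariates, modifier_label=str(label),
    )


def _continuous_interaction(
    df: pd.DataFrame, trait_col: str, alcohol_col: str,
    tert: np.ndarray, covariates: list[str],
) -> tuple[float, float]:
    """Pooled product-term test for a rank-normalised continuous trait."""
    y = rank_inverse_normal(df[trait_col].to_numpy(dtype=float))
    alcohol = df[alcohol_col].to_numpy(dtype=float)
    X, names = build_design(
        df, covariates,
        lead_columns={
            "alcohol_level": alcohol,
            "tertile": tert.astype(float),
            "tertile_x_alcohol": tert * alcohol,
        },
    )
    res = sm.OLS(y, X).fit(cov_type="HC3")
    i = names.index("tertile_x_alcohol")
    return float(res.params[i]), float(res.pvalues[i])


DEFAULT_TRAITS = (
    "homa_ir", "ogtt_2h_glucose", "bmi", "fasting_insulin", "fasting_glucose",
    "hba1c", "homa_b", "hdl_c", "ldl_c", "triglycerides",
)


def continuous_trait_battery(
    cohort: pd.DataFrame,
    modifier_tertile,
    traits: list[str] | None = None,
    alcohol_col: str = "alcohol_level",
    covariates: list[str] | None = None,
    modifier_label: str = "gms",
) -> dict[str, InteractionResult]:
    """Per-tertile rank-robust trends plus interaction test for each trait.

    Traits missing from the table are skipped with a logged warning. Returns
    a mapping trait name -> :class:`InteractionResult` whose per-stratum
    entries carry rank-normal-scale coefficients.
    """
    covariates = list(covariates or [])
    traits = list(traits if traits is not None else DEFAULT_TRAITS)
    tert = np.asarray(modifier_tertile, dtype=float)
    if tert.shape[0] != len(cohort):
        raise ValueError("modifier_tertile must align with cohort rows")
    work = cohort.copy()
    work["_tertile"] = tert

    out: dict[str, InteractionResult] = {}
    for trait in traits:
        if trait not in work.columns:
            logger.warning("trait column %r missing; skipped", trait)
            continue
        strata = []
        try:
            for level in (1, 2, 3):
                sub = work.loc[work["_tertile"] == level]
                strata.append(rank_robust_regression(
                    sub, trait, alcohol_col=alcohol_col, covariates=covariates,
                    stratum_label=f"{modifier_label}_tertile_{level}",
                ))
            df = _complete_cases(work, [trait, alcohol_col] + covariates)
            coef, p_int = _continuous_interaction(
                df, trait, alcohol_col, df["_tertile"].to_numpy(), covariates
            )
        except ValueError as exc:
            logger.warning("trait %r skipped: %s", trait, exc)
            continue
        out[trait] = InteractionResult(
            modifier=modifier_label, outcome=trait, strata=strata,
            p_interaction=p_int, interaction_coef=coef,
        )
    return out
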