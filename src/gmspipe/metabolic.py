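"""Metabolic phenotyping: HOMA indices, insulin-resistance status, diabetes
exclusion criteria, and ordinal alcohol-consumption coding.

All scalar functions also accept numpy arrays and broadcast elementwise.
Units follow clinical convention: glucose in mg/dL, insulin in mU/L
(numerically identical to mIU/L), HbA1c in percent, fasting time in hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Denominator of the insulin-resistance index (glucose * insulin / 405).
HOMA_IR_DENOMINATOR = 405.0
#: Glucose offset in the beta-cell index (20 * insulin / (glucose - 63)).
HOMA_B_GLUCOSE_OFFSET = 63.0
#: Default insulin-resistance cutoff on the HOMA-IR scale.
IR_CUTOFF = 2.5

# Diabetes exclusion thresholds.
FASTING_GLUCOSE_LIMIT = 126.0       # mg/dL, applies when fasting time > 8 h
SHORT_FAST_GLUCOSE_LIMIT = 200.0    # mg/dL, applies when fasting time <= 8 h
OGTT_2H_LIMIT = 200.0               # mg/dL
HBA1C_LIMIT = 6.5                   # %

# Weekly-drink boundaries for the ordinal alcohol level among current drinkers.
ALCOHOL_MEDIAN_DRINKS = 2.0
ALCOHOL_Q3_DRINKS = 6.0


def _as_float(x):
    arr = np.asarray(x, dtype=float)
    return arr


def homa_ir(fasting_glucose, fasting_insulin):
    """Homeostasis-model index of insulin resistance.

    Parameters
    ----------
    fasting_glucose
        Fasting plasma glucose in mg/dL; must be strictly positive.
    fasting_insulin
        Fasting insulin in mU/L; must be strictly positive.

    Returns
    -------
    float or ndarray
        ``glucose * insulin / 405``.
    """
    g, i = _as_float(fasting_glucose), _as_float(fasting_insulin)
    if np.any(g <= 0):
        raise ValueError("fasting_glucose must be strictly positive")
    if np.any(i <= 0):
        raise ValueError("fasting_insulin must be strictly positive")
    out = g * i / HOMA_IR_DENOMINATOR
    return float(out) if out.ndim == 0 else out


def homa_b(fasting_glucose, fasting_insulin):
    """Homeostasis-model index of beta-cell function.

    Returns ``20 * insulin / (glucose - 63)``; defined only for glucose
    strictly above 63 mg/dL.
    """
    g, i = _as_float(fasting_glucose), _as_float(fasting_insulin)
    if np.any(i <= 0):
        raise ValueError("fasting_insulin must be strictly positive")
    if np.any(g <= HOMA_B_GLUCOSE_OFFSET):
        raise ValueError(
            f"fasting_glucose must exceed {HOMA_B_GLUCOSE_OFFSET} mg/dL for HOMA-B"
        )
    out = 20.0 * i / (g - HOMA_B_GLUCOSE_OFFSET)
    return float(out) if out.ndim == 0 else out


def classify_insulin_resistance(homa_ir_value, cutoff: float = IR_CUTOFF,
                                inclusive: bool = True):
    """Binary insulin-resistance status from a HOMA-IR value.

    ``inclusive=True`` classifies values exactly at the cutoff as resistant;
    the exclusive variant is kept as a switch because both conventions appear
    in the clinical literature. Negative input is rejected.
    """
    h = _as_float(homa_ir_value)
    if np.any(h < 0):
        raise ValueError("homa_ir must be non-negative")
    out = (h >= cutoff) if inclusive else (h > cutoff)
    return bool(out) if out.ndim == 0 else out


@dataclass
class MetabolicRecord:
    """Per-participant metabolic measurements used by the exclusion rules.

    Missing values (None/NaN) count as "criterion not met".
    """

    fasting_glucose: float | None = None      # mg/dL
    fasting_insulin: float | None = None      # mU/L
    hba1c: float | None = None                # %
    ogtt_2h_glucose: float | None = None      # mg/dL
    fasting_time: float | None = None         # hours
    on_antidiabetic_med: bool = False
    self_reported_t2d: bool = False


def _present(x) -> bool:
    return x is not None and not (isinstance(x, float) and np.isnan(x))


def diabetes_exclusion(record: MetabolicRecord) -> bool:
    """True when any diabetes criterion is met (participant is excluded).

    Criteria: fasting glucose >= 126 mg/dL with fasting time > 8 h; fasting
    glucose >= 200 mg/dL with fasting time <= 8 h; 2-h post-load glucose
    >= 200 mg/dL; HbA1c >= 6.5%; antidiabetic medication; self-reported
    physician-diagnosed type-2 diabetes.
    """
    g, ft = record.fasting_glucose, record.fasting_time
    if _present(g) and _present(ft):
        if g >= FASTING_GLUCOSE_LIMIT and ft > 8.0:
            return True
        if g >= SHORT_FAST_GLUCOSE_LIMIT and ft <= 8.0:
            return True
    if _present(record.ogtt_2h_glucose) and record.ogtt_2h_glucose >= OGTT_2H_LIMIT:
        return True
    if _present(record.hba1c) and record.hba1c >= HBA1C_LIMIT:
        return True
    if bool(record.on_antidiabetic_med) or bool(record.self_reported_t2d):
        return True
    return False


def diabetes_exclusion_frame(df: pd.DataFrame) -> pd.Series:
    """Vectorised :func:`diabetes_exclusion` over a cohort table.

    Expects columns ``fasting_glucose, fasting_time, ogtt_2h_glucose, hba1c,
    on_antidiabetic_med, self_reported_t2d`` (missing columns are treated as
    all-missing). NaN comparisons are False, matching the scalar rule.
    """
    def col(name, default=np.nan):
        if name in df.columns:
            return df[name]
        return pd.Series(default, index=df.index)

    g = pd.to_numeric(col("fasting_glucose"), errors="coerce")
    ft = pd.to_numeric(col("fasting_time"), errors="coerce")
    ogtt = pd.to_numeric(col("ogtt_2h_glucose"), errors="coerce")
    a1c = pd.to_numeric(col("hba1c"), errors="coerce")
    med = col("on_antidiabetic_med", False).fillna(False).astype(bool)
    t2d = col("self_reported_t2d", False).fillna(False).astype(bool)

    crit = (
        ((g >= FASTING_GLUCOSE_LIMIT) & (ft > 8.0))
        | ((g >= SHORT_FAST_GLUCOSE_LIMIT) & (ft <= 8.0))
        | (ogtt >= OGTT_2H_LIMIT)
        | (a1c >= HBA1C_LIMIT)
        | med
        | t2d
    )
    return crit.fillna(False)


def alcohol_level(weekly_drinks, current_drinker):
    """Ordinal alcohol-consumption level in {0, 1, 2, 3}.

    0 = non-user (never or former drinker), 1 = current drinker below the
    median intake (< 2 drinks/week), 2 = between the median and third
    quartile (>= 2 and < 6), 3 = 6 or more drinks/week.
    """
    drinks = _as_float(weekly_drinks)
    if np.any(drinks < 0):
        raise ValueError("weekly_drinks must be non-negative")
    drinker = np.asarray(current_drinker, dtype=bool)
    level = np.where(
        ~drinker,
        0,
        np.where(drinks < ALCOHOL_MEDIAN_DRINKS, 1,
                 np.where(drinks < ALCOHOL_Q3_DRINKS, 2, 3)),
    )
    return int(level) if level.ndim == 0 else level.astype(int)


def annotate_cohort(df: pd.DataFrame, *, ir_cutoff: float = IR_CUTOFF,
                    ir_inclusive: bool = True) -> pd.DataFrame:
    """Add derived columns to a cohort table.

    Adds ``homa_ir``, ``homa_b`` (NaN when glucose <= 63), ``insulin_resistant``
    (nullable boolean, missing where HOMA-IR is missing), ``alcohol_level``
    (recomputed from ``weekly_drinks``/``current_drinker`` when present) and
    ``exclude_diabetes``. Returns a copy.
    """
    out = df.copy()
    g = pd.to_numeric(out.get("fasting_glucose"), errors="coerce")
    ins = pd.to_numeric(out.get("fasting_insulin"), errors="coerce")
    valid = (g > 0) & (ins > 0)
    hir = pd.Series(np.nan, index=out.index)
    hir[valid] = g[valid] * ins[valid] / HOMA_IR_DENOMINATOR
    out["homa_ir"] = hir
    hb = pd.Series(np.nan, index=out.index)
    ok_b = valid & (g > HOMA_B_GLUCOSE_OFFSET)
    hb[ok_b] = 20.0 * ins[ok_b] / (g[ok_b] - HOMA_B_GLUCOSE_OFFSET)
    out["homa_b"] = hb
    ir = pd.Series(pd.NA, index=out.index, dtype="boolean")
    has = hir.notna()
    ir[has] = (hir[has] >= ir_cutoff) if ir_inclusive else (hir[has] > ir_cutoff)
    out["insulin_resistant"] = ir
    if "weekly_drinks" in out.columns and "current_drinker" in out.columns:
        out["alcohol_level"] = alcohol_level(
            out["weekly_drinks"].to_numpy(), out["current_drinker"].to_numpy()
        )
    out["exclude_diabetes"] = diabetes_exclusion_frame(out)
    return out
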