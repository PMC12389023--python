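"""Synthetic cohort generator.

Produces a participant metadata table, a species-by-sample count matrix and a
ground-truth record with the statistical structure the downstream analysis
assumes: a minority genotype-carrier group, a four-level ordinal alcohol
distribution per genotype, genotype-specific per-species log-fold-change
effects of alcohol on abundance, and an insulin-resistance outcome whose
alcohol effect may depend on a latent microbiome-score modifier.

Count model
-----------
Logistic-normal multinomial: per sample, per-species log relative abundance
is ``baseline + planted_lfc(genotype) * alcohol_level + Normal(0, dispersion)``,
soft-maxed to a composition and drawn multinomially at a log-normal depth.
This gives direct control of effects on the same log-fold-change scale the
differential-abundance stage estimates.

Random-stream layout
--------------------
A single seed feeds :class:`numpy.random.SeedSequence`, whose spawned
children are assigned, in order, to the named streams in :data:`STREAMS`.
Each sub-draw therefore reproduces independently of unrelated parameters.

Metabolic outcomes
------------------
log(HOMA-IR) is drawn around a location mapped from a per-row linear
predictor on the log-odds scale; fasting glucose is truncated normal, and
fasting insulin is back-solved as ``HOMA-IR * 405 / glucose`` so the
downstream index computation recovers the drawn value exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .metabolic import HOMA_IR_DENOMINATOR, IR_CUTOFF
from .score import tertile_assign

#: Named substreams spawned (in this order) from the master seed.
STREAMS = (
    "genotype", "alcohol", "covariates", "baseline",
    "abundance", "depth", "counts", "metabolic", "diabetic",
)

#: Ordinal alcohol-level probabilities for non-carriers / carriers, from the
#: marginal distribution of the four consumption levels in the source cohort.
ALCOHOL_PROBS_NONCARRIER = (0.38, 0.33, 0.15, 0.14)
ALCOHOL_PROBS_CARRIER = (0.42, 0.33, 0.14, 0.11)

SITES = ("site_A", "site_B", "site_C", "site_D")

#: Approximate logit-to-probit slope; used to map log-odds-scale effects to
#: the latent log(HOMA-IR) location so implied logistic coefficients match
#: the requested ones.
LOGIT_PROBIT_FACTOR = 1.702


@dataclass
class SimParams:
    """Parameters of one synthetic cohort. See module docstring for the model."""

    n_participants: int
    carrier_fraction: float = 0.12
    alcohol_level_probs_noncarrier: tuple = ALCOHOL_PROBS_NONCARRIER
    alcohol_level_probs_carrier: tuple = ALCOHOL_PROBS_CARRIER
    n_species: int = 100
    baseline_log_abundance: np.ndarray | None = None
    baseline_log_sd: float = 2.0
    dispersion: float = 1.0
    sequencing_depth_mean: int = 20000
    depth_log_sd: float = 0.3
    planted_lfc_noncarrier: np.ndarray | None = None
    planted_lfc_carrier: np.ndarray | None = None
    covariate_effect_sizes: np.ndarray | None = None  # (age_std, sex, smoking, diet)
    ir_intercept: float = 0.2
    ir_alcohol_main: float = 0.0
    ir_gms_main: float = 0.0
    ir_alcohol_gms_interaction: float = 0.0
    #: Optional per-tertile alcohol effects (log-odds per alcohol level) that
    #: override the main + product parameterisation when provided.
    ir_alcohol_by_gms_tertile: tuple | None = None
    log_homa_scale: float = 0.6
    diabetic_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_log_abundance is not None:
            self.baseline_log_abundance = np.asarray(
                self.baseline_log_abundance, dtype=float)
        self.planted_lfc_noncarrier = self._lfc(self.planted_lfc_noncarrier)
        self.planted_lfc_carrier = self._lfc(self.planted_lfc_carrier)
        if self.covariate_effect_sizes is None:
            self.covariate_effect_sizes = np.zeros(4)
        else:
            self.covariate_effect_sizes = np.asarray(
                self.covariate_effect_sizes, dtype=float)
        self.validate()

    def _lfc(self, v):
        if v is None:
            return np.zeros(self.n_species)
        return np.asarray(v, dtype=float)

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.n_species < 3:
            raise ValueError("n_species must be at least 3 (CLR needs >= 3 parts)")
        for name in ("carrier_fraction", "diabetic_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("alcohol_level_probs_noncarrier", "alcohol_level_probs_carrier"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.shape != (4,) or np.any(p < 0) or np.any(p > 1):
                raise ValueError(f"{name} must be a 4-vector of proportions")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9")
        for name in ("planted_lfc_noncarrier", "planted_lfc_carrier"):
            v = getattr(self, name)
            if v.shape != (self.n_species,):
                raise ValueError(f"{name} must have length n_species")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be finite")
        if self.baseline_log_abundance is not None:
            if self.baseline_log_abundance.shape != (self.n_species,):
                raise ValueError("baseline_log_abundance must have length n_species")
            if not np.all(np.isfinite(self.baseline_log_abundance)):
                raise ValueError("baseline_log_abundance must be finite")
        scalars = (self.dispersion, self.sequencing_depth_mean, self.depth_log_sd,
                   self.ir_intercept, self.ir_alcohol_main, self.ir_gms_main,
                   self.ir_alcohol_gms_interaction, self.log_homa_scale)
        if not np.all(np.isfinite(np.asarray(scalars, dtype=float))):
            raise ValueError("non-finite scalar parameter")
        if self.dispersion <= 0 or self.log_homa_scale <= 0:
            raise ValueError("dispersion and log_homa_scale must be positive")
        if self.sequencing_depth_mean < 10:
            raise ValueError("sequencing_depth_mean is too small")
        if self.ir_alcohol_by_gms_tertile is not None:
            t = np.asarray(self.ir_alcohol_by_gms_tertile, dtype=float)
            if t.shape != (3,) or not np.all(np.isfinite(t)):
                raise ValueError("ir_alcohol_by_gms_tertile must be a finite 3-vector")


@dataclass
class SimTruth:
    """Planted quantities recorded for recovery testing."""

    planted_lfc: dict
    interaction_coefficient: float
    alcohol_by_tertile: tuple | None
    sampling_offsets: pd.Series          # centered true log depths
    null_species: list[str]
    nonnull_species: list[str]
    true_homa_ir: pd.Series
    latent_modifier: pd.Series
    latent_tertile: pd.Series
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        payload = {
            "planted_lfc": {k: np.asarray(v).tolist()
                            for k, v in self.planted_lfc.items()},
            "interaction_coefficient": self.interaction_coefficient,
            "alcohol_by_tertile": (list(self.alcohol_by_tertile)
                                   if self.alcohol_by_tertile is not None else None),
            "sampling_offsets": self.sampling_offsets.to_dict(),
            "null_species": self.null_species,
            "nonnull_species": self.nonnull_species,
            "true_homa_ir": self.true_homa_ir.to_dict(),
            "latent_modifier": self.latent_modifier.to_dict(),
            "latent_tertile": {k: int(v) for k, v in self.latent_tertile.items()},
            "seed": self.seed,
            "extras": self.extras,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(STREAMS))
    return {name: np.random.default_rng(c) for name, c in zip(STREAMS, children)}


def simulate_metabolic_outcomes(
    linear_predictor: np.ndarray,
    params: SimParams,
    rng: np.random.Generator,
    diabetic_rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw metabolic measurements for each row of ``linear_predictor``.

    Returns ``(frame, true_homa_ir)``. ``log(HOMA-IR)`` is Normal with
    location ``log(2.5) + (log_homa_scale / 1.702) * lp`` so that the implied
    logistic coefficients of the binary insulin-resistance status approximate
    the log-odds-scale parameters in ``lp``. Fasting insulin is back-solved
    from the drawn index and glucose, making the downstream computation an
    exact inverse. A ``diabetic_fraction`` of rows is overwritten with values
    violating one randomly chosen diabetes criterion (insulin is re-solved so
    the index round-trip still holds).
    """
    lp = np.asarray(linear_predictor, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor must be finite")
    n = lp.size
    if diabetic_rng is None:
        diabetic_rng = rng

    location = np.log(IR_CUTOFF) + (params.log_homa_scale / LOGIT_PROBIT_FACTOR) * lp
    log_homa = rng.normal(location, params.log_homa_scale)
    true_homa = np.exp(log_homa)

    a, b = (63.0 - 95.0) / 8.0, (126.0 - 95.0) / 8.0
    glucose = stats.truncnorm.rvs(a, b, loc=95.0, scale=8.0, size=n,
                                  random_state=rng)
    hba1c = np.clip(rng.normal(5.5, 0.35, n), 4.0, 6.4)
    ogtt = np.clip(rng.normal(118.0, 25.0, n), 50.0, 199.0)
    fasting_time = rng.uniform(8.5, 14.0, n)
    med = np.zeros(n, dtype=bool)
    t2d = np.zeros(n, dtype=bool)

    # Correlated ancillary traits (BMI shares the insulin-resistance latent).
    bmi = np.clip(29.0 + 3.0 * (log_homa - np.log(IR_CUTOFF))
                  / params.log_homa_scale + rng.normal(0.0, 3.5, n), 16.0, 55.0)
    hdl = np.clip(rng.normal(50.0, 12.0, n), 20.0, None)
    ldl = np.clip(rng.normal(117.0, 30.0, n), 40.0, None)
    trig = rng.lognormal(np.log(105.0), 0.45, n)

    if params.diabetic_fraction > 0:
        hit = diabetic_rng.random(n) < params.diabetic_fraction
        kind = diabetic_rng.integers(0, 5, n)
        u = diabetic_rng.random(n)
        sel = hit & (kind == 0)
        glucose[sel] = 126.0 + 60.0 * u[sel]
        fasting_time[sel] = 9.0 + 5.0 * u[sel]
        sel = hit & (kind == 1)
        glucose[sel] = 200.0 + 60.0 * u[sel]
        fasting_time[sel] = 4.0 + 4.0 * u[sel]
        sel = hit & (kind == 2)
        ogtt[sel] = 200.0 + 100.0 * u[sel]
        sel = hit & (kind == 3)
        hba1c[sel] = 6.5 + 2.5 * u[sel]
        sel = hit & (kind == 4)
        med[sel] = True

    insulin = true_homa * HOMA_IR_DENOMINATOR / glucose
    frame = pd.DataFrame({
        "fasting_glucose": glucose,
        "fasting_insulin": insulin,
        "hba1c": hba1c,
        "ogtt_2h_glucose": ogtt,
        "fasting_time": fasting_time,
        "on_antidiabetic_med": med,
        "self_reported_t2d": t2d,
        "bmi": bmi,
        "hdl_c": hdl,
        "ldl_c": ldl,
        "triglycerides": trig,
    })
    return frame, true_homa


def _latent_modifier(eta: np.ndarray, lfc: np.ndarray,
                     fallback: np.ndarray) -> np.ndarray:
    """Standardised planted-weight score of the latent composition.

    ``eta`` is samples x species log relative abundance; the modifier is the
    planted-lfc-weighted, species-centered latent profile. When no effects
    are planted the provided independent normal fallback is used.
    """
    if np.all(lfc == 0):
        out = fallback.copy()
    else:
        centered = eta - eta.mean(axis=1, keepdims=True)
        out = centered @ lfc
    sd = out.std()
    if sd > 0:
        out = (out - out.mean()) / sd
    return out


def simulate_cohort(params: SimParams):
    """Generate ``(cohort, counts, truth)`` for one synthetic cohort.

    ``cohort`` is one row per participant (indexed by sample id), ``counts``
    a species-by-sample integer DataFrame, and ``truth`` a :class:`SimTruth`.
    Identical parameters (including seed) reproduce identical outputs.
    """
    params.validate()
    n, K = params.n_participants, params.n_species
    rngs = _spawn_rngs(params.seed)

    sample_ids = [f"S{j:05d}" for j in range(n)]
    species_ids = [f"sp{k:04d}" for k in range(K)]

    carrier = rngs["genotype"].random(n) < params.carrier_fraction
    hom = rngs["genotype"].random(n) < 0.15  # minority of carriers are TT
    genotype = np.where(carrier, np.where(hom, "TT", "CT"), "CC")

    probs_nc = np.asarray(params.alcohol_level_probs_noncarrier, dtype=float)
    probs_c = np.asarray(params.alcohol_level_probs_carrier, dtype=float)
    u = rngs["alcohol"].random(n)
    cum_nc, cum_c = probs_nc.cumsum(), probs_c.cumsum()
    level = np.where(
        carrier,
        np.searchsorted(cum_c, u, side="right"),
        np.searchsorted(cum_nc, u, side="right"),
    ).clip(0, 3)
    # Weekly drinks consistent with the ordinal coding.
    v = rngs["alcohol"].random(n)
    drinks = np.select(
        [level == 0, level == 1, level == 2],
        [0.0, 0.1 + 1.8 * v, 2.0 + 3.9 * v],
        default=6.0 + rngs["alcohol"].exponential(3.0, n),
    )
    current = level > 0

    cov_rng = rngs["covariates"]
    age = cov_rng.normal(52.0, 10.0, n)
    sex = cov_rng.random(n) < 0.37          # True = male
    smoking = cov_rng.random(n) < 0.16
    site = np.asarray(SITES)[cov_rng.integers(0, len(SITES), n)]
    diet = cov_rng.normal(0.0, 1.0, n)

    if params.baseline_log_abundance is None:
        baseline = rngs["baseline"].normal(0.0, params.baseline_log_sd, K)
    else:
        baseline = params.baseline_log_abundance
    lfc = np.where(carrier[:, None],
                   params.planted_lfc_carrier[None, :],
                   params.planted_lfc_noncarrier[None, :])
    eta = (baseline[None, :] + lfc * level[:, None]
           + rngs["abundance"].normal(0.0, params.dispersion, (n, K)))
    # softmax per sample
    shifted = eta - eta.max(axis=1, keepdims=True)
    comp = np.exp(shifted)
    comp /= comp.sum(axis=1, keepdims=True)

    mu_log = np.log(params.sequencing_depth_mean) - 0.5 * params.depth_log_sd ** 2
    depth = np.maximum(
        np.rint(rngs["depth"].lognormal(mu_log, params.depth_log_sd, n)), 100
    ).astype(np.int64)
    counts = rngs["counts"].multinomial(depth, comp)
    counts_df = pd.DataFrame(counts.T, index=species_ids, columns=sample_ids)

    # Latent microbiome-score modifier and its within-stratum tertile.
    fallback = rngs["metabolic"].normal(0.0, 1.0, n)
    g = np.zeros(n)
    tert = np.full(n, 2, dtype=int)
    for mask, w in ((~carrier, params.planted_lfc_noncarrier),
                    (carrier, params.planted_lfc_carrier)):
        if mask.sum() == 0:
            continue
        g[mask] = _latent_modifier(eta[mask], w, fallback[mask])
        if mask.sum() >= 3 and np.unique(g[mask]).size >= 3:
            tert[mask] = tertile_assign(g[mask])

    lp = (params.ir_intercept
          + params.covariate_effect_sizes[0] * (age - 52.0) / 10.0
          + params.covariate_effect_sizes[1] * sex
          + params.covariate_effect_sizes[2] * smoking
          + params.covariate_effect_sizes[3] * diet)
    if params.ir_alcohol_by_gms_tertile is not None:
        slopes = np.asarray(params.ir_alcohol_by_gms_tertile, dtype=float)
        lp = lp + slopes[tert - 1] * level + params.ir_gms_main * (tert - 2)
    else:
        lp = (lp + params.ir_alcohol_main * level + params.ir_gms_main * g
              + params.ir_alcohol_gms_interaction * level * g)

    metabolic, true_homa = simulate_metabolic_outcomes(
        lp, params, rngs["metabolic"], rngs["diabetic"])

    cohort = pd.DataFrame({
        "sample_id": sample_ids,
        "genotype": genotype,
        "genotype_group": np.where(carrier, "carrier", "noncarrier"),
        "alcohol_level": level.astype(int),
        "weekly_drinks": drinks,
        "current_drinker": current,
        "age": age,
        "sex": np.where(sex, "male", "female"),
        "site": site,
        "smoking": smoking.astype(int),
        "diet_score": diet,
    }).set_index("sample_id")
    cohort = pd.concat([cohort, metabolic.set_index(cohort.index)], axis=1)

    nonnull = ((params.planted_lfc_noncarrier != 0)
               | (params.planted_lfc_carrier != 0))
    truth = SimTruth(
        planted_lfc={
            "noncarrier": params.planted_lfc_noncarrier.copy(),
            "carrier": params.planted_lfc_carrier.copy(),
        },
        interaction_coefficient=params.ir_alcohol_gms_interaction,
        alcohol_by_tertile=params.ir_alcohol_by_gms_tertile,
        sampling_offsets=pd.Series(
            np.log(depth) - np.log(depth).mean(), index=sample_ids),
        null_species=[s for s, nz in zip(species_ids, nonnull) if not nz],
        nonnull_species=[s for s, nz in zip(species_ids, nonnull) if nz],
        true_homa_ir=pd.Series(true_homa, index=sample_ids),
        latent_modifier=pd.Series(g, index=sample_ids),
        latent_tertile=pd.Series(tert, index=sample_ids),
        seed=params.seed,
        extras={"depth_mean": float(depth.mean())},
    )
    return cohort, counts_df, truth


def write_outputs(cohort: pd.DataFrame, counts: pd.DataFrame, truth: SimTruth,
                  out_dir) -> dict:
    """Write cohort TSV, counts TSV and truth JSON into ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_path = out / "cohort.tsv"
    counts_path = out / "counts.tsv"
    truth_path = out / "truth.json"
    cohort.to_csv(cohort_path, sep="\t", index_label="sample_id")
    counts.to_csv(counts_path, sep="\t", index_label="species_id")
    truth.to_json(truth_path)
    return {"cohort": str(cohort_path), "counts": str(counts_path),
            "truth": str(truth_path)}
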