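"""End-to-end orchestration: exclusion -> filtering -> stratified differential
abundance -> score building/validation -> interaction analyses, from a single
config, with per-stage logging and a machine-readable report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metabolic import annotate_cohort
from .prep import (DEFAULT_MEAN_COUNT_MIN, DEFAULT_PREVALENCE_MIN,
                   DEFAULT_PSEUDOCOUNT, clr_transform, filter_species,
                   read_counts_tsv)
from .diffabund import fit_species_associations, genotype_alcohol_interaction
from .score import build_gms_model, compute_gms, tertile_assign, validate_gms
from .assoc import (continuous_trait_battery, logistic_trend,
                    category_contrasts, species_modifier_analysis,
                    stratified_interaction)

logger = logging.getLogger(__name__)

VALID_GENOTYPES = {"CC", "CT", "TT"}
DEFAULT_COVARIATES = ["age", "sex", "site", "smoking", "diet_score"]


class StageError(RuntimeError):
    """Wraps an error with the pipeline stage where it occurred."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[stage: {stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class PipelineConfig:
    cohort_path: str
    counts_path: str
    out_dir: str
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))
    prevalence_min: float = DEFAULT_PREVALENCE_MIN
    mean_count_min: float = DEFAULT_MEAN_COUNT_MIN
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    p_cutoff: float = 0.05
    fdr_cutoff: float = 0.05
    ir_cutoff: float = 2.5
    ir_inclusive: bool = True
    eig_floor: float = 1e-6
    seed: int = 0

    def validate(self) -> None:
        if self.cohort_path == self.counts_path:
            raise ValueError("cohort and counts paths must be distinct")
        for name, lo, hi in (("prevalence_min", 0, 1), ("p_cutoff", 0, 1),
                             ("fdr_cutoff", 0, 1)):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"{name} must lie in [{lo}, {hi}]")
        if self.mean_count_min < 0 or self.pseudocount < 0:
            raise ValueError("mean_count_min and pseudocount must be >= 0")
        if self.ir_cutoff <= 0 or self.eig_floor <= 0:
            raise ValueError("ir_cutoff and eig_floor must be positive")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class PipelineReport:
    counts: dict = field(default_factory=dict)
    settings: dict = field(default_factory=dict)
    validations: list = field(default_factory=list)
    interactions: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)   # name -> DataFrame (written as TSV)
    version: str = __version__
    timestamp: float = 0.0

    def to_json(self, path=None) -> str:
        payload = {
            "version": self.version,
            "timestamp": self.timestamp,
            "settings": self.settings,
            "counts": self.counts,
            "validations": self.validations,
            "interactions": self.interactions,
            "tables": sorted(self.tables),
        }
        text = json.dumps(payload, indent=2, default=_jsonable)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"cannot serialise {type(obj)!r}")


def _stage(name):
    def wrap(fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
        logger.info("stage %-28s done in %.2fs", name, time.perf_counter() - t0)
        return result
    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis described by ``config``.

    Writes intermediate tables, the fitted score models and ``report.json``
    into ``config.out_dir`` and returns the in-memory report. Deterministic
    given the same inputs and config (the timestamp field aside).
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(settings=asdict(config), timestamp=time.time())
    cov = list(config.covariates)

    cohort = _stage("load_cohort")(pd.read_csv, config.cohort_path, sep="\t")
    if "sample_id" in cohort.columns:
        cohort = cohort.set_index("sample_id")
    counts = _stage("load_counts")(read_counts_tsv, config.counts_path)
    report.counts["participants_input"] = int(len(cohort))

    bad = set(cohort["genotype"].unique()) - VALID_GENOTYPES
    if bad:
        raise StageError("genotype_validation",
                         ValueError(f"invalid genotype strings: {sorted(bad)}"))
    if "genotype_group" not in cohort.columns:
        cohort["genotype_group"] = np.where(
            cohort["genotype"].isin({"CT", "TT"}), "carrier", "noncarrier")

    cohort = _stage("metabolic_annotation")(
        annotate_cohort, cohort,
        ir_cutoff=config.ir_cutoff, ir_inclusive=config.ir_inclusive)
    excluded = int(cohort["exclude_diabetes"].sum())
    report.counts["excluded_diabetes"] = excluded
    cohort = cohort.loc[~cohort["exclude_diabetes"]]
    report.counts["participants_analyzed"] = int(len(cohort))
    missing_ir = int(cohort["insulin_resistant"].isna().sum())
    report.counts["missing_ir_status"] = missing_ir
    for group in ("carrier", "noncarrier"):
        report.counts[f"n_{group}"] = int((cohort["genotype_group"] == group).sum())

    # Alcohol-IR trend in all and per genotype group (regression cohort).
    ir_cohort = cohort.loc[cohort["insulin_resistant"].notna()].copy()
    ir_cohort["insulin_resistant"] = ir_cohort["insulin_resistant"].astype(bool)
    trend_rows = []
    for label, frame in (("all", ir_cohort),
                         ("noncarrier", ir_cohort[ir_cohort.genotype_group == "noncarrier"]),
                         ("carrier", ir_cohort[ir_cohort.genotype_group == "carrier"])):
        try:
            trend_rows.append(_stage(f"ir_trend_{label}")(
                logistic_trend, frame, covariates=cov,
                stratum_label=label).as_dict())
        except StageError as exc:
            logger.warning("skipping IR trend for %s: %s", label, exc)
    try:
        for row in _stage("ir_category_contrasts")(
                category_contrasts, ir_cohort, covariates=cov):
            trend_rows.append(row.as_dict())
    except StageError as exc:
        logger.warning("skipping category contrasts: %s", exc)
    report.tables["ir_alcohol_trend"] = pd.DataFrame(trend_rows)

    # Microbiome subcohort.
    micro_samples = [s for s in counts.columns if s in cohort.index]
    report.counts["microbiome_samples"] = len(micro_samples)
    counts = counts[micro_samples]
    micro = cohort.loc[micro_samples]

    filtered = _stage("filter_species")(
        filter_species, counts, config.prevalence_min, config.mean_count_min)
    report.counts["species_input"] = int(len(counts))
    report.counts["species_filtered"] = int(len(filtered))
    clr = _stage("clr_transform")(clr_transform, filtered, config.pseudocount)

    models, scores = {}, {}
    diff_tables = {}
    for stratum in ("noncarrier", "carrier"):
        diff = _stage(f"diff_abund_{stratum}")(
            fit_species_associations, filtered, micro, stratum, cov,
            config.pseudocount)
        diff_tables[stratum] = diff
        report.tables[f"diff_abund_{stratum}"] = diff
        selected = diff.loc[diff.p_value < config.p_cutoff]
        report.counts[f"species_selected_{stratum}"] = int(len(selected))
        stratum_samples = micro.index[micro.genotype_group == stratum].tolist()
        try:
            model = _stage(f"gms_model_{stratum}")(
                build_gms_model, diff, clr, stratum_samples, config.p_cutoff,
                "pearson", config.eig_floor, stratum)
        except StageError as exc:
            logger.warning("no score model for %s: %s", stratum, exc)
            continue
        models[stratum] = model
        model.to_json(out_dir / f"gms_model_{stratum}.json")
        report.counts[f"gms_k_{stratum}"] = model.k
        scores[stratum] = _stage(f"gms_scores_{stratum}")(
            compute_gms, model, clr)

    # Genotype-specificity validation: each model against each stratum.
    for model_stratum, sc in scores.items():
        for target in ("noncarrier", "carrier"):
            try:
                res = _stage(f"validate_{model_stratum}_on_{target}")(
                    validate_gms, sc.scores, micro, target, cov)
            except StageError as exc:
                logger.warning("validation skipped: %s", exc)
                continue
            res["model"] = model_stratum
            report.validations.append(res)

    # Effect modification within each stratum by its own score tertiles.
    micro_ir = micro.loc[micro["insulin_resistant"].notna()].copy()
    micro_ir["insulin_resistant"] = micro_ir["insulin_resistant"].astype(bool)
    for stratum, sc in scores.items():
        target = micro_ir.loc[micro_ir.genotype_group == stratum]
        if len(target) == 0:
            continue
        own = sc.scores.loc[target.index].to_numpy()
        try:
            tert = tertile_assign(own)
            inter = _stage(f"gms_interaction_{stratum}")(
                stratified_interaction, target, tert,
                covariates=cov, modifier_label=f"gms_{stratum}")
            report.interactions[f"gms_{stratum}"] = {
                "p_interaction": inter.p_interaction,
                "coef": inter.interaction_coef,
                "strata": [r.as_dict() for r in inter.strata],
            }
            battery = _stage(f"trait_battery_{stratum}")(
                continuous_trait_battery, target, tert,
                covariates=cov, modifier_label=f"gms_{stratum}")
            report.tables[f"trait_battery_{stratum}"] = pd.concat(
                [r.as_frame() for r in battery.values()], ignore_index=True
            ) if battery else pd.DataFrame()
        except StageError as exc:
            logger.warning("interaction analyses skipped for %s: %s",
                           stratum, exc)

    # Individual species modifiers: FDR-significant species in non-carriers.
    if "noncarrier" in diff_tables:
        top = diff_tables["noncarrier"]
        top = top.loc[top.q_value < config.fdr_cutoff, "species_id"].tolist()
        report.counts["species_fdr_noncarrier"] = len(top)
        nc_ir = micro_ir.loc[micro_ir.genotype_group == "noncarrier"]
        rows = []
        for sp in top:
            try:
                inter = species_modifier_analysis(
                    nc_ir, clr.values.loc[sp], covariates=cov,
                    species_label=sp)
                rows.append({"species_id": sp,
                             "p_interaction": inter.p_interaction,
                             "coef": inter.interaction_coef})
            except (ValueError, RuntimeError) as exc:
                logger.warning("species modifier %s skipped: %s", sp, exc)
        report.tables["species_modifiers_noncarrier"] = pd.DataFrame(rows)

    # Per-species genotype x alcohol interaction over the union of selections.
    union = []
    for stratum, diff in diff_tables.items():
        union.extend(diff.loc[diff.p_value < config.p_cutoff, "species_id"])
    union = sorted(set(union))
    rows = []
    for sp in union:
        try:
            rows.append(genotype_alcohol_interaction(
                filtered, micro, sp, cov, config.pseudocount))
        except (ValueError, KeyError) as exc:
            logger.warning("genotype interaction %s skipped: %s", sp, exc)
    report.tables["genotype_alcohol_interaction"] = pd.DataFrame(rows)
    if rows:
        report.counts["species_genotype_interaction_p05"] = int(
            (pd.DataFrame(rows)["p_interaction"] < 0.05).sum())

    for stratum, sc in scores.items():
        report.tables[f"gms_scores_{stratum}"] = sc.frame()

    for name, frame in report.tables.items():
        frame.to_csv(out_dir / f"{name}.tsv", sep="\t",
                     index=bool(frame.index.name))
    report.to_json(out_dir / "report.json")
    return report
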