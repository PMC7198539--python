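"""End-to-end orchestration: claims -> cohort -> adherence -> weights -> effects.

`run_pipeline` realizes the full study flow on either simulated claims or
four claims CSVs, and renders the study-shaped outputs: an attrition flow
table, a baseline characteristics table with group summaries and tests, a
persistence/implementation table with the weighted HR and RR, plus a
manifest recording the configuration hash and seed so runs are
reproducible byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from . import adherence, cohort as cohort_mod, models, weights as weights_mod
from .synthetic import SimulationParams, simulate

logger = logging.getLogger(__name__)


def percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Percentage at fixed decimals with half-up rounding (table convention)."""
    if denominator == 0:
        return float("nan")
    q = Decimal(str(numerator)) * 100 / Decimal(str(denominator))
    exp = Decimal(1).scaleb(-decimals)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


class PipelineStageError(RuntimeError):
    """An error in a named pipeline stage; the cause is chained."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage {stage!r} failed: {exc}")
        self.stage = stage


class RunConfig(BaseModel):
    """Configuration of one pipeline run: either claims paths or a simulate block."""

    input_dir: Optional[Path] = None
    simulate: Optional[SimulationParams] = None
    cohort: cohort_mod.CohortConfig = Field(default_factory=cohort_mod.CohortConfig)
    cma_threshold: float = Field(default=0.90, gt=0.0, le=1.0)
    gap_multiplier: float = Field(default=2.0, gt=0.0)
    anchor: Literal["dispensation", "exhaustion"] = "dispensation"
    output_dir: Optional[Path] = None
    seed: Optional[int] = None          # overrides simulate.seed when given
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if self.input_dir is None and self.simulate is None:
            raise ValueError("config needs either input_dir or a simulate block")
        return self

    def config_hash(self) -> str:
        payload = self.model_dump_json(exclude={"output_dir", "log_level"})
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    cohort: pd.DataFrame
    attrition: cohort_mod.AttritionRecord
    details: dict
    episode_frame: pd.DataFrame
    persistence: pd.DataFrame
    cma_table: pd.DataFrame
    implementation: pd.DataFrame
    weighted: pd.DataFrame
    balance: pd.DataFrame
    baseline: pd.DataFrame
    estimates: dict
    manifest: dict
    tables: dict = field(default_factory=dict, repr=False)


# ---------------------------------------------------------------------------
# Baseline table
# ---------------------------------------------------------------------------

BASELINE_COVARIATES = [
    ("age", "continuous"),
    ("sex", "categorical"),
    ("ald", "binary"),
    ("cmu", "binary"),
    ("polypharmacy", "binary"),
    ("fracture_history", "binary"),
    ("charlson_class", "categorical"),
    ("year", "categorical"),
    ("molecule", "categorical"),
    ("frequency", "categorical"),
    ("specialty", "categorical"),
]


def describe_baseline(cohort: pd.DataFrame,
                      covariates: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Per-covariate group summaries with Wilcoxon (continuous, normal
    approximation) and chi-square (categorical, no continuity correction)
    p-values; percentages at one decimal, half-up."""
    covariates = covariates or BASELINE_COVARIATES
    brand = cohort[cohort["group"] == "brand"]
    generic = cohort[cohort["group"] == "generic"]
    rows = []
    for name, kind in covariates:
        if name not in cohort:
            continue
        if kind == "continuous":
            p = stats.ranksums(brand[name], generic[name]).pvalue
            rows.append({
                "covariate": name, "level": "mean_sd",
                "brand": f"{brand[name].mean():.1f} ± {brand[name].std(ddof=1):.1f}",
                "generic": f"{generic[name].mean():.1f} ± {generic[name].std(ddof=1):.1f}",
                "p_value": p, "note": "wilcoxon"})
            continue
        col = cohort[name].astype(str)
        levels = sorted(col.dropna().unique())
        if len(levels) < 2:
            rows.append({"covariate": name, "level": levels[0] if levels else "",
                         "brand": f"{len(brand)} (100.0)",
                         "generic": f"{len(generic)} (100.0)",
                         "p_value": np.nan, "note": "single level; test skipped"})
            continue
        table = pd.crosstab(col, cohort["group"])
        chi2 = stats.chi2_contingency(table.to_numpy(), correction=False)
        for lev in levels:
            nb = int((brand[name].astype(str) == lev).sum())
            ng = int((generic[name].astype(str) == lev).sum())
            rows.append({
                "covariate": name, "level": lev,
                "brand": f"{nb} ({percent(nb, len(brand))})",
                "generic": f"{ng} ({percent(ng, len(generic))})",
                "p_value": chi2.pvalue, "note": "chi2"})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _stage(name: str):
    def deco(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (models.DegenerateOutcomeError, PipelineStageError):
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return inner
    return deco


def load_tables(config: RunConfig) -> dict[str, pd.DataFrame]:
    if config.simulate is not None:
        params = config.simulate
        if config.seed is not None:
            params = params.model_copy(update={"seed": config.seed})
        sim = simulate(params)
        disp = sim.dispensing.copy()
        hosp = sim.hospitalizations.copy()
        deaths = sim.deaths.copy()
        pats = sim.patients.copy()
        for frame, cols in [(disp, ["date"]), (pats, ["birth_date"]),
                            (hosp, ["admission_date", "discharge_date"]),
                            (deaths, ["death_date"])]:
            for c in cols:
                frame[c] = pd.to_datetime(frame[c])
        return {"patients": pats, "dispensing": disp,
                "hospitalizations": hosp, "deaths": deaths,
                "ground_truth": sim.ground_truth}
    return cohort_mod.read_claims_tables(config.input_dir)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run generate/load -> cohort -> adherence -> weights -> effect models."""
    logging.basicConfig(level=config.log_level)
    tables = _stage("load")(load_tables)(config)

    cohort, attrition, details = _stage("cohort")(cohort_mod.build_cohort)(
        tables, config.cohort)
    groups = cohort.set_index("patient_id")["group"]

    episodes = _stage("adherence")(adherence.build_episodes)(
        cohort, tables["dispensing"], tables["hospitalizations"], tables["deaths"],
        config.cohort.followup_days, config.gap_multiplier, config.anchor)
    ep_frame = adherence.episodes_frame(episodes, groups)
    persistence = adherence.persistence_summary(ep_frame, config.cohort.followup_days)
    cma_table = adherence.compute_cma_table(episodes, config.cma_threshold, groups)
    implementation = adherence.classify_implementation(cma_table, config.cma_threshold)

    weighted, n_dropped, _ = _stage("weights")(weights_mod.compute_weights)(cohort)
    balance = weights_mod.balance_report(weighted, weighted["sw"].to_numpy())

    estimates: dict = {"n_excluded_missing_specialty": n_dropped}
    sw = weighted.set_index("patient_id")["sw"]
    surv = ep_frame.copy()
    surv["time"] = surv["end_day"].astype(float)
    surv["event"] = np.select(
        [surv["status"] == "discontinued", surv["status"] == "died"], [1, 2], 0)
    surv["sw"] = surv["patient_id"].map(sw)
    surv = surv.dropna(subset=["sw"])
    surv["group"] = (surv["group"] == "brand").astype(int)
    try:
        hr = _stage("fine_gray")(models.fit_fine_gray)(surv)
        hr.n_excluded = n_dropped
        estimates["hr_discontinuation"] = hr.as_dict()
    except models.DegenerateOutcomeError as exc:
        estimates["hr_discontinuation"] = {"error": str(exc)}

    impl = cma_table.copy()
    if len(impl):
        impl["sw"] = impl["patient_id"].map(sw)
        impl = impl.dropna(subset=["sw"])
        impl["group"] = (impl["group"] == "brand").astype(int)
        impl["good"] = impl["good"].astype(int)
    try:
        if not len(impl):
            raise models.DegenerateOutcomeError("no CMA7-eligible patients")
        rr = _stage("log_binomial")(models.fit_log_binomial)(impl)
        rr.n_excluded = n_dropped
        estimates["rr_good_implementation"] = rr.as_dict()
    except models.DegenerateOutcomeError as exc:
        estimates["rr_good_implementation"] = {"error": str(exc)}

    baseline = describe_baseline(cohort)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": (config.seed if config.seed is not None
                 else (config.simulate.seed if config.simulate else None)),
        "n_analysis": len(cohort),
        "attrition": attrition.as_dict(),
    }
    result = PipelineResult(cohort=cohort, attrition=attrition, details=details,
                            episode_frame=ep_frame, persistence=persistence,
                            cma_table=cma_table, implementation=implementation,
                            weighted=weighted, balance=balance, baseline=baseline,
                            estimates=estimates, manifest=manifest, tables=tables)
    if config.output_dir is not None:
        write_bundle(result, config)
    return result


def write_bundle(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.attrition.to_frame().to_csv(out / "attrition.csv", index=False)
    (out / "attrition.json").write_text(
        json.dumps(result.attrition.as_dict(), indent=1, sort_keys=True))
    result.baseline.to_csv(out / "baseline.csv", index=False)
    result.episode_frame.to_csv(out / "episodes.csv", index=False)
    result.persistence.to_csv(out / "persistence.csv", index=False)
    result.cma_table.to_csv(out / "cma.csv", index=False)
    result.implementation.to_csv(out / "implementation.csv", index=False)
    result.weighted[["patient_id", "propensity", "sw", "group"]].to_csv(
        out / "weights.csv", index=False)
    result.balance.to_csv(out / "balance.csv", index=False)
    (out / "estimates.json").write_text(
        json.dumps(result.estimates, indent=1, sort_keys=True))
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=1, sort_keys=True))
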