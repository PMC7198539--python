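"""New-user cohort construction from dispensing claims.

Identifies incident users of the study drugs (24-month washout by default),
applies the primary-osteoporosis exclusion filters (long-term corticosteroid
use, hospitalizations with configured ICD-10 diagnosis patterns in the
lookback window), assigns the treatment group from the first qualifying
dispensation, removes switchers during follow-up, and keeps an attrition
record of every filter.

ICD pattern matching is prefix-based on dot-stripped codes ("S720" matches
"S72.00"), since claims extracts vary in dot usage. Month-denominated
windows are converted to days as months x 30.4375 rounded down.
"""

from __future__ import annotations

import datetime as dt
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .synthetic import ConfigurationError

logger = logging.getLogger(__name__)

#: ICD-10 diagnosis prefixes marking probable secondary osteoporosis or
#: contraindication: bone/cartilage neoplasms (C79.5), hypercortisolism (E24),
#: multiple myeloma (C90.0), Paget's disease (M88), upper-GI adverse events
#: (K20-K21, K22.1-3/6/8, K25-K28, K29.0/7-9, K30, K92.0-2), hyperthyroidism /
#: thyroiditis / hyperparathyroidism excluding E21.4-5 (E05, E06, E21.0-3).
DEFAULT_EXCLUSION_ICD = [
    "C795", "E24", "C900", "M88",
    "K20", "K21", "K221", "K222", "K223", "K226", "K228",
    "K25", "K26", "K27", "K28", "K290", "K297", "K298", "K299",
    "K30", "K920", "K921", "K922",
    "E05", "E06", "E210", "E211", "E212", "E213",
]

#: osteoporotic fracture sites: hip, vertebral, humerus, forearm, tibia, fibula
DEFAULT_FRACTURE_ICD = [
    "S720", "S721", "S722",
    "S220", "S221", "S320", "S327",
    "S422", "S525", "S526", "S821", "S824",
]

DEFAULT_STUDY_MOLECULES = ["alendronic", "risedronic", "ibandronic", "etidronic"]
DEFAULT_CORTICOSTEROIDS = ["prednisone", "prednisolone", "methylprednisolone"]

DAYS_PER_MONTH = 30.4375


def months_to_days(months: float) -> int:
    return math.floor(months * DAYS_PER_MONTH)


class CohortConfig(BaseModel):
    """Selection rules for the new-user cohort."""

    min_age: int = Field(default=50, ge=0)
    washout_months: int = Field(default=24, gt=0)
    study_start: dt.date = dt.date(2009, 1, 1)
    study_end: dt.date = dt.date(2015, 12, 31)
    followup_days: int = Field(default=365, gt=0)
    lookback_months: int = Field(default=24, gt=0)
    corticosteroid_threshold: int = Field(default=3, ge=1)
    exclusion_icd_codes: list[str] = Field(default_factory=lambda: list(DEFAULT_EXCLUSION_ICD))
    fracture_icd_codes: list[str] = Field(default_factory=lambda: list(DEFAULT_FRACTURE_ICD))
    study_molecules: list[str] = Field(default_factory=lambda: list(DEFAULT_STUDY_MOLECULES))
    corticosteroid_molecules: list[str] = Field(default_factory=lambda: list(DEFAULT_CORTICOSTEROIDS))
    combination_markers: list[str] = Field(default_factory=lambda: ["vitd", "vitamin"])

    @property
    def washout_days(self) -> int:
        return months_to_days(self.washout_months)

    @property
    def lookback_days(self) -> int:
        return months_to_days(self.lookback_months)


class ClaimsParseError(ValueError):
    """A claims row could not be parsed; the message carries the line number."""


@dataclass
class AttritionRecord:
    """Ordered (filter name, n remaining) counts; n must never increase."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def add(self, name: str, n_remaining: int) -> None:
        if self.steps and n_remaining > self.steps[-1][1]:
            raise ValueError(
                f"attrition must be non-increasing: {name}={n_remaining} after "
                f"{self.steps[-1][0]}={self.steps[-1][1]}")
        self.steps.append((name, int(n_remaining)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps, columns=["filter", "n_remaining"])

    def as_dict(self) -> dict[str, int]:
        return dict(self.steps)


# ---------------------------------------------------------------------------
# Parsing helpers
# ---------------------------------------------------------------------------

def parse_date_column(frame: pd.DataFrame, column: str, *, table: str) -> pd.Series:
    """Parse an ISO-8601 date column; malformed rows raise with line numbers."""
    raw = frame[column]
    parsed = pd.to_datetime(raw, format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        lines = [int(i) + 2 for i in frame.index[bad][:5]]  # +2: header + 1-based
        raise ClaimsParseError(
            f"{table}: unparseable {column} value(s) at line(s) {lines} "
            f"(first bad value: {raw[bad].iloc[0]!r})")
    return parsed


def read_claims_tables(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read the four delimited claims tables and parse their date columns."""
    directory = Path(directory)
    tables = {}
    for name, date_cols in [("patients", ["birth_date"]),
                            ("dispensing", ["date"]),
                            ("hospitalizations", ["admission_date", "discharge_date"]),
                            ("deaths", ["death_date"])]:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing input file: {path}")
        frame = pd.read_csv(path)
        for col in date_cols:
            frame[col] = parse_date_column(frame, col, table=name)
        tables[name] = frame
    return tables


def _strip_dots(codes: Iterable[str]) -> list[str]:
    out = []
    for c in codes:
        c = str(c).replace(".", "").strip().upper()
        if not c or not c[0].isalpha() or not c[1:].isalnum():
            raise ConfigurationError(f"ICD pattern {c!r}: expected letter + alphanumerics")
        out.append(c)
    return out


def icd_prefix_match(codes: pd.Series, patterns: Iterable[str]) -> pd.Series:
    """Prefix match on dot-stripped upper-cased ICD codes."""
    pats = tuple(_strip_dots(patterns))
    cleaned = codes.astype(str).str.replace(".", "", regex=False).str.upper()
    if not pats:
        return pd.Series(False, index=codes.index)
    return cleaned.str.startswith(pats)


# ---------------------------------------------------------------------------
# Cohort operations
# ---------------------------------------------------------------------------

def _study_drug_mask(dispensing: pd.DataFrame, config: CohortConfig) -> pd.Series:
    mol = dispensing["molecule"].astype(str).str.lower()
    is_study = pd.Series(False, index=dispensing.index)
    for m in config.study_molecules:
        is_study |= mol.str.contains(m.lower(), regex=False)
    return is_study


def _is_combination(molecule: pd.Series, config: CohortConfig) -> pd.Series:
    mol = molecule.astype(str).str.lower()
    combo = pd.Series(False, index=molecule.index)
    for marker in config.combination_markers:
        combo |= mol.str.contains(marker.lower(), regex=False)
    return combo


def identify_new_users(dispensing: pd.DataFrame, patients: pd.DataFrame,
                       config: CohortConfig) -> tuple[pd.DataFrame, AttritionRecord]:
    """Find each patient's first qualifying dispensation (index event).

    A dispensation qualifies when it falls inside the study window and no
    study-drug dispensation (including vitamin-D combinations) occurred in
    the preceding washout. Patients whose qualifying product is a
    combination, or who are younger than ``min_age`` at index, are excluded.
    """
    attrition = AttritionRecord()
    attrition.add("patients_in_claims", dispensing["patient_id"].nunique())

    study = dispensing[_study_drug_mask(dispensing, config)].copy()
    study = study.sort_values(["patient_id", "date", "molecule", "brand"],
                              kind="mergesort").reset_index(drop=True)
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)

    in_window = (study["date"] >= start) & (study["date"] <= end)
    attrition.add("study_drug_in_window", study.loc[in_window, "patient_id"].nunique())

    # most recent strictly-earlier study-drug date per row (same-day rows are
    # not prior use; the design takes the first record of the sorted day)
    dedup = study[["patient_id", "date"]].drop_duplicates()
    dedup["prev_date"] = dedup.groupby("patient_id")["date"].shift()
    study = study.merge(dedup, on=["patient_id", "date"], how="left")
    washout_ok = study["prev_date"].isna() | (
        (study["date"] - study["prev_date"]).dt.days >= config.washout_days)

    cand = study[in_window.to_numpy() & washout_ok.to_numpy()]
    cand = cand.groupby("patient_id", sort=True).head(1)  # first qualifying event
    attrition.add("new_users_washout_ok", len(cand))

    cand = cand[~_is_combination(cand["molecule"], config)]
    attrition.add("non_combination_product", len(cand))

    birth = patients.set_index("patient_id")["birth_date"]
    bdates = cand["patient_id"].map(birth)
    age = np.floor((cand["date"] - bdates).dt.days / 365.25)
    cand = cand[age.notna() & (age >= config.min_age)]
    age = age[age.notna() & (age >= config.min_age)]

    index_events = pd.DataFrame({
        "patient_id": cand["patient_id"].to_numpy(),
        "index_date": cand["date"].to_numpy(),
        "molecule": cand["molecule"].to_numpy(),
        "group": np.where(cand["brand"].astype(int) == 1, "brand", "generic"),
        "frequency": (cand["frequency"].to_numpy()
                      if "frequency" in cand else None),
        "specialty": (cand["prescriber_specialty"].to_numpy()
                      if "prescriber_specialty" in cand else None),
        "age": age.astype(int).to_numpy(),
    })
    attrition.add("age_at_least_min", len(index_events))
    return index_events, attrition


def apply_exclusions(candidates: pd.DataFrame, dispensing: pd.DataFrame,
                     hospitalizations: pd.DataFrame, config: CohortConfig,
                     attrition: AttritionRecord | None = None,
                     ) -> tuple[pd.DataFrame, AttritionRecord, dict[str, int]]:
    """Remove long-term corticosteroid users and patients hospitalized for a
    configured exclusion diagnosis in the lookback window before index."""
    if attrition is None:
        attrition = AttritionRecord()
        attrition.add("candidates", len(candidates))
    lookback = pd.Timedelta(days=config.lookback_days)

    cortico_mol = [m.lower() for m in config.corticosteroid_molecules]
    disp = dispensing.merge(candidates[["patient_id", "index_date"]], on="patient_id")
    is_cortico = disp["molecule"].astype(str).str.lower().isin(cortico_mol)
    in_lb = (disp["date"] >= disp["index_date"] - lookback) & \
            (disp["date"] < disp["index_date"])
    counts = disp.loc[is_cortico & in_lb].groupby("patient_id").size()
    cortico_excluded = set(counts[counts >= config.corticosteroid_threshold].index)

    hosp = hospitalizations.merge(candidates[["patient_id", "index_date"]],
                                  on="patient_id")
    if len(hosp):
        match = icd_prefix_match(hosp["icd_code"], config.exclusion_icd_codes)
        in_lb_h = (hosp["admission_date"] >= hosp["index_date"] - lookback) & \
                  (hosp["admission_date"] < hosp["index_date"])
        icd_excluded = set(hosp.loc[match & in_lb_h, "patient_id"])
    else:
        icd_excluded = set()

    removed = {
        "corticosteroid_long_term": len(cortico_excluded),
        "exclusion_diagnosis": len(icd_excluded),
    }
    keep = ~candidates["patient_id"].isin(cortico_excluded | icd_excluded)
    filtered = candidates[keep].reset_index(drop=True)
    attrition.add("no_long_term_corticosteroids",
                  len(candidates) - len(cortico_excluded))
    attrition.add("no_exclusion_diagnosis", len(filtered))
    return filtered, attrition, removed


def detect_switchers(index_events: pd.DataFrame, dispensing: pd.DataFrame,
                     followup_days: int = 365,
                     config: CohortConfig | None = None,
                     ) -> tuple[pd.DataFrame, dict[str, dict[str, int]]]:
    """Remove patients who switch brand<->generic within the same molecule or
    change molecule during follow-up; counts are returned per group and kind.

    A patient with no post-index dispensations is retained: non-persistence
    is not switching.
    """
    config = config or CohortConfig()
    study = dispensing[_study_drug_mask(dispensing, config)]
    merged = study.merge(
        index_events[["patient_id", "index_date", "molecule", "group"]],
        on="patient_id", suffixes=("", "_index"))
    post = merged[(merged["date"] > merged["index_date"]) &
                  (merged["date"] <= merged["index_date"]
                   + pd.Timedelta(days=followup_days))].copy()
    post = post.sort_values(["patient_id", "date"], kind="mergesort")

    index_flag = index_events.set_index("patient_id")["group"].map(
        {"brand": 1, "generic": 0})
    post["index_brand"] = post["patient_id"].map(index_flag)
    same_mol = post["molecule"] == post["molecule_index"]
    flag_flip = post["brand"].astype(int) != post["index_brand"].astype(int)
    post["kind"] = np.select(
        [same_mol & flag_flip, ~same_mol],
        ["brand_generic", "molecule"], default="none")
    switch_events = post[post["kind"] != "none"]
    first_kind = switch_events.groupby("patient_id")["kind"].first()

    counts: dict[str, dict[str, int]] = {}
    for grp in ["brand", "generic"]:
        ids = set(index_events.loc[index_events["group"] == grp, "patient_id"])
        kinds = first_kind[first_kind.index.isin(ids)]
        counts[grp] = {
            "brand_generic": int((kinds == "brand_generic").sum()),
            "molecule": int((kinds == "molecule").sum()),
        }
    analysis = index_events[~index_events["patient_id"].isin(first_kind.index)]
    return analysis.reset_index(drop=True), counts


def fracture_history(index_events: pd.DataFrame,
                     hospitalizations: pd.DataFrame,
                     config: CohortConfig) -> pd.Series:
    """Per-patient flag: any hospitalization with an osteoporotic-fracture
    diagnosis in the lookback window before the index date."""
    out = pd.Series(False, index=index_events["patient_id"],
                    name="fracture_history")
    if not len(hospitalizations):
        return out
    hosp = hospitalizations.merge(index_events[["patient_id", "index_date"]],
                                  on="patient_id")
    if not len(hosp):
        return out
    lookback = pd.Timedelta(days=config.lookback_days)
    match = icd_prefix_match(hosp["icd_code"], config.fracture_icd_codes)
    in_lb = (hosp["admission_date"] >= hosp["index_date"] - lookback) & \
            (hosp["admission_date"] < hosp["index_date"])
    with_fx = hosp.loc[match & in_lb, "patient_id"].unique()
    out[out.index.isin(with_fx)] = True
    return out


def build_cohort(tables: dict[str, pd.DataFrame], config: CohortConfig | None = None,
                 ) -> tuple[pd.DataFrame, AttritionRecord, dict]:
    """Run the full selection: new users -> exclusions -> switchers.

    Returns the analysis cohort (one row per patient with index event,
    covariates, and fracture history), the attrition record, and a detail
    dict with per-rule removal counts.
    """
    config = config or CohortConfig()
    dispensing = tables["dispensing"]
    patients = tables["patients"]
    hospitalizations = tables["hospitalizations"]

    index_events, attrition = identify_new_users(dispensing, patients, config)
    filtered, attrition, removed = apply_exclusions(
        index_events, dispensing, hospitalizations, config, attrition)
    analysis, switch_counts = detect_switchers(
        filtered, dispensing, config.followup_days, config)
    attrition.add("no_switch_in_followup", len(analysis))

    fx = fracture_history(analysis, hospitalizations, config)
    cohort = analysis.merge(patients, on="patient_id", how="left")
    cohort["fracture_history"] = cohort["patient_id"].map(fx).astype(int)
    cohort["year"] = cohort["index_date"].dt.year
    details = {"exclusions": removed, "switchers": switch_counts}

    # invariant: the group label always equals the index dispensation's flag
    assert set(cohort["group"]) <= {"brand", "generic"}
    return cohort, attrition, details
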