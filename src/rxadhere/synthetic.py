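"""Synthetic dispensing-claims generator.

Emulates the longitudinal structure of a national claims extract for a
new-user cohort of oral bisphosphonate initiators: per-patient dispensing
trajectories with 1- or 3-month package supplies, group-dependent
discontinuation hazards, refill-delay jitter, hospitalizations that may
overlap refill gaps, deaths, and the baseline covariates used by the
propensity model (age, sex, ALD, CMU, polypharmacy, fracture history,
Charlson class, year of initiation, administration frequency, prescriber
specialty).

The generator works on integer day offsets from each patient's index date
and emits ISO-8601 dates by adding the offset to the index date; this
avoids any month-length ambiguity. Discontinuation is generated per refill
cycle (geometric), matching the refill-event granularity that the
persistence rule observes downstream.

Ground truth (latent group, planned discontinuation cycle, death day,
implementation class) is exported for parameter-recovery tests.
"""

from __future__ import annotations

import datetime as dt
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.optimize import brentq
from scipy.special import expit, logit


class ConfigurationError(ValueError):
    """A simulation or pipeline parameter is invalid; the message names the field."""


# ---------------------------------------------------------------------------
# Covariate marginals of the emulated source population
# ---------------------------------------------------------------------------

YEARS = list(range(2009, 2016))
# initiations per calendar year in the emulated source population
YEAR_PROBS = np.array([1254, 1095, 1111, 880, 767, 788, 717], dtype=float)
YEAR_PROBS /= YEAR_PROBS.sum()

FREQUENCIES = ["daily", "weekly", "monthly"]
FREQ_PROBS = np.array([0.02, 0.60, 0.38])

SPECIALTIES = ["general", "specialist", "hospital", "unknown"]
SPECIALTY_PROBS = np.array([0.658, 0.180, 0.157, 0.005])

CHARLSON_CLASSES = ["0", "1-2", "3+"]
CHARLSON_PROBS = np.array([0.661, 0.334, 0.005])

P_FEMALE = 0.893
P_ALD = 0.42
P_CMU = 0.025
P_POLYPHARMACY = 0.70
P_FRACTURE_HISTORY = 0.055
AGE_MEAN, AGE_SD = 70.5, 10.5

MOLECULES_BRAND = (["risedronic", "ibandronic", "alendronic", "etidronic"],
                   np.array([0.535, 0.369, 0.089, 0.007]))
MOLECULES_GENERIC = (["alendronic", "risedronic", "etidronic"],
                     np.array([0.472, 0.523, 0.005]))

FRACTURE_EMIT_CODES = ["S720", "S721", "S220", "S320", "S525", "S821"]
EXCLUSION_EMIT_CODES = ["C900", "M88", "E24", "K250"]
BENIGN_CODES = ["I10", "J18", "N39", "Z501"]

#: features accepted in ``covariate_effects`` (log-odds on brand assignment)
EFFECT_FEATURES = (
    "sex_female", "age_centered", "ald", "cmu", "polypharmacy",
    "fracture_history", "charlson_1_2", "charlson_3p", "year_centered",
    "frequency_weekly", "frequency_monthly",
    "specialty_specialist", "specialty_hospital",
)


class DistributionSpec(BaseModel):
    """Nonnegative-integer distribution spec: constant, uniform_int or shifted Poisson."""

    family: Literal["constant", "uniform_int", "poisson"]
    value: int = 0
    low: int = 0
    high: int = 0
    lam: float = 1.0
    shift: int = 0

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        if self.family == "uniform_int" and self.low > self.high:
            raise ValueError("uniform_int requires low <= high")
        if self.family == "poisson" and self.lam < 0:
            raise ValueError("poisson requires lam >= 0")
        return self

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "constant":
            return np.full(size, self.value, dtype=int)
        if self.family == "uniform_int":
            return rng.integers(self.low, self.high + 1, size=size)
        return rng.poisson(self.lam, size=size) + self.shift

    def minimum(self) -> int:
        if self.family == "constant":
            return self.value
        if self.family == "uniform_int":
            return self.low
        return self.shift


class SimulationParams(BaseModel):
    """Parameters of the claims data-generating process.

    Defaults describe the study conditions the analysis assumes: ~56% brand
    share, per-cycle discontinuation hazards giving ~29%/31% 12-month
    persistence, a 25% share of 3-month packages, late-skewed refill jitter,
    0.2 hospitalizations per patient-year, and a 0.4% annual death rate.
    """

    n_patients: int = Field(ge=1)
    brand_share: float = Field(default=0.56, gt=0.0, lt=1.0)
    covariate_effects: dict[str, float] = Field(default_factory=lambda: {
        "year_centered": -0.55,
        "frequency_monthly": 1.8,
        "frequency_weekly": 0.3,
        "fracture_history": -0.5,
        "sex_female": 0.25,
        "age_centered": -0.05,
        "specialty_specialist": 0.5,
        "specialty_hospital": -0.6,
    })
    discontinuation_hazard_brand: float = Field(default=0.165, ge=0.0, le=1.0)
    discontinuation_hazard_generic: float = Field(default=0.14, ge=0.0, le=1.0)
    refill_delay_distribution: DistributionSpec = Field(
        default_factory=lambda: DistributionSpec(family="uniform_int", low=-3, high=14))
    package_mix: float = Field(default=0.25, ge=0.0, le=1.0)  # P(3-month package)
    hosp_rate: float = Field(default=0.2, ge=0.0)  # hospitalizations / patient-year
    hosp_duration_days: DistributionSpec = Field(
        default_factory=lambda: DistributionSpec(family="poisson", lam=6.0, shift=1))
    death_rate: float = Field(default=0.004, ge=0.0, le=1.0)  # annual probability
    good_implementation_rr: Optional[float] = Field(default=0.9, gt=0.0)
    p_good_generic: float = Field(default=0.78, gt=0.0, lt=1.0)
    switch_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    prior_use_rate: float = Field(default=0.02, ge=0.0, le=1.0)
    cortico_rate: float = Field(default=0.015, ge=0.0, le=0.4)
    exclusion_hosp_rate: float = Field(default=0.005, ge=0.0, le=1.0)
    underage_rate: float = Field(default=0.01, ge=0.0, le=1.0)
    followup_days: int = Field(default=365, ge=1)
    seed: int = 0

    @field_validator("covariate_effects")
    @classmethod
    def _known_features(cls, v: dict[str, float]) -> dict[str, float]:
        for key in v:
            if key not in EFFECT_FEATURES:
                raise ValueError(
                    f"covariate_effects: unknown feature {key!r}; "
                    f"known features are {EFFECT_FEATURES}")
        return v

    @model_validator(mode="after")
    def _check_distributions(self) -> "SimulationParams":
        if self.hosp_duration_days.minimum() < 1:
            raise ConfigurationError(
                "hosp_duration_days: distribution must yield positive durations")
        if self.good_implementation_rr is not None:
            if self.good_implementation_rr * self.p_good_generic >= 1.0:
                raise ConfigurationError(
                    "good_implementation_rr: rr * p_good_generic must be < 1")
        return self


# ---------------------------------------------------------------------------
# Patients
# ---------------------------------------------------------------------------

def _design_features(df: pd.DataFrame) -> pd.DataFrame:
    """Map raw covariates to the features covariate_effects refers to."""
    feats = pd.DataFrame(index=df.index)
    feats["sex_female"] = (df["sex"] == "F").astype(float)
    feats["age_centered"] = (df["age"] - AGE_MEAN) / 10.0
    feats["ald"] = df["ald"].astype(float)
    feats["cmu"] = df["cmu"].astype(float)
    feats["polypharmacy"] = df["polypharmacy"].astype(float)
    feats["fracture_history"] = df["fracture_history"].astype(float)
    feats["charlson_1_2"] = (df["charlson_class"] == "1-2").astype(float)
    feats["charlson_3p"] = (df["charlson_class"] == "3+").astype(float)
    feats["year_centered"] = df["year"] - 2012.0
    feats["frequency_weekly"] = (df["frequency"] == "weekly").astype(float)
    feats["frequency_monthly"] = (df["frequency"] == "monthly").astype(float)
    feats["specialty_specialist"] = (df["specialty"] == "specialist").astype(float)
    feats["specialty_hospital"] = (df["specialty"] == "hospital").astype(float)
    return feats


def generate_patients(params: SimulationParams) -> pd.DataFrame:
    """Draw baseline covariates and latent assignments for every patient.

    Returns one row per patient with both the observable covariates and the
    latent columns (``group``, ``planned_cycles``, ``death_day``,
    ``good_class`` ...) that drive dispensing generation; :func:`simulate`
    strips the latent columns before writing the public patients table.

    Group is assigned by a logistic model on the covariates, with the
    intercept calibrated so that the marginal brand probability equals
    ``brand_share`` exactly on the drawn covariates, making confounding real
    while keeping the marginal share a known truth.
    """
    rng = np.random.default_rng([params.seed, 101])
    n = params.n_patients

    df = pd.DataFrame({"patient_id": [f"P{i:07d}" for i in range(n)]})
    df["sex"] = np.where(rng.random(n) < P_FEMALE, "F", "M")
    age = np.clip(rng.normal(AGE_MEAN, AGE_SD, n), 50.0, 99.0)
    under = rng.random(n) < params.underage_rate
    age[under] = rng.integers(46, 50, under.sum())
    df["age"] = np.round(age, 1)
    df["ald"] = (rng.random(n) < P_ALD).astype(int)
    df["cmu"] = (rng.random(n) < P_CMU).astype(int)
    df["polypharmacy"] = (rng.random(n) < P_POLYPHARMACY).astype(int)
    df["fracture_history"] = (rng.random(n) < P_FRACTURE_HISTORY).astype(int)
    df["charlson_class"] = rng.choice(CHARLSON_CLASSES, size=n, p=CHARLSON_PROBS)
    df["year"] = rng.choice(YEARS, size=n, p=YEAR_PROBS)
    df["frequency"] = rng.choice(FREQUENCIES, size=n, p=FREQ_PROBS)
    df["specialty"] = rng.choice(SPECIALTIES, size=n, p=SPECIALTY_PROBS)

    # treatment assignment: logistic on covariates, intercept calibrated so the
    # finite-sample mean assignment probability equals brand_share
    feats = _design_features(df)
    lp = np.zeros(n)
    for key, beta in params.covariate_effects.items():
        lp += beta * feats[key].to_numpy()
    lo, hi = logit(1e-6), logit(1 - 1e-6)

    def _gap(a: float) -> float:
        return float(expit(a + lp).mean()) - params.brand_share

    alpha = brentq(_gap, lo - lp.max(), hi - lp.min(), xtol=1e-12)
    df["group"] = np.where(rng.random(n) < expit(alpha + lp), "brand", "generic")

    haz = np.where(df["group"] == "brand",
                   params.discontinuation_hazard_brand,
                   params.discontinuation_hazard_generic)
    # zero hazard = never stop within follow-up (cycle cap far beyond one year)
    cycles = np.full(n, np.iinfo(np.int32).max, dtype=np.int64)
    pos = haz > 0
    if pos.any():
        cycles[pos] = rng.geometric(haz[pos])
    df["planned_cycles"] = cycles

    dies = rng.random(n) < params.death_rate * params.followup_days / 365.0
    death_day = np.where(dies, rng.integers(1, params.followup_days + 1, n), -1)
    df["death_day"] = death_day  # -1 = no death within follow-up

    if params.good_implementation_rr is None:
        df["good_class"] = -1  # not controlled; delays come from the shared spec
    else:
        p_good = np.where(df["group"] == "generic", params.p_good_generic,
                          params.p_good_generic * params.good_implementation_rr)
        df["good_class"] = (rng.random(n) < p_good).astype(int)

    # index date: day within the drawn initiation year
    day_in_year = rng.integers(0, 365, n)
    df["index_date"] = [dt.date(y, 1, 1) + dt.timedelta(days=int(d))
                        for y, d in zip(df["year"], day_in_year)]
    df["birth_date"] = [idx - dt.timedelta(days=int(round(a * 365.25)) + 100)
                        for idx, a in zip(df["index_date"], df["age"])]

    molecules = np.empty(n, dtype=object)
    for grp, (mols, probs) in (("brand", MOLECULES_BRAND),
                               ("generic", MOLECULES_GENERIC)):
        mask = (df["group"] == grp).to_numpy()
        molecules[mask] = rng.choice(mols, size=int(mask.sum()), p=probs)
    df["molecule"] = molecules

    # realism flags exercising the cohort filters
    u = rng.random(n)
    df["prior_use"] = (u < params.prior_use_rate).astype(int)
    v = rng.random(n)
    df["cortico_count"] = np.select(
        [v < params.cortico_rate, v < 2 * params.cortico_rate],
        [3 + rng.poisson(1.0, n), 1 + (rng.random(n) < 0.5)], default=0)
    df["exclusion_hosp"] = (rng.random(n) < params.exclusion_hosp_rate).astype(int)
    if params.switch_rate > 0:
        w = rng.random(n)
        df["switch_kind"] = np.select(
            [w < params.switch_rate / 2, w < params.switch_rate],
            ["brand_generic", "molecule"], default="none")
    else:
        df["switch_kind"] = "none"
    return df


# ---------------------------------------------------------------------------
# Dispensing trajectories
# ---------------------------------------------------------------------------

def _draw_delay(rng: np.random.Generator, params: SimulationParams,
                good_class: int, prev_supply: int) -> int:
    if good_class < 0:
        return int(params.refill_delay_distribution.draw(rng, 1)[0])
    if good_class == 1:
        return int(rng.integers(-3, 1))  # on time or early -> full coverage
    # poor implementer: late by >= 28% of the previous supply, which keeps
    # CMA7 < 0.9 for every eligible window while staying inside the 2x-supply
    # persistence allowance
    return math.ceil(0.28 * prev_supply) + int(rng.integers(0, 7))


def generate_dispensing(params: SimulationParams,
                        patients: pd.DataFrame) -> pd.DataFrame:
    """Emit per-patient dispensing events.

    The index dispensation sits at day 0 of the patient's follow-up clock;
    refills follow at supply-duration + jitter intervals until the latent
    discontinuation cycle, death, or the end of follow-up. Package size is
    drawn per event from ``package_mix``. Pre-index rows (prior study-drug
    use, corticosteroid reimbursements) exercise the cohort filters.
    """
    rng = np.random.default_rng([params.seed, 202])
    fup = params.followup_days
    rows: list[tuple] = []

    for pat in patients.itertuples(index=False):
        death = pat.death_day if pat.death_day >= 0 else None
        brand_flag = 1 if pat.group == "brand" else 0
        day = 0
        months = 3 if rng.random() < params.package_mix else 1
        days_supplies = [(0, months)]
        for _ in range(int(pat.planned_cycles) - 1):
            prev_supply = 30 * days_supplies[-1][1]
            delay = _draw_delay(rng, params, int(pat.good_class), prev_supply)
            day = day + max(1, prev_supply + delay)
            if day >= fup or (death is not None and day >= death):
                break
            months = 3 if rng.random() < params.package_mix else 1
            days_supplies.append((day, months))

        molecule = pat.molecule
        flags = [brand_flag] * len(days_supplies)
        mols = [molecule] * len(days_supplies)
        if pat.switch_kind != "none":
            if len(days_supplies) == 1:  # force a second event carrying the switch
                extra = days_supplies[0][1] * 30 + int(rng.integers(1, 11))
                if extra < fup and (death is None or extra < death):
                    months = 3 if rng.random() < params.package_mix else 1
                    days_supplies.append((extra, months))
                    flags.append(brand_flag)
                    mols.append(molecule)
            if len(days_supplies) > 1:
                pos = int(rng.integers(1, len(days_supplies)))
                for k in range(pos, len(days_supplies)):
                    if pat.switch_kind == "brand_generic":
                        flags[k] = 1 - brand_flag
                    else:
                        alt = "alendronic" if molecule != "alendronic" else "risedronic"
                        mols[k] = alt

        for (d, months), fl, mol in zip(days_supplies, flags, mols):
            rows.append((pat.patient_id,
                         pat.index_date + dt.timedelta(days=int(d)),
                         mol, fl, months, pat.frequency, pat.specialty))

        if pat.prior_use:
            back = int(rng.integers(60, 701))
            rows.append((pat.patient_id,
                         pat.index_date - dt.timedelta(days=back),
                         molecule, brand_flag,
                         3 if rng.random() < params.package_mix else 1,
                         pat.frequency, pat.specialty))
        for _ in range(int(pat.cortico_count)):
            back = int(rng.integers(10, 721))
            rows.append((pat.patient_id,
                         pat.index_date - dt.timedelta(days=back),
                         "prednisone", 0, 1, pat.frequency, pat.specialty))

    out = pd.DataFrame(rows, columns=[
        "patient_id", "date", "molecule", "brand", "package_months",
        "frequency", "prescriber_specialty"])
    return out.sort_values(
        ["patient_id", "date", "molecule", "brand"], kind="mergesort",
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Hospitalizations and deaths
# ---------------------------------------------------------------------------

def generate_hospitalizations(params: SimulationParams,
                              patients: pd.DataFrame) -> pd.DataFrame:
    """Emit hospitalization intervals [admission, discharge].

    Post-index stays arrive at ~Poisson(hosp_rate x exposure) per patient and
    may overlap refill gaps; pre-index stays carry fracture-history or
    exclusion diagnoses where the patient's latent flags call for them.
    """
    rng = np.random.default_rng([params.seed, 303])
    fup = params.followup_days
    rows: list[tuple] = []

    for pat in patients.itertuples(index=False):
        death = pat.death_day if pat.death_day >= 0 else None
        exposure_end = min(fup, death) if death is not None else fup
        n_stays = rng.poisson(params.hosp_rate * exposure_end / 365.0)
        for _ in range(int(n_stays)):
            admit = int(rng.integers(0, max(1, exposure_end)))
            dur = int(params.hosp_duration_days.draw(rng, 1)[0])
            discharge = min(admit + dur, exposure_end)
            code = BENIGN_CODES[int(rng.integers(0, len(BENIGN_CODES)))]
            rows.append((pat.patient_id,
                         pat.index_date + dt.timedelta(days=admit),
                         pat.index_date + dt.timedelta(days=discharge),
                         code))
        if pat.fracture_history:
            back = int(rng.integers(10, 721))
            dur = int(params.hosp_duration_days.draw(rng, 1)[0])
            code = FRACTURE_EMIT_CODES[int(rng.integers(0, len(FRACTURE_EMIT_CODES)))]
            rows.append((pat.patient_id,
                         pat.index_date - dt.timedelta(days=back),
                         pat.index_date - dt.timedelta(days=max(0, back - dur)),
                         code))
        if pat.exclusion_hosp:
            back = int(rng.integers(10, 721))
            dur = int(params.hosp_duration_days.draw(rng, 1)[0])
            code = EXCLUSION_EMIT_CODES[int(rng.integers(0, len(EXCLUSION_EMIT_CODES)))]
            rows.append((pat.patient_id,
                         pat.index_date - dt.timedelta(days=back),
                         pat.index_date - dt.timedelta(days=max(0, back - dur)),
                         code))

    out = pd.DataFrame(rows, columns=[
        "patient_id", "admission_date", "discharge_date", "icd_code"])
    return out.sort_values(
        ["patient_id", "admission_date", "icd_code"], kind="mergesort",
    ).reset_index(drop=True)


def generate_deaths(params: SimulationParams, patients: pd.DataFrame) -> pd.DataFrame:
    dead = patients[patients["death_day"] >= 0]
    out = pd.DataFrame({
        "patient_id": dead["patient_id"].to_numpy(),
        "death_date": [idx + dt.timedelta(days=int(d))
                       for idx, d in zip(dead["index_date"], dead["death_day"])],
    })
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Ground truth + bundle
# ---------------------------------------------------------------------------

def export_ground_truth(params: SimulationParams, patients: pd.DataFrame,
                        path: str | Path | None = None) -> dict:
    """Machine-readable latent truth for parameter-recovery tests."""
    truth = {
        "params": json.loads(params.model_dump_json()),
        "true_brand_share": params.brand_share,
        "true_good_implementation_rr": params.good_implementation_rr,
        "discontinuation_hazard_brand": params.discontinuation_hazard_brand,
        "discontinuation_hazard_generic": params.discontinuation_hazard_generic,
        "true_subdistribution_effect_direction": (
            "brand_discontinues_faster"
            if params.discontinuation_hazard_brand > params.discontinuation_hazard_generic
            else "generic_discontinues_faster"
            if params.discontinuation_hazard_generic > params.discontinuation_hazard_brand
            else "null"),
        "patients": [
            {
                "patient_id": pat.patient_id,
                "group": pat.group,
                "planned_cycles": int(pat.planned_cycles),
                "death_day": int(pat.death_day) if pat.death_day >= 0 else None,
                "good_class": int(pat.good_class) if pat.good_class >= 0 else None,
                "index_date": pat.index_date.isoformat(),
                "fracture_history": int(pat.fracture_history),
            }
            for pat in patients.itertuples(index=False)
        ],
    }
    if path is not None:
        Path(path).write_text(json.dumps(truth, indent=1, sort_keys=True))
    return truth


def recovery_study_params(n_patients: int, seed: int, **overrides) -> SimulationParams:
    """Conditions for parameter-recovery (calibration) studies.

    All packages cover 1 month, hospitalizations and prior study-drug use are
    off. Under these conditions the latent implementation class determines
    the measured CMA7 class deterministically (a good implementer's worst
    persistent window is 335/365 = 0.918 covered; a poor implementer's best
    eligible window stays below 0.81), so recovery simulations measure the
    estimators rather than generator-side classification noise. Deaths stay
    on so the competing-risk machinery is exercised.
    """
    base = dict(n_patients=n_patients, seed=seed, package_mix=0.0,
                hosp_rate=0.0, prior_use_rate=0.0)
    base.update(overrides)
    return SimulationParams(**base)


PUBLIC_PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "ald", "cmu",
                          "polypharmacy", "charlson_class"]


@dataclass
class SimulatedClaims:
    """The four claims tables plus latent truth from one generator run."""

    params: SimulationParams
    patients: pd.DataFrame          # public columns only
    dispensing: pd.DataFrame
    hospitalizations: pd.DataFrame
    deaths: pd.DataFrame
    ground_truth: dict
    latent: pd.DataFrame            # full patient frame incl. latent columns


def simulate(params: SimulationParams,
             outdir: str | Path | None = None) -> SimulatedClaims:
    """Run the full generator; optionally write the claims CSVs + truth JSON."""
    latent = generate_patients(params)
    dispensing = generate_dispensing(params, latent)
    hospitalizations = generate_hospitalizations(params, latent)
    deaths = generate_deaths(params, latent)
    truth = export_ground_truth(params, latent)
    patients = latent[PUBLIC_PATIENT_COLUMNS].copy()

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        patients.to_csv(outdir / "patients.csv", index=False)
        dispensing.to_csv(outdir / "dispensing.csv", index=False)
        hospitalizations.to_csv(outdir / "hospitalizations.csv", index=False)
        deaths.to_csv(outdir / "deaths.csv", index=False)
        (outdir / "ground_truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True))
    return SimulatedClaims(params=params, patients=patients,
                           dispensing=dispensing,
                           hospitalizations=hospitalizations, deaths=deaths,
                           ground_truth=truth, latent=latent)
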