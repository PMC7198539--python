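"""Shared fixtures: hand-built claims tables and small simulated bundles."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

import rxadhere as rx

INDEX = pd.Timestamp("2012-06-01")


def disp(pid, date, molecule="alendronic", brand=1, months=1,
         frequency="weekly", specialty="general"):
    return {"patient_id": pid, "date": pd.Timestamp(date), "molecule": molecule,
            "brand": brand, "package_months": months, "frequency": frequency,
            "prescriber_specialty": specialty}


def hosp(pid, admit, discharge, icd="I10"):
    return {"patient_id": pid, "admission_date": pd.Timestamp(admit),
            "discharge_date": pd.Timestamp(discharge), "icd_code": icd}


def patient(pid, birth="1940-01-01", sex="F", ald=0, cmu=0, poly=1, charlson="0"):
    return {"patient_id": pid, "birth_date": pd.Timestamp(birth), "sex": sex,
            "ald": ald, "cmu": cmu, "polypharmacy": poly,
            "charlson_class": charlson}


def make_tables(dispensing_rows, patient_rows, hosp_rows=(), death_rows=()):
    return {
        "dispensing": pd.DataFrame(dispensing_rows),
        "patients": pd.DataFrame(patient_rows),
        "hospitalizations": pd.DataFrame(
            list(hosp_rows) or [],
            columns=["patient_id", "admission_date", "discharge_date", "icd_code"]),
        "deaths": pd.DataFrame(
            list(death_rows) or [], columns=["patient_id", "death_date"]),
    }


@pytest.fixture(scope="session")
def small_sim():
    """A small default-conditions simulated claims bundle."""
    return rx.simulate(rx.SimulationParams(n_patients=500, seed=20))


@pytest.fixture(scope="session")
def small_pipeline_result():
    cfg = rx.RunConfig(simulate=rx.SimulationParams(n_patients=1200, seed=20))
    return rx.run_pipeline(cfg)
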