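"""Cohort selection: washout, exclusions, switchers, fracture history, attrition."""

import numpy as np
import pandas as pd
import pytest

import rxadhere as rx
from rxadhere.cohort import (AttritionRecord, ClaimsParseError, CohortConfig,
                             apply_exclusions, detect_switchers,
                             fracture_history, icd_prefix_match,
                             identify_new_users, parse_date_column)
from conftest import disp, hosp, make_tables, patient

CFG = CohortConfig()


def _index_events(tables, config=CFG):
    events, attrition = identify_new_users(
        tables["dispensing"], tables["patients"], config)
    return events, attrition


class TestNewUsers:
    def test_washout_boundary(self):
        # pre-window dispensation 25 months before candidate: washout satisfied;
        # 20 months before: violated (24-month washout = 730 days)
        tables = make_tables(
            [disp("A", "2008-05-01"), disp("A", "2010-06-01"),    # 761 d apart
             disp("B", "2008-10-01"), disp("B", "2010-06-01")],   # 608 d apart
            [patient("A"), patient("B")])
        events, _ = _index_events(tables)
        assert list(events["patient_id"]) == ["A"]
        assert events["index_date"].iloc[0] == pd.Timestamp("2010-06-01")

    def test_underage_patient_excluded(self):
        tables = make_tables(
            [disp("A", "2012-06-01"), disp("B", "2012-06-01")],
            [patient("A", birth="1963-01-01"),   # 49 at index
             patient("B", birth="1962-05-01")])  # 50 at index
        events, attrition = _index_events(tables)
        assert list(events["patient_id"]) == ["B"]
        assert attrition.as_dict()["age_at_least_min"] == 1

    def test_combination_product_index_excluded(self):
        tables = make_tables(
            [disp("A", "2012-06-01", molecule="alendronic_vitD")],
            [patient("A")])
        events, attrition = _index_events(tables)
        assert len(events) == 0
        assert attrition.as_dict()["new_users_washout_ok"] == 1
        assert attrition.as_dict()["non_combination_product"] == 0

    def test_later_initiation_after_clean_gap_qualifies(self):
        # prior use early in the window, then a 25-month clean gap: the later
        # dispensation becomes the index
        tables = make_tables(
            [disp("A", "2009-03-01"), disp("A", "2013-06-01")],
            [patient("A")])
        events, _ = _index_events(tables)
        assert events["index_date"].iloc[0] == pd.Timestamp("2009-03-01")
        # the first event qualifies directly (no prior history at all)

    def test_group_label_equals_index_flag(self):
        tables = make_tables(
            [disp("A", "2012-06-01", brand=0), disp("B", "2012-06-01", brand=1)],
            [patient("A"), patient("B")])
        events, _ = _index_events(tables)
        assert dict(zip(events["patient_id"], events["group"])) == {
            "A": "generic", "B": "brand"}


class TestExclusions:
    def _candidates(self):
        tables = make_tables(
            [disp(p, "2012-06-01") for p in "ABC"],
            [patient(p) for p in "ABC"])
        events, att = _index_events(tables)
        return events, att, tables

    def test_corticosteroid_threshold(self):
        events, att, tables = self._candidates()
        cortico = [disp("A", d, molecule="prednisone")
                   for d in ["2011-01-01", "2011-06-01", "2012-01-01"]]   # 3 -> out
        cortico += [disp("B", d, molecule="prednisone")
                    for d in ["2011-01-01", "2012-01-01"]]                # 2 -> kept
        dispensing = pd.concat([tables["dispensing"], pd.DataFrame(cortico)])
        kept, _, removed = apply_exclusions(events, dispensing,
                                            tables["hospitalizations"], CFG, att)
        assert set(kept["patient_id"]) == {"B", "C"}
        assert removed["corticosteroid_long_term"] == 1

    def test_exclusion_diagnosis_in_lookback(self):
        events, att, tables = self._candidates()
        stays = pd.DataFrame([
            hosp("A", "2011-06-01", "2011-06-05", icd="C90.0"),  # myeloma -> out
            hosp("B", "2009-01-01", "2009-01-05", icd="C90.0"),  # before lookback
            hosp("C", "2011-06-01", "2011-06-05", icd="I10"),    # benign
        ])
        kept, _, removed = apply_exclusions(events, tables["dispensing"], stays,
                                            CFG, att)
        assert set(kept["patient_id"]) == {"B", "C"}
        assert removed["exclusion_diagnosis"] == 1

    def test_empty_exclusion_list_is_identity(self):
        events, att, tables = self._candidates()
        stays = pd.DataFrame([hosp("A", "2011-06-01", "2011-06-05", icd="C90.0")])
        cfg = CohortConfig(exclusion_icd_codes=[], corticosteroid_threshold=99)
        kept, _, _ = apply_exclusions(events, tables["dispensing"], stays, cfg, att)
        assert len(kept) == len(events)


class TestSwitchers:
    def _events(self, tables):
        events, _ = _index_events(tables)
        return events

    def test_brand_generic_switch_and_molecule_change(self):
        rows = [
            disp("A", "2012-06-01", brand=1),
            disp("A", "2012-08-01", brand=0),                      # flag flip
            disp("B", "2012-06-01", brand=1),
            disp("B", "2012-09-01", molecule="risedronic", brand=1),  # molecule
            disp("C", "2012-06-01", brand=0),                      # no post-index
            disp("D", "2012-06-01", brand=0),
            disp("D", "2012-07-01", brand=0),                      # plain refill
        ]
        tables = make_tables(rows, [patient(p) for p in "ABCD"])
        analysis, counts = detect_switchers(self._events(tables),
                                            tables["dispensing"])
        assert set(analysis["patient_id"]) == {"C", "D"}
        assert counts["brand"] == {"brand_generic": 1, "molecule": 1}
        assert counts["generic"] == {"brand_generic": 0, "molecule": 0}

    def test_switch_after_followup_is_not_a_switch(self):
        rows = [disp("A", "2012-06-01", brand=1),
                disp("A", "2013-08-01", brand=0)]  # 14 months later
        tables = make_tables(rows, [patient("A")])
        analysis, counts = detect_switchers(self._events(tables),
                                            tables["dispensing"])
        assert list(analysis["patient_id"]) == ["A"]

    def test_flow_count_arithmetic(self):
        # initiator counts minus the two switcher kinds give the analysis groups
        att = AttritionRecord()
        att.add("brand_initiators", 2193)
        att.add("after_same_molecule_switch", 2193 - 232)
        att.add("after_molecule_change", 2193 - 232 - 127)
        assert att.as_dict()["after_molecule_change"] == 1834
        assert 1710 - 156 - 59 == 1495


class TestFractureHistoryAndCodes:
    def test_prefix_match_is_dot_insensitive(self):
        codes = pd.Series(["S72.00", "S720", "S7", "M80.0", "K25.1"])
        m = icd_prefix_match(codes, ["S720", "K25"])
        assert list(m) == [True, True, False, False, True]

    def test_fracture_lookback_window(self):
        events = pd.DataFrame({"patient_id": ["A", "B", "C"],
                               "index_date": [pd.Timestamp("2012-06-01")] * 3})
        stays = pd.DataFrame([
            hosp("A", "2011-06-01", "2011-06-04", icd="S72.0"),  # 12 mo: yes
            hosp("B", "2009-12-01", "2009-12-04", icd="S72.0"),  # 30 mo: no
        ])
        fx = fracture_history(events, stays, CFG)
        assert fx["A"] and not fx["B"] and not fx["C"]


class TestAttritionAndParsing:
    def test_attrition_must_not_increase(self):
        att = AttritionRecord()
        att.add("a", 10)
        att.add("b", 10)
        with pytest.raises(ValueError):
            att.add("c", 11)

    def test_malformed_date_reports_line_number(self):
        frame = pd.DataFrame({"date": ["2012-01-01", "not-a-date"]})
        with pytest.raises(ClaimsParseError, match="line.*3"):
            parse_date_column(frame, "date", table="dispensing")

    def test_missing_input_file_names_path(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="patients.csv"):
            rx.read_claims_tables(tmp_path)

    def test_partition_no_patient_counted_twice(self, small_sim):
        cfg = rx.RunConfig(simulate=small_sim.params)
        tables = rx.pipeline.load_tables(cfg)
        cohort, attrition, details = rx.build_cohort(tables)
        steps = attrition.to_frame()["n_remaining"].to_numpy()
        assert (np.diff(steps) <= 0).all()
        sw = details["switchers"]
        n_switch = sum(sum(kind.values()) for kind in sw.values())
        assert attrition.as_dict()["no_exclusion_diagnosis"] - n_switch == len(cohort)
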