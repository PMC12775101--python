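"""Eligibility rules on hand-built micro claims and on generator truth."""

import numpy as np
import pandas as pd
import pytest

from oncnet import cohort_builder as cb
from oncnet.errors import ReferentialIntegrityError, UnmappedZipError

YEARS = (2016, 2017, 2018, 2019)
T = pd.Timestamp


def claims_frame(rows):
    """rows: (physician, patient, date, dx, biopsy, surgery[, source, zip])"""
    recs = []
    for i, row in enumerate(rows):
        phys, pat, date, dx, biopsy, surgery = row[:6]
        source = row[6] if len(row) > 6 else "carrier"
        zip_ = row[7] if len(row) > 7 else "00001"
        recs.append(
            {
                "claim_id": f"C{i:06d}",
                "physician_id": phys,
                "patient_id": pat,
                "service_date": T(date),
                "billing_zip": zip_,
                "file_source": source,
                "dx": dx,
                "proc_biopsy": biopsy,
                "proc_cancer_surgery": surgery,
            }
        )
    return pd.DataFrame(recs)


def patient_row(pid, birth="1950-06-01", enroll="2015-01-01:2020-12-31",
                race="NH-White"):
    return {
        "patient_id": pid,
        "birth_date": T(birth),
        "enrollment": enroll,
        "race_ethnicity": race,
    }


class TestPatientEligibility:
    def base_claims(self, pid="P1", biopsy="2017-03-01"):
        b = T(biopsy)
        return [
            ("D1", pid, b, "C50.9", True, False),
            ("D2", pid, b + pd.Timedelta(days=10), "C50.9", False, False),
            ("D2", pid, b + pd.Timedelta(days=40), "C50.9", False, False),
        ]

    def test_confirmed_incident_case_eligible(self):
        claims = claims_frame(self.base_claims())
        pats = pd.DataFrame([patient_row("P1")])
        out = cb.select_patient_cohort(claims, pats, YEARS)
        assert out.iloc[0]["eligible"]
        assert out.iloc[0]["exclusion_reason"] == "none"

    def test_lookback_dx_marks_prevalent(self):
        rows = self.base_claims() + [
            ("D3", "P1", T("2017-03-01") - pd.Timedelta(days=60), "C50.9",
             False, False)
        ]
        out = cb.select_patient_cohort(
            claims_frame(rows), pd.DataFrame([patient_row("P1")]), YEARS
        )
        assert out.iloc[0]["exclusion_reason"] == "prevalent"

    def test_age_65_boundary_excluded(self):
        pats = pd.DataFrame([patient_row("P1", birth="1951-06-01")])
        # age 65 at the 2017-03-01 biopsy
        out = cb.select_patient_cohort(claims_frame(self.base_claims()), pats, YEARS)
        assert out.iloc[0]["exclusion_reason"] == "age"

    def test_age_66_boundary_included(self):
        pats = pd.DataFrame([patient_row("P1", birth="1951-02-01")])
        out = cb.select_patient_cohort(claims_frame(self.base_claims()), pats, YEARS)
        assert out.iloc[0]["eligible"]

    def test_single_confirmatory_day_insufficient(self):
        rows = self.base_claims()[:2]  # biopsy plus one dx day
        out = cb.select_patient_cohort(
            claims_frame(rows), pd.DataFrame([patient_row("P1")]), YEARS
        )
        assert out.iloc[0]["exclusion_reason"] == "no_confirmatory_dx"

    def test_confirmatory_must_match_biopsy_family(self):
        b = T("2017-03-01")
        rows = [
            ("D1", "P1", b, "C50.9", True, False),
            ("D2", "P1", b + pd.Timedelta(days=10), "C34.9", False, False),
            ("D2", "P1", b + pd.Timedelta(days=40), "C34.9", False, False),
        ]
        out = cb.select_patient_cohort(
            claims_frame(rows), pd.DataFrame([patient_row("P1")]), YEARS
        )
        assert out.iloc[0]["exclusion_reason"] == "no_confirmatory_dx"

    def test_enrollment_gap_excluded(self):
        pats = pd.DataFrame(
            [patient_row("P1", enroll="2015-01-01:2017-06-01;2017-09-01:2020-12-31")]
        )
        out = cb.select_patient_cohort(claims_frame(self.base_claims()), pats, YEARS)
        assert out.iloc[0]["exclusion_reason"] == "enrollment"

    def test_first_failing_rule_wins(self):
        # one confirmatory day AND under age: confirmation is checked first
        rows = self.base_claims()[:2]
        pats = pd.DataFrame([patient_row("P1", birth="1955-01-01")])
        out = cb.select_patient_cohort(claims_frame(rows), pats, YEARS)
        assert out.iloc[0]["exclusion_reason"] == "no_confirmatory_dx"

    def test_unknown_patient_raises(self):
        claims = claims_frame(self.base_claims(pid="P9"))
        with pytest.raises(ReferentialIntegrityError):
            cb.select_patient_cohort(claims, pd.DataFrame([patient_row("P1")]), YEARS)

    def test_exact_confusion_matrix_against_truth(self, small_study, small_result):
        merged = small_result.eligibility.merge(
            small_study.patients[["patient_id", "truth_category"]], on="patient_id"
        )
        assert (
            (merged["truth_category"] == "eligible")
            == (merged["exclusion_reason"] == "none")
        ).all()
        planted = merged[merged["truth_category"] != "eligible"]
        assert (planted["truth_category"] == planted["exclusion_reason"]).all()


def _mk_cohort(pid="P1", biopsy="2017-03-01", race="NH-White"):
    return pd.DataFrame(
        [{"patient_id": pid, "biopsy_date": T(biopsy), "race_ethnicity": race}]
    )


class TestPhysicianCohort:
    def physicians(self, rows):
        return pd.DataFrame(
            [
                {"physician_id": p, "taxonomy_codes": tax, "sex": "F"}
                for p, tax in rows
            ]
        )

    def test_surgeon_requires_cancer_surgery(self):
        claims = claims_frame([
            ("D1", "P1", "2017-03-05", "", False, False),
        ])
        docs = self.physicians([("D1", "208600000X")])
        prof = cb.identify_oncologists(claims, docs, _mk_cohort())
        assert prof.iloc[0]["specialty"] == "other"
        claims2 = claims_frame([
            ("D1", "P1", "2017-03-05", "", False, False),
            ("D1", "P1", "2017-03-22", "", False, True, "medpar"),
        ])
        prof2 = cb.identify_oncologists(claims2, docs, _mk_cohort())
        assert prof2.iloc[0]["specialty"] == "surgery"

    def test_specialty_from_any_of_first_three_codes(self):
        claims = claims_frame([("D1", "P1", "2017-03-05", "", False, False)])
        docs = self.physicians([("D1", "207R00000X;207RX0202X;207Q00000X")])
        prof = cb.identify_oncologists(claims, docs, _mk_cohort())
        assert prof.iloc[0]["specialty"] == "medical oncology"

    def test_encounter_outside_window_excluded(self):
        # four months before the biopsy: outside (-3, +12 months)
        claims = claims_frame([("D1", "P1", "2016-11-01", "", False, False)])
        docs = self.physicians([("D1", "207RX0202X")])
        prof = cb.identify_oncologists(claims, docs, _mk_cohort())
        assert len(prof) == 0

    def test_retention_requires_all_years(self):
        prof = pd.DataFrame(
            [
                {"physician_id": "D1", "is_oncologist": True,
                 "active_years": frozenset({2016, 2017, 2018})},
                {"physician_id": "D2", "is_oncologist": True,
                 "active_years": frozenset(YEARS)},
            ]
        )
        movers = pd.DataFrame(columns=["physician_id", "excluded"])
        kept = cb.select_retained_cohort(prof, movers, YEARS)
        assert kept == {"D2"}

    def test_multi_year_mover_excluded_single_mover_kept(self):
        prof = pd.DataFrame(
            [
                {"physician_id": d, "is_oncologist": True,
                 "active_years": frozenset(YEARS)}
                for d in ("D1", "D2")
            ]
        )
        movers = pd.DataFrame(
            [
                {"physician_id": "D1", "excluded": True},
                {"physician_id": "D1", "excluded": True},
                {"physician_id": "D2", "excluded": False},
            ]
        )
        kept = cb.select_retained_cohort(prof, movers, YEARS)
        assert kept == {"D2"}

    def test_retention_monotone_in_activity(self):
        movers = pd.DataFrame(columns=["physician_id", "excluded"])
        less = pd.DataFrame(
            [{"physician_id": "D1", "is_oncologist": True,
              "active_years": frozenset({2016, 2017, 2018})}]
        )
        more = pd.DataFrame(
            [{"physician_id": "D1", "is_oncologist": True,
              "active_years": frozenset(YEARS)}]
        )
        assert cb.select_retained_cohort(less, movers, YEARS) <= (
            cb.select_retained_cohort(more, movers, YEARS)
        )


class TestCovariates:
    def crosswalk(self):
        return pd.DataFrame(
            {
                "zip": ["00001", "00002"],
                "hrr_id": ["HRR000", "HRR000"],
                "ruca_code": [1, 7],
                "rural_flag": [False, True],
            }
        )

    def profile(self):
        return pd.DataFrame(
            [{"physician_id": "D1", "specialty": "medical oncology",
              "is_oncologist": True, "sex": "F",
              "active_years": frozenset(YEARS)}]
        )

    def test_plurality_zip_mode(self):
        rows = [("D1", "P1", f"2017-03-{d:02d}", "", False, False, "carrier",
                 "00001") for d in range(5, 11)]
        rows += [("D1", "P1", f"2017-04-{d:02d}", "", False, False, "carrier",
                  "00002") for d in range(5, 9)]
        out = cb.compute_covariates(
            self.profile(), claims_frame(rows), _mk_cohort(), self.crosswalk()
        )
        assert out.iloc[0]["plurality_zip"] == "00001"
        assert not out.iloc[0]["rural"]

    def test_zip_tie_breaks_lexicographically(self):
        rows = [("D1", "P1", f"2017-03-{d:02d}", "", False, False, "carrier",
                 "00002") for d in range(5, 10)]
        rows += [("D1", "P1", f"2017-04-{d:02d}", "", False, False, "carrier",
                  "00001") for d in range(5, 10)]
        out = cb.compute_covariates(
            self.profile(), claims_frame(rows), _mk_cohort(), self.crosswalk()
        )
        assert out.iloc[0]["plurality_zip"] == "00001"

    def test_panel_composition_percentages(self):
        cohort = pd.DataFrame(
            [
                {"patient_id": f"P{i}", "biopsy_date": T("2017-03-01"),
                 "race_ethnicity": race}
                for i, race in enumerate(
                    ["Hispanic", "NH-Black", "NH-White", "NH-White"]
                )
            ]
        )
        rows = [("D1", f"P{i}", "2017-03-05", "", False, False) for i in range(4)]
        out = cb.compute_covariates(
            self.profile(), claims_frame(rows), cohort, self.crosswalk()
        )
        row = out.iloc[0]
        assert (row["panel_pct_hispanic"], row["panel_pct_nh_black"],
                row["panel_pct_nh_white"]) == (25.0, 25.0, 50.0)

    def test_unmapped_zip_raises_with_offenders(self):
        rows = [("D1", "P1", "2017-03-05", "", False, False, "carrier", "99999")]
        with pytest.raises(UnmappedZipError) as err:
            cb.compute_covariates(
                self.profile(), claims_frame(rows), _mk_cohort(), self.crosswalk()
            )
        assert "99999" in str(err.value)

    def test_panel_percentages_bounded(self, small_result):
        prof = small_result.profiles
        total = (
            prof["panel_pct_hispanic"]
            + prof["panel_pct_nh_black"]
            + prof["panel_pct_nh_white"]
        )
        assert (total <= 100.0 + 1e-9).all()
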