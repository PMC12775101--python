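"""Patient and physician eligibility rules.

The patient cohort requires, in fixed order of evaluation: a diagnostic
biopsy in the study years confirmed by two same-family cancer diagnosis
codes on separate days within the following 12 months; no cancer
diagnosis in the 12 months before the biopsy (incident, not prevalent,
disease); age 66-99 at biopsy; and continuous enrollment from 12 months
before to 12 months after the biopsy.

The physician cohort keeps everyone with at least one encounter with a
cohort patient inside that patient's care window, classifies oncology
specialty from the first three taxonomy codes (surgeons additionally
need a cancer-directed surgical procedure on a cohort patient), and
restricts the analytic set to oncologists billing in every study year.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import TAXONOMY
from .errors import ReferentialIntegrityError, UnmappedZipError
from .network_builder import CARE_WINDOW_MONTHS

log = logging.getLogger(__name__)

EXCLUSION_ORDER = ("no_confirmatory_dx", "prevalent", "age", "enrollment")

_FAMILY_PREFIXES = {
    "breast": ("C50",),
    "lung": ("C34",),
    "colorectal": ("C18", "C19", "C20"),
}


def dx_family(code: str):
    """Map an ICD-10-style code to its cancer family, or None."""
    for family, prefixes in _FAMILY_PREFIXES.items():
        if any(code.startswith(p) for p in prefixes):
            return family
    return None


def parse_enrollment(spec: str):
    """Parse 'start:end;start:end' enrollment interval strings."""
    out = []
    for part in str(spec).split(";"):
        if not part:
            continue
        a, b = part.split(":")
        out.append((pd.Timestamp(a), pd.Timestamp(b)))
    return sorted(out)


def format_enrollment(intervals) -> str:
    return ";".join(f"{a.date()}:{b.date()}" for a, b in intervals)


def _covers(intervals, start, end) -> bool:
    """True if merged intervals cover [start, end] without gaps."""
    cursor = start
    for a, b in intervals:
        if a > cursor:
            break
        cursor = max(cursor, b)
        if cursor >= end:
            return True
    return cursor >= end


def select_patient_cohort(
    claims: pd.DataFrame, patients: pd.DataFrame, study_years
) -> pd.DataFrame:
    """Apply the eligibility rules; one row per patient with the first
    failing rule recorded as the exclusion reason.

    Rules, evaluated in order: a study-period diagnostic biopsy with two
    same-family confirmatory diagnosis codes on separate days within the
    following 12 months; no cancer diagnosis in the 12 months before the
    biopsy; age 66-99 at biopsy; continuous enrollment over the biopsy
    +/- 12 month span.
    """
    known = set(patients["patient_id"])
    orphans = set(claims["patient_id"]) - known
    if orphans:
        raise ReferentialIntegrityError(
            f"claims reference unknown patients: {sorted(orphans)[:5]}..."
        )
    y0, y1 = min(study_years), max(study_years)

    biopsies = claims.loc[claims["proc_biopsy"], ["patient_id", "service_date", "dx"]]
    biopsies = biopsies[
        (biopsies["service_date"].dt.year >= y0)
        & (biopsies["service_date"].dt.year <= y1)
    ]
    fb = (
        biopsies.sort_values(["patient_id", "service_date"])
        .groupby("patient_id", sort=False)
        .first()
        .rename(columns={"service_date": "biopsy", "dx": "biopsy_dx"})
    )
    fb["family"] = fb["biopsy_dx"].map(lambda c: dx_family(c) if c else None)
    with pd.option_context("mode.chained_assignment", None):
        fb["confirm_end"] = fb["biopsy"] + pd.DateOffset(months=12)
        fb["lookback"] = fb["biopsy"] - pd.DateOffset(months=12)

    dx_claims = claims.loc[claims["dx"] != "", ["patient_id", "service_date", "dx"]]
    dx_claims = dx_claims.assign(family=dx_claims["dx"].map(dx_family))
    dx_claims = dx_claims[dx_claims["family"].notna()]
    merged = dx_claims.merge(
        fb[["biopsy", "family", "confirm_end", "lookback"]].rename(
            columns={"family": "b_family"}
        ),
        left_on="patient_id",
        right_index=True,
        how="inner",
    )
    confirm = merged[
        (merged["family"] == merged["b_family"])
        & (merged["service_date"] > merged["biopsy"])
        & (merged["service_date"] <= merged["confirm_end"])
    ]
    n_confirm_days = (
        confirm.assign(day=confirm["service_date"].dt.normalize())
        .groupby("patient_id")["day"]
        .nunique()
    )
    prevalent_ids = set(
        merged.loc[
            (merged["service_date"] >= merged["lookback"])
            & (merged["service_date"] < merged["biopsy"]),
            "patient_id",
        ]
    )

    out = patients[["patient_id", "birth_date", "enrollment"]].merge(
        fb[["biopsy", "confirm_end", "lookback"]],
        left_on="patient_id",
        right_index=True,
        how="left",
    )
    has_biopsy = out["biopsy"].notna()
    confirmed = out["patient_id"].map(n_confirm_days).fillna(0) >= 2

    b, bd = out["biopsy"], out["birth_date"]
    age = b.dt.year - bd.dt.year - (
        (b.dt.month * 100 + b.dt.day) < (bd.dt.month * 100 + bd.dt.day)
    ).astype("Int64")
    age_ok = (age >= 66) & (age <= 99)

    # enrollment: vectorized single-interval fast path, loop for the rest
    enroll_ok = pd.Series(False, index=out.index)
    single = ~out["enrollment"].astype(str).str.contains(";")
    if single.any():
        parts = out.loc[single, "enrollment"].astype(str).str.split(":", expand=True)
        starts = pd.to_datetime(parts[0], errors="coerce")
        ends = pd.to_datetime(parts[1], errors="coerce")
        enroll_ok.loc[single] = (starts <= out.loc[single, "lookback"]) & (
            ends >= out.loc[single, "confirm_end"]
        )
    for i in out.index[~single]:
        if pd.notna(out.at[i, "biopsy"]):
            enroll_ok.at[i] = _covers(
                parse_enrollment(out.at[i, "enrollment"]),
                out.at[i, "lookback"],
                out.at[i, "confirm_end"],
            )

    reason = pd.Series("none", index=out.index)
    reason[~enroll_ok.fillna(False)] = "enrollment"
    reason[~age_ok.fillna(False).astype(bool)] = "age"
    reason[out["patient_id"].isin(prevalent_ids)] = "prevalent"
    reason[~(has_biopsy & confirmed)] = "no_confirmatory_dx"
    return pd.DataFrame(
        {
            "patient_id": out["patient_id"],
            "eligible": (reason == "none").to_numpy(),
            "exclusion_reason": reason.to_numpy(),
            "biopsy_date": out["biopsy"],
        }
    )


def eligible_cohort(patients: pd.DataFrame, eligibility: pd.DataFrame) -> pd.DataFrame:
    """Demographic table of eligible patients with their index biopsy date."""
    elig = eligibility[eligibility["eligible"]][["patient_id", "biopsy_date"]]
    return elig.merge(patients.drop(columns=["biopsy_date"], errors="ignore"),
                      on="patient_id")


def attrition_summary(eligibility: pd.DataFrame) -> pd.DataFrame:
    counts = eligibility["exclusion_reason"].value_counts()
    rows = [("assessed", len(eligibility))]
    rows += [(r, int(counts.get(r, 0))) for r in EXCLUSION_ORDER]
    rows.append(("eligible", int(eligibility["eligible"].sum())))
    return pd.DataFrame(rows, columns=["stage", "n"])


def _specialty_from_taxonomy(codes: str):
    """Specialty from the first three listed taxonomy codes."""
    listed = [c for c in str(codes).split(";") if c][:3]
    for specialty in ("medical oncology", "radiation oncology", "surgery"):
        if any(c in TAXONOMY[specialty] for c in listed):
            return specialty
    return "other"


def window_encounters(claims: pd.DataFrame, patient_cohort: pd.DataFrame) -> pd.DataFrame:
    """Claims with cohort patients restricted to each patient's care window."""
    sub = claims.merge(
        patient_cohort[["patient_id", "biopsy_date"]], on="patient_id", how="inner"
    )
    start = sub["biopsy_date"] - pd.DateOffset(months=CARE_WINDOW_MONTHS[0])
    end = sub["biopsy_date"] + pd.DateOffset(months=CARE_WINDOW_MONTHS[1])
    return sub[(sub["service_date"] >= start) & (sub["service_date"] <= end)]


def identify_oncologists(
    claims: pd.DataFrame, physicians: pd.DataFrame, patient_cohort: pd.DataFrame
) -> pd.DataFrame:
    """Physician profiles for everyone with cohort-window encounters.

    Physicians with surgical taxonomy but no cancer-directed surgery claim
    on a cohort patient are labeled non-oncologists (kept for network
    construction, excluded from the analytic cohort).
    """
    enc = window_encounters(claims, patient_cohort)
    seen = set(enc["physician_id"].unique())
    cohort_ids = set(patient_cohort["patient_id"])
    surgery_ok = set(
        claims.loc[
            claims["proc_cancer_surgery"] & claims["patient_id"].isin(cohort_ids),
            "physician_id",
        ].unique()
    )
    active = (
        claims[claims["file_source"] == "carrier"]
        .assign(year=lambda d: d["service_date"].dt.year)
        .groupby("physician_id")["year"]
        .agg(lambda s: frozenset(s))
    )
    rows = []
    for doc in physicians.itertuples(index=False):
        if doc.physician_id not in seen:
            continue
        if not str(doc.taxonomy_codes).strip(";"):
            log.warning("physician %s has no taxonomy codes", doc.physician_id)
            specialty = "other"
        else:
            specialty = _specialty_from_taxonomy(doc.taxonomy_codes)
        if specialty == "surgery" and doc.physician_id not in surgery_ok:
            specialty = "other"
        rows.append(
            (
                doc.physician_id,
                specialty,
                specialty != "other",
                doc.sex,
                active.get(doc.physician_id, frozenset()),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["physician_id", "specialty", "is_oncologist", "sex", "active_years"],
    )


def select_retained_cohort(
    profiles: pd.DataFrame, movers: pd.DataFrame, years
) -> set:
    """Oncologists billing in every study year, minus multi-year movers."""
    need = set(years)
    kept = {
        p.physician_id
        for p in profiles.itertuples(index=False)
        if p.is_oncologist and need <= set(p.active_years)
    }
    if len(movers):
        multi = set(movers.loc[movers["excluded"], "physician_id"])
        kept -= multi
    return kept


def compute_covariates(
    profiles: pd.DataFrame,
    claims: pd.DataFrame,
    patient_cohort: pd.DataFrame,
    crosswalk: pd.DataFrame,
    movers: pd.DataFrame = None,
) -> pd.DataFrame:
    """Complete the physician profiles with plurality ZIP, rurality and
    patient-panel composition.

    Plurality ZIP is the modal billing ZIP over the physician's
    cohort-patient window claims (ties to the lexicographically smallest
    ZIP); rurality comes from the crosswalk RUCA flag of that ZIP, except
    for movers, whose rurality is evaluated at their departure ZIP.
    """
    enc = window_encounters(claims, patient_cohort)
    zips = enc.groupby(["physician_id", "billing_zip"]).size().reset_index(name="n")
    zips = zips.sort_values(["physician_id", "n", "billing_zip"],
                            ascending=[True, False, True])
    plurality = zips.groupby("physician_id").first()["billing_zip"]

    per_year = (
        enc.assign(year=enc["service_date"].dt.year)
        .groupby(["physician_id", "year", "billing_zip"])
        .size()
        .reset_index(name="n")
        .sort_values(["physician_id", "year", "n", "billing_zip"],
                     ascending=[True, True, False, True])
        .groupby(["physician_id", "year"])
        .first()["billing_zip"]
    )

    zmap = crosswalk.set_index("zip")
    rural_by_zip = zmap["rural_flag"].to_dict()
    hrr_by_zip = zmap["hrr_id"].to_dict()

    departure_zip = {}
    if movers is not None and len(movers):
        ok = movers[~movers["excluded"]]
        departure_zip = dict(zip(ok["physician_id"], ok["departure_zip"]))

    race = patient_cohort.set_index("patient_id")["race_ethnicity"]
    panel = enc[["physician_id", "patient_id"]].drop_duplicates()
    panel = panel.assign(race=panel["patient_id"].map(race))
    comp = panel.groupby("physician_id")["race"].value_counts(normalize=True).unstack(
        fill_value=0.0
    )

    out = profiles.copy()
    out["plurality_zip"] = out["physician_id"].map(plurality)
    anchor_zip = out["physician_id"].map(
        lambda p: departure_zip.get(p, plurality.get(p))
    )
    missing = [z for z in anchor_zip.dropna().unique() if z not in rural_by_zip]
    if missing:
        raise UnmappedZipError(missing)
    out["rural"] = anchor_zip.map(rural_by_zip)
    out["hrr_id"] = anchor_zip.map(hrr_by_zip)
    for cat, col in [
        ("Hispanic", "panel_pct_hispanic"),
        ("NH-Black", "panel_pct_nh_black"),
        ("NH-White", "panel_pct_nh_white"),
    ]:
        if cat in comp.columns:
            out[col] = out["physician_id"].map(comp[cat]).fillna(0.0) * 100
        else:
            out[col] = 0.0
    out.attrs["plurality_zip_by_year"] = per_year
    return out
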