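"""Departure detection from billing-ZIP sequences.

An oncologist is considered to have moved in a calendar year if their
date-ordered Carrier-claim billing ZIP changed exactly once during that
year, or (to accommodate multi-site practices such as rural outreach)
if the HRR of those ZIPs changed exactly once. The departure location is
the plurality billing ZIP over the claims before the final transition.
Physicians qualifying in two or more calendar years are flagged for
exclusion: their network measures are unstable over the study window.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, UnmappedZipError

MOVER_COLUMNS = [
    "physician_id",
    "departure_year",
    "departure_zip",
    "departure_hrr",
    "departure_rural",
    "rule",
    "excluded",
]


def _transition_count(seq: np.ndarray) -> int:
    if len(seq) < 2:
        return 0
    return int(np.sum(seq[1:] != seq[:-1]))


def _year_zips(claims: pd.DataFrame, physician, year: int) -> np.ndarray:
    sub = claims[
        (claims["physician_id"] == physician)
        & (claims["file_source"] == "carrier")
        & (claims["service_date"].dt.year == year)
    ]
    sub = sub.sort_values(["service_date", "claim_id"])
    return sub["billing_zip"].to_numpy()


def zip_transitions(claims: pd.DataFrame, physician, year: int) -> int:
    """Number of billing-ZIP changes between consecutive date-ordered
    Carrier claims within the calendar year (0 when inactive)."""
    return _transition_count(_year_zips(claims, physician, year))


def hrr_transitions(claims: pd.DataFrame, physician, year: int, crosswalk) -> int:
    """Transition count on the HRR-mapped billing sequence."""
    zips = _year_zips(claims, physician, year)
    return _transition_count(_map_hrr(zips, _hrr_map(crosswalk)))


def _hrr_map(crosswalk) -> dict:
    if isinstance(crosswalk, dict):
        return crosswalk
    return dict(zip(crosswalk["zip"], crosswalk["hrr_id"]))


def _map_hrr(zips: np.ndarray, hrr_map: dict) -> np.ndarray:
    missing = [z for z in np.unique(zips) if z not in hrr_map]
    if missing:
        raise UnmappedZipError(missing)
    return np.array([hrr_map[z] for z in zips])


def _plurality(values: np.ndarray):
    """Most frequent value; ties go to the lexicographically smallest."""
    uniq, counts = np.unique(values, return_counts=True)  # uniq is sorted
    return uniq[int(np.argmax(counts))]


def classify_movers(
    claims: pd.DataFrame,
    physicians: pd.DataFrame,
    crosswalk: pd.DataFrame,
    years,
    rule: str = "union",
) -> pd.DataFrame:
    """One row per (physician, qualifying year); the ZIP criterion takes
    precedence over the HRR criterion when both fire. `rule` selects
    which criteria may fire: "zip", "hrr", or their union (default)."""
    if rule not in {"zip", "hrr", "union"}:
        raise InvalidConfigError(f"unknown mover rule {rule!r}")
    hrr_map = _hrr_map(crosswalk)
    rural_map = dict(zip(crosswalk["zip"], crosswalk["rural_flag"]))

    carrier = claims[claims["file_source"] == "carrier"].copy()
    carrier["year"] = carrier["service_date"].dt.year
    carrier = carrier.sort_values(["service_date", "claim_id"])
    wanted = set(physicians["physician_id"])

    records = []
    for (phys, year), grp in carrier.groupby(["physician_id", "year"], sort=True):
        if phys not in wanted or year not in years:
            continue
        zips = grp["billing_zip"].to_numpy()
        hrrs = _map_hrr(zips, hrr_map)
        z_n = _transition_count(zips)
        h_n = _transition_count(hrrs)
        if rule in ("zip", "union") and z_n == 1:
            fired, level = "zip_single_change", zips
        elif rule in ("hrr", "union") and h_n == 1:
            fired, level = "hrr_single_change", hrrs
        else:
            continue
        changes = np.nonzero(level[1:] != level[:-1])[0]
        pre = zips[: changes[-1] + 1]
        dep_zip = _plurality(pre)
        records.append(
            (
                phys,
                int(year),
                dep_zip,
                hrr_map[dep_zip],
                bool(rural_map[dep_zip]),
                fired,
                False,
            )
        )
    out = pd.DataFrame(records, columns=MOVER_COLUMNS)
    if len(out):
        multi = out["physician_id"].value_counts()
        out.loc[out["physician_id"].isin(multi[multi > 1].index), "excluded"] = True
    return out
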