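"""Exposure counting and the physician-year analysis table.

A retained oncologist is "connected" to an oncologist departing in year
y when the pair shared at least k patients (default 2) over the
departure year and the year before, summing the two annual shared-patient
counts (a per-year variant requiring >= k in each year is available).
Exposure counts are kept overall, for same-specialty movers, and for
linchpin movers (linchpin status evaluated in the mover's last full year
before departure). Outcomes are one-year changes in node strength, local
transitivity, Burt's constraint, linchpin score and cohort patient
volume; a change is missing whenever either year's measure is undefined.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError

OUTCOMES = ("strength", "transitivity", "constraint", "linchpin", "volume")

VOLUME_BINS = ((0, 5, "low"), (5, 10, "medium"), (10, np.inf, "high"))


def volume_category(v) -> str:
    """Low < 5, Medium 5-9, High >= 10 cohort patients."""
    for lo, hi, name in VOLUME_BINS:
        if lo <= v < hi:
            return name
    raise InvalidInputError(f"negative volume {v!r}")


def annotate_movers(
    movers: pd.DataFrame, metrics_by_year: dict, specialty_map: dict
) -> pd.DataFrame:
    """Attach specialty and pre-departure linchpin status to mover records."""
    out = movers.copy()
    out["specialty"] = out["physician_id"].map(
        lambda p: specialty_map.get(p, "other")
    )
    flags = []
    for rec in out.itertuples(index=False):
        prior = metrics_by_year.get(int(rec.departure_year) - 1)
        flag = False
        if prior is not None:
            row = prior[prior["physician_id"] == rec.physician_id]
            if len(row):
                flag = bool(row["linchpin_flag"].iloc[0])
        flags.append(flag)
    out["linchpin_flag_at_departure"] = flags
    return out


def count_connections(
    retained_id,
    year: int,
    movers: pd.DataFrame,
    networks: dict,
    specialty_map: dict,
    k: int = 2,
    pooled: bool = True,
) -> tuple[int, int, int]:
    """(any, same-specialty, linchpin) counts of departing-oncologist
    connections for one retained physician-year."""
    if k < 1:
        raise InvalidConfigError("connection threshold k must be >= 1")
    departing = movers[
        (movers["departure_year"] == year) & ~movers["excluded"]
    ]
    if (departing["physician_id"] == retained_id).any():
        raise InvalidInputError(
            f"{retained_id!r} is itself a mover in {year}; exclude upstream"
        )
    net_y, net_prev = networks[year], networks[year - 1]
    n_any = n_same = n_linch = 0
    spec_r = specialty_map.get(retained_id, "other")
    for m in departing.itertuples(index=False):
        w_y = net_y.weight(retained_id, m.physician_id)
        w_prev = net_prev.weight(retained_id, m.physician_id)
        hit = (w_y + w_prev >= k) if pooled else (w_y >= k and w_prev >= k)
        if not hit:
            continue
        n_any += 1
        if m.specialty == spec_r:
            n_same += 1
        if m.linchpin_flag_at_departure:
            n_linch += 1
    return n_any, n_same, n_linch


def build_analysis_table(
    metrics_by_year: dict,
    movers: pd.DataFrame,
    networks: dict,
    profiles: pd.DataFrame,
    retained: set,
    years,
    k: int = 2,
    pooled: bool = True,
) -> pd.DataFrame:
    """One row per retained oncologist per observation year (the study
    years after the first): outcome deltas, exposure counts, covariates.

    Movers contribute rows only for years before their departure;
    never-connected physicians carry exposure 0 in all years. Baseline
    covariates are the first-year (2016) measures.
    """
    specialty_map = dict(zip(profiles["physician_id"], profiles["specialty"]))
    prof = profiles.set_index("physician_id")
    base_year = years[0]
    baseline = metrics_by_year[base_year].set_index("physician_id")
    departure_of = dict(
        zip(
            movers.loc[~movers["excluded"], "physician_id"],
            movers.loc[~movers["excluded"], "departure_year"],
        )
    )
    indexed = {y: m.set_index("physician_id") for y, m in metrics_by_year.items()}

    rows = []
    for year in years[1:]:
        cur, prev = indexed[year], indexed[year - 1]
        for r in sorted(retained):
            dep = departure_of.get(r)
            if dep is not None and year >= dep:
                continue
            if r not in cur.index or r not in prev.index:
                raise InvalidInputError(
                    f"metrics missing for retained physician {r!r} around {year}"
                )
            n_any, n_same, n_linch = count_connections(
                r, year, movers, networks, specialty_map, k=k, pooled=pooled
            )
            base = baseline.loc[r] if r in baseline.index else None
            if base is None:
                raise InvalidInputError(f"no baseline metrics for {r!r}")
            row = {
                "physician_id": r,
                "year": int(year),
                "rural": bool(prof.loc[r, "rural"]),
                "hrr_id": prof.loc[r, "hrr_id"],
                "sex": prof.loc[r, "sex"],
                "specialty": specialty_map[r],
                "exposure_any": n_any,
                "exposure_same_specialty": n_same,
                "exposure_linchpin": n_linch,
                "baseline_strength": base["strength"],
                "baseline_transitivity": base["transitivity"],
                "baseline_constraint": base["constraint"],
                "baseline_linchpin": base["linchpin"],
                "baseline_volume": base["volume"],
                "volume_category": volume_category(base["volume"]),
            }
            for outcome in OUTCOMES:
                row[f"delta_{outcome}"] = (
                    cur.loc[r, outcome] - prev.loc[r, outcome]
                )
            rows.append(row)
    return pd.DataFrame(rows)


def ever_connected(analysis: pd.DataFrame) -> pd.Series:
    """Per-physician indicator of any departing-oncologist connection over
    the observation years."""
    return analysis.groupby("physician_id")["exposure_any"].max() > 0


def build_paired_strength_table(
    metrics_by_year: dict,
    analysis: pd.DataFrame,
    profiles: pd.DataFrame,
    weights: pd.Series | None = None,
    min_departure_year: int | None = None,
) -> pd.DataFrame:
    """Pre/post persistent- and new-tie strength around each departure
    exposure event.

    One row per (physician, departure year) with exposure >= 1,
    restricted to departure years whose prior year has a tie
    classification (the second observation year onward, 2018-2019 in the
    default four-year study).
    """
    years_with_ties = sorted(
        y for y, m in metrics_by_year.items()
        if "strength_persistent" in m and m["strength_persistent"].notna().any()
    )
    if min_departure_year is None:
        min_departure_year = years_with_ties[1] if len(years_with_ties) > 1 else None
    if min_departure_year is None:
        return pd.DataFrame()
    prof = profiles.set_index("physician_id")
    indexed = {y: m.set_index("physician_id") for y, m in metrics_by_year.items()}
    rows = []
    exposed = analysis[
        (analysis["exposure_any"] > 0) & (analysis["year"] >= min_departure_year)
    ]
    for rec in exposed.itertuples(index=False):
        pre, post = indexed[rec.year - 1], indexed[rec.year]
        if rec.physician_id not in pre.index or rec.physician_id not in post.index:
            continue
        rows.append(
            {
                "physician_id": rec.physician_id,
                "pre_year": rec.year - 1,
                "post_year": rec.year,
                "rural": bool(prof.loc[rec.physician_id, "rural"]),
                "pre_persistent": pre.loc[rec.physician_id, "strength_persistent"],
                "post_persistent": post.loc[rec.physician_id, "strength_persistent"],
                "pre_new": pre.loc[rec.physician_id, "strength_new"],
                "post_new": post.loc[rec.physician_id, "strength_new"],
                "weight": 1.0
                if weights is None
                else float(weights.get(rec.physician_id, 1.0)),
            }
        )
    return pd.DataFrame(rows)
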