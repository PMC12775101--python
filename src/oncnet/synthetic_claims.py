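"""Synthetic Medicare-style claims with planted ground truth.

The generator emulates the study's inputs end to end: a ZIP->HRR->RUCA
geography, an oncologist workforce with NPPES-style taxonomy codes, a
beneficiary population with planted eligibility violations, four years
of day-granular carrier/inpatient claims induced by per-patient care
teams drawn within hospital referral regions, mover trajectories
expressed purely through billing-ZIP patterns, and per-departure effects
planted as integer shared-patient increments.

Two structural choices keep the planted truth exactly recoverable:

* A physician's billing ZIP is a pure function of the calendar date, so
  every date-ordered claim sequence realizes the intended transition
  pattern no matter how many claims fall in a year, and same-day claims
  always share a ZIP. Monthly "anchor" office visits (billed to planted
  non-cohort patients, so they never touch the patient-sharing networks)
  guarantee enough claims on both sides of every move.
* A mover's care-team participation is stationary: the departure changes
  where they bill, never whom they share patients with. Under a zero
  effect plan, exposure to a departure is therefore unrelated to outcome
  changes, and every planted effect enters only through the effect plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import largest_remainder, spawn_rng, stochastic_round
from .config import (
    DEFAULT_RURAL_RUCA,
    EffectPlan,
    SPECIALTIES,
    SimulationConfig,
    TAXONOMY,
)
from .errors import InvalidConfigError
from .network_builder import build_annual_network

DX_CODE = {"breast": "C50.9", "lung": "C34.9", "colorectal": "C18.9"}

MOVER_KINDS = ("single_site_move", "within_hrr_move", "cross_hrr_multisite_move")

CLAIM_COLUMNS = [
    "claim_id",
    "physician_id",
    "patient_id",
    "service_date",
    "billing_zip",
    "file_source",
    "dx",
    "proc_biopsy",
    "proc_cancer_surgery",
]


# ---------------------------------------------------------------------------
# geography


def generate_crosswalk(
    n_hrrs: int,
    zips_per_hrr: int,
    rural_fraction: float,
    seed: int,
    rural_ruca_codes=DEFAULT_RURAL_RUCA,
) -> pd.DataFrame:
    """Synthetic ZIP->HRR->RUCA crosswalk.

    Exactly floor(rural_fraction * n_zips + 0.5) ZIPs are rural (half-up
    rounding); which ones is a seeded permutation. RUCA codes are drawn
    from the rural or urban side of `rural_ruca_codes`, and rural_flag is
    by construction the dichotomy of the RUCA code.
    """
    if n_hrrs < 1 or zips_per_hrr < 2:
        raise InvalidConfigError("need n_hrrs >= 1 and zips_per_hrr >= 2")
    if not 0 <= rural_fraction <= 1:
        raise InvalidConfigError("rural_fraction must be in [0, 1]")
    rural_codes = sorted(rural_ruca_codes)
    urban_codes = sorted(set(range(1, 11)) - set(rural_codes))
    if rural_fraction > 0 and not rural_codes:
        raise InvalidConfigError("rural_fraction > 0 needs rural RUCA codes")
    if rural_fraction < 1 and not urban_codes:
        raise InvalidConfigError("rural_fraction < 1 needs urban RUCA codes")
    rng = spawn_rng(seed, 0)
    n = n_hrrs * zips_per_hrr
    zips = [f"{h:02d}{k:03d}" for h in range(n_hrrs) for k in range(zips_per_hrr)]
    hrrs = [f"HRR{h:03d}" for h in range(n_hrrs) for _ in range(zips_per_hrr)]
    n_rural = int(np.floor(rural_fraction * n + 0.5))
    rural = np.zeros(n, dtype=bool)
    rural[rng.permutation(n)[:n_rural]] = True
    ruca = np.where(
        rural,
        rng.choice(rural_codes or [4], size=n),
        rng.choice(urban_codes or [1], size=n),
    )
    return pd.DataFrame(
        {"zip": zips, "hrr_id": hrrs, "ruca_code": ruca, "rural_flag": rural}
    )


# ---------------------------------------------------------------------------
# population


def _taxonomy_list(specialty: str, rng) -> str:
    """First-three taxonomy list containing the specialty code once, mixed
    with generic internal/family-medicine codes."""
    if specialty == "other":
        return rng.choice(TAXONOMY["other"])
    code = rng.choice(TAXONOMY[specialty])
    length = int(rng.integers(1, 4))
    pos = int(rng.integers(0, length))
    listed = [rng.choice(TAXONOMY["other"]) for _ in range(length)]
    listed[pos] = code
    return ";".join(listed)


def _pick_zip(rng, crosswalk, hrr, exclude=(), match_rural=None):
    sub = crosswalk[crosswalk["hrr_id"] == hrr]
    sub = sub[~sub["zip"].isin(exclude)]
    if match_rural is not None and (sub["rural_flag"] == match_rural).any():
        sub = sub[sub["rural_flag"] == match_rural]
    if sub.empty:
        raise InvalidConfigError(f"no ZIP available in {hrr} excluding {exclude}")
    return sub["zip"].iloc[int(rng.integers(0, len(sub)))]


def generate_population(
    config: SimulationConfig, crosswalk: pd.DataFrame, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Physicians (with planted trajectories) and patients (with planted
    eligibility-violation categories, allocated exactly by largest
    remainder)."""
    config.validate()
    rng = spawn_rng(seed, 1)
    hrr_ids = sorted(crosswalk["hrr_id"].unique())

    # --- physicians -------------------------------------------------------
    rows = []
    idx = 0
    for specialty in list(SPECIALTIES) + ["other"]:
        count = (
            config.specialty_counts.get(specialty, 0)
            if specialty != "other"
            else config.n_other_physicians
        )
        for _ in range(count):
            hrr = hrr_ids[int(rng.integers(0, len(hrr_ids)))]
            rows.append(
                {
                    "physician_id": f"D{idx:05d}",
                    "specialty_truth": specialty,
                    "sex": "M" if rng.random() < config.male_fraction else "F",
                    "taxonomy_codes": _taxonomy_list(specialty, rng),
                    "home_hrr": hrr,
                    "home_zip": _pick_zip(rng, crosswalk, hrr),
                    "attractiveness": float(rng.lognormal(0.0, config.attractiveness_sigma)),
                    "trajectory_kind": "non_mover",
                    "alt_zip": "",
                    "to_zip": "",
                    "to_zip2": "",
                    "departure_year": np.nan,
                    "departure_year2": np.nan,
                    "move_date": pd.NaT,
                    "move_date2": pd.NaT,
                    "exit_year": np.nan,
                    "entry_year": np.nan,
                }
            )
            idx += 1
    docs = pd.DataFrame(rows)

    onc_idx = docs.index[docs["specialty_truth"] != "other"].to_numpy()
    n_onc = len(onc_idx)
    n_mov = int(np.floor(config.mover_fraction * n_onc + 0.5))
    kind_names = list(config.mover_kind_mix)
    kind_counts = (
        largest_remainder(np.array([config.mover_kind_mix[k] for k in kind_names]), n_mov)
        if n_mov
        else np.zeros(len(kind_names), int)
    )
    n_multi = int(np.floor(config.multi_year_mover_fraction * n_onc + 0.5))
    n_attr = int(np.floor(config.attrition_fraction * n_onc + 0.5))
    if n_mov + n_multi + n_attr > n_onc:
        raise InvalidConfigError("mover/attrition fractions exceed the oncologist count")
    if len(hrr_ids) < 2 and dict(zip(kind_names, kind_counts)).get(
        "cross_hrr_multisite_move", 0
    ):
        raise InvalidConfigError("cross-HRR trajectories need at least 2 HRRs")
    dep_choices = list(config.years[1:])
    if n_multi and len(dep_choices) < 2:
        raise InvalidConfigError("multi-year movers need at least 3 study years")

    perm = rng.permutation(onc_idx)
    cursor = 0
    assigned = []
    for kind, cnt in zip(kind_names, kind_counts):
        assigned += [(i, kind) for i in perm[cursor : cursor + cnt]]
        cursor += cnt
    assigned += [(i, "multi_year_move") for i in perm[cursor : cursor + n_multi]]
    cursor += n_multi
    attrition = perm[cursor : cursor + n_attr]
    cursor += n_attr
    rest = perm[cursor:]
    n_out = int(np.floor(config.outreach_fraction * len(rest) + 0.5))
    assigned += [(i, "outreach_multisite") for i in rest[:n_out]]

    for i, kind in assigned:
        docs.loc[i, "trajectory_kind"] = kind
        home_hrr = docs.loc[i, "home_hrr"]
        home_zip = docs.loc[i, "home_zip"]
        home_rural = bool(
            crosswalk.loc[crosswalk["zip"] == home_zip, "rural_flag"].iloc[0]
        )
        if kind in ("outreach_multisite", "cross_hrr_multisite_move"):
            docs.loc[i, "alt_zip"] = _pick_zip(
                rng, crosswalk, home_hrr, exclude=[home_zip], match_rural=home_rural
            )
        if kind == "within_hrr_move":
            docs.loc[i, "to_zip"] = _pick_zip(rng, crosswalk, home_hrr, [home_zip])
        elif kind in ("single_site_move", "cross_hrr_multisite_move", "multi_year_move"):
            others = [h for h in hrr_ids if h != home_hrr] or [home_hrr]
            dest = others[int(rng.integers(0, len(others)))]
            to_zip = _pick_zip(rng, crosswalk, dest, [home_zip])
            docs.loc[i, "to_zip"] = to_zip
            if kind == "cross_hrr_multisite_move":
                docs.loc[i, "to_zip2"] = _pick_zip(rng, crosswalk, dest, [to_zip])
            elif kind == "multi_year_move":
                dest2 = others[int(rng.integers(0, len(others)))]
                docs.loc[i, "to_zip2"] = _pick_zip(rng, crosswalk, dest2, [to_zip])
        if kind == "multi_year_move":
            y1, y2 = sorted(
                rng.choice(dep_choices, size=2, replace=False).tolist()
            )
            docs.loc[i, "departure_year"] = y1
            docs.loc[i, "departure_year2"] = y2
            docs.loc[i, "move_date"] = _move_date(rng, y1)
            docs.loc[i, "move_date2"] = _move_date(rng, y2)
        elif kind in MOVER_KINDS:
            y = int(rng.choice(dep_choices))
            docs.loc[i, "departure_year"] = y
            docs.loc[i, "move_date"] = _move_date(rng, y)
    docs.loc[attrition, "exit_year"] = config.years[1]
    # every exit is matched by a same-specialty entrant joining the
    # following year, so workforce capacity (hence every survivor's
    # expected patient load) stays stationary across calendar years
    entrant_rows = []
    for i in attrition:
        hrr = hrr_ids[int(rng.integers(0, len(hrr_ids)))]
        specialty = docs.loc[i, "specialty_truth"]
        entrant_rows.append(
            {
                "physician_id": f"D{len(docs) + len(entrant_rows):05d}",
                "specialty_truth": specialty,
                "sex": "M" if rng.random() < config.male_fraction else "F",
                "taxonomy_codes": _taxonomy_list(specialty, rng),
                "home_hrr": hrr,
                "home_zip": _pick_zip(rng, crosswalk, hrr),
                "attractiveness": float(
                    rng.lognormal(0.0, config.attractiveness_sigma)
                ),
                "trajectory_kind": "non_mover",
                "alt_zip": "",
                "to_zip": "",
                "to_zip2": "",
                "departure_year": np.nan,
                "departure_year2": np.nan,
                "move_date": pd.NaT,
                "move_date2": pd.NaT,
                "exit_year": np.nan,
                "entry_year": config.years[1] + 1,
            }
        )
    if entrant_rows:
        docs = pd.concat([docs, pd.DataFrame(entrant_rows)], ignore_index=True)

    # referral communities: stable practice clusters within each HRR
    comm_rng = spawn_rng(seed, 10)
    docs["community"] = ""
    for hrr, idx in docs.groupby("home_hrr").groups.items():
        n_comm = max(1, int(round(len(idx) / config.community_size)))
        labels = comm_rng.integers(0, n_comm, size=len(idx))
        docs.loc[idx, "community"] = [f"{hrr}:c{int(c)}" for c in labels]

    # --- patients ---------------------------------------------------------
    categories = ["eligible"] + list(config.ineligible_fractions)
    fracs = np.array(
        [1 - sum(config.ineligible_fractions.values())]
        + [config.ineligible_fractions[c] for c in categories[1:]]
    )
    counts = largest_remainder(fracs, config.n_patients)
    cat_col = np.repeat(categories, counts)

    start = pd.Timestamp(config.years[0], 1, 1)
    end = pd.Timestamp(config.years[-1], 12, 31)
    # cycle diagnosis years so every calendar year accrues the same
    # patient volume (and each planted category is spread over years):
    # the four study years are then statistically exchangeable
    diag_year = np.array([config.years[i % len(config.years)] for i in range(config.n_patients)])
    biopsy_lo = np.where(cat_col == "prevalent", 75, 0)
    biopsy_off = rng.integers(biopsy_lo, 274)  # through ~Oct 1, room to confirm
    biopsy = pd.to_datetime(
        {"year": diag_year, "month": 1, "day": 1}
    ) + pd.to_timedelta(biopsy_off, unit="D")

    age_hi = min(95, config.age_range[1])
    ages = rng.integers(config.age_range[0], age_hi + 1, size=config.n_patients)
    ages = np.where(cat_col == "age", rng.integers(62, 66, size=config.n_patients), ages)

    cancers = rng.choice(
        list(config.cancer_type_mix),
        size=config.n_patients,
        p=_norm(list(config.cancer_type_mix.values())),
    )
    races = rng.choice(
        list(config.race_mix),
        size=config.n_patients,
        p=_norm(list(config.race_mix.values())),
    )
    p_female = np.where(cancers == "breast", 0.99, 0.45)
    sexes = np.where(rng.random(config.n_patients) < p_female, "F", "M")
    hrr_pick = rng.integers(0, len(hrr_ids), size=config.n_patients)

    full_enroll = f"{(start - pd.Timedelta(days=370)).date()}:{(end + pd.Timedelta(days=370)).date()}"
    patients = pd.DataFrame(
        {
            "patient_id": [f"P{i:06d}" for i in range(config.n_patients)],
            "birth_date": _birth_dates(biopsy, ages, rng),
            "sex": sexes,
            "race_ethnicity": races,
            "cancer_type": cancers,
            "biopsy_date": biopsy,
            "home_hrr": [hrr_ids[h] for h in hrr_pick],
            "truth_category": cat_col,
            "planted_role": "base",
            "enrollment": full_enroll,
        }
    )
    gap = patients["truth_category"] == "enrollment"
    if gap.any():
        b = patients.loc[gap, "biopsy_date"]
        patients.loc[gap, "enrollment"] = [
            f"{(start - pd.Timedelta(days=370)).date()}:{(d + pd.Timedelta(days=100)).date()};"
            f"{(d + pd.Timedelta(days=200)).date()}:{(end + pd.Timedelta(days=370)).date()}"
            for d in b
        ]
    patients["prevalent_flag"] = patients["truth_category"] == "prevalent"
    return patients, docs


def _norm(v):
    v = np.asarray(v, float)
    return v / v.sum()


def _move_date(rng, year: int) -> pd.Timestamp:
    return pd.Timestamp(int(year), 7, 1) + pd.Timedelta(days=int(rng.integers(-45, 46)))


def _birth_dates(biopsy, ages, rng):
    """Birth dates giving exactly the requested completed age at biopsy."""
    out = []
    extra = rng.integers(0, 300, size=len(ages))
    for b, a, e in zip(biopsy, ages, extra):
        base = pd.Timestamp(b.year - int(a), b.month, min(b.day, 28))
        out.append(base - pd.Timedelta(days=int(e)))
    return out


# ---------------------------------------------------------------------------
# billing geography as a pure function of the calendar date


def billing_zips_for(doc, dates: pd.Series) -> np.ndarray:
    """Vectorized billing ZIP for one physician truth row at given dates."""
    kind = doc["trajectory_kind"]
    dates = pd.to_datetime(pd.Series(dates).reset_index(drop=True))
    home = doc["home_zip"]
    # multi-site practices visit the secondary site in months 4 and 8:
    # at least two ZIP transitions every year (never mistaken for a
    # move), while the primary site keeps the plurality of claims
    alt_month = dates.dt.month.isin((4, 8)).to_numpy()
    if kind == "non_mover":
        return np.full(len(dates), home, dtype=object)
    if kind == "outreach_multisite":
        return np.where(alt_month, doc["alt_zip"], home)
    if kind in ("single_site_move", "within_hrr_move"):
        return np.where(dates < doc["move_date"], home, doc["to_zip"])
    if kind == "cross_hrr_multisite_move":
        pre = np.where(alt_month, doc["alt_zip"], home)
        post = np.where(alt_month, doc["to_zip2"], doc["to_zip"])
        return np.where(dates < doc["move_date"], pre, post)
    if kind == "multi_year_move":
        return np.where(
            dates < doc["move_date"],
            home,
            np.where(dates < doc["move_date2"], doc["to_zip"], doc["to_zip2"]),
        )
    raise InvalidConfigError(f"unknown trajectory kind {kind!r}")


# ---------------------------------------------------------------------------
# claims


@dataclass
class SyntheticStudy:
    """Bundle of generator outputs plus ground-truth labels."""

    seed: int
    config: SimulationConfig
    crosswalk: pd.DataFrame
    patients: pd.DataFrame
    physicians: pd.DataFrame
    claims: pd.DataFrame
    truth: dict = field(default_factory=dict)


class _ClaimSink:
    """Accumulates claim rows cheaply before the final table build."""

    def __init__(self):
        self.rows = {
            "physician_id": [],
            "patient_id": [],
            "service_date": [],
            "file_source": [],
            "dx": [],
            "proc_biopsy": [],
            "proc_cancer_surgery": [],
        }

    def add(self, phys, pat, date, source="carrier", dx="", biopsy=False, surgery=False):
        r = self.rows
        r["physician_id"].append(phys)
        r["patient_id"].append(pat)
        r["service_date"].append(date)
        r["file_source"].append(source)
        r["dx"].append(dx)
        r["proc_biopsy"].append(biopsy)
        r["proc_cancer_surgery"].append(surgery)

    def add_many(self, phys_arr, pat_arr, date_arr, source="carrier", dx_arr=None,
                 biopsy=False, surgery=False):
        n = len(phys_arr)
        r = self.rows
        r["physician_id"].extend(phys_arr)
        r["patient_id"].extend(pat_arr)
        r["service_date"].extend(date_arr)
        r["file_source"].extend([source] * n)
        r["dx"].extend(dx_arr if dx_arr is not None else [""] * n)
        r["proc_biopsy"].extend([biopsy] * n)
        r["proc_cancer_surgery"].extend([surgery] * n)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        df["service_date"] = pd.to_datetime(df["service_date"])
        return df


def _team_pools(docs: pd.DataFrame):
    pools = {}
    cols = ["physician_id", "home_hrr", "community", "attractiveness",
            "exit_year", "entry_year"]
    for specialty in list(SPECIALTIES) + ["other"]:
        sub = docs[docs["specialty_truth"] == specialty]
        pools[specialty] = sub[cols].reset_index(drop=True)
    return pools


def _draw_specialty(pool, hrrs, years_ok, leak, rng, communities=None):
    """Draw one physician of a specialty per patient.

    Preference order: the referral community (when given), the home HRR,
    anywhere; cross-HRR "leakage" patients skip the local preference.
    Physicians must be active (exit/entry years) through the patient's
    follow-up year."""
    n = len(hrrs)
    out = np.empty(n, dtype=object)
    comm = communities if communities is not None else np.full(n, "", dtype=object)
    key = pd.DataFrame({"hrr": hrrs, "comm": comm, "ymax": years_ok, "leak": leak})
    for (hrr, cm, ymax, lk), grp in key.groupby(
        ["hrr", "comm", "ymax", "leak"], sort=True
    ):
        ok = (pool["exit_year"].isna() | (pool["exit_year"] >= ymax)) & (
            pool["entry_year"].isna() | (pool["entry_year"] <= ymax)
        )
        if lk:
            cand = pool[ok]
        else:
            cand = pool.iloc[0:0]
            if cm:
                cand = pool[ok & (pool["community"] == cm)]
            if cand.empty:
                cand = pool[ok & (pool["home_hrr"] == hrr)]
        if cand.empty:
            cand = pool[ok]
        if cand.empty:
            raise InvalidConfigError("no active physician available for a care team")
        w = _norm(cand["attractiveness"].to_numpy())
        pick = rng.choice(len(cand), size=len(grp), p=w)
        out[grp.index.to_numpy()] = cand["physician_id"].to_numpy()[pick]
    return out


def simulate_claims(
    patients: pd.DataFrame,
    physicians: pd.DataFrame,
    crosswalk: pd.DataFrame,
    effect_plan: EffectPlan,
    years,
    seed: int,
    config: SimulationConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate the claim table; returns (claims, patients_out, truth).

    `patients_out` extends the input with planted connection/effect
    patients. `truth` holds the mover-connection table and per-year
    exposure counts implied by the planted and naturally arising
    shared-patient relationships.
    """
    config = config or SimulationConfig()
    rural_by_zip = dict(zip(crosswalk["zip"], crosswalk["rural_flag"]))
    if (
        effect_plan.rural_strength_effect_per_connection
        or effect_plan.rural_volume_effect_per_connection
    ) and not any(rural_by_zip.values()):
        raise InvalidConfigError("rural effects planted but the crosswalk has no rural ZIPs")

    rng_team = spawn_rng(seed, 2)
    rng_enc = spawn_rng(seed, 3)
    rng_anchor = spawn_rng(seed, 4)
    rng_conn = spawn_rng(seed, 5)
    rng_eff = spawn_rng(seed, 6)

    start = pd.Timestamp(years[0], 1, 1)
    end = pd.Timestamp(years[-1], 12, 31)
    sink = _ClaimSink()
    pools = _team_pools(physicians)

    # --- per-patient care teams and encounters ---------------------------
    pats = patients.reset_index(drop=True)
    n = len(pats)
    biopsy = pd.to_datetime(pats["biopsy_date"])
    ymax = biopsy.dt.year  # team members must still bill the diagnosis year
    leak = rng_team.random(n) < config.cross_hrr_leakage
    hrrs = pats["home_hrr"].to_numpy()

    team = {}
    team["medical oncology"] = _draw_specialty(
        pools["medical oncology"], hrrs, ymax, leak, rng_team
    )
    # remaining roles are drawn from the medical oncologist's referral
    # community with high probability
    community_of = dict(zip(physicians["physician_id"], physicians["community"]))
    med_comm = np.array(
        [community_of[m] for m in team["medical oncology"]], dtype=object
    )
    in_comm = rng_team.random(n) < config.community_prob
    comm_pref = np.where(in_comm & ~leak, med_comm, "")
    for specialty in ("surgery", "other"):
        team[specialty] = _draw_specialty(
            pools[specialty], hrrs, ymax, leak, rng_team, communities=comm_pref
        )
    rad_p = pats["cancer_type"].map(config.radiation_prob_by_cancer).fillna(0.5)
    has_rad = rng_team.random(n) < rad_p.to_numpy()
    if len(pools["radiation oncology"]):
        team["radiation oncology"] = _draw_specialty(
            pools["radiation oncology"], hrrs, ymax, leak, rng_team,
            communities=comm_pref,
        )
    else:
        has_rad[:] = False
        team["radiation oncology"] = np.empty(n, dtype=object)

    codes = pats["cancer_type"].map(DX_CODE).to_numpy()
    cat = pats["truth_category"].to_numpy()
    pid = pats["patient_id"].to_numpy()
    b_arr = biopsy.to_numpy()
    day = pd.Timedelta(days=1)

    surg = team["surgery"]
    med = team["medical oncology"]
    pcp = team["other"]
    sink.add_many(surg, pid, b_arr, dx_arr=list(codes), biopsy=True)
    # procedure claims carry no dx code: only the planted confirmatory
    # claims may count toward the two-diagnosis rule
    sink.add_many(surg, pid, b_arr + 21 * day, "medpar", surgery=True)
    sink.add_many(med, pid, b_arr + 10 * day, dx_arr=list(codes))
    confirm2 = cat != "no_confirmatory_dx"
    sink.add_many(
        med[confirm2], pid[confirm2], (b_arr + 40 * day)[confirm2],
        dx_arr=list(codes[confirm2]),
    )
    prev = cat == "prevalent"
    sink.add_many(pcp[prev], pid[prev], (b_arr - 60 * day)[prev], dx_arr=list(codes[prev]))

    # extra evaluation/management encounters: inside the care window and
    # the diagnosis calendar year, so the four study years stay
    # exchangeable (cross-year ties arise from recurring team draws, not
    # from individual patients straddling a year boundary)
    year_start = pd.to_datetime({"year": biopsy.dt.year, "month": 1, "day": 1})
    year_end = pd.to_datetime({"year": biopsy.dt.year, "month": 12, "day": 31})
    lo = np.maximum((biopsy - pd.Timedelta(days=91)).to_numpy(), year_start.to_numpy())
    hi = np.minimum((biopsy + pd.Timedelta(days=364)).to_numpy(), year_end.to_numpy())
    lo_d = lo.astype("datetime64[D]").astype(int)
    hi_d = hi.astype("datetime64[D]").astype(int)
    for role, base_n in [
        ("medical oncology", 2),
        ("radiation oncology", 2),
        ("surgery", 1),
        ("other", 1),
    ]:
        mask = has_rad if role == "radiation oncology" else np.ones(n, bool)
        counts = (1 + rng_enc.poisson(base_n - 1, size=n)) * mask
        rep = np.repeat(np.arange(n), counts)
        dates = rng_enc.integers(lo_d[rep], hi_d[rep] + 1).astype("datetime64[D]")
        sink.add_many(team[role][rep], pid[rep], dates)

    # --- monthly anchor visits (never cohort patients) --------------------
    anchor_pool = pats.loc[
        pats["truth_category"].isin(["prevalent", "age", "no_confirmatory_dx"]),
        "patient_id",
    ].to_numpy()
    if not len(anchor_pool):
        anchor_pool = pid[:1]
    for doc in physicians.itertuples(index=False):
        apid = anchor_pool[int(rng_anchor.integers(0, len(anchor_pool)))]
        active = [
            y for y in years
            if (np.isnan(doc.exit_year) or y <= doc.exit_year)
            and (np.isnan(doc.entry_year) or y >= doc.entry_year)
        ]
        dates = [pd.Timestamp(y, m, 15) for y in active for m in range(1, 13)]
        sink.add_many([doc.physician_id] * len(dates), [apid] * len(dates), dates)

    # --- planted mover connections ---------------------------------------
    new_patients = []
    next_pid = n

    def _new_patient(home_hrr, year, role):
        nonlocal next_pid
        pid_new = f"P{next_pid:06d}"
        next_pid += 1
        b = pd.Timestamp(int(year), 4, 1) + pd.Timedelta(days=int(rng_eff.integers(0, 61)))
        age = int(rng_eff.integers(66, 96))
        new_patients.append(
            {
                "patient_id": pid_new,
                "birth_date": pd.Timestamp(b.year - age, b.month, min(b.day, 28))
                - pd.Timedelta(days=int(rng_eff.integers(0, 300))),
                "sex": "F" if rng_eff.random() < 0.7 else "M",
                "race_ethnicity": rng_eff.choice(
                    list(config.race_mix), p=_norm(list(config.race_mix.values()))
                ),
                "cancer_type": rng_eff.choice(
                    list(config.cancer_type_mix),
                    p=_norm(list(config.cancer_type_mix.values())),
                ),
                "biopsy_date": b,
                "home_hrr": home_hrr,
                "truth_category": "eligible",
                "planted_role": role,
                "enrollment": f"{(start - pd.Timedelta(days=370)).date()}:"
                f"{(end + pd.Timedelta(days=370)).date()}",
                "prevalent_flag": False,
            }
        )
        return pid_new, b

    def _cancer_claims(pid_new, b, biller, surgeon_truth):
        code = DX_CODE["breast"]
        sink.add(biller, pid_new, b, dx=code, biopsy=True)
        sink.add(biller, pid_new, b + 10 * day, dx=code)
        sink.add(biller, pid_new, b + 40 * day, dx=code)
        if surgeon_truth:
            sink.add(biller, pid_new, b + 21 * day, "medpar", surgery=True)

    specialty_of = dict(zip(physicians["physician_id"], physicians["specialty_truth"]))
    docs_by_id = physicians.set_index("physician_id")

    movers = physicians[physicians["trajectory_kind"].isin(MOVER_KINDS)]
    recipients = physicians[
        (physicians["specialty_truth"] != "other")
        & physicians["trajectory_kind"].isin(["non_mover", "outreach_multisite"])
        & physicians["exit_year"].isna()
        & physicians["entry_year"].isna()
    ].reset_index(drop=True)
    planted_pairs = set()
    if len(recipients):
        z = np.log(recipients["attractiveness"].to_numpy())
        z = (z - z.mean()) / (z.std() or 1.0)
        sel_w = np.exp(effect_plan.confounding_strength * z)
        for m in movers.itertuples(index=False):
            y = int(m.departure_year)
            local = recipients.index[
                (recipients["home_hrr"] == m.home_hrr)
                & (recipients["physician_id"] != m.physician_id)
            ].to_numpy()
            if not len(local):
                local = recipients.index.to_numpy()
            mean_c = max(config.mean_connections_per_mover - 1, 0.0)
            n_c = min(1 + rng_conn.poisson(mean_c), len(local))
            p = _norm(sel_w[local])
            chosen = rng_conn.choice(local, size=n_c, replace=False, p=p)
            for ridx in chosen:
                r = recipients.iloc[ridx]
                planted_pairs.add((r["physician_id"], m.physician_id, y))
                # the planted relationship is stationary: the pair shares
                # total//2 patients every study year, so connecting to a
                # future mover carries no onset/offset jump in any outcome
                total = int(rng_conn.choice([2, 4, 6], p=[0.5, 0.35, 0.15]))
                for yr in years:
                    for _ in range(total // 2):
                        pid_new, b = _new_patient(r["home_hrr"], yr, "connection")
                        _cancer_claims(
                            pid_new, b, r["physician_id"],
                            r["specialty_truth"] == "surgery",
                        )
                        sink.add(m.physician_id, pid_new, b + 14 * day)
                        if m.specialty_truth == "surgery":
                            sink.add(
                                m.physician_id, pid_new, b + 17 * day, "medpar",
                                surgery=True,
                            )

    # --- realized connections and planted effects -------------------------
    base_claims = sink.frame()
    pats_all = pd.concat(
        [pats, pd.DataFrame(new_patients)], ignore_index=True
    ) if new_patients else pats
    cohort_truth = pats_all[pats_all["truth_category"] == "eligible"][
        ["patient_id", "biopsy_date"]
    ]
    nets = {
        y: build_annual_network(base_claims, cohort_truth, y) for y in years
    }

    conn_rows = []
    for m in movers.itertuples(index=False):
        y = int(m.departure_year)
        w_prev = nets[y - 1].neighbors(m.physician_id)
        w_dep = nets[y].neighbors(m.physician_id)
        for r_id in set(w_prev) | set(w_dep):
            total = w_prev.get(r_id, 0) + w_dep.get(r_id, 0)
            if total < 2:
                continue
            if specialty_of.get(r_id, "other") == "other":
                continue
            rdoc = docs_by_id.loc[r_id]
            if (
                rdoc["trajectory_kind"] == "multi_year_move"
                or not np.isnan(rdoc["exit_year"])
                or not np.isnan(rdoc["entry_year"])
            ):
                continue
            if not np.isnan(rdoc["departure_year"]) and y >= rdoc["departure_year"]:
                continue  # not retained in the departure year
            conn_rows.append(
                {
                    "physician_id": r_id,
                    "mover_id": m.physician_id,
                    "departure_year": y,
                    "w_prev": w_prev.get(r_id, 0),
                    "w_dep": w_dep.get(r_id, 0),
                    "planted": (r_id, m.physician_id, y) in planted_pairs,
                    "same_specialty": specialty_of[r_id] == m.specialty_truth,
                }
            )
    connections = pd.DataFrame(
        conn_rows,
        columns=[
            "physician_id", "mover_id", "departure_year", "w_prev", "w_dep",
            "planted", "same_specialty",
        ],
    )

    if not effect_plan.is_null() and len(connections):
        _plant_effects(
            sink, connections, docs_by_id, rural_by_zip, effect_plan, nets,
            years, physicians, rng_eff, _new_patient, _cancer_claims,
        )

    # --- finalize ---------------------------------------------------------
    claims = sink.frame()
    zips = np.empty(len(claims), dtype=object)
    for phys, grp in claims.groupby("physician_id", sort=False):
        zips[grp.index.to_numpy()] = billing_zips_for(
            docs_by_id.loc[phys], grp["service_date"]
        )
    claims["billing_zip"] = zips
    claims = claims.sort_values(
        ["physician_id", "service_date", "patient_id", "file_source", "dx"],
        kind="stable",
    ).reset_index(drop=True)
    claims.insert(0, "claim_id", [f"C{i:08d}" for i in range(len(claims))])
    claims = claims[CLAIM_COLUMNS]

    pats_out = pd.concat(
        [pats, pd.DataFrame(new_patients)], ignore_index=True
    ) if new_patients else pats

    exposure = (
        connections.groupby(["physician_id", "departure_year"])
        .agg(
            exposure_any=("mover_id", "size"),
            exposure_same_specialty=("same_specialty", "sum"),
        )
        .reset_index()
        if len(connections)
        else pd.DataFrame(
            columns=["physician_id", "departure_year", "exposure_any",
                     "exposure_same_specialty"]
        )
    )
    truth = {"connections": connections, "exposure": exposure}
    return claims, pats_out, truth


def _plant_effects(
    sink, connections, docs_by_id, rural_by_zip, plan, nets, years,
    physicians, rng, new_patient, cancer_claims,
):
    """Apply the effect plan, one connection event at a time.

    Strength enters as extra shared-patient weight, volume as extra
    unique patients, and the urban transitivity effect as closed open
    neighbor pairs. Every strength increment rides on a "hub" patient
    seen only by the focal physician and non-oncologist partner
    physicians, so planting never leaks weight onto other analyzed
    oncologists and never changes who counts as connected to a
    departing oncologist. The planted relationships are renewed in
    every year from the departure year to the end of the study: the
    departure shifts the physician's level once (the full effect
    appears in the departure-year change), and later-year changes are
    unaffected.
    """
    day = pd.Timedelta(days=1)
    partners = physicians[
        (physicians["specialty_truth"] == "other")
        & physicians["exit_year"].isna()
        & physicians["entry_year"].isna()
    ]
    partner_by_hrr = {
        h: g["physician_id"].to_numpy() for h, g in partners.groupby("home_hrr")
    }
    all_partners = partners["physician_id"].to_numpy()
    noise = plan.noise_scales
    mover_ids = set(connections["mover_id"])

    for conn in connections.itertuples(index=False):
        r = conn.physician_id
        y = int(conn.departure_year)
        rdoc = docs_by_id.loc[r]
        rural = bool(rural_by_zip.get(rdoc["home_zip"], False))
        if rural:
            s_eff = plan.rural_strength_effect_per_connection
            v_eff = plan.rural_volume_effect_per_connection
            t_eff = 0.0
        else:
            s_eff, v_eff = 0.0, 0.0
            t_eff = plan.urban_transitivity_effect
        if noise.get("strength"):
            s_eff += rng.normal(0, noise["strength"])
        if noise.get("volume"):
            v_eff += rng.normal(0, noise["volume"])
        if noise.get("transitivity"):
            t_eff += rng.normal(0, noise["transitivity"])
        s_int, v_int = stochastic_round(s_eff, rng), stochastic_round(v_eff, rng)
        shared_new = min(s_int, v_int)
        solo_new = v_int - shared_new
        remaining = s_int - shared_new
        hrr_partners = partner_by_hrr.get(rdoc["home_hrr"], all_partners)
        if not len(hrr_partners):
            hrr_partners = all_partners

        is_surgeon = rdoc["specialty_truth"] == "surgery"
        extra_hub = remaining > 0 and shared_new == 0
        for yr in range(y, years[-1] + 1):  # the new relationships persist
            hubs = []  # (patient, biopsy, partner ids already on the patient)
            for _ in range(solo_new):
                pid_new, b = new_patient(rdoc["home_hrr"], yr, "effect_volume")
                cancer_claims(pid_new, b, r, is_surgeon)
            n_hubs = shared_new + (1 if extra_hub else 0)
            left = remaining - (1 if extra_hub else 0)
            for _ in range(n_hubs):
                pid_new, b = new_patient(rdoc["home_hrr"], yr, "effect_strength")
                cancer_claims(pid_new, b, r, is_surgeon)
                partner = hrr_partners[int(rng.integers(0, len(hrr_partners)))]
                sink.add(partner, pid_new, b + 14 * day)
                hubs.append((pid_new, b, {partner}))
            for t in range(left):
                pid_h, b_h, used = hubs[t % len(hubs)]
                partner = None
                for _ in range(20):
                    cand = hrr_partners[int(rng.integers(0, len(hrr_partners)))]
                    if cand not in used:
                        partner = cand
                        break
                if partner is None:
                    continue
                used.add(partner)
                sink.add(partner, pid_h, b_h + 15 * day + t * day)

        n_close = stochastic_round(t_eff, rng)
        if n_close:
            nbrs = [
                j for j in nets[y].neighbors(r)
                if j in docs_by_id.index
                and j not in mover_ids
                and docs_by_id.loc[j, "trajectory_kind"]
                in ("non_mover", "outreach_multisite")
            ]
            closed = 0
            for _ in range(20 * n_close):
                if closed >= n_close or len(nbrs) < 2:
                    break
                j, q = rng.choice(len(nbrs), size=2, replace=False)
                j, q = nbrs[int(j)], nbrs[int(q)]
                if nets[y].weight(j, q):
                    continue
                for yr in range(y, years[-1] + 1):  # the closed tie persists
                    pid_new, b = new_patient(
                        rdoc["home_hrr"], yr, "effect_transitivity"
                    )
                    cancer_claims(
                        pid_new, b, j,
                        docs_by_id.loc[j, "specialty_truth"] == "surgery",
                    )
                    sink.add(q, pid_new, b + 14 * day)
                a, c = (j, q) if j < q else (q, j)
                nets[y].weights[(a, c)] = 1  # mark closed for later draws
                closed += 1


def simulate_study(config: SimulationConfig, seed: int) -> SyntheticStudy:
    """Run the full generator: crosswalk, population, claims, truth."""
    config.validate()
    crosswalk = generate_crosswalk(
        config.n_hrrs,
        config.zips_per_hrr,
        config.rural_fraction,
        seed,
        config.rural_ruca_codes,
    )
    patients, physicians = generate_population(config, crosswalk, seed)
    claims, patients_out, truth = simulate_claims(
        patients, physicians, crosswalk, config.effects, config.years, seed, config
    )
    return SyntheticStudy(
        seed=seed,
        config=config,
        crosswalk=crosswalk,
        patients=patients_out,
        physicians=physicians,
        claims=claims,
        truth=truth,
    )
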