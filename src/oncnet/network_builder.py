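"""Annual physician patient-sharing networks.

One undirected weighted graph per calendar year: nodes are physicians (of
any specialty) with at least one encounter with a cohort patient that
year, and the weight of edge (i, j) is the number of unique cohort
patients with encounters with both i and j during the calendar year.
Encounters only count inside the patient's care window (3 months before
to 12 months after their diagnostic biopsy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError

CARE_WINDOW_MONTHS = (3, 12)  # months before / after the diagnostic biopsy


def care_window(biopsy_date):
    """(start, end] interval of care relevant to one patient's diagnosis."""
    start = biopsy_date - pd.DateOffset(months=CARE_WINDOW_MONTHS[0])
    end = biopsy_date + pd.DateOffset(months=CARE_WINDOW_MONTHS[1])
    return start, end


@dataclass
class AnnualNetwork:
    """Year-indexed undirected weighted graph over physicians.

    `weights` maps frozenset-free canonical pairs (i, j) with i < j to the
    shared-patient count; `adj` maps each node to {neighbor: weight}.
    """

    year: int
    weights: dict = field(default_factory=dict)
    adj: dict = field(default_factory=dict)

    @property
    def nodes(self):
        return self.adj.keys()

    def weight(self, i, j) -> int:
        if i == j:
            return 0
        return self.weights.get((i, j) if i < j else (j, i), 0)

    def degree(self, i) -> int:
        return len(self.adj.get(i, ()))

    def neighbors(self, i):
        return self.adj.get(i, {})

    @property
    def edges(self):
        return self.weights.items()

    @classmethod
    def from_edges(cls, year: int, edges) -> "AnnualNetwork":
        net = cls(year)
        for i, j, w in edges:
            if i == j:
                raise InvalidInputError(f"self-loop on node {i}")
            a, b = (i, j) if i < j else (j, i)
            net.weights[(a, b)] = int(w)
            net.adj.setdefault(a, {})[b] = int(w)
            net.adj.setdefault(b, {})[a] = int(w)
        return net

    def add_isolates(self, nodes):
        for n in nodes:
            self.adj.setdefault(n, {})

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.weights.items())
        return pd.DataFrame(
            [(i, j, w) for (i, j), w in rows], columns=["i", "j", "weight"]
        )


def cohort_year_encounters(
    claims: pd.DataFrame, patient_cohort: pd.DataFrame, year: int
) -> pd.DataFrame:
    """Distinct (patient, physician) encounter pairs for one calendar year,
    restricted to cohort patients and each patient's care window."""
    cohort = patient_cohort[["patient_id", "biopsy_date"]]
    sub = claims[claims["patient_id"].isin(set(cohort["patient_id"]))]
    if sub.empty:
        return sub.iloc[:0][["patient_id", "physician_id"]]
    sub = sub[sub["service_date"].dt.year == year]
    if sub.empty:
        return sub.iloc[:0][["patient_id", "physician_id"]]
    sub = sub.merge(cohort, on="patient_id", how="left")
    start = sub["biopsy_date"] - pd.DateOffset(months=CARE_WINDOW_MONTHS[0])
    end = sub["biopsy_date"] + pd.DateOffset(months=CARE_WINDOW_MONTHS[1])
    sub = sub[(sub["service_date"] >= start) & (sub["service_date"] <= end)]
    return sub[["patient_id", "physician_id"]].drop_duplicates()


def build_annual_network(
    claims: pd.DataFrame, patient_cohort: pd.DataFrame, year: int
) -> AnnualNetwork:
    """Construct the patient-sharing network for one calendar year.

    `patient_cohort` needs columns patient_id and biopsy_date (eligible
    patients only). An empty claim set yields an empty network.
    """
    pairs = cohort_year_encounters(claims, patient_cohort, year)
    net = AnnualNetwork(year)
    if pairs.empty:
        return net
    # join the encounter list with itself patient-wise to enumerate
    # physician pairs, then count unique patients per pair
    merged = pairs.merge(pairs, on="patient_id")
    merged = merged[merged["physician_id_x"] < merged["physician_id_y"]]
    wts = (
        merged.groupby(["physician_id_x", "physician_id_y"], sort=True)["patient_id"]
        .nunique()
    )
    net = AnnualNetwork.from_edges(
        year, ((i, j, w) for (i, j), w in wts.items())
    )
    net.add_isolates(pairs["physician_id"].unique())
    return net


def classify_ties(net_y: AnnualNetwork, net_prev: AnnualNetwork) -> pd.DataFrame:
    """Label every edge of `net_y` persistent (also present in year-1) or
    new (absent in year-1). Ties dropped since the prior year are not an
    outcome and are not emitted."""
    if net_prev.year != net_y.year - 1:
        raise InvalidInputError(
            f"prior-year network is {net_prev.year}, expected {net_y.year - 1}"
        )
    rows = [
        (net_y.year, i, j, "persistent" if (i, j) in net_prev.weights else "new")
        for (i, j) in sorted(net_y.weights)
    ]
    return pd.DataFrame(rows, columns=["year", "i", "j", "status"])
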