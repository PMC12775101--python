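"""Node-level measures on annual patient-sharing networks.

Node strength and the linchpin score use the shared-patient edge
weights; local transitivity and Burt's constraint are computed on the
unweighted skeleton. The linchpin score of an oncologist of specialty s
is the (weight-)fraction of their neighbors of other specialties who
have no tie to specialty s except through the focal oncologist — a high
score marks a locally irreplaceable specialist.

Undefined values (transitivity below degree 2, constraint and linchpin
at degree 0) propagate as None/NaN; they are never imputed as zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, InvalidInputError, MissingNodeError
from .network_builder import AnnualNetwork, cohort_year_encounters

log = logging.getLogger(__name__)


def _require(net: AnnualNetwork, i):
    if i not in net.adj:
        raise MissingNodeError(f"node {i!r} not in the {net.year} network")


def compute_strength(net: AnnualNetwork, i) -> float:
    """Sum of shared-patient edge weights incident to i."""
    _require(net, i)
    return float(sum(net.adj[i].values()))


def compute_local_transitivity(net: AnnualNetwork, i):
    """Fraction of i's neighbor pairs that are themselves connected;
    undefined (None) below degree 2."""
    _require(net, i)
    nbrs = set(net.adj[i])
    k = len(nbrs)
    if k < 2:
        return None
    closed = sum(len(nbrs & net.adj[j].keys()) for j in nbrs) // 2
    return 2.0 * closed / (k * (k - 1))


def compute_constraint(net: AnnualNetwork, i):
    """Burt's constraint on the unweighted skeleton; undefined at degree 0.

    c_i = sum_j (p_ij + sum_q p_iq p_qj)^2 over direct neighbors j, with
    p_ab = 1/degree(a) for each edge (a, b) and q ranging over i's other
    neighbors also tied to j.
    """
    _require(net, i)
    nbrs = net.adj[i]
    k = len(nbrs)
    if k == 0:
        return None
    p_i = 1.0 / k
    total = 0.0
    for j in nbrs:
        indirect = sum(
            p_i / len(net.adj[q]) for q in nbrs if q != j and j in net.adj[q]
        )
        total += (p_i + indirect) ** 2
    return total


def compute_linchpin(net: AnnualNetwork, i, specialty_map, weighted: bool = True):
    """Linchpin score of oncologist i; undefined at degree 0.

    A neighbor j counts toward the numerator when j is of a different
    specialty than i and has no neighbor of i's specialty other than i.
    The weighted form (default) sums shared-patient weights; the
    unweighted form counts neighbors.
    """
    _require(net, i)
    if i not in specialty_map:
        raise InvalidInputError(f"no specialty label for node {i!r}")
    s = specialty_map[i]
    nbrs = net.adj[i]
    if not nbrs:
        return None
    num = den = 0.0
    for j, w in nbrs.items():
        wt = w if weighted else 1.0
        den += wt
        if specialty_map.get(j, "other") == s:
            continue
        if any(
            q != i and specialty_map.get(q, "other") == s for q in net.adj[j]
        ):
            continue
        num += wt
    return num / den


def flag_linchpins(
    scores: pd.Series, specialties: pd.Series, pct: float = 0.15
) -> pd.Series:
    """Flag oncologists whose linchpin score is in the top `pct` of their
    specialty.

    The threshold is the order statistic of rank floor((1-pct)*n)+1 among
    the n defined scores of the specialty (ascending), so with distinct
    scores exactly the top floor(pct*n)-ish are flagged and exact ties at
    the threshold are all flagged. Undefined scores are never flagged;
    specialties with fewer than two defined scores are left unflagged.
    """
    if not 0 < pct < 1:
        raise InvalidConfigError("pct must be in the open interval (0, 1)")
    flags = pd.Series(False, index=scores.index)
    for specialty, idx in scores.groupby(specialties).groups.items():
        vals = scores.loc[idx].dropna()
        if len(vals) < 2:
            log.warning(
                "specialty %r has %d defined linchpin scores; none flagged",
                specialty, len(vals),
            )
            continue
        ordered = np.sort(vals.to_numpy())
        rank = int(np.floor((1 - pct) * len(ordered)))  # 0-based rank+1 below
        threshold = ordered[min(rank, len(ordered) - 1)]
        flags.loc[vals.index[vals >= threshold]] = True
    return flags


def decompose_strength(
    net_y: AnnualNetwork, tie_classes: pd.DataFrame, i
) -> tuple[float, float]:
    """Split node strength into persistent-tie and new-tie components."""
    _require(net_y, i)
    status = {
        (r.i, r.j): r.status for r in tie_classes.itertuples(index=False)
    }
    pers = new = 0.0
    for j, w in net_y.adj[i].items():
        key = (i, j) if i < j else (j, i)
        if status.get(key) == "persistent":
            pers += w
        else:
            new += w
    return pers, new


def compute_volume(
    claims: pd.DataFrame, patient_cohort: pd.DataFrame, i, year: int
) -> int:
    """Unique cohort patients with >= 1 encounter with physician i in the
    calendar year (within each patient's care window)."""
    pairs = cohort_year_encounters(claims, patient_cohort, year)
    return int((pairs["physician_id"] == i).sum())


def compute_node_metrics(
    net: AnnualNetwork,
    specialty_map: dict,
    tie_classes: pd.DataFrame | None = None,
    linchpin_weighted: bool = True,
    linchpin_pct: float = 0.15,
) -> pd.DataFrame:
    """All per-node measures for one annual network in a single pass.

    Linchpin scores (and flags) are computed for oncologists only;
    strength decomposition needs `tie_classes` from the prior year.
    """
    status = None
    if tie_classes is not None:
        status = {
            (r.i, r.j): r.status for r in tie_classes.itertuples(index=False)
        }
    rows = []
    for i in sorted(net.adj):
        nbrs = net.adj[i]
        s = float(sum(nbrs.values()))
        pers = new = np.nan
        if status is not None:
            pers = new = 0.0
            for j, w in nbrs.items():
                key = (i, j) if i < j else (j, i)
                if status.get(key) == "persistent":
                    pers += w
                else:
                    new += w
        linch = np.nan
        if specialty_map.get(i, "other") != "other" and nbrs:
            linch = compute_linchpin(net, i, specialty_map, linchpin_weighted)
        trans = compute_local_transitivity(net, i)
        cons = compute_constraint(net, i)
        rows.append(
            (
                i,
                net.year,
                s,
                np.nan if trans is None else trans,
                np.nan if cons is None else cons,
                linch,
                pers,
                new,
            )
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "physician_id",
            "year",
            "strength",
            "transitivity",
            "constraint",
            "linchpin",
            "strength_persistent",
            "strength_new",
        ],
    )
    specialties = out["physician_id"].map(lambda p: specialty_map.get(p, "other"))
    onc = specialties.isin(["medical oncology", "radiation oncology", "surgery"])
    out["linchpin_flag"] = False
    if onc.any():
        out.loc[onc, "linchpin_flag"] = flag_linchpins(
            out.loc[onc, "linchpin"], specialties[onc], linchpin_pct
        )
    return out
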