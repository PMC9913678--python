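"""Per-individual, per-stratum response variables.

Four indices are computed for every individual in every (phase, season)
stratum it was rostered in:

* **VSC** (vertex strength centrality): summed outgoing grooming percentage
  divided by the number of potential partners ``n - 1`` — the mean
  percentage of co-present scans spent grooming each group member,
  comparable across group sizes.
* **H** (edge weight disparity): the sum of squared shares of the
  individual's outgoing grooming across partners.  ``1/(n-1)`` when
  grooming is spread perfectly evenly, 1 when concentrated on a single
  partner.  Undefined for non-groomers (zero outgoing strength).
* **DEWD** (deviation from edge weight disparity): ``H - 1/(n-1)``, the
  disparity above its even-distribution floor, comparable across group
  sizes; ranges 0 .. (n-2)/(n-1).
* **GAI** (general activity index): ``(A - I)/(A + I)`` over active and
  inactive scan counts, in [-1, 1], 0 meaning activity and inactivity are
  equally frequent.
* **undesired proportion**: scans spent on abnormal or self-directed
  behaviors over all of the individual's scans, in [0, 1].

Undefined cells (no scans, or zero grooming for the disparity measures)
are carried as missing, never imputed.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .networks import GroomingNetwork, Stratum
from .scans import ACTIVE, COLD, INACTIVE, WARM, BehaviorCatalog, Individual, ScanTable, StudyPhase

logger = logging.getLogger("groomnet")

#: Column order of the index table CSV.
INDEX_COLUMNS = [
    "individual",
    "phase",
    "season",
    "group_size",
    "sex_ratio",
    "sex",
    "origin",
    "strength",
    "vsc",
    "disparity",
    "dewd",
    "active",
    "inactive",
    "gai",
    "undesired",
    "total_scans",
]


# ---------------------------------------------------------------------------
# Network-based indices
# ---------------------------------------------------------------------------


def vertex_strength_centrality(net: GroomingNetwork, i: str) -> float:
    """Outgoing strength over ``n - 1`` potential partners.

    Missing (never co-present) edges contribute nothing to the strength but
    the divisor stays ``n - 1`` from the roster: the index explicitly takes
    the group size into account.
    """
    if i not in net.graph:
        raise KeyError(f"{i} is not a node of the network")
    if net.n < 2:
        raise ValueError("group size must be at least 2")
    s = sum(net.out_weights(i).values())
    return s / (net.n - 1)


def edge_weight_disparity(net: GroomingNetwork, i: str) -> float | None:
    """Sum of squared outgoing weight shares; None when i never groomed."""
    if i not in net.graph:
        raise KeyError(f"{i} is not a node of the network")
    weights = np.array(list(net.out_weights(i).values()), float)
    s = weights.sum()
    if s == 0:
        logger.debug("disparity undefined for non-groomer %s in %s", i, net.stratum)
        return None
    shares = weights / s
    return float((shares**2).sum())


def dewd(net: GroomingNetwork, i: str) -> float | None:
    """Disparity above the even-distribution floor ``1/(n-1)``; None if undefined."""
    h = edge_weight_disparity(net, i)
    if h is None:
        return None
    return h - 1.0 / (net.n - 1)


# ---------------------------------------------------------------------------
# Activity-budget indices
# ---------------------------------------------------------------------------


def general_activity_index(active: int, inactive: int) -> float | None:
    """(A - I)/(A + I); None (undefined) when there are no scans at all."""
    if active < 0 or inactive < 0:
        raise ValueError("counts must be non-negative")
    total = active + inactive
    if total == 0:
        logger.debug("GAI undefined: no scans")
        return None
    return (active - inactive) / total


def undesired_proportion(
    table: ScanTable, catalog: BehaviorCatalog, i: str, stratum: Stratum
) -> float | None:
    """Share of i's scans in a stratum spent on undesired behaviors."""
    df = table.df
    mask = (df["individual"] == i) & (df["phase"] == stratum[0]) & (df["season"] == stratum[1])
    total = int(mask.sum())
    if total == 0:
        logger.debug("undesired proportion undefined: %s has no scans in %s", i, stratum)
        return None
    bad = int((df.loc[mask, "behavior"].isin(catalog.undesired_set)).sum())
    return bad / total


def activity_counts(
    table: ScanTable, catalog: BehaviorCatalog, i: str, stratum: Stratum
) -> tuple[int, int]:
    """(active, inactive) scan counts of i in a stratum via the class map."""
    df = table.df
    mask = (df["individual"] == i) & (df["phase"] == stratum[0]) & (df["season"] == stratum[1])
    classes = df.loc[mask, "behavior"].map(catalog.class_map)
    return int((classes == ACTIVE).sum()), int((classes == INACTIVE).sum())


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def build_index_table(
    table: ScanTable,
    nets: Mapping[Stratum, GroomingNetwork] | None,
    phases: Sequence[StudyPhase],
    roster: Sequence[Individual],
    catalog: BehaviorCatalog,
) -> pd.DataFrame:
    """One row per rostered individual per stratum.

    ``nets`` may be None to skip the network indices (their columns are
    then missing values); a stratum with scan data but no network is an
    error when networks are requested.
    """
    if not table.stratified:
        raise ValueError("scan table must be stratified first (assign_strata)")
    by_id = {ind.id: ind for ind in roster}
    df = table.df

    rows = []
    grouped = df.groupby(["individual", "phase", "season"])
    observed = {
        (str(p), str(s))
        for p, s in df[["phase", "season"]].drop_duplicates().itertuples(index=False)
    }
    for ph in phases:
        for season in (COLD, WARM):
            stratum = (ph.label, season)
            if nets is not None and stratum in observed and stratum not in nets:
                raise ValueError(f"stratum {stratum} has scan data but no network")
            net = nets.get(stratum) if nets is not None else None
            for pid in ph.roster:
                ind = by_id[pid]
                key = (pid, ph.label, season)
                sub = grouped.get_group(key) if key in grouped.groups else None
                if sub is None:
                    active = inactive = total = 0
                    undes = None
                else:
                    classes = sub["behavior"].map(catalog.class_map)
                    active = int((classes == ACTIVE).sum())
                    inactive = int((classes == INACTIVE).sum())
                    total = len(sub)
                    undes = float(sub["behavior"].isin(catalog.undesired_set).mean())
                gai = general_activity_index(active, inactive)
                if net is not None and pid in net.graph:
                    strength = sum(net.out_weights(pid).values())
                    vsc = vertex_strength_centrality(net, pid)
                    h = edge_weight_disparity(net, pid)
                    d = dewd(net, pid)
                else:
                    strength = vsc = h = d = None
                rows.append(
                    {
                        "individual": pid,
                        "phase": ph.label,
                        "season": season,
                        "group_size": ph.n,
                        "sex_ratio": ph.sex_ratio,
                        "sex": ind.sex,
                        "origin": ind.origin,
                        "strength": strength,
                        "vsc": vsc,
                        "disparity": h,
                        "dewd": d,
                        "active": active,
                        "inactive": inactive,
                        "gai": gai,
                        "undesired": undes,
                        "total_scans": total,
                    }
                )
    out = pd.DataFrame(rows, columns=INDEX_COLUMNS)
    return out


def write_index_table(table: pd.DataFrame, path) -> None:
    """Index CSV with empty cells for missing values."""
    table.to_csv(path, index=False)


def read_index_table(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        float_precision="round_trip",
        dtype={
            "individual": str,
            "phase": str,
            "season": str,
            "sex_ratio": str,
            "sex": str,
            "origin": str,
        },
    )
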