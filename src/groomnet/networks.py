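"""Co-presence-corrected grooming networks, per stratum.

A dyad's grooming rate is the number of scans at which the groomer was seen
grooming the groomee, divided by the number of scans at which both were
present in the enclosure ("co-present"), times 100.  Correcting by
co-presence matters because individuals are occasionally absent (veterinary
care etc.); a raw count would confound absence with disinterest.

Dyads that were never co-present have an *undefined* rate and are carried
as missing edges, never as zeros — a zero means "could have groomed, never
did", which is real information about the relationship.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .scans import COLD, GIVEN, WARM, BehaviorCatalog, Individual, ScanTable, StudyPhase

logger = logging.getLogger("groomnet")

Stratum = tuple[str, str]  # (phase label, season)


@dataclass
class CoPresenceMatrix:
    """Symmetric counts of scan slots with both individuals present.

    The diagonal holds each individual's own presence count.
    """

    stratum: Stratum
    counts: pd.DataFrame  # square, index == columns == individual ids

    def __post_init__(self) -> None:
        c = self.counts
        if not (c.index == c.columns).all():
            raise ValueError("co-presence matrix must be square with matching labels")
        if not np.allclose(c.values, c.values.T):
            raise ValueError("co-presence matrix must be symmetric")

    def p(self, i: str, j: str) -> int:
        return int(self.counts.at[i, j])


@dataclass
class GroomingCountMatrix:
    """c[i, j]: scans at which i groomed j (ordered dyad, canonical direction)."""

    stratum: Stratum
    counts: pd.DataFrame

    def c(self, i: str, j: str) -> int:
        return int(self.counts.at[i, j])

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())


@dataclass
class GroomingNetwork:
    """Weighted directed grooming graph for one stratum.

    Nodes carry ``sex``/``origin``; edges exist only for *defined* dyads
    (co-presence > 0) and carry ``weight`` (percent of co-present scans),
    ``copresent`` and ``groomed`` counts.  ``n`` is the roster group size.
    """

    stratum: Stratum
    graph: nx.DiGraph
    n: int

    def __post_init__(self) -> None:
        if self.graph.number_of_nodes() != self.n:
            raise ValueError("node count must equal roster size n")
        for u, v, w in self.graph.edges(data="weight"):
            if u == v:
                raise ValueError("self-edges are not allowed")
            if not 0 <= w <= 100:
                raise ValueError(f"edge weight out of [0, 100]: {u}->{v} = {w}")

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def weight(self, i: str, j: str) -> float | None:
        """Edge weight in percent, or None where the dyad is undefined."""
        data = self.graph.get_edge_data(i, j)
        return None if data is None else float(data["weight"])

    def out_weights(self, i: str) -> dict[str, float]:
        """Defined outgoing edge weights of i (zeros included)."""
        return {j: float(d["weight"]) for _, j, d in self.graph.out_edges(i, data=True)}


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


def _require_stratified(table: ScanTable) -> None:
    if not table.stratified:
        raise ValueError("scan table must be stratified first (assign_strata)")


def _presence_pivot(df: pd.DataFrame) -> pd.DataFrame:
    """Slot x individual presence indicator; a slot is (session, timepoint)."""
    slots = df.drop_duplicates(["session_id", "timepoint", "individual"])
    return (
        slots.assign(present=1)
        .pivot_table(
            index=["session_id", "timepoint"],
            columns="individual",
            values="present",
            fill_value=0,
            aggfunc="max",
        )
        .astype(int)
    )


def copresence_counts(
    table: ScanTable, ids: Mapping[Stratum, Sequence[str]] | None = None
) -> dict[Stratum, CoPresenceMatrix]:
    """Per-stratum co-presence counts.

    An individual is present at a slot iff a scan record exists for it
    there.  ``ids`` optionally fixes the matrix labels per stratum (e.g. the
    phase roster); individuals without any record then appear with zero
    counts.
    """
    _require_stratified(table)
    out: dict[Stratum, CoPresenceMatrix] = {}
    for stratum, sub in table.df.groupby(["phase", "season"], sort=True):
        b = _presence_pivot(sub)
        mat = b.T @ b  # symmetric; diagonal = own presence
        if ids is not None:
            labels = list(ids[stratum])
            mat = mat.reindex(index=labels, columns=labels, fill_value=0)
        else:
            mat = mat.sort_index(axis=0).sort_index(axis=1)
        mat.index.name = mat.columns.name = "individual"
        out[stratum] = CoPresenceMatrix(stratum, mat)
    return out


def grooming_counts(
    table: ScanTable,
    catalog: BehaviorCatalog,
    ids: Mapping[Stratum, Sequence[str]] | None = None,
) -> dict[Stratum, GroomingCountMatrix]:
    """Per-stratum ordered grooming counts from canonical "given" records.

    Only records with the grooming code and direction "given" are counted,
    so mutual grooming (two paired directed records) increments both ordered
    dyads exactly once.  A canonical grooming record without a partner is a
    hard error.
    """
    _require_stratified(table)
    df = table.df
    groom = df[(df["behavior"] == catalog.grooming_code) & (df["direction"] == GIVEN)]
    missing = groom["partner"].isna() | (groom["partner"] == "")
    if missing.any():
        bad = groom.index[missing][:5].tolist()
        raise ValueError(f"grooming records without partner at row positions {bad}")

    out: dict[Stratum, GroomingCountMatrix] = {}
    for stratum, sub in table.df.groupby(["phase", "season"], sort=True):
        labels = (
            list(ids[stratum]) if ids is not None else sorted(sub["individual"].unique())
        )
        g = groom[(groom["phase"] == stratum[0]) & (groom["season"] == stratum[1])]
        mat = (
            g.groupby(["individual", "partner"])
            .size()
            .unstack(fill_value=0)
            .reindex(index=labels, columns=labels, fill_value=0)
            .astype(int)
        )
        np.fill_diagonal(mat.values, 0)
        mat.index.name = mat.columns.name = "individual"
        out[stratum] = GroomingCountMatrix(stratum, mat)
    return out


# ---------------------------------------------------------------------------
# Rates and assembly
# ---------------------------------------------------------------------------


def dyadic_grooming_rate(
    c: GroomingCountMatrix,
    p: CoPresenceMatrix,
    node_attrs: Mapping[str, Mapping[str, str]] | None = None,
) -> GroomingNetwork:
    """w[i, j] = 100 * c[i, j] / p[i, j]; undefined (missing) where p = 0.

    ``c > p`` anywhere indicates corrupted input and raises.
    """
    if list(c.counts.index) != list(p.counts.index):
        raise ValueError("count and co-presence matrices must share labels")
    ids = list(c.counts.index)
    graph = nx.DiGraph()
    for i in ids:
        attrs = dict(node_attrs.get(i, {})) if node_attrs else {}
        graph.add_node(i, **attrs)
    for i in ids:
        for j in ids:
            if i == j:
                continue
            pij, cij = p.p(i, j), c.c(i, j)
            if cij > pij:
                raise ValueError(
                    f"{c.stratum}: grooming count exceeds co-presence for {i}->{j} "
                    f"({cij} > {pij})"
                )
            if pij > 0:
                graph.add_edge(i, j, weight=100.0 * cij / pij, copresent=pij, groomed=cij)
    return GroomingNetwork(c.stratum, graph, n=len(ids))


def build_networks(
    table: ScanTable,
    catalog: BehaviorCatalog,
    phases: Sequence[StudyPhase],
    roster: Sequence[Individual],
) -> dict[Stratum, GroomingNetwork]:
    """End-to-end per-stratum networks with roster-defined node sets."""
    ids = {
        (ph.label, season): list(ph.roster)
        for ph in phases
        for season in (COLD, WARM)
    }
    observed = {
        (str(p), str(s))
        for p, s in table.df[["phase", "season"]].drop_duplicates().itertuples(index=False)
    }
    present = {s: ids[s] for s in ids if s in observed}
    cop = copresence_counts(table, ids=present)
    cnt = grooming_counts(table, catalog, ids=present)
    attrs = {ind.id: {"sex": ind.sex, "origin": ind.origin} for ind in roster}
    return {s: dyadic_grooming_rate(cnt[s], cop[s], node_attrs=attrs) for s in cop}


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

EDGE_LIST_COLUMNS = ["stratum", "from", "to", "weight_percent", "copresent_scans", "groom_scans"]


def export_network(net: GroomingNetwork, path: str | Path, format: str = "edge_list_csv") -> None:
    """Write a network as an edge-list CSV or GraphML.

    Both formats list only defined edges (zero-weight edges included), so
    the missing-vs-zero distinction survives a round trip.  GraphML carries
    the node attributes.
    """
    path = Path(path)
    if format == "edge_list_csv":
        rows = [
            (
                f"{net.stratum[0]}:{net.stratum[1]}",
                u,
                v,
                d["weight"],
                d["copresent"],
                d["groomed"],
            )
            for u, v, d in sorted(net.graph.edges(data=True))
        ]
        # %.17g round-trips every IEEE double exactly
        pd.DataFrame(rows, columns=EDGE_LIST_COLUMNS).to_csv(
            path, index=False, float_format="%.17g"
        )
    elif format == "graphml":
        g = net.graph.copy()
        g.graph["phase"], g.graph["season"] = net.stratum
        g.graph["n"] = net.n
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_network(path: str | Path, format: str = "edge_list_csv", n: int | None = None) -> GroomingNetwork:
    """Re-import a network written by :func:`export_network`."""
    path = Path(path)
    if format == "edge_list_csv":
        df = pd.read_csv(path, dtype={"from": str, "to": str}, float_precision="round_trip")
        if df.empty:
            raise ValueError(f"{path}: empty edge list; cannot recover the stratum")
        phase, season = df["stratum"].iloc[0].split(":")
        graph = nx.DiGraph()
        for _, r in df.iterrows():
            graph.add_edge(
                r["from"],
                r["to"],
                weight=float(r["weight_percent"]),
                copresent=int(r["copresent_scans"]),
                groomed=int(r["groom_scans"]),
            )
        size = n if n is not None else graph.number_of_nodes()
        return GroomingNetwork((phase, season), graph, n=size)
    if format == "graphml":
        g = nx.read_graphml(path)
        graph = nx.DiGraph()
        for node, data in g.nodes(data=True):
            graph.add_node(node, **data)
        for u, v, d in g.edges(data=True):
            graph.add_edge(
                u, v, weight=float(d["weight"]), copresent=int(d["copresent"]), groomed=int(d["groomed"])
            )
        stratum = (g.graph["phase"], g.graph["season"])
        return GroomingNetwork(stratum, graph, n=int(g.graph.get("n", graph.number_of_nodes())))
    raise ValueError(f"unknown import format {format!r}")
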