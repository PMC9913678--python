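"""Shared builders for hand-crafted fixtures."""

import networkx as nx
import pandas as pd

from groomnet import GroomingNetwork, ScanTable
from groomnet.scans import SCAN_COLUMNS


def make_scans(rows, stratified=False):
    """Build a ScanTable from tuples.

    Rows are (session_id, timestamp, timepoint, individual, behavior,
    sub_behavior, partner, direction[, phase, season]).
    """
    cols = SCAN_COLUMNS + (["phase", "season"] if stratified else [])
    df = pd.DataFrame(rows, columns=cols)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return ScanTable(df)


def rec(session, ts, tp, ind, behavior="resting", sub=None, partner=None,
        direction=None, stratum=None):
    base = (session, ts, tp, ind, behavior, sub, partner, direction)
    return base + stratum if stratum else base


def make_network(weights, n, stratum=("phase1", "cold"), extra_nodes=()):
    """GroomingNetwork from {(i, j): (weight, copresent, groomed)} or
    {(i, j): weight} (co-presence defaulting to 100 scans).

    Pads with isolated nodes up to the requested group size n.
    """
    g = nx.DiGraph()
    for node in extra_nodes:
        g.add_node(node)
    for (i, j), value in weights.items():
        if isinstance(value, tuple):
            w, p, c = value
        else:
            w, p, c = value, 100, round(value)
        g.add_edge(i, j, weight=float(w), copresent=p, groomed=c)
    k = 0
    while g.number_of_nodes() < n:
        g.add_node(f"pad{k}")
        k += 1
    return GroomingNetwork(stratum, g, n=n)
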