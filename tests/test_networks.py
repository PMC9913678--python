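"""Co-presence counting, grooming counts, rates and network export."""

import numpy as np
import pandas as pd
import pytest

import groomnet as gn
from helpers import make_scans, rec

S = ("phase1", "cold")  # single stratum used by hand fixtures


def stratified_rows(rows):
    return make_scans([r + S for r in rows], stratified=True)


def session(sid, day, ids, timepoints=range(10), behavior="resting"):
    return [
        rec(sid, f"{day}T10:{2*t:02d}", t, i, behavior)
        for t in timepoints
        for i in ids
    ]


def random_fixture(seed, n_sessions=3, ids=("BON", "CHA", "JUA", "MAR", "TON"),
                   timepoints=10, groom_p=0.3):
    """Random presence + random grooming; returns (table, raw row list)."""
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_sessions):
        present = [i for i in ids if rng.random() > 0.25]
        for t in range(timepoints):
            for i in present:
                others = [j for j in present if j != i]
                if others and rng.random() < groom_p:
                    j = others[int(rng.integers(len(others)))]
                    rows.append(rec(f"s{k}", f"2016-02-0{k+1}T10:{2*t:02d}", t, i,
                                    "groom", None, j, "given"))
                else:
                    rows.append(rec(f"s{k}", f"2016-02-0{k+1}T10:{2*t:02d}", t, i,
                                    "resting"))
    return stratified_rows(rows), rows


class TestCoPresence:
    def test_both_present_all_session(self):
        table = session("s1", "2016-02-01", ["BON", "CHA"])
        cop = gn.copresence_counts(stratified_rows(table))[S]
        assert cop.p("BON", "CHA") == 10
        assert cop.p("BON", "BON") == 10

    def test_absent_session_contributes_zero(self):
        rows = session("s1", "2016-02-01", ["BON", "CHA"]) + session(
            "s2", "2016-02-02", ["BON"]
        )
        cop = gn.copresence_counts(stratified_rows(rows))[S]
        assert cop.p("BON", "CHA") == 10
        assert cop.p("BON", "BON") == 20
        assert cop.p("CHA", "CHA") == 10

    def test_matches_bruteforce_enumeration(self):
        table, rows = random_fixture(seed=42)
        cop = gn.copresence_counts(table)[S]
        # oracle: direct double loop over slots
        slots = {}
        for r in rows:
            slots.setdefault((r[0], r[2]), set()).add(r[3])
        ids = sorted({r[3] for r in rows})
        for i in ids:
            for j in ids:
                expected = sum(1 for m in slots.values() if i in m and j in m)
                assert cop.p(i, j) == expected

    def test_requires_stratified_table(self):
        plain = make_scans([rec("s1", "2016-02-01T10:00", 0, "BON")])
        with pytest.raises(ValueError, match="stratified"):
            gn.copresence_counts(plain)


class TestGroomingCounts:
    def test_directed_counts(self):
        rows = [
            rec("s1", "2016-02-01T10:00", t, "BON", "groom", None, "CHA", "given")
            for t in range(5)
        ] + session("s1", "2016-02-01", ["CHA"], range(5))
        cnt = gn.grooming_counts(stratified_rows(rows), gn.default_catalog())[S]
        assert cnt.c("BON", "CHA") == 5
        assert cnt.c("CHA", "BON") == 0

    def test_mutual_grooming_increments_both(self):
        rows = [
            rec("s1", "2016-02-01T10:00", 0, "BON", "groom", None, "CHA", "given"),
            rec("s1", "2016-02-01T10:00", 0, "CHA", "groom", None, "BON", "given"),
        ]
        cnt = gn.grooming_counts(stratified_rows(rows), gn.default_catalog())[S]
        assert cnt.c("BON", "CHA") == 1
        assert cnt.c("CHA", "BON") == 1

    def test_received_records_not_counted(self):
        rows = [
            rec("s1", "2016-02-01T10:00", 0, "BON", "groom", None, "CHA", "given"),
            rec("s1", "2016-02-01T10:00", 0, "CHA", "groom", None, "BON", "received"),
        ]
        cnt = gn.grooming_counts(stratified_rows(rows), gn.default_catalog())[S]
        assert cnt.total == 1

    def test_missing_partner_is_hard_error(self):
        rows = [rec("s1", "2016-02-01T10:00", 0, "BON", "groom", None, None, "given")]
        with pytest.raises(ValueError, match="without partner"):
            gn.grooming_counts(stratified_rows(rows), gn.default_catalog())

    def test_matches_bruteforce_recount(self):
        table, rows = random_fixture(seed=7, n_sessions=4)
        cnt = gn.grooming_counts(table, gn.default_catalog())[S]
        ids = sorted({r[3] for r in rows})
        for i in ids:
            for j in ids:
                expected = sum(
                    1 for r in rows if r[3] == i and r[4] == "groom" and r[6] == j
                )
                assert cnt.c(i, j) == expected

    def test_conservation_total_equals_canonical_records(self):
        table, rows = random_fixture(seed=13)
        cnt = gn.grooming_counts(table, gn.default_catalog())[S]
        assert cnt.total == sum(1 for r in rows if r[4] == "groom" and r[7] == "given")


class TestRates:
    def test_direct_arithmetic(self):
        c = gn.GroomingCountMatrix(S, pd.DataFrame([[0, 5], [0, 0]], index=["A", "B"], columns=["A", "B"]))
        p = gn.CoPresenceMatrix(S, pd.DataFrame([[60, 50], [50, 55]], index=["A", "B"], columns=["A", "B"]))
        net = gn.dyadic_grooming_rate(c, p)
        assert net.weight("A", "B") == 10.0

    def test_zero_rate_vs_missing_edge(self):
        # B co-present but never groomed -> 0.0; C never co-present -> missing
        ids = ["A", "B", "C"]
        c = gn.GroomingCountMatrix(S, pd.DataFrame(0, index=ids, columns=ids))
        pm = pd.DataFrame(
            [[20, 10, 0], [10, 20, 0], [0, 0, 0]], index=ids, columns=ids
        )
        net = gn.dyadic_grooming_rate(c, gn.CoPresenceMatrix(S, pm))
        assert net.weight("A", "B") == 0.0
        assert net.weight("A", "C") is None

    def test_count_exceeding_presence_is_corruption(self):
        ids = ["A", "B"]
        c = gn.GroomingCountMatrix(S, pd.DataFrame([[0, 9], [0, 0]], index=ids, columns=ids))
        p = gn.CoPresenceMatrix(S, pd.DataFrame([[9, 5], [5, 9]], index=ids, columns=ids))
        with pytest.raises(ValueError, match="exceeds co-presence"):
            gn.dyadic_grooming_rate(c, p)

    def test_weights_match_bruteforce_from_raw_records(self, design):
        table, rows = random_fixture(seed=99, n_sessions=5)
        cop = gn.copresence_counts(table)
        cnt = gn.grooming_counts(table, design["catalog"])
        net = gn.dyadic_grooming_rate(cnt[S], cop[S])
        slots = {}
        for r in rows:
            slots.setdefault((r[0], r[2]), set()).add(r[3])
        ids = net.nodes
        for i in ids:
            for j in ids:
                if i == j:
                    continue
                pij = sum(1 for m in slots.values() if i in m and j in m)
                cij = sum(1 for r in rows if r[3] == i and r[4] == "groom" and r[6] == j)
                if pij == 0:
                    assert net.weight(i, j) is None
                else:
                    assert net.weight(i, j) == pytest.approx(100.0 * cij / pij)

    def test_session_duplication_leaves_weights_unchanged(self, design):
        table, rows = random_fixture(seed=3)
        doubled = stratified_rows(
            [r for r in rows] + [("dup_" + r[0],) + r[1:] for r in rows]
        )
        net1 = gn.dyadic_grooming_rate(
            gn.grooming_counts(table, design["catalog"])[S],
            gn.copresence_counts(table)[S],
        )
        net2 = gn.dyadic_grooming_rate(
            gn.grooming_counts(doubled, design["catalog"])[S],
            gn.copresence_counts(doubled)[S],
        )
        for i in net1.nodes:
            for j in net1.nodes:
                if i != j:
                    w1, w2 = net1.weight(i, j), net2.weight(i, j)
                    assert (w1 is None) == (w2 is None)
                    if w1 is not None:
                        assert w1 == pytest.approx(w2)


class TestExport:
    def test_edge_list_single_edge(self, tmp_path):
        from helpers import make_network

        net = make_network({("A", "B"): (10.0, 50, 5)}, n=2)
        path = tmp_path / "net.csv"
        gn.export_network(net, path, "edge_list_csv")
        df = pd.read_csv(path)
        assert len(df) == 1
        assert df.iloc[0]["weight_percent"] == 10.0

    def test_edge_list_roundtrip_preserves_weights(self, nets, tmp_path):
        net = nets[("phase2", "cold")]
        path = tmp_path / "p2c.csv"
        gn.export_network(net, path, "edge_list_csv")
        back = gn.read_network(path, "edge_list_csv", n=net.n)
        for i in net.nodes:
            for j in net.nodes:
                if i != j:
                    assert back.weight(i, j) == net.weight(i, j)

    def test_graphml_roundtrip_and_counts(self, nets, tmp_path):
        net = nets[("phase2", "warm")]
        assert net.n == 7
        path = tmp_path / "p2w.graphml"
        gn.export_network(net, path, "graphml")
        back = gn.read_network(path, "graphml")
        assert back.stratum == net.stratum
        assert back.graph.number_of_nodes() == 7
        assert back.graph.number_of_edges() == net.graph.number_of_edges()
        for i in net.nodes:
            for j in net.nodes:
                if i != j:
                    assert back.weight(i, j) == net.weight(i, j)
        # node attributes survive
        assert back.graph.nodes["AFR"]["sex"] == "F"

    def test_missing_vs_zero_distinction_survives_export(self, tmp_path):
        from helpers import make_network

        net = make_network(
            {("A", "B"): (0.0, 20, 0), ("B", "A"): (5.0, 20, 1)},
            n=3, extra_nodes=("C",),
        )
        path = tmp_path / "mv0.graphml"
        gn.export_network(net, path, "graphml")
        back = gn.read_network(path, "graphml")
        assert back.weight("A", "B") == 0.0  # defined zero stays zero
        assert back.weight("A", "C") is None  # undefined stays missing

    def test_unknown_format_rejected(self, nets, tmp_path):
        net = next(iter(nets.values()))
        with pytest.raises(ValueError, match="unknown export format"):
            gn.export_network(net, tmp_path / "x", "ucinet")
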