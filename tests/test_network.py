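"""Energy aggregation/binning and bipartite network construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lncnet.coexpression import CoexpressionEdge
from lncnet.exceptions import BipartiteError, ParseError
from lncnet.network import (
    WEIGHT_CLASSES,
    aggregate_energy,
    build_network,
    extract_subnetwork,
    lncrna_degree_table,
    naive_duplex_sum_energy,
    weight_class,
)
from lncnet.records import DERecord, EnergyRecord


def _sites(rows):
    return pd.DataFrame(rows, columns=["lncrna_id", "mrna_id", "energy"])


class TestAggregateEnergy:
    def test_sum_of_magnitudes(self):
        recs = aggregate_energy(_sites([("l1", "m1", -3.2), ("l1", "m1", -1.8)]))
        assert recs == [EnergyRecord("l1", "m1", 5.0)]

    def test_single_site(self):
        recs = aggregate_energy(_sites([("l1", "m1", -10.0)]))
        assert recs[0].sum_energy == 10.0

    def test_pair_without_sites_is_absent(self):
        recs = aggregate_energy(_sites([("l1", "m1", -2.0)]))
        assert {(r.lncrna_id, r.mrna_id) for r in recs} == {("l1", "m1")}

    def test_alternative_modes(self):
        df = _sites([("l1", "m1", -3.0), ("l1", "m1", 1.0)])
        assert aggregate_energy(df, "sum_abs")[0].sum_energy == 4.0
        assert aggregate_energy(df, "abs_sum")[0].sum_energy == 2.0
        assert aggregate_energy(df, "min_site")[0].sum_energy == 3.0

    def test_malformed_table_rejected(self):
        with pytest.raises(ParseError):
            aggregate_energy(pd.DataFrame({"lncrna_id": ["a"], "mrna_id": ["b"]}))
        with pytest.raises(ParseError):
            aggregate_energy(_sites([("a", "b", "oops")]))


class TestWeightClass:
    @pytest.mark.parametrize(
        "value, expected", [(5.0, "thin"), (10.0, "dotted"), (250.0, "thick")]
    )
    def test_legend_bins(self, value, expected):
        assert weight_class(value) == expected

    def test_boundaries_lower_inclusive(self):
        assert weight_class(100.0) == "thick"
        assert weight_class(99.999) == "dotted"

    @given(st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    def test_partition_and_monotonicity(self, value):
        cls = weight_class(value)
        assert cls in WEIGHT_CLASSES
        bigger = weight_class(value * 1.5)
        assert WEIGHT_CLASSES.index(bigger) >= WEIGHT_CLASSES.index(cls)

    def test_non_positive_falls_back_to_thin(self, caplog):
        with caplog.at_level("WARNING"):
            assert weight_class(0.0) == "thin"
        assert "SUMENERGY" in caplog.text


def _edges(pairs):
    return [CoexpressionEdge(l, m, 0.97, 1e-4) for l, m in pairs]


class TestBuildNetwork:
    def test_counts_and_bipartiteness(self):
        net = build_network(_edges([("l1", "m1"), ("l1", "m2"), ("l2", "m3")]))
        assert len(net.lncrna_ids) == 2 and len(net.mrna_ids) == 3
        assert net.n_edges == 3
        net.validate()

    def test_empty_edge_list(self):
        net = build_network([])
        assert net.n_edges == 0 and net.graph.number_of_nodes() == 0

    def test_id_on_both_sides_rejected(self):
        with pytest.raises(BipartiteError):
            build_network(_edges([("x", "m1"), ("l1", "x")]))

    def test_de_join_defaults_to_ns_and_energy_is_left_join(self):
        net = build_network(
            _edges([("l1", "m1"), ("l2", "m2")]),
            energies=[EnergyRecord("l1", "m1", 50.0)],
            de_records=[DERecord("l1", -2.0, 1e-4, 1e-3, "down")],
        )
        assert net.graph.nodes["l1"]["de"] == "down"
        assert net.graph.nodes["m1"]["de"] == "ns"
        assert net.graph.edges["l1", "m1"]["weight_class"] == "dotted"
        assert "sum_energy" not in net.graph.edges["l2", "m2"]

    def test_degree_sums_equal_edge_count(self, small_study):
        from lncnet.coexpression import call_edges, log_expression, normalize_counts

        _, norm = normalize_counts(small_study.counts)
        expr = log_expression(norm)
        lnc = sorted(small_study.truth.true_lncrna_ids)
        mrna = sorted(small_study.truth.true_coding_ids)
        edges, _ = call_edges(expr.loc[lnc], expr.loc[mrna])
        net = build_network(edges)
        lnc_deg = sum(net.graph.degree(n) for n in net.lncrna_ids)
        mrna_deg = sum(net.graph.degree(n) for n in net.mrna_ids)
        assert lnc_deg == mrna_deg == net.n_edges == len(edges)
        # brute-force set construction of the node sets
        assert set(net.lncrna_ids) == {e.lncrna_id for e in edges}
        assert set(net.mrna_ids) == {e.mrna_id for e in edges}


class TestSubnetwork:
    def _net(self, labels):
        edges = _edges([("l1", "m1"), ("l1", "m2"), ("l2", "m2")])
        de = [DERecord(t, -1.0 if d == "down" else 1.0, 1e-3, 1e-2, d)
              for t, d in labels.items() if d != "ns"]
        return build_network(edges, de_records=de)

    def test_down_down_edge_only(self):
        net = self._net({"l1": "down", "m1": "down", "m2": "up"})
        sub = extract_subnetwork(net, "down")
        assert set(sub.graph.edges) == {("l1", "m1")}

    def test_no_down_nodes_gives_empty_subnetwork(self):
        net = self._net({"l1": "up", "m1": "up"})
        sub = extract_subnetwork(net, "down")
        assert sub.graph.number_of_nodes() == 0

    def test_idempotent_and_matches_brute_filter(self):
        rng = np.random.default_rng(12)
        edges = _edges(
            [(f"l{i}", f"m{j}") for i in range(8) for j in range(10) if rng.random() < 0.4]
        )
        nodes = {e.lncrna_id for e in edges} | {e.mrna_id for e in edges}
        labels = {n: rng.choice(["up", "down", "ns"]) for n in sorted(nodes)}
        de = [DERecord(n, -1.0 if d == "down" else 1.0, 0.001, 0.01, d)
              for n, d in labels.items() if d != "ns"]
        net = build_network(edges, de_records=de)
        sub = extract_subnetwork(net, "down")
        brute = {
            frozenset((e.lncrna_id, e.mrna_id))
            for e in edges
            if labels[e.lncrna_id] == "down" and labels[e.mrna_id] == "down"
        }
        assert {frozenset(e) for e in sub.graph.edges} == brute
        again = extract_subnetwork(sub, "down")
        assert again == sub


class TestDegreeTable:
    def test_sorted_descending_with_id_ties(self):
        net = build_network(
            _edges([("b", "m1"), ("b", "m2"), ("a", "m3"), ("c", "m4")])
        )
        table = lncrna_degree_table(net)
        assert list(table["lncrna_id"]) == ["b", "a", "c"]
        assert list(table["n_targets"]) == [2, 1, 1]
        assert table["n_targets"].sum() == net.n_edges

    def test_empty_network(self):
        assert lncrna_degree_table(build_network([])).empty


class TestNaiveScorer:
    def test_complementary_sequences_score_positive(self):
        lnc = "ACGTACGTACGTACGT"
        comp = str.maketrans("ACGT", "TGCA")
        mrna = lnc.translate(comp)[::-1]
        assert naive_duplex_sum_energy(lnc, mrna) > 0

    def test_short_or_unrelated_sequences_score_zero(self):
        assert naive_duplex_sum_energy("ACGT", "ACGT") == 0.0
        assert naive_duplex_sum_energy("A" * 30, "C" * 30, k=8) == 0.0
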