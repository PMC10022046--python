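"""Journey indices: degrees, flows, flow-weighted mean arc lengths, NA rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odflow.indices import (
    IndexRow,
    in_degree,
    incoming_flow,
    index_row,
    macroregion_breakdown,
    mean_arc_length,
    out_degree,
    outgoing_flow,
    time_series,
)
from odflow.network import FlowNetwork

from conftest import make_muni, make_network

FOCAL = "293330"


def random_star_network(rng, year=2020):
    """Random in/out star around FOCAL plus unrelated edges."""
    n_in = int(rng.integers(0, 12))
    n_out = int(rng.integers(0, 6))
    edges = []
    for i in range(n_in):
        edges.append((f"10{i:04d}", FOCAL, int(rng.integers(1, 30)),
                      float(rng.uniform(5, 500))))
    for i in range(n_out):
        edges.append((FOCAL, f"20{i:04d}", int(rng.integers(1, 30)),
                      float(rng.uniform(5, 500))))
    # noise edges not touching the focal vertex
    for i in range(int(rng.integers(0, 5))):
        edges.append((f"30{i:04d}", f"40{i:04d}", int(rng.integers(1, 10)),
                      float(rng.uniform(5, 500))))
    return make_network(year, edges), n_in, n_out


class TestDegrees:
    def test_star_of_eight_origins(self):
        net = make_network(2010, [(f"29000{i}", FOCAL, 1, 50.0) for i in range(8)])
        assert in_degree(net, FOCAL) == 8

    def test_absent_focal_is_zero(self):
        net = make_network(2010, [("A", "B", 1, 10.0)])
        assert in_degree(net, FOCAL) == 0
        assert out_degree(net, FOCAL) == 0

    def test_out_degree_single_and_double(self):
        net1 = make_network(2010, [(FOCAL, "292740", 35, 326.52)])
        assert out_degree(net1, FOCAL) == 1
        net2 = make_network(2012, [(FOCAL, "292740", 20, 326.52),
                                   (FOCAL, "291480", 6, 135.0)])
        assert out_degree(net2, FOCAL) == 2

    def test_random_network_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            net, n_in, n_out = random_star_network(rng)
            assert in_degree(net, FOCAL) == n_in
            assert out_degree(net, FOCAL) == n_out


class TestFlows:
    def test_incoming_sum(self):
        net = make_network(2010, [("A", FOCAL, 13, 100.0), ("B", FOCAL, 7, 200.0)])
        assert incoming_flow(net, FOCAL) == 20

    def test_no_incoming_edges_zero(self):
        net = make_network(2010, [(FOCAL, "A", 5, 100.0)])
        assert incoming_flow(net, FOCAL) == 0
        assert outgoing_flow(net, FOCAL) == 5

    def test_random_network_flow_recount(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            net, _, _ = random_star_network(rng)
            assert incoming_flow(net, FOCAL) == sum(
                e.weight for e in net.edges.values() if e.dest_code == FOCAL)
            assert outgoing_flow(net, FOCAL) == sum(
                e.weight for e in net.edges.values() if e.origin_code == FOCAL)


class TestMeanArcLength:
    def test_single_destination_any_weight(self):
        for w in (1, 35, 400):
            net = make_network(2008, [(FOCAL, "292740", w, 326.52)])
            assert mean_arc_length(net, FOCAL, "outgoing") == pytest.approx(326.52)

    def test_two_arc_weighted_mean(self):
        # (100*1 + 300*3) / 4 = 250
        net = make_network(2020, [("A", FOCAL, 1, 100.0), ("B", FOCAL, 3, 300.0)])
        assert mean_arc_length(net, FOCAL, "incoming") == pytest.approx(250.0)

    def test_degree_zero_is_na(self):
        net = make_network(2008, [(FOCAL, "292740", 35, 326.52)])
        assert mean_arc_length(net, FOCAL, "incoming") is None
        assert mean_arc_length(net, FOCAL, "outgoing") is not None

    def test_missing_distance_is_error(self):
        net = make_network(2020, [("A", FOCAL, 1, None)])
        with pytest.raises(ValueError, match="distance"):
            mean_arc_length(net, FOCAL, "incoming")

    def test_invalid_direction(self):
        net = make_network(2020, [("A", FOCAL, 1, 10.0)])
        with pytest.raises(ValueError):
            mean_arc_length(net, FOCAL, "sideways")

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_loop_oracle(self, data):
        arcs = data.draw(st.lists(
            st.tuples(st.integers(1, 50), st.floats(1.0, 1000.0)),
            min_size=1, max_size=20))
        net = make_network(
            2020, [(f"O{i}", FOCAL, w, d) for i, (w, d) in enumerate(arcs)])
        num = sum(d * w for w, d in arcs)
        den = sum(w for w, _ in arcs)
        got = mean_arc_length(net, FOCAL, "incoming")
        assert abs(got - num / den) <= 1e-9 * abs(num / den)

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_weight_scale_invariance(self, data):
        arcs = data.draw(st.lists(
            st.tuples(st.integers(1, 20), st.floats(1.0, 800.0)),
            min_size=1, max_size=12))
        k = data.draw(st.integers(2, 9))
        net = make_network(
            2020, [(f"O{i}", FOCAL, w, d) for i, (w, d) in enumerate(arcs)])
        scaled = make_network(
            2020, [(f"O{i}", FOCAL, w * k, d) for i, (w, d) in enumerate(arcs)])
        d_bar = mean_arc_length(net, FOCAL, "incoming")
        dists = [d for _, d in arcs]
        assert min(dists) - 1e-9 <= d_bar <= max(dists) + 1e-9
        assert mean_arc_length(scaled, FOCAL, "incoming") == pytest.approx(
            d_bar, rel=1e-12)


class TestIndexRow:
    def test_2010_style_row(self):
        net = make_network(2010, [("290160", FOCAL, 13, 131.57),
                                  (FOCAL, "292740", 25, 326.52)])
        row = index_row(net, FOCAL)
        assert (row.in_degree, row.out_degree) == (1, 1)
        assert (row.incoming_flow, row.outgoing_flow) == (13, 25)
        assert row.mean_in_length == pytest.approx(131.57)
        assert row.mean_out_length == pytest.approx(326.52)

    def test_empty_network(self):
        row = index_row(FlowNetwork(year=2005), FOCAL)
        assert row == IndexRow(2005, FOCAL, 0, 0, 0, 0, None, None)
        assert row.as_csv_row() == ["2005", "0", "0", "0", "0", "NA", "NA"]

    def test_componentwise_consistency_random(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            net, _, _ = random_star_network(rng)
            row = index_row(net, FOCAL)
            assert row.in_degree == in_degree(net, FOCAL)
            assert row.out_degree == out_degree(net, FOCAL)
            assert row.incoming_flow == incoming_flow(net, FOCAL)
            assert row.outgoing_flow == outgoing_flow(net, FOCAL)
            assert row.mean_in_length == mean_arc_length(net, FOCAL, "incoming")
            assert row.mean_out_length == mean_arc_length(net, FOCAL, "outgoing")

    def test_invariant_violations_rejected(self):
        with pytest.raises(ValueError):
            IndexRow(2020, FOCAL, 2, 0, 1, 0, 100.0, None)  # F_I < k_I
        with pytest.raises(ValueError):
            IndexRow(2020, FOCAL, 0, 0, 0, 0, 5.0, None)  # mean without degree
        with pytest.raises(ValueError):
            IndexRow(2020, FOCAL, 1, 0, 1, 0, None, None)  # NA with degree


class TestTimeSeries:
    def test_three_years_sorted(self):
        nets = [make_network(y, [("A", FOCAL, y - 2009, 100.0)])
                for y in (2012, 2010, 2011)]
        rows = time_series(nets, FOCAL)
        assert [r.year for r in rows] == [2010, 2011, 2012]
        assert [r.incoming_flow for r in rows] == [1, 2, 3]

    def test_gap_year_filled_with_na_row(self):
        nets = [make_network(2010, [("A", FOCAL, 1, 100.0)]),
                make_network(2012, [("A", FOCAL, 2, 100.0)])]
        rows = time_series(nets, FOCAL)
        assert [r.year for r in rows] == [2010, 2011, 2012]
        gap = rows[1]
        assert gap.in_degree == gap.incoming_flow == 0
        assert gap.mean_in_length is None and gap.mean_out_length is None

    def test_explicit_year_range(self):
        nets = [make_network(2010, [("A", FOCAL, 1, 100.0)])]
        rows = time_series(nets, FOCAL, years=range(2008, 2013))
        assert [r.year for r in rows] == [2008, 2009, 2010, 2011, 2012]

    def test_duplicate_years_rejected(self):
        nets = [make_network(2010, [("A", FOCAL, 1, 100.0)]),
                make_network(2010, [("B", FOCAL, 1, 100.0)])]
        with pytest.raises(ValueError, match="duplicate"):
            time_series(nets, FOCAL)

    def test_rows_equal_per_year_index_row(self, small_synth):
        from odflow.network import records_to_network
        _, registry, records = small_synth
        years = sorted({r.year for r in records})
        nets = [records_to_network(records, y, registry)[0] for y in years]
        rows = time_series(nets, FOCAL, years=years)
        for net, row in zip(nets, rows):
            assert row == index_row(net, FOCAL)


class TestMacroregionBreakdown:
    def build_115_origin_star(self):
        munis, edges = {}, []
        labels = ["Southwest"] * 71 + ["West"] * 23 + ["South"] * 18 + ["East"] * 3
        for i, label in enumerate(labels):
            code = f"29{i:04d}"
            munis[code] = make_muni(code, macroregion=label)
            edges.append((code, FOCAL, 1 + i % 4, 100.0))
        munis[FOCAL] = make_muni(FOCAL, macroregion="Southwest")
        return make_network(2020, edges, munis=munis)

    def test_published_percentages(self):
        bd = macroregion_breakdown(self.build_115_origin_star(), FOCAL, "incoming")
        assert bd.degree == 115
        assert bd.counts == {"Southwest": 71, "West": 23, "South": 18, "East": 3}
        rounded = bd.rounded()
        assert rounded["Southwest"] == 61.7
        assert rounded["West"] == 20.0
        assert rounded["South"] == 15.7
        assert sum(bd.percentages.values()) == pytest.approx(100.0)

    def test_single_region_is_100_percent(self):
        munis = {c: make_muni(c, macroregion="Southwest")
                 for c in ("A", "B", "C", FOCAL)}
        net = make_network(2010, [("A", FOCAL, 2, 50.0), ("B", FOCAL, 1, 60.0),
                                  ("C", FOCAL, 9, 70.0)], munis=munis)
        bd = macroregion_breakdown(net, FOCAL, "incoming")
        assert bd.rounded() == {"Southwest": 100.0}

    def test_counts_partition_degree_not_flow(self):
        munis = {"A": make_muni("A", macroregion="West"),
                 "B": make_muni("B", macroregion="South"),
                 FOCAL: make_muni(FOCAL, macroregion="Southwest")}
        net = make_network(2010, [("A", FOCAL, 100, 50.0), ("B", FOCAL, 1, 60.0)],
                           munis=munis)
        bd = macroregion_breakdown(net, FOCAL, "incoming")
        assert bd.counts == {"West": 1, "South": 1}  # weights irrelevant

    def test_missing_label_buckets_unknown(self):
        net = make_network(2010, [("A", FOCAL, 1, 50.0)])
        bd = macroregion_breakdown(net, FOCAL, "incoming")
        assert bd.counts == {"unknown": 1}

    def test_degree_zero_empty_breakdown(self):
        net = make_network(2010, [(FOCAL, "A", 1, 50.0)])
        bd = macroregion_breakdown(net, FOCAL, "incoming")
        assert bd.counts == {} and bd.percentages == {}

    def test_outgoing_direction(self):
        munis = {"A": make_muni("A", macroregion="East"),
                 FOCAL: make_muni(FOCAL, macroregion="Southwest")}
        net = make_network(2010, [(FOCAL, "A", 4, 300.0)], munis=munis)
        bd = macroregion_breakdown(net, FOCAL, "outgoing")
        assert bd.counts == {"East": 1}
        assert bd.rounded() == {"East": 100.0}
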