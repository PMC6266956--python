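"""Role coordinates, region assignment, hub classes and switch calling."""

import numpy as np
import pandas as pd
import pytest
import networkx as nx

import swimnet as sw
from swimnet.clustering import Partition
from swimnet.cartography import histogram_modes


def graph_with_partition(edges, modules):
    net = nx.Graph()
    net.add_nodes_from(modules)
    for u, v in edges:
        net.add_edge(u, v, weight=0.9)
    assignment = pd.Series(modules, name="module")
    return net, Partition(assignment=assignment, sse=0.0, k=len(set(modules.values())))


class TestClusterphobicCoefficient:
    def test_limits_and_formula(self):
        # hub with 10 links, 4 internal -> K_pi = 1 - (4/10)^2 = 0.84
        modules = {"hub": 1, **{f"in{i}": 1 for i in range(4)}, **{f"out{i}": 2 for i in range(6)}}
        edges = [("hub", n) for n in modules if n != "hub"]
        net, part = graph_with_partition(edges, modules)
        assert sw.clusterphobic_coefficient(net, part, "hub") == pytest.approx(0.84)
        # all-internal and all-external limits
        assert sw.clusterphobic_coefficient(net, part, "in0") == pytest.approx(0.0)
        assert sw.clusterphobic_coefficient(net, part, "out0") == pytest.approx(1.0)

    def test_isolated_node_marker(self):
        modules = {"a": 1, "b": 1, "lonely": 1}
        net, part = graph_with_partition([("a", "b")], modules)
        assert np.isnan(sw.clusterphobic_coefficient(net, part, "lonely"))


class TestWithinModuleDegree:
    def test_population_sd_formula(self):
        # module {a,b,c,d}: internal degrees a=3, b=2, c=2, d=1
        modules = {"a": 1, "b": 1, "c": 1, "d": 1, "x": 2, "y": 2}
        edges = [("a", "b"), ("a", "c"), ("a", "d"), ("b", "c"), ("a", "x"), ("x", "y")]
        net, part = graph_with_partition(edges, modules)
        internal = np.array([3.0, 2.0, 2.0, 1.0])
        expected = (3 - internal.mean()) / internal.std()  # population sd
        assert sw.within_module_degree(net, part, "a") == pytest.approx(expected)
        # the arithmetic convention on the canonical example: degrees {2,4,6},
        # k_in = 6 -> (6-4)/sqrt(8/3)
        assert (6 - np.mean([2, 4, 6])) / np.std([2, 4, 6]) == pytest.approx(1.22474487, abs=1e-8)

    def test_exact_value_on_constructed_module(self):
        # module {a, b, c} with internal degrees 1, 1, 2
        modules = {"a": 1, "b": 1, "c": 1}
        edges = [("a", "c"), ("b", "c")]
        net, part = graph_with_partition(edges, modules)
        values = np.array([1.0, 1.0, 2.0])
        expected = (2 - values.mean()) / values.std()
        assert sw.within_module_degree(net, part, "c") == pytest.approx(expected)

    def test_degenerate_sd_zero(self):
        modules = {"a": 1, "b": 1, "c": 1}
        edges = [("a", "b"), ("b", "c"), ("a", "c")]
        net, part = graph_with_partition(edges, modules)
        assert all(sw.within_module_degree(net, part, n) == 0.0 for n in "abc")


class TestAssignRegion:
    @pytest.mark.parametrize(
        "k_pi, z_g, region",
        [
            (0.9, 1.0, "R4"),   # non-hub kinless: K_pi > 0.8
            (0.0, 0.0, "R1"),   # ultra-peripheral
            (0.9, 3.0, "R7"),   # kinless hub: K_pi > 0.75
            (0.05, 0.0, "R1"),  # boundary: R1 includes 0.05
            (0.625, 2.49, "R2"),
            (0.8, 0.0, "R3"),
            (0.81, 2.499, "R4"),
            (0.30, 2.5, "R5"),  # z boundary: 2.5 is a local hub
            (0.75, 10.0, "R6"),
            (0.751, 2.5, "R7"),
        ],
    )
    def test_rule_table(self, k_pi, z_g, region):
        assert sw.assign_region(k_pi, z_g) == region

    def test_out_of_range_k_pi_rejected(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                sw.assign_region(bad, 0.0)


class TestClassifyHubs:
    def make_star(self, degree, weight):
        net = nx.Graph()
        for i in range(degree):
            net.add_edge("hub", f"n{i}", weight=weight)
        return net

    def test_degree_five_is_not_a_hub(self):
        net = self.make_star(5, 0.9)
        apcc = sw.compute_apcc(net)
        assert sw.classify_hubs(net, apcc)["hub"] == "non-hub"

    def test_negative_apcc_is_fight_club(self):
        net = self.make_star(20, -0.3)
        assert sw.classify_hubs(net, sw.compute_apcc(net))["hub"] == "fight-club"

    def test_high_apcc_is_party_low_is_date(self):
        net = self.make_star(20, 0.9)
        assert sw.classify_hubs(net, sw.compute_apcc(net), apcc_split=0.5)["hub"] == "party"
        net2 = self.make_star(20, 0.3)
        assert sw.classify_hubs(net2, sw.compute_apcc(net2), apcc_split=0.5)["hub"] == "date"


class TestSwitchGenes:
    def cart_row(self, **overrides):
        row = {
            "module": 1,
            "degree": 10,
            "k_in": 1,
            "k_pi": 0.85,
            "z_g": 1.0,
            "apcc": -0.2,
            "region": "R4",
            "hub_class": "fight-club",
            "is_switch": True,
        }
        row.update(overrides)
        return row

    def test_criteria_combinations(self):
        cart = pd.DataFrame(
            {
                "sw1": self.cart_row(),
                "notsw_pos_apcc": self.cart_row(apcc=0.1, hub_class="date", is_switch=False),
                "notsw_local_hub": self.cart_row(z_g=3.0, region="R7", is_switch=False),
                "sw2": self.cart_row(apcc=-0.5),
            }
        ).T
        assert sw.find_switch_genes(cart) == ["sw2", "sw1"]  # ascending APCC

    def test_switch_subset_of_fight_club_on_fixture(self, default_run):
        cart = default_run["cart"]
        switch = set(default_run["switch"])
        fight_club = set(cart.index[cart["hub_class"] == "fight-club"])
        assert switch <= fight_club

    def test_stable_under_module_relabeling(self, default_run):
        net, part = default_run["net"], default_run["partition"]
        relabeled = Partition(
            assignment=part.assignment.map({1: 7, 2: 5, 3: 9}),
            sse=part.sse,
            k=part.k,
        )
        cart2 = sw.build_cartography(net, relabeled)
        cart1 = default_run["cart"]
        pd.testing.assert_frame_equal(
            cart1.drop(columns="module"), cart2.drop(columns="module")
        )

    def test_module_sizes_sum_to_clustered_nodes(self, default_run):
        part = default_run["partition"]
        sizes = part.assignment.value_counts()
        assert sizes.sum() == len(part.assignment)


class TestHistogramModes:
    def test_detects_three_separated_peaks(self):
        rng = np.random.default_rng(0)
        values = np.concatenate(
            [rng.normal(-0.6, 0.02, 40), rng.normal(0.2, 0.02, 60), rng.normal(0.8, 0.02, 50)]
        )
        modes = histogram_modes(values)
        assert len(modes) == 3
        assert modes[0] < 0 < modes[1] < modes[2]

    def test_single_peak(self):
        rng = np.random.default_rng(1)
        assert len(histogram_modes(rng.normal(0.2, 0.03, 200))) == 1


def test_randomized_fixture_has_no_switch_genes(default_run):
    """Degree-preserving nulls lose the anti-correlated periphery entirely."""
    net, part = default_run["net"], default_run["partition"]
    n_nodes = net.number_of_nodes()
    for seed in range(10):
        randomized = sw.degree_preserving_randomization(net, seed=seed)
        cart = sw.build_cartography(randomized, part)
        n_switch = int(cart["is_switch"].sum())
        assert n_switch <= 0.01 * n_nodes
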