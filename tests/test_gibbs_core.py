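import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from gibbsnet.energy import (
    chemical_potential,
    gibbs_per_sample,
    node_gibbs,
    rescale_concentrations,
    total_gibbs,
)


class TestRescaleConcentrations:
    @pytest.mark.parametrize(
        "sample, expected",
        [
            ({"A": 2.0, "B": 4.0, "C": 6.0}, {"A": 0.0, "B": 0.5, "C": 1.0}),
            ({"A": -1.0, "B": 0.0, "C": 3.0}, {"A": 0.0, "B": 0.25, "C": 1.0}),
        ],
    )
    def test_min_max_formula(self, sample, expected):
        result = rescale_concentrations(sample)
        for gene, value in expected.items():
            assert result[gene] == pytest.approx(value, abs=1e-15)

    def test_constant_sample_collapses_to_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="gibbsnet.energy"):
            result = rescale_concentrations({"A": 5.0, "B": 5.0})
        assert result.tolist() == [0.0, 0.0]
        assert "degenerate" in caplog.text

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            rescale_concentrations({})


class TestChemicalPotential:
    def test_isolated_node_has_zero_potential(self):
        net = nx.Graph()
        net.add_node("D")
        assert chemical_potential(net, {"D": 0.7}, "D") == 0.0

    def test_path_middle_node(self, path_network, path_concentrations):
        mu_b = chemical_potential(path_network, path_concentrations, "B")
        assert mu_b == pytest.approx(math.log(0.5 / 1.75), rel=1e-12)
        assert mu_b == pytest.approx(-1.252763, abs=1e-6)

    def test_zero_concentration_node_is_zero_by_convention(self, path_network):
        assert chemical_potential(path_network, {"A": 0.0, "B": 1.0}, "A") == 0.0

    def test_all_zero_neighborhood_gives_log_argument_one(self, path_network):
        assert chemical_potential(path_network, {"B": 0.4}, "B") == 0.0

    def test_absent_node_raises(self, path_network):
        with pytest.raises(KeyError):
            chemical_potential(path_network, {}, "Z")


class TestNodeAndTotalGibbs:
    def test_single_edge_equal_concentrations(self):
        net = nx.Graph([("A", "B")])
        assert node_gibbs(net, {"A": 1.0, "B": 1.0}, "A") == pytest.approx(
            math.log(0.5), rel=1e-12
        )

    def test_hand_worked_path_total_and_terms(self, path_network, path_concentrations):
        terms = {n: node_gibbs(path_network, path_concentrations, n) for n in "ABC"}
        assert terms["A"] == pytest.approx(-0.405465, abs=1e-6)
        assert terms["B"] == pytest.approx(-0.626381, abs=1e-6)
        assert terms["C"] == pytest.approx(-0.274653, abs=1e-6)
        total = total_gibbs(path_network, path_concentrations)
        assert total == pytest.approx(-1.306500, abs=1e-6)
        assert total == pytest.approx(sum(terms.values()), rel=1e-12)

    def test_triangle_symmetry(self):
        tri = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        total = total_gibbs(tri, {"A": 1.0, "B": 1.0, "C": 1.0})
        assert total == pytest.approx(3 * math.log(1 / 3), rel=1e-12)

    def test_edgeless_network_is_zero(self):
        net = nx.Graph()
        net.add_nodes_from("ABC")
        assert total_gibbs(net, {"A": 0.9, "B": 0.1, "C": 0.5}) == 0.0

    def test_genes_outside_network_are_inert(self, path_network, path_concentrations):
        extended = dict(path_concentrations, ZZZ=0.8)
        assert total_gibbs(path_network, extended) == total_gibbs(
            path_network, path_concentrations
        )


class TestGibbsPerSample:
    @pytest.fixture
    def expression(self):
        return pd.DataFrame(
            {"s1": [2.0, 4.0, 6.0], "s2": [1.0, 5.0, 3.0]},
            index=pd.Index(["A", "B", "C"], name="gene"),
        )

    def test_matches_manual_composition(self, path_network, expression):
        results = gibbs_per_sample(path_network, expression)
        assert [r.sample_id for r in results] == ["s1", "s2"]
        for r in results:
            conc = rescale_concentrations(expression[r.sample_id])
            assert r.total_G == pytest.approx(total_gibbs(path_network, dict(conc)), rel=1e-12)

    def test_non_network_genes_do_not_change_g(self, path_network, expression):
        # an extra off-network gene inside the expression range leaves the
        # per-sample rescale untouched, so G must be identical with or
        # without that row
        extra = pd.concat(
            [expression, pd.DataFrame({"s1": [4.0], "s2": [3.0]}, index=["ZZZ"])]
        )
        with_extra = [r.total_G for r in gibbs_per_sample(path_network, extra)]
        without = [r.total_G for r in gibbs_per_sample(path_network, expression)]
        assert with_extra == without

    def test_determinism_is_bitwise(self, path_network, expression):
        g1 = [r.total_G for r in gibbs_per_sample(path_network, expression)]
        g2 = [r.total_G for r in gibbs_per_sample(path_network, expression)]
        assert g1 == g2

    def test_zero_overlap_is_an_error(self, expression):
        net = nx.Graph([("X", "Y")])
        with pytest.raises(ValueError, match="overlap"):
            gibbs_per_sample(net, expression)

    def test_per_node_breakdown_sums_to_total(self, path_network, expression):
        (r1, _) = gibbs_per_sample(path_network, expression, keep_per_node=True)
        assert r1.per_node["contribution"].sum() == pytest.approx(r1.total_G, rel=1e-12)
        assert (r1.per_node["contribution"] <= 0).all()
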