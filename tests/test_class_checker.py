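"""SR-graph construction and the C1/C2 (C*) class test."""

import numpy as np
import pytest

import rdintegral as rd
from rdintegral.class_checker import block_decomposition, build_sr_graph, to_dot
from rdintegral.fixtures import example_networks

from conftest import permute_network


class TestSRGraph:
    def test_complexform_graph(self, complexform):
        g = rd.build_sr_graph(complexform)
        # L diffuses (black); R and C are immobile (red)
        assert g.s_colors == ("red", "black", "red")
        # binding is the only nonlinear (red) reaction
        assert g.r_colors == ("red", "black", "black")
        j_bind = [r.name for r in complexform.reactions].index("binding")
        adj = {
            g.species_names[i]
            for i in range(3)
            if j_bind in g.species_neighbors(i)
        }
        assert adj == {"R", "L", "C"}

    def test_all_affine_network_has_no_red_reactions(self):
        spec = {
            "species": [{"name": "s", "diffusion": 1.0, "initial": 0.0}],
            "reactions": [
                {"name": "r", "stoich": {"s": 1}, "kind": "affine",
                 "affine": {"const": 1.0, "coeffs": {"s": -1.0}}}
            ],
            "domain": {"length": 1.0},
        }
        g = rd.build_sr_graph(rd.build_network(spec))
        assert "red" not in g.r_colors

    def test_isolated_species_has_no_edges_and_warns(self):
        spec = {
            "species": [
                {"name": "s", "diffusion": 1.0, "initial": 0.0},
                {"name": "inert", "diffusion": 1.0, "initial": 0.0},
            ],
            "reactions": [
                {"name": "r", "stoich": {"s": 1}, "kind": "affine",
                 "affine": {"const": 0.0, "coeffs": {"s": -1.0}}}
            ],
            "domain": {"length": 1.0},
        }
        net = rd.build_network(spec)
        g = rd.build_sr_graph(net)
        assert g.species_neighbors(1) == set()
        with pytest.warns(UserWarning, match="inert"):
            cert = rd.check_conditions(net)
        assert cert.passes
        assert 1 not in cert.c1_indices


class TestCheckConditions:
    def test_complexform_passes_with_expected_partition(self, complexform, cert):
        assert cert.passes
        assert [complexform.species_names[i] for i in cert.c1_indices] == ["C"]
        assert [complexform.species_names[i] for i in cert.c2_indices] == ["R", "L"]
        assert cert.blocks["N11"].tolist() == [[1]]
        assert cert.blocks["N21"].tolist() == [[-1], [-1]]
        assert cert.blocks["N22"].tolist() == [[1, 0], [0, 1]]
        assert cert.affine_params["W"].tolist() == [[-1.0, 0.0], [0.0, -1.0]]
        assert cert.affine_params["w"].tolist() == [1.0, 1.0]

    def test_complex_degradation_fails_count_clause(self):
        fx = example_networks()["complexform_complex_degradation"]
        cert = rd.check_conditions(fx.net)
        assert not cert.passes
        assert cert.c1_indices == []
        assert any("C2" in f for f in cert.failures)

    def test_diffusing_complex_fails_c1(self):
        fx = example_networks()["complexform_diffusing_complex"]
        cert = rd.check_conditions(fx.net)
        assert not cert.passes
        assert any("C1" in f for f in cert.failures)

    def test_singular_n11_flips_verdict(self):
        # two nonlinear reactions with identical columns on the two
        # nondiffusive species: counts match but N11 is rank deficient
        spec = {
            "species": [
                {"name": "a", "diffusion": 1.0, "initial": 1.0},
                {"name": "x1", "diffusion": 0.0, "initial": 1.0},
                {"name": "x2", "diffusion": 0.0, "initial": 1.0},
            ],
            "reactions": [
                {"name": "nl1", "stoich": {"a": -1, "x1": 1, "x2": 1},
                 "kind": "nonlinear",
                 "nonlinear": {"preset": "custom",
                               "rate_fn": lambda c: c[0] / (1 + c[1]),
                               "depends_on": ["a", "x1"]}},
                {"name": "nl2", "stoich": {"a": -1, "x1": 1, "x2": 1},
                 "kind": "nonlinear",
                 "nonlinear": {"preset": "custom",
                               "rate_fn": lambda c: c[0] / (1 + c[2]),
                               "depends_on": ["a", "x2"]}},
                {"name": "turn_a", "stoich": {"a": 1}, "kind": "affine",
                 "affine": {"const": 1.0, "coeffs": {"a": -1.0}}},
            ],
            "domain": {"length": 1.0},
        }
        cert = rd.check_conditions(rd.build_network(spec))
        assert not cert.passes
        assert any("singular" in f for f in cert.failures)

    def test_condition_number_reported_for_passing_networks(self, cert):
        assert cert.n11_condition_number == pytest.approx(1.0)

    @pytest.mark.parametrize("name", list(example_networks()))
    def test_fixture_verdicts(self, name):
        fx = example_networks()[name]
        cert = rd.check_conditions(fx.net)
        assert cert.passes == fx.expect_pass
        if not fx.expect_pass:
            assert cert.failures

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("name", ["complexform", "double_binding"])
    def test_verdict_invariant_under_permutation(self, name, seed):
        fx = example_networks()[name]
        base = rd.check_conditions(fx.net)
        shuffled = permute_network(fx.net, seed)
        cert = rd.check_conditions(shuffled)
        assert cert.passes == base.passes
        base_c1 = {fx.net.species_names[i] for i in base.c1_indices}
        new_c1 = {shuffled.species_names[i] for i in cert.c1_indices}
        assert new_c1 == base_c1


class TestBlockDecomposition:
    def test_zero_block_exactly_zero(self):
        for name, fx in example_networks().items():
            cert = rd.check_conditions(fx.net)
            if not cert.passes:
                continue
            N12 = fx.net.N[np.ix_(cert.c1_indices, cert.r2_indices)]
            assert np.all(N12 == 0), name

    @pytest.mark.parametrize("seed", [3, 11])
    def test_permutation_round_trip(self, seed):
        # reassembling the permuted blocks must reproduce N up to permutation
        net = permute_network(example_networks()["double_binding"].net, seed)
        cert = rd.check_conditions(net)
        assert cert.passes
        rows = cert.c1_indices + cert.c2_indices
        cols = cert.r1_indices + cert.r2_indices
        n1, m1 = len(cert.c1_indices), len(cert.r1_indices)
        rebuilt = np.block(
            [
                [cert.blocks["N11"], np.zeros((n1, len(cert.r2_indices)), dtype=int)],
                [cert.blocks["N21"], cert.blocks["N22"]],
            ]
        )
        assert np.array_equal(rebuilt, net.N[np.ix_(rows, cols)])
        assert cert.blocks["N11"].shape == (n1, m1) and n1 == m1

    def test_requires_passing_certificate(self):
        fx = example_networks()["complexform_diffusing_complex"]
        cert = rd.check_conditions(fx.net)
        with pytest.raises(ValueError):
            block_decomposition(fx.net, cert)


class TestDot:
    def test_complexform_dot_counts(self, complexform):
        dot = to_dot(build_sr_graph(complexform))
        assert dot.count("shape=circle") == 3
        assert dot.count("shape=box") == 3
        assert dot.count(" -- ") == build_sr_graph(complexform).graph.number_of_edges()
        assert "color=red" in dot and "color=black" in dot

    def test_empty_graph_is_valid(self):
        spec = {
            "species": [{"name": "s", "diffusion": 0.0, "initial": 0.0}],
            "reactions": [],
            "domain": {"length": 1.0},
        }
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            g = build_sr_graph(rd.build_network(spec))
        dot = to_dot(g)
        assert dot.startswith("graph") and dot.endswith("}")
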