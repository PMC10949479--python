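"""Flux coupling classification, network topology, and rewiring scores."""

import math

import networkx as nx
import numpy as np
import pytest

from bifidoflux import couplenet, fluxcalc
from bifidoflux.netcore import Metabolite, MetabolicModel, Reaction
from bifidoflux.synthetic_data import END_PRODUCT_EXCHANGES
from .oracles import arrays_to_model, coupling_from_rays, random_network


def _linear_chain():
    """EX_a <- a -> b -> c -> EX_c with a 2:1 stoichiometric step."""
    mets = [Metabolite("a_e", compartment="e"), Metabolite("a_c"),
            Metabolite("b_c"), Metabolite("c_e", compartment="e")]
    rxns = [Reaction("EX_a", {"a_e": -1}, -10, 1000),
            Reaction("At", {"a_e": -1, "a_c": 1}, 0, 1000),
            Reaction("A2B", {"a_c": -1, "b_c": 2}, 0, 1000),
            Reaction("Bt", {"b_c": -1, "c_e": 1}, 0, 1000),
            Reaction("EX_c", {"c_e": -1}, 0, 1000)]
    return MetabolicModel(id="chain", metabolites=mets, reactions=rxns)


def test_chain_interior_pair_fully_coupled_ratio():
    coupling = couplenet.fca(_linear_chain())
    rel = coupling.relation("At", "A2B")
    assert rel.type == "fully"
    # v(A2B) = v(At): one a_c per transported a
    ratio = rel.ratio if rel.reaction_a == "At" else 1 / rel.ratio
    assert ratio == pytest.approx(1.0, abs=1e-6)
    # the 2:1 step doubles downstream flux
    rel = coupling.relation("A2B", "Bt")
    ratio = rel.ratio if rel.reaction_a == "A2B" else 1 / rel.ratio
    assert rel.type == "fully" and ratio == pytest.approx(2.0, abs=1e-6)


def test_branch_point_directional_coupling():
    """A->B with two competing exports: upstream is directionally coupled to
    neither branch alone, but each branch forces the upstream."""
    mets = [Metabolite("a_e", compartment="e"), Metabolite("a_c"),
            Metabolite("b_e", compartment="e"),
            Metabolite("c_e", compartment="e")]
    rxns = [Reaction("EX_a", {"a_e": -1}, -10, 1000),
            Reaction("AB", {"a_e": -1, "a_c": 1}, 0, 1000),
            Reaction("BC", {"a_c": -1, "b_e": 1}, 0, 1000),
            Reaction("BD", {"a_c": -1, "c_e": 1}, 0, 1000),
            Reaction("EX_b", {"b_e": -1}, 0, 1000),
            Reaction("EX_c", {"c_e": -1}, 0, 1000)]
    model = MetabolicModel(id="branch", metabolites=mets, reactions=rxns)
    coupling = couplenet.fca(model)
    rel = coupling.relation("AB", "BC")
    assert rel.type == "directional"
    # the branch (BC) forces the trunk (AB), not vice versa
    forced = rel.reaction_b if rel.direction == "a_to_b" else rel.reaction_a
    assert forced == "AB"
    # the two branches exclude each other on extreme rays: uncoupled
    assert coupling.relation("BC", "BD").type == "uncoupled"


def test_fully_coupled_is_equivalence_with_multiplied_ratios():
    coupling = couplenet.fca(_linear_chain())

    def ratio(a, b):
        rel = coupling.relation(a, b)
        assert rel.type == "fully"
        return rel.ratio if rel.reaction_a == a else 1 / rel.ratio

    assert ratio("At", "Bt") == pytest.approx(
        ratio("At", "A2B") * ratio("A2B", "Bt"), rel=1e-6)


@pytest.mark.parametrize("trial", range(12))
def test_fca_matches_extreme_ray_oracle(trial):
    """LP classification equals brute-force extreme-ray enumeration on
    random networks of <=6 reactions."""
    rng = np.random.default_rng(500 + trial)
    S, lb, ub = random_network(rng, n_mets=int(rng.integers(2, 4)),
                               n_rxns=int(rng.integers(3, 7)))
    model = arrays_to_model(S, lb, ub)
    coupling = couplenet.fca(model)
    A, cols = couplenet._cone_columns(
        model, [r for r in model.reaction_ids() if r not in coupling.blocked])
    expected, ray_blocked = coupling_from_rays(np.asarray(A), cols)
    for pair, (kind, ratio, direction) in expected.items():
        got = coupling.relations.get(pair)
        if got is None:
            continue     # implementation dropped a cone-blocked reaction
        assert got.type == kind, (pair, got, kind)
        if kind == "fully":
            assert got.ratio == pytest.approx(ratio, rel=1e-5), pair
        if kind == "directional":
            assert got.direction == direction, pair


def test_fully_coupled_ratio_holds_in_fva_solutions(bounded_models):
    """A fully coupled pair satisfies v_b = r * v_a in optimal solutions."""
    bounded = bounded_models["3FL"]
    coupling = couplenet.fca(bounded)
    sol = fluxcalc.pfba(bounded)
    checked = 0
    for rel in coupling.pairs(("fully",)):
        va, vb = sol.fluxes[rel.reaction_a], sol.fluxes[rel.reaction_b]
        if abs(va) > 1e-6:
            assert vb == pytest.approx(rel.ratio * va, rel=1e-4, abs=1e-6)
            checked += 1
    assert checked > 5


def test_network_anchored_at_seeds(bounded_models):
    coupling = couplenet.fca(bounded_models["3FL"])
    network = couplenet.build_coupled_network(coupling,
                                              END_PRODUCT_EXCHANGES)
    # the fucosylated condition couples the 1,2-PD exchange to the
    # lactaldehyde reductase step
    assert network.has_edge("EX_12ppd__R_e", "LCARS")
    # blocked succinate seed survives as an isolated node
    assert "EX_succ_e" in network
    assert network.degree("EX_succ_e") == 0
    # every edge endpoint is a node and no self-loops exist
    assert all(u != v for u, v in network.edges)


def test_isolated_seeds_when_uncoupled():
    """Two independent chains: each seed sits in its own component."""
    mets = [Metabolite("a_e", compartment="e"),
            Metabolite("b_e", compartment="e")]
    rxns = [Reaction("EX_a", {"a_e": -1}, -10, 1000),
            Reaction("Adrain", {"a_e": -1}, 0, 1000),
            Reaction("EX_b", {"b_e": -1}, -10, 1000),
            Reaction("Bdrain", {"b_e": -1}, 0, 1000)]
    model = MetabolicModel(id="split", metabolites=mets, reactions=rxns)
    coupling = couplenet.fca(model)
    network = couplenet.build_coupled_network(coupling, ["EX_a", "EX_b"])
    assert not network.has_edge("EX_a", "EX_b")
    assert nx.number_connected_components(network) >= 2


def test_topology_metrics_hand_computed():
    triangle = nx.Graph([(1, 2), (2, 3), (1, 3)])
    metrics = couplenet.topology_metrics(triangle)
    assert metrics["clustering_coefficient"] == pytest.approx(1.0)
    star = nx.star_graph(3)
    assert couplenet.topology_metrics(star)["clustering_coefficient"] == 0.0
    # 5-node toy graph: triangle 1-2-3 plus path 3-4-5
    toy = nx.Graph([(1, 2), (2, 3), (1, 3), (3, 4), (4, 5)])
    metrics = couplenet.topology_metrics(toy)
    assert metrics["n_nodes"] == 5 and metrics["n_edges"] == 5
    # local coefficients: 1, 1, 1/3 (deg 3, one closed pair of 3), 0, 0
    assert metrics["clustering_coefficient"] == pytest.approx(
        (1 + 1 + 1 / 3 + 0 + 0) / 5)
    assert metrics["degree_sequence"] == [3, 2, 2, 2, 1]
    # edge 3-4 lies on all 6 shortest paths between {1,2,3} and {4,5};
    # betweenness normalization divides by n(n-1)/2 = 10
    assert metrics["edge_betweenness"][(3, 4)] == pytest.approx(6 / 10)


def test_power_law_alpha_mle():
    # alpha = 1 + n / sum(ln d): degrees 1,1,2,4 -> 1 + 4/(ln2 + ln4)
    alpha = couplenet.power_law_alpha([1, 1, 2, 4])
    assert alpha == pytest.approx(1 + 4 / (math.log(2) + math.log(4)))
    assert couplenet.power_law_alpha([1, 1]) is None


def test_dn_identical_networks_score_zero():
    g = nx.Graph([(1, 2), (2, 3)])
    scores, consensus = couplenet.dn_rewiring([g.copy(), g.copy()])
    assert all(s.dn_score == 0.0 for s in scores)
    assert consensus.number_of_edges() == 2
    assert all(d["multiplicity"] == 2 for *_, d in consensus.edges(data=True))


def test_dn_disjoint_neighbor_sets_hand_value():
    """Node 0 with neighbors {1,2} in one network and {3,4} in the other:
    incidence vectors (1,1,0,0)/(0,0,1,1), centroid distance sqrt(4)/2 = 1
    per network, mean degree 2 -> Dn = 1/2."""
    g1 = nx.Graph([(0, 1), (0, 2)])
    g2 = nx.Graph([(0, 3), (0, 4)])
    scores, _ = couplenet.dn_rewiring([g1, g2])
    dn = {s.node: s.dn_score for s in scores}
    assert dn[0] == pytest.approx(0.5)


def test_dn_requires_two_networks():
    with pytest.raises(ValueError):
        couplenet.dn_rewiring([nx.Graph()])


def test_graphml_export_roundtrip(tmp_path, bounded_models):
    coupling = couplenet.fca(bounded_models["lactose"])
    network = couplenet.build_coupled_network(coupling,
                                              END_PRODUCT_EXCHANGES)
    path = tmp_path / "net.graphml"
    couplenet.write_graphml(network, path, bounded_models["lactose"])
    back = nx.read_graphml(path)
    assert back.number_of_nodes() == network.number_of_nodes()
    assert back.number_of_edges() == network.number_of_edges()
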