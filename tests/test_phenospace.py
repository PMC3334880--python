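"""Phenotype-space search: neighbors, distances, Steiner trees, forces,
channel redundancy."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest

import phylometab as pm
from phylometab.knowledge_base import EnvironmentSpec, PhenotypeDef
from phylometab import phenospace as ps
from phylometab.phenospace import (
    Change,
    EditAlphabet,
    apply_change,
    channel_redundancy,
    classify_force,
    default_alphabet,
    min_edit_paths,
    steiner_parsimony_tree,
    to_newick,
)


def test_alphabet_is_involutive(bundle):
    alph = default_alphabet(bundle)
    for c in alph.changes:
        assert c.inverse() in alph.changes
        # applying a change then its inverse restores the state
        st = frozenset({"gcs", "ccs"})
        nxt = apply_change(st, c)
        if nxt is not None:
            assert apply_change(nxt, c.inverse()) == st


def test_non_involutive_alphabet_rejected():
    with pytest.raises(ValueError):
        EditAlphabet((Change("add", "ccs"),))


def test_linked_network_neighbors_include_both_divergences(bundle, space):
    """From the linked rTCA-WL network, losing ACS yields the rTCA-hybrid
    phenotype and losing citrate cleavage yields the WL phenotype."""
    nbrs = space.neighbors(space.state_of("linked_rtca_wl"))
    by_change = {c.label(): st for c, st in nbrs}
    assert by_change["-acs"] == space.state_of("rtca_hybrid")
    assert by_change["-ccs"] == space.state_of("wl_acetogen")


def test_neighbors_all_re_pass_viability(bundle, space):
    st = space.state_of("wl_acetogen")
    listed = space.neighbors(st)
    for change, nxt in listed:
        assert space.is_viable(nxt)
    # every omitted applicable variant fails the viability check
    listed_states = {s for _, s in listed}
    for change in space.alphabet.changes:
        nxt = apply_change(st, change)
        if nxt is not None and nxt not in listed_states:
            assert not space.is_viable(nxt)


def test_empty_alphabet_gives_no_neighbors(bundle):
    sp = ps.PhenoSpace(bundle, EditAlphabet(()))
    assert sp.neighbors(sp.state_of("linked_rtca_wl")) == []


def test_rtca_to_wl_distance_two_unique_path_through_linked(bundle, space):
    """No single change connects the rTCA and WL phenotypes while keeping
    autotrophy; the unique two-change path passes through the linked
    rTCA-WL network."""
    d, paths = min_edit_paths("rtca_hybrid", "wl_acetogen", bundle, space=space)
    assert d == 2
    assert len(paths) == 1
    assert paths[0][1] == space.state_of("linked_rtca_wl")


def test_distance_to_self_is_zero(bundle, space):
    d, paths = min_edit_paths("wl_acetogen", "wl_acetogen", bundle, space=space)
    assert d == 0 and len(paths) == 1


def test_edit_distance_is_a_metric_on_tree_nodes(bundle, space):
    """Symmetry (involutive alphabet) and triangle inequality."""
    ids = ["linked_rtca_wl", "rtca_hybrid", "wl_acetogen", "wl_4hb", "dc_4hb"]
    d = {}
    for a, b in itertools.combinations(ids, 2):
        d[(a, b)], _ = min_edit_paths(a, b, bundle, space=space)
        d[(b, a)], _ = min_edit_paths(b, a, bundle, space=space)
        assert d[(a, b)] == d[(b, a)]
    for a, b, c in itertools.permutations(ids, 3):
        assert d[(a, b)] <= d[(a, c)] + d[(c, b)]


def test_observed_set_steiner_inserts_exactly_the_linked_root(bundle, space):
    """The reconstruction inserts exactly one unobserved node -- the linked
    rTCA-WL network -- and its two outgoing edges carry the O2 and ATP
    force labels."""
    res = steiner_parsimony_tree(ps.OBSERVED_SET, bundle, space=space)
    assert res.feasible and res.ties_exhaustive
    assert len(res.trees) == 1
    tree = res.best
    assert tree.inserted_count == 1
    assert tree.inserted[0] == space.state_of("linked_rtca_wl")
    assert tree.root == tree.inserted[0]
    root_edges = [(c, f) for p, _, c, f in tree.rooted_edges(bundle) if p == "HYP_1"]
    assert sorted(f.label for _, f in root_edges) == ["ATP", "O2"]
    # every edge joins viable phenotypes differing by one alphabet change
    for a, b in tree.graph.edges:
        assert space.is_viable(a) and space.is_viable(b)
        assert tree.graph.edges[a, b]["change_from"][a] is not None


def test_single_observed_phenotype_trivial_tree(bundle, space):
    res = steiner_parsimony_tree(["wl_acetogen"], bundle, space=space)
    assert res.feasible and res.optimal_cost == 0
    assert res.best.inserted_count == 0


def test_newick_export(bundle, space):
    res = steiner_parsimony_tree(ps.OBSERVED_SET, bundle, space=space)
    nwk = to_newick(res.best, bundle)
    assert nwk.endswith("HYP_1;")
    import dendropy
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    labels = {l.taxon.label if l.taxon else None for l in tree.leaf_node_iter()}
    assert "hp 4hb" in labels or "hp_4hb" in labels


def _toy_universe(bundle, rng, n_toggles=4):
    """Random sub-alphabet universe over the linked-network core."""
    toggles = list(rng.choice(ps.DEFAULT_TOGGLE_MODULES, size=n_toggles,
                              replace=False))
    changes = []
    for m in toggles:
        changes += [Change("add", m), Change("remove", m)]
    alph = EditAlphabet(tuple(changes))
    sp = ps.PhenoSpace(bundle, alph)
    core = sp.state_of("linked_rtca_wl") - set(ps.DEFAULT_TOGGLE_MODULES)
    fixed = sp.state_of("linked_rtca_wl") & set(ps.DEFAULT_TOGGLE_MODULES) - set(toggles)
    states = []
    for r in range(len(toggles) + 1):
        for combo in itertools.combinations(toggles, r):
            states.append(frozenset(core | fixed | set(combo)))
    viable = [s for s in states if sp.is_viable(s)]
    g = nx.Graph()
    g.add_nodes_from(viable)
    for a, b in itertools.combinations(viable, 2):
        if len(a ^ b) == 1:
            g.add_edge(a, b)
    return sp, g, viable


def _brute_force_steiner_cost(g, terminals):
    """Smallest connected viable superset of the terminals (exhaustive)."""
    others = [n for n in g.nodes if n not in terminals]
    for extra in range(len(others) + 1):
        for combo in itertools.combinations(others, extra):
            nodes = set(terminals) | set(combo)
            if all(n in g for n in terminals):
                sub = g.subgraph(nodes)
                if len(sub) == len(nodes) and nx.is_connected(sub):
                    return len(nodes) - 1
    return None


def test_steiner_matches_brute_force_on_random_toy_universes(bundle):
    """Exact search optimum equals exhaustive Steiner enumeration on random
    small universes."""
    rng = np.random.default_rng(55)
    compared = 0
    for _ in range(12):
        sp, g, viable = _toy_universe(bundle, rng)
        if len(viable) < 3:
            continue
        idx = rng.choice(len(viable), size=min(3, len(viable)), replace=False)
        terminals = [viable[i] for i in idx]
        oracle = _brute_force_steiner_cost(g, terminals)
        res = steiner_parsimony_tree(terminals, bundle, space=sp,
                                     max_inserted=len(viable), no_regain=())
        if oracle is None:
            assert not res.feasible
        else:
            assert res.feasible and res.optimal_cost == oracle
            compared += 1
    assert compared >= 5


def test_infeasibility_reported_when_max_inserted_too_small(bundle, space):
    res = steiner_parsimony_tree(["rtca_hybrid", "wl_acetogen"], bundle,
                                 space=space, max_inserted=0)
    assert not res.feasible
    assert res.disconnected_components


@pytest.mark.parametrize("change,expected", [
    (Change("remove", "acs"), "O2"),
    (Change("remove", "scs"), "ATP"),
    (Change("remove", "ccs"), "ATP"),
    (Change("swap", "pyc", "pyc_hco3"), "ALK"),
    (Change("add", "hp3_arc"), "ALK"),
    (Change("add", "hb4_arc"), "other"),
])
def test_force_classification_rules(bundle, change, expected):
    assert classify_force(change, bundle).label == expected


def test_channel_redundancy_two_at_root_one_elsewhere(bundle):
    """The linked network has two reaction-disjoint acetyl-CoA input
    channels; every derived phenotype has one."""
    assert channel_redundancy("linked_rtca_wl", bundle) == 2
    for pid in ps.OBSERVED_SET:
        assert channel_redundancy(pid, bundle) == 1, pid


def test_channel_redundancy_zero_without_carbon(bundle):
    env = EnvironmentSpec(inorganic_carbon=frozenset())
    assert channel_redundancy("linked_rtca_wl", bundle, environment=env) == 0


def test_redundancy_agrees_with_min_cut(bundle):
    """Max-flow/min-cut cross-check: acetyl-CoA production in the linked
    network survives loss of either single channel but not both, while the
    WL phenotype dies with its single channel."""
    from phylometab.viability import check_viability

    def producible(pid, drop):
        ph = bundle.phenotypes[pid]
        rids = tuple(sorted(ph.reaction_ids(bundle) - set(drop)))
        sub = PhenotypeDef(id="cut", name="", modules=(), extra_reactions=rids,
                           environment=ph.environment)
        rep = check_viability(sub, bundle, targets=("acetyl_coa",))
        return rep.targets["acetyl_coa"].feasible

    assert producible("linked_rtca_wl", [])
    assert producible("linked_rtca_wl", ["acs"])       # rTCA channel remains
    assert producible("linked_rtca_wl", ["ccl"])       # WL channel remains
    assert not producible("linked_rtca_wl", ["acs", "ccl"])
    assert not producible("wl_acetogen", ["acs"])      # single channel
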