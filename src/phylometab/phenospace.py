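"""Phenotype space under the autotrophy constraint.

Phenotypes are module sets; the edit alphabet is a set of involutive atomic
changes (gain or loss of one pathway module, or a CO2<->bicarbonate swap on
the anaplerotic carboxylation).  Every state visited by any search must pass
the autotrophic viability check, which encodes the requirement that
evolutionary sequences maintain uninterrupted access to all biomass entry
points.  On top of this constrained graph the module provides single-change
neighborhoods, minimal edit paths (breadth-first search over viable states
only), an exact Steiner maximum-parsimony tree with inserted unobserved
nodes, rule-based evolutionary-force labels for changes, and the
acetyl-CoA input-channel redundancy count.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .knowledge_base import Bundle, EnvironmentSpec, PhenotypeDef
from .stoich import build_flux_problem
from .viability import default_targets

__all__ = [
    "Change",
    "EditAlphabet",
    "default_alphabet",
    "PhenoSpace",
    "ForceLabel",
    "classify_force",
    "viable_neighbors",
    "min_edit_paths",
    "SteinerResult",
    "ParsimonyTree",
    "steiner_parsimony_tree",
    "channel_redundancy",
    "to_newick",
    "OBSERVED_SET",
    "SEARCH_ENVIRONMENT",
]

#: default observed terminal set for the carbon-fixation tree reconstruction
OBSERVED_SET = ("rtca_hybrid", "wl_acetogen", "wl_4hb", "dc_4hb", "hp_4hb",
                 "cbb_lineage", "cbb_glyox")

#: permissive anoxic search environment: both dissolved CO2 and bicarbonate
#: available, reductant and ATP supplied.  Evolutionary forces are attributes
#: of changes, not of this environment.
SEARCH_ENVIRONMENT = EnvironmentSpec(
    o2_present=False, inorganic_carbon=frozenset({"CO2", "HCO3"}))

#: modules toggled by the default (innovation-granular) edit alphabet
DEFAULT_TOGGLE_MODULES = (
    "acs", "ccs", "scs", "hb4_arc", "hp3_arc", "rtca_arc1", "rtca_arc2",
    "cbb", "ox_serine", "glyox",
)
DEFAULT_SWAPS = (("pyc", "pyc_hco3"),)

#: loss-only characters in the reconstruction profile: once the complex
#: ATP-dependent citryl-CoA / succinyl-CoA synthetases or the CODH/ACS
#: complex are lost they are not easily recovered, so rooted trees may not
#: gain them along any root-to-leaf edge.
DEFAULT_NO_REGAIN = ("ccs", "scs", "acs")


@dataclass(frozen=True)
class Change:
    """One atomic phenotype change: ``add``/``remove`` a module, or ``swap``
    module ``module`` for ``other`` (carbon-species swap)."""

    kind: str
    module: str
    other: str | None = None

    def inverse(self) -> "Change":
        if self.kind == "add":
            return Change("remove", self.module)
        if self.kind == "remove":
            return Change("add", self.module)
        return Change("swap", self.other, self.module)

    def label(self) -> str:
        if self.kind == "swap":
            return f"{self.module}->{self.other}"
        return f"{'+' if self.kind == 'add' else '-'}{self.module}"


@dataclass(frozen=True)
class EditAlphabet:
    changes: tuple[Change, ...]

    def __post_init__(self) -> None:
        have = set(self.changes)
        missing = [c for c in self.changes if c.inverse() not in have]
        if missing:
            raise ValueError(f"alphabet not involutive; missing inverses for {missing}")


def default_alphabet(
    bundle: Bundle,
    granularity: str = "module",
) -> EditAlphabet:
    """Module-granular alphabet (innovation level).  ``granularity='reaction'``
    instead toggles every reaction of the listed modules individually, for
    sensitivity analysis."""
    changes: list[Change] = []
    if granularity == "module":
        for mod in DEFAULT_TOGGLE_MODULES:
            changes += [Change("add", mod), Change("remove", mod)]
    elif granularity == "reaction":
        for mod in DEFAULT_TOGGLE_MODULES:
            for rid in bundle.modules[mod]:
                changes += [Change("add", f"rxn:{rid}"), Change("remove", f"rxn:{rid}")]
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    for a, b in DEFAULT_SWAPS:
        changes += [Change("swap", a, b), Change("swap", b, a)]
    return EditAlphabet(tuple(changes))


def apply_change(state: frozenset[str], change: Change) -> frozenset[str] | None:
    """Apply a change to a module-set state; None if not applicable."""
    if change.kind == "add":
        return state | {change.module} if change.module not in state else None
    if change.kind == "remove":
        return state - {change.module} if change.module in state else None
    if change.module in state and change.other not in state:
        return (state - {change.module}) | {change.other}
    return None


class PhenoSpace:
    """Cached viability oracle and adjacency over module-set states."""

    def __init__(self, bundle: Bundle, alphabet: EditAlphabet | None = None,
                 environment: EnvironmentSpec = SEARCH_ENVIRONMENT):
        self.bundle = bundle
        self.alphabet = alphabet or default_alphabet(bundle)
        self.environment = environment
        self.targets = default_targets(bundle)
        self._viable: dict[frozenset[str], bool] = {}

    def state_of(self, phenotype: PhenotypeDef | str) -> frozenset[str]:
        if isinstance(phenotype, str):
            phenotype = self.bundle.phenotypes[phenotype]
        mods: set[str] = set(phenotype.modules)
        for rid in phenotype.extra_reactions:
            mods.add(f"rxn:{rid}")
        return frozenset(mods)

    def _phenotype(self, state: frozenset[str]) -> PhenotypeDef:
        mods = tuple(sorted(m for m in state if not m.startswith("rxn:")))
        extra = tuple(sorted(m[4:] for m in state if m.startswith("rxn:")))
        return PhenotypeDef(id="state", name="", modules=mods,
                            extra_reactions=extra, environment=self.environment)

    def is_viable(self, state: frozenset[str]) -> bool:
        """Single feasibility LP: all targets simultaneously at unit demand
        (equivalent to per-target feasibility since resources are unbounded)."""
        if state not in self._viable:
            problem = build_flux_problem(self._phenotype(state), self.bundle,
                                         targets=self.targets,
                                         environment=self.environment)
            caps = {}
            for t in self.targets:
                j = problem.col_index("demand", t)
                caps[j] = 1.0
            sol = problem.solve(np.zeros(len(problem.columns)),
                                extra_lb=caps, extra_ub=caps)
            self._viable[state] = sol is not None
        return self._viable[state]

    def neighbors(self, state: frozenset[str]) -> list[tuple[Change, frozenset[str]]]:
        """Viable single-change variants."""
        out = []
        for change in self.alphabet.changes:
            nxt = apply_change(state, change)
            if nxt is not None and self.is_viable(nxt):
                out.append((change, nxt))
        return out

    def viable_component(self, seeds: Iterable[frozenset[str]]) -> nx.Graph:
        """Full viable component(s) reachable from the seed states."""
        g = nx.Graph()
        stack = [s for s in seeds if self.is_viable(s)]
        g.add_nodes_from(stack)
        seen = set(stack)
        while stack:
            state = stack.pop()
            for change, nxt in self.neighbors(state):
                g.add_edge(state, nxt, change=change)
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return g


def viable_neighbors(
    phenotype: PhenotypeDef | str,
    bundle: Bundle,
    alphabet: EditAlphabet | None = None,
    environment: EnvironmentSpec = SEARCH_ENVIRONMENT,
) -> list[tuple[Change, frozenset[str]]]:
    space = PhenoSpace(bundle, alphabet, environment)
    return space.neighbors(space.state_of(phenotype))


def min_edit_paths(
    a: PhenotypeDef | str,
    b: PhenotypeDef | str,
    bundle: Bundle,
    alphabet: EditAlphabet | None = None,
    environment: EnvironmentSpec = SEARCH_ENVIRONMENT,
    space: PhenoSpace | None = None,
) -> tuple[float, list[tuple[frozenset[str], ...]]]:
    """BFS over viable states only; returns (distance, all minimal paths).

    Distance is ``math.inf`` when the goal is not in the viable component of
    the start.
    """
    space = space or PhenoSpace(bundle, alphabet, environment)
    start, goal = space.state_of(a), space.state_of(b)
    if not (space.is_viable(start) and space.is_viable(goal)):
        raise ValueError("min_edit_paths requires viable endpoints")
    if start == goal:
        return 0, [(start,)]
    dist = {start: 0}
    preds: dict[frozenset[str], list[frozenset[str]]] = {start: []}
    frontier = [start]
    d = 0
    while frontier and goal not in dist:
        d += 1
        nxt_frontier: list[frozenset[str]] = []
        for state in frontier:
            for _, nxt in space.neighbors(state):
                if nxt not in dist:
                    dist[nxt] = d
                    preds[nxt] = [state]
                    nxt_frontier.append(nxt)
                elif dist[nxt] == d:
                    preds[nxt].append(state)
        frontier = nxt_frontier
    if goal not in dist:
        return math.inf, []

    paths: list[tuple[frozenset[str], ...]] = []

    def _walk(node: frozenset[str], tail: tuple[frozenset[str], ...]) -> None:
        if node == start:
            paths.append((start,) + tail)
            return
        for p in preds[node]:
            _walk(p, (node,) + tail)

    _walk(goal, ())
    return dist[goal], sorted(paths, key=lambda p: [sorted(s) for s in p])


@dataclass(frozen=True)
class ForceLabel:
    label: str  # O2 | ATP | ALK | other
    rationale: str


def classify_force(change: Change, bundle: Bundle) -> ForceLabel:
    """Rule-based evolutionary force behind a change.

    Loss of an O2-sensitive reaction -> O2 (oxygen toxicity); loss of an
    ATP-consuming reaction -> ATP (energy optimization); a CO2->bicarbonate
    swap or gain of a bicarbonate-using module -> ALK (alkalinity shift);
    anything else -> other.
    """
    def rxns(mod: str):
        if mod.startswith("rxn:"):
            return (bundle.reactions[mod[4:]],)
        return tuple(bundle.reactions[r] for r in bundle.modules.get(mod, ()))

    if change.kind == "swap":
        gained = rxns(change.other)
        if any(r.carbon_species == "HCO3" for r in gained):
            return ForceLabel("ALK", "swap to a bicarbonate-consuming carboxylation")
        return ForceLabel("other", "carbon-species swap")
    if change.kind == "remove":
        rs = rxns(change.module)
        if any(r.o2_sensitive for r in rs):
            return ForceLabel("O2", "loss of an oxygen-sensitive enzyme")
        if any(r.atp_events > 0 for r in rs):
            return ForceLabel("ATP", "elimination of an ATP-consuming reaction")
        return ForceLabel("other", "module loss")
    rs = rxns(change.module)
    if any(r.carbon_species == "HCO3" for r in rs):
        return ForceLabel("ALK", "gain of a bicarbonate-consuming pathway")
    return ForceLabel("other", "module gain")


@dataclass(frozen=True)
class ParsimonyTree:
    """Tree over observed + inserted phenotype states with labeled edges."""

    graph: nx.Graph
    root: frozenset[str]
    observed: Mapping[frozenset[str], str]  # state -> phenotype id
    inserted: tuple[frozenset[str], ...]
    total_changes: int

    @property
    def inserted_count(self) -> int:
        return len(self.inserted)

    def node_name(self, state: frozenset[str]) -> str:
        if state in self.observed:
            return self.observed[state]
        idx = self.inserted.index(state)
        return f"HYP_{idx + 1}"

    def rooted_edges(self, bundle: Bundle) -> list[tuple[str, str, Change, ForceLabel]]:
        """Edges oriented away from the root, with change and force labels."""
        out = []
        for parent, child in nx.bfs_edges(self.graph, self.root):
            change = self.graph.edges[parent, child]["change_from"][parent]
            out.append((self.node_name(parent), self.node_name(child),
                        change, classify_force(change, bundle)))
        return out


@dataclass(frozen=True)
class SteinerResult:
    trees: tuple[ParsimonyTree, ...]
    optimal_cost: int | None
    feasible: bool
    disconnected_components: tuple[tuple[str, ...], ...] = ()
    ties_exhaustive: bool = True

    @property
    def best(self) -> ParsimonyTree:
        if not self.trees:
            raise ValueError("no feasible parsimony tree")
        return self.trees[0]


def _change_between(a: frozenset[str], b: frozenset[str],
                    alphabet: EditAlphabet) -> Change | None:
    for change in alphabet.changes:
        if apply_change(a, change) == b:
            return change
    return None


def _valid_rootings(tree: nx.Graph, forbidden: Iterable[str]) -> list:
    """Roots under which no forbidden module is gained on a rooted edge."""
    forbidden = set(forbidden)
    roots = []
    for root in tree.nodes:
        ok = True
        for parent, child in nx.bfs_edges(tree, root):
            change = tree.edges[parent, child]["change_from"][parent]
            if change is not None and change.kind == "add" and change.module in forbidden:
                ok = False
                break
        if ok:
            roots.append(root)
    return roots


def steiner_parsimony_tree(
    observed: Sequence[str],
    bundle: Bundle,
    alphabet: EditAlphabet | None = None,
    max_inserted: int = 3,
    environment: EnvironmentSpec = SEARCH_ENVIRONMENT,
    space: PhenoSpace | None = None,
    no_regain: Sequence[str] = DEFAULT_NO_REGAIN,
) -> SteinerResult:
    """Minimum-change tree over viable phenotypes connecting the observed set.

    Every tree node (observed terminals and inserted unobserved nodes alike)
    must be a viable phenotype and every edge a single alphabet change, so the
    total change count of a tree on ``k`` nodes is ``k - 1`` and the optimum
    is the smallest viable node superset of the terminals whose induced
    single-change graph is connected.  The search enumerates the full viable
    component around the terminals (exhaustive at fixture scale), finds the
    optimal insertion count by exhaustive subset search (a Steiner-tree
    dynamic program over terminal subsets provides the admissible bound), and
    returns all co-optimal trees in deterministic order.  For more than two
    insertions only the dynamic-program optimum is returned
    (``ties_exhaustive=False``).

    ``no_regain`` applies the reconstruction profile's directionality
    constraint as a tie filter: co-optimal trees are kept only if some
    rooting gains none of the listed loss-only modules along a rooted edge
    (the root is then chosen among valid rootings, preferring inserted
    nodes).  It never changes the optimal cost; pass ``no_regain=()`` for the
    unconstrained tie set.
    """
    space = space or PhenoSpace(bundle, alphabet, environment)
    alphabet = space.alphabet
    term_states: dict[frozenset[str], str] = {}
    for i, pid in enumerate(observed):
        st = pid if isinstance(pid, frozenset) else space.state_of(pid)
        name = pid if isinstance(pid, str) else f"T{i}"
        if not space.is_viable(st):
            raise ValueError(f"observed phenotype {name} is not viable in the search environment")
        term_states[st] = name
    terminals = list(term_states)

    g = space.viable_component(terminals)
    comp_of = {n: i for i, comp in enumerate(nx.connected_components(g)) for n in comp}
    groups: dict[int, list[str]] = {}
    for st, pid in term_states.items():
        groups.setdefault(comp_of[st], []).append(pid)
    if len(groups) > 1:
        return SteinerResult(trees=(), optimal_cost=None, feasible=False,
                             disconnected_components=tuple(
                                 tuple(sorted(v)) for v in groups.values()))

    # Steiner DP (Dreyfus-Wagner) for the optimal edge count.
    opt_cost = _dreyfus_wagner(g, terminals)
    extra_needed = opt_cost + 1 - len(terminals)

    trees: list[ParsimonyTree] = []
    exhaustive = extra_needed <= 2
    if exhaustive:
        pool = sorted((n for n in g.nodes if n not in term_states),
                      key=lambda s: tuple(sorted(s)))
        for combo in itertools.combinations(pool, extra_needed):
            nodes = set(terminals) | set(combo)
            sub = g.subgraph(nodes)
            if sub.number_of_nodes() == len(nodes) and nx.is_connected(sub):
                trees.extend(_trees_from_nodes(sub, term_states, combo, alphabet,
                                               opt_cost))
    else:
        nodes = _dreyfus_wagner(g, terminals, return_nodes=True)
        sub = g.subgraph(nodes)
        combo = tuple(n for n in nodes if n not in term_states)
        trees.extend(_trees_from_nodes(sub, term_states, combo, alphabet, opt_cost))

    if extra_needed > max_inserted:
        return SteinerResult(trees=(), optimal_cost=opt_cost, feasible=False,
                             disconnected_components=(tuple(sorted(observed)),),
                             ties_exhaustive=exhaustive)
    if no_regain:
        constrained = []
        for t in trees:
            roots = _valid_rootings(t.graph, no_regain)
            if roots:
                root = next((r for r in t.inserted if r in roots),
                            sorted(roots, key=lambda s: tuple(sorted(s)))[0])
                constrained.append(replace(t, root=root))
        if constrained:  # directionality is a tie filter, never a cost constraint
            trees = constrained
    trees.sort(key=lambda t: tuple(sorted(tuple(sorted(s)) for s in t.graph.nodes)))
    return SteinerResult(trees=tuple(trees), optimal_cost=opt_cost, feasible=True,
                         ties_exhaustive=exhaustive)


def _trees_from_nodes(sub: nx.Graph, term_states, inserted, alphabet,
                      opt_cost) -> list[ParsimonyTree]:
    out = []
    base = nx.Graph(sub.edges)
    count = 0
    for t in nx.SpanningTreeIterator(base):
        tree = nx.Graph()
        tree.add_nodes_from(sub.nodes)
        for a, b in t.edges:
            ch_ab = _change_between(a, b, alphabet)
            tree.add_edge(a, b, change_from={a: ch_ab, b: ch_ab.inverse() if ch_ab else None})
        root = inserted[0] if inserted else sorted(
            term_states, key=lambda s: tuple(sorted(s)))[0]
        out.append(ParsimonyTree(graph=tree, root=root,
                                 observed=dict(term_states),
                                 inserted=tuple(inserted),
                                 total_changes=opt_cost))
        count += 1
        if count >= 20:  # deterministic cap on tie enumeration
            break
    return out


def _dreyfus_wagner(g: nx.Graph, terminals: Sequence, return_nodes: bool = False):
    """Exact minimum Steiner tree (edge count) via the Dreyfus-Wagner DP."""
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    dist = dict(nx.all_pairs_shortest_path_length(g))
    t = len(terminals)
    full = (1 << t) - 1
    INF = float("inf")
    dp = [[INF] * len(nodes) for _ in range(full + 1)]
    choice: dict[tuple[int, int], tuple] = {}
    for i, term in enumerate(terminals):
        for n in nodes:
            d = dist[term].get(n, INF)
            dp[1 << i][idx[n]] = d
    for mask in range(1, full + 1):
        if mask & (mask - 1) == 0:
            continue
        for n in nodes:
            j = idx[n]
            sub = (mask - 1) & mask
            while sub:
                if sub < (mask ^ sub):  # each split once
                    val = dp[sub][j] + dp[mask ^ sub][j]
                    if val < dp[mask][j]:
                        dp[mask][j] = val
                        choice[(mask, j)] = ("split", sub)
                sub = (sub - 1) & mask
        # relax by shortest paths
        order = sorted(nodes, key=lambda n: dp[mask][idx[n]])
        for n in order:
            j = idx[n]
            for m in nodes:
                k = idx[m]
                d = dist[n].get(m, INF)
                if dp[mask][j] + d < dp[mask][k]:
                    dp[mask][k] = dp[mask][j] + d
                    choice[(mask, k)] = ("walk", j)
    best_j = min(range(len(nodes)), key=lambda j: dp[full][j])
    if not return_nodes:
        return int(dp[full][best_j])

    # traceback one optimal node set
    used: set = set()

    def _trace(mask: int, j: int) -> None:
        used.add(nodes[j])
        if mask & (mask - 1) == 0:
            i = mask.bit_length() - 1
            path = nx.shortest_path(g, terminals[i], nodes[j])
            used.update(path)
            return
        act = choice.get((mask, j))
        if act is None:
            i = mask.bit_length() - 1
            used.update(nx.shortest_path(g, terminals[i], nodes[j]))
            return
        if act[0] == "split":
            _trace(act[1], j)
            _trace(mask ^ act[1], j)
        else:
            used.update(nx.shortest_path(g, nodes[act[1]], nodes[j]))
            _trace(mask, act[1])

    _trace(full, best_j)
    return used


def channel_redundancy(
    phenotype: PhenotypeDef | str,
    bundle: Bundle,
    target: str = "acetyl_coa",
    environment: EnvironmentSpec | None = None,
) -> int:
    """Maximum number of reaction-disjoint inorganic-carbon -> target routes.

    Computed as a max-flow LP with unit capacity on every reaction column
    (each direction of a reversible reaction counts separately) and the
    target demand maximized; the optimum is integral on the packaged
    networks and is cross-validated by route enumeration in the test suite.
    """
    if isinstance(phenotype, str):
        phenotype = bundle.phenotypes[phenotype]
    problem = build_flux_problem(phenotype, bundle, targets=(target,),
                                 environment=environment)
    jd = problem.col_index("demand", target)
    obj = np.zeros(len(problem.columns))
    obj[jd] = -1.0
    caps = {j: 1.0 for j, c in enumerate(problem.columns) if c.kind == "rxn"}
    caps[jd] = float(len(problem.columns))
    problem.ub[jd] = float(len(problem.columns))
    sol = problem.solve(obj, extra_ub=caps)
    if sol is None:
        return 0
    val = -sol[0]
    return int(round(val)) if abs(val - round(val)) < 1e-6 else int(val)


def to_newick(tree: ParsimonyTree, bundle: Bundle) -> str:
    """Newick export rooted at the tree's root; inserted nodes named HYP_*."""
    def _sub(node, parent) -> str:
        children = [n for n in tree.graph.neighbors(node) if n != parent]
        name = tree.node_name(node)
        if not children:
            return name
        inner = ",".join(sorted(_sub(c, node) for c in children))
        return f"({inner}){name}"

    return _sub(tree.root, None) + ";"
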