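# phylometab

Phylometabolic analysis of carbon-fixation evolution: a toolkit that joins
metabolic flux-balance viability constraints with phylogenetic gene-profile
comparison to reconstruct how the six known autotrophic carbon-fixation
pathways diverged from a single ancestral network.

It is written for researchers in systems biology and early evolution who
want to (a) test whether a hypothesized carbon-fixation phenotype is a
viable autotroph, (b) account for the ATP and reductant cost of biosynthetic
routes, (c) call pathway completeness from enzyme presence/absence profiles
and aggregate it across clades, and (d) search phenotype space for
maximum-parsimony trees whose every node — including inserted, unobserved
ancestors — remains a viable autotroph.

## The model in brief

A phenotype is a reaction-module set plus an environment.  Autotrophic
viability is flux-balance feasibility at steady state,

    dC_n/dt = sum_m S_nm v_m = 0,    Z = sum_m c_m v_m > 0,

demanded separately for each biomass entry point: the five universal
anabolic precursors (acetyl-CoA, pyruvate, oxaloacetate, succinyl-CoA,
2-oxoglutarate) plus glycine and serine, the only precursors reachable
directly from CO2 on the tetrahydrofolate (THF) one-carbon pathway.
Biosynthetic costs are lexicographic LP minima (ATP first, then reductant in
H2 equivalents) at unit production; the degree of reduction
γ/2 = (4C + H − 2O − 3N)/2 gives the exact reductant lower bound.
Parsimony search runs over an involutive edit alphabet of pathway-module
gains and losses, with every visited state filtered by the viability LP; the
Steiner optimum is found exactly and inserted nodes are reported as
hypothesized ancestors.  See `docs/methods.md` for conventions and
limitations.

## Worked example

```python
import phylometab as pm
from phylometab import phenospace as ps

bundle = pm.default_knowledge_base()

# 1. Is the linked rTCA-WL network a viable autotroph on CO2?
report = pm.check_viability(bundle.phenotypes["linked_rtca_wl"], bundle)
print(report.overall_viable)            # True (all 7 targets producible)

# 2. What does glycine cost on the reductive THF pathway?
cost = pm.min_cost(bundle.phenotypes["ctx_red_thf"], bundle, "glycine")
print(cost.cell())                      # 1 ATP+3 Red

# 3. How are the rTCA and WL phenotypes connected?
d, paths = ps.min_edit_paths("rtca_hybrid", "wl_acetogen", bundle)
print(d, len(paths))                    # 2 1   (unique two-change path)

# 4. Reconstruct the phylometabolic tree over the observed phenotypes.
res = ps.steiner_parsimony_tree(ps.OBSERVED_SET, bundle)
tree = res.best
print(tree.inserted_count)              # 1   (the linked rTCA-WL root)
print(ps.channel_redundancy("linked_rtca_wl", bundle))  # 2
```

The single inserted node is the linked rTCA-WL network; its two outgoing
edges carry the O2 (loss of the oxygen-sensitive CODH/ACS complex, toward
the rTCA lineage) and ATP (loss of the ATP-dependent citrate cleavage,
toward the WL lineage) force labels.  Interpretation: no single change
connects rTCA and WL phenotypes while maintaining autotrophy, and the unique
two-change path passes through a root with two redundant acetyl-CoA input
channels — every derived phenotype has one.

The same computations are exposed on the command line:

```
phylometab validate-kb
phylometab cost-table
phylometab summarize            # clade pathway-call table (359 strains)
phylometab tree --newick-out tree.nwk
phylometab simulate-profiles --seed 7 --miss-rate 0.1
```

`phylometab cost-table` prints, per context, the glycine and serine costs —
for the reductive pathway `1 ATP+3 Red` / `2 ATP+5 Red`, for the oxidative
route in an rTCA autotroph `3 ATP+4 Red` / `3 ATP+5 Red`, and for WL
contexts on THF and H4MPT carriers `2 ATP+4 Red` / `2 ATP+5 Red` and
`1 ATP+4 Red` / `1 ATP+5 Red` respectively — the H4MPT row showing the ATP
saving of ATP-free formyl activation on modified folates.

## Data tables

The packaged knowledge base (`src/phylometab/data/`) ships as plain TSV:
reactions (EC-annotated stoichiometry with module assignments), metabolites
(formulas, the five precursor flags, carrier flags), pathway-call
definitions, phenotype definitions, per-clade call counts, and synthetic
exemplar profiles.  User-supplied tables in the same schemas can override
any of them (`load_knowledge_base({"reactions": path, ...})`).
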