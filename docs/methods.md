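# Methods

`phylometab` implements *phylometabolic analysis* — the joint use of
metabolic flux-balance constraints and phylogenetic gene-profile comparison —
for the early evolution of biological carbon fixation.  This note documents
the model, the conventions behind every number the toolkit produces, and the
limits of what the packaged fixtures can show.

## The viability model

A carbon-fixation phenotype is a named set of reaction modules plus an
environment.  Viability is the biochemical autotrophy constraint: every
universal anabolic precursor — acetyl-CoA, pyruvate, oxaloacetate,
succinyl-CoA and 2-oxoglutarate, the five metabolites from which all
anabolic pathways branch — plus glycine and serine (the only biomass entry
points reachable from inorganic carbon without passing through the TCA
intermediates) must be producible from the environment.

Producibility is decided by linear programming over the steady-state
constraint `S v = 0`:

* reversible reactions are split into two irreversible columns with bounds
  `[0, 1000]` (the LP is scale-free; the demand is fixed at one unit);
* the environment contributes import columns (its inorganic carbon species,
  ammonia, water, phosphate, and — when enabled — reductant and ATP) and a
  fixed list of waste exports (CO2, formate, ammonia, water, phosphate,
  reductant);
* each target gets a unit-capacity demand column; carrier-bound targets
  (acetyl-CoA, succinyl-CoA) release their free carrier on exit;
* a target is producible iff the maximized demand flux exceeds 1e-6
  (operationalizing a strictly positive output, which is not directly
  LP-expressible), and a phenotype is viable iff every target is producible.
  Each target gets its own LP because the criterion is access to each
  anabolic branching point, not a growth-rate optimum.

Oxygen is a binary selective filter, not a rate effect: when the
environment contains O2, oxygen-sensitive reactions (the CODH/ACS complex)
are removed before solving.

### Bookkeeping conventions

ATP and reductant are dedicated pseudo-metabolites.  One ATP unit is one
ATP-to-ADP-equivalent hydrolysis (ATP-to-AMP counts two; GTP counts as ATP;
pyruvate-to-PEP is counted as one unit).  One reductant unit is one H2
equivalent (two electrons): NAD(P)H, a reduced ferredoxin pair and H2 each
count one.  Cofactors (THF, H4MPT, lipoamide, CoA, the glutamate/2-
oxoglutarate amino shuttle) are conserved internal pairs, never exchanged.

To make element balance checkable, the ATP pseudo-metabolite carries the
nominal formula of the transferred phosphoryl group (HO3P) and reductant the
formula H2; carrier moieties are pseudo-elements (`Thf`, `Mpt`, `Lip`,
`Coa`).  With these conventions every packaged reaction balances C, N, O, P
and the carrier moieties exactly; protons and water are free, so H is not
balanced per-reaction (the validator and tests check this invariant).

The *degree of reduction* of a metabolite with formula CcHhNnOo is
`(4c + h - 2o - 3n)/2` H2 equivalents relative to the CO2/H2O/NH3 baseline.
It is an exact lower bound on the reductant cost of producing that
metabolite and is additive over balanced reactions, which the test suite
uses as an independent check on every reductant entry.

## Cost accounting

`min_cost` fixes the target demand at one unit, minimizes the ATP import
flux, then minimizes the reductant import flux with ATP capped at its
optimum plus 1e-7 (lexicographic LP).  Costs within 1e-6 of an integer are
snapped and flagged integral; anything else is reported as-is and flagged.

The four packaged costing contexts reproduce the glycine/serine cost table:

| context | glycine | serine |
|---|---|---|
| reductive THF pathway | 1 ATP + 3 Red | 2 ATP + 5 Red |
| oxidative route in an rTCA autotroph | 3 ATP + 4 Red | 3 ATP + 5 Red |
| oxidative route in a WL (THF) autotroph | 2 ATP + 4 Red | 2 ATP + 5 Red |
| oxidative route in a WL (H4MPT) autotroph | 1 ATP + 4 Red | 1 ATP + 5 Red |

Conventions that these cells depend on (each encoded as explicit reaction
stoichiometry in `reactions.tsv`, hence overridable by a user table):

* rTCA charges two ATP-coupled CoA activations per acetyl-CoA (succinyl-CoA
  and citryl-CoA synthetases); WL on THF charges one ATP (formyl-THF
  synthase); WL on H4MPT charges none (the H4MPT formyl activation is
  ATP-free — the energetic consequence of the modified-folate chemistry,
  which is the only aspect of pterin structure this package encodes).
* Transamination costs one reductant through glutamate regeneration and the
  3-PG oxidation credits one; they cancel, so oxidative serine always costs
  the 5 H2 equivalents of its degree of reduction.
* Surplus methylene-THF released by serine cleavage in oxidative contexts is
  discharged as formate: one reductant credited, no ATP.  In the WL contexts
  this is encoded as a lumped convention reaction (`shmtox`) whose formate
  leaves as non-recyclable waste: a whole-network optimum would otherwise
  recycle the surplus C1 through the methyl branch and acetyl-CoA synthase
  back into the next serine, which the route-level accounting deliberately
  excludes.  The rTCA oxidative context needs no lump — its discharge runs
  mechanistically through SHMT reverse and the formyl-THF hydrolase.
* ATP-coupled activations are written irreversible so ATP is never
  recovered by running them backwards; succinyl-CoA synthetase is the
  deliberate exception (substrate-level phosphorylation), and formate
  dehydrogenase is written CO2-to-formate only, following the observation
  that the enzyme does not run oxidatively in obligate autotrophs of the
  relevant clades.

Step counting finds a minimal-total-flux route on the pathway definition's
reaction set and counts its support, with the glycine cleavage system
counted as its four protein components (P, H, T, L; the H carrier protein
has no EC number, which is why the EC list shows only three entries).  This
yields 8 steps for autotrophic CO2-to-glycine, 7 for the heterotrophic
formate entry, 3 for the oxidative route and 1 for glyoxylate
transamination.

## Pathway calling and the clade table

A pathway call requires every reaction of the definition present and every
reaction of its exclusion set absent.  The reductive call (`Red`) requires
reactions 2–8: the clade table combines the autotrophic (from CO2) and
heterotrophic (from formate) forms, so formate dehydrogenase (reaction 1) is
counted in its own column — this is also the only reading consistent with
the Thermotogae row (11 Red, 1 FDH).  `Red(-2)` requires 3–8 present *and*
reaction 2 absent.  A `?` entry is treated as absent but surfaces as a
coverage caveat on the clade summary.

The strain-level fixture behind the clade table is synthesized: the original
359 genome annotations are not shipped, so `synthesize_clade_profiles`
constructs, per clade row, a minimal strain set whose calls aggregate to the
row counts exactly (reductive strains get 2–8, the seven-reaction form
gets 3–8, glycine-cycle-only strains 5–8, with oxidative/glyoxylate/FDH
complements overlaid).  The six exemplar profiles in
`example_profiles.tsv` are likewise synthetic reconstructions of described
full profiles.  Archaeal reductive calls are structurally undercounted in
homology-based searches (pterin-C1 enzymes diverge from their THF
homologues); the toolkit exposes this as a caveat rather than inventing a
correction, and the archaeal "lacking only reaction 5" variant can be
expressed as a user pathway definition.

The profile generator emulates annotation misses only: each assigned
enzyme is dropped independently at a global or per-reaction rate.  It does
not model correlated misses within operons, contamination, or genuine gene
content variation within clades, so generator-based tests validate the
calling and aggregation machinery, not annotation pipelines.

## Phenotype space and the parsimony reconstruction

The edit alphabet is innovation-granular: gain or loss of the acetyl-CoA
synthase (CODH/ACS), citryl-CoA synthetase, succinyl-CoA synthetase, the two
rTCA arcs, the 4HB and 3HP arcs, CBB, the oxidative serine route and the
glyoxylate route, plus a CO2-to-bicarbonate swap on the anaplerotic
carboxylation (one swap per arc).  A reaction-granular alphabet is available
for sensitivity analysis.  All changes are involutive, so edit distance is
symmetric; searches run in a permissive anoxic environment (CO2 and
bicarbonate, reductant and ATP available) and every visited state must pass
the viability check — evolutionary forces are attributes of changes, not of
the search environment.

`min_edit_paths` is breadth-first search over viable states returning all
minimal paths.  `steiner_parsimony_tree` exploits the fact that every tree
edge is a single change, so a tree on k viable nodes costs k-1 changes and
the optimum is the smallest viable node superset of the terminals whose
induced single-change graph is connected.  The search enumerates the viable
component around the terminals (about 1.6k states on the packaged problem, a
few seconds of LP time), computes the optimal cost with the Dreyfus–Wagner
Steiner dynamic program, and enumerates all co-optimal node sets
exhaustively when at most two insertions are needed; spanning-tree ties are
enumerated (capped at 20) in deterministic order.  A brute-force oracle in
the test suite confirms the optimum on random toy universes.

The reconstruction profile applies one directionality constraint as a
*tie filter*: the complex ATP-dependent citryl-CoA/succinyl-CoA synthetases
and the CODH/ACS complex are loss-only characters (once lost, not easily
recovered), so co-optimal trees requiring their re-gain under every rooting
are discarded.  On the packaged terminal set this uniquely selects the tree
rooted at the inserted linked rTCA-WL network, whose two root edges carry
the O2 (loss of CODH/ACS) and ATP (loss of citrate cleavage) force labels;
with the filter off, one alternative co-optimal connector (rTCA plus 4HB
arc) is reported as a tie.  The filter never changes the optimal cost.

Force labels are rule-derived from reaction attributes: loss of an
O2-sensitive reaction is labeled O2; loss of an ATP-consuming reaction ATP;
a bicarbonate swap or gain of a bicarbonate-consuming module ALK; all else
`other`.

Channel redundancy is the maximum number of reaction-disjoint routes from
inorganic carbon to a target (default acetyl-CoA), computed as a max-flow LP
with unit capacity per reaction column; a min-cut argument cross-checks it
in the tests.  The linked rTCA-WL root counts two channels (the WL chain and
the rTCA loop); every derived phenotype counts one.

### Encoding choices for the packaged phenotype set

The observed terminal set is the subset of named phenotypes that the
innovation-granular alphabet connects by single changes with a single
insertion: the Aquifex-like rTCA hybrid, the WL acetogen, a WL phenotype
carrying a latent 4HB arc (the *C. kluyveri*-like state), DC-4HB, 3HP-4HB,
and two CBB-bearing nodes (with and without the glyoxylate glycine route).
The 3HP bicycle ships as a viable phenotype but not as a default terminal —
its compound innovation (3HP arc plus glyoxylate-assimilation completion)
cannot be chained through single module changes without positing
intermediates the reconstruction does not claim.  The latent 4HB arc of the
WL carrier node counts toward gene content (edit distance) but is excluded
from the active network, so its channel redundancy remains one.  Several
multi-step pathway segments (malonyl-CoA to propionyl-CoA, the 4HB arc, the
pentose regeneration of CBB, the glyoxylate-propionyl assimilation) are
lumped single reactions with textbook net stoichiometry; their internal
step structure is irrelevant to viability, cost and module-level parsimony.
The anaplerotic carboxylation is written with CO2 in the default form and
bicarbonate in the swap form; cells of the cost table are insensitive to
this choice (no cost cell routes through it at optimum).

The producibility closure (scope expansion) is the necessary-condition
oracle for the LP: forward reachability from the importable set, seeded
with the unloaded carrier forms and — when the network touches it — the
TCA-loop anchor oxaloacetate, because conserved carriers and autocatalytic
loop intermediates cycle catalytically and cannot bootstrap themselves
under forward expansion even though the steady-state LP can run them.

## Numerical choices

LPs are solved with HiGHS through scipy at default tolerances; steady-state
residuals of returned witnesses are checked at 1e-6.  Stoichiometries are
stored as exact rationals and converted to floats only at matrix
construction.  The viability epsilon is 1e-6, the lexicographic ATP cap
tolerance 1e-7, integer snapping 1e-6.  Ties in path and tree enumeration
are ordered by serialized node sets.  Degenerate inputs: an empty reaction
set is a valid phenotype (nothing organic is producible); an environment
without inorganic carbon yields zero redundancy and universal
infeasibility; dead-end metabolites produce warnings on the flux problem,
not errors.

## Known limitations

The toolkit models the carbon-fixation core only — no full intermediary
metabolism, no thermodynamic (free-energy) constraints, no growth-rate
objectives, no kinetics, and no sequence-level phylogenetics (likelihood or
Bayesian reconstruction over these networks is an explicit non-goal).  The
clade fixture reproduces aggregate counts, not the underlying annotations,
so strain-level co-occurrence statistics beyond the constructed structure
(for example the reported near-perfect linkage of the glycine cycle with
the reductive forms) are not reproducible from the package.  Pterin structural chemistry enters only
through its energetic consequence (ATP-free formyl activation on H4MPT).
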