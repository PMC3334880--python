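"""Autotrophic viability: can a phenotype produce every biomass entry point?

A phenotype is a viable autotroph when every universal anabolic precursor
(acetyl-CoA, pyruvate, oxaloacetate, succinyl-CoA, alpha-ketoglutarate) plus
glycine and serine can be produced at positive flux from the environment's
inorganic carbon.  Each target is tested with its own LP (maximize the
target's demand flux; feasible iff the optimum exceeds a small epsilon), which
operationalizes the requirement of positive output rather than any growth-rate
optimum.  A fast reachability closure provides a necessary-condition oracle
for the LP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .knowledge_base import Bundle, CARBON_METABOLITE, EnvironmentSpec, PhenotypeDef
from .stoich import FluxProblem, build_flux_problem

__all__ = [
    "EPSILON",
    "GLYCINE_SERINE",
    "default_targets",
    "TargetResult",
    "ViabilityReport",
    "check_viability",
    "producibility_closure",
]

EPSILON = 1e-6
GLYCINE_SERINE = ("glycine", "serine")
#: catalytic-cycle intermediates seeded by the closure (see
#: :func:`producibility_closure`); the TCA loop regenerates its anchor.
CYCLE_ANCHORS = ("oaa",)


def default_targets(bundle: Bundle) -> tuple[str, ...]:
    """Five universal precursors plus glycine and serine."""
    return tuple(bundle.precursors()) + GLYCINE_SERINE


@dataclass(frozen=True)
class TargetResult:
    target: str
    feasible: bool
    max_flux: float
    witness: np.ndarray | None


@dataclass(frozen=True)
class ViabilityReport:
    phenotype_id: str
    targets: Mapping[str, TargetResult]
    disabled_reactions: tuple[str, ...]
    problem: FluxProblem

    @property
    def overall_viable(self) -> bool:
        return all(t.feasible for t in self.targets.values())

    def infeasible_targets(self) -> tuple[str, ...]:
        return tuple(t for t, r in self.targets.items() if not r.feasible)


def check_viability(
    phenotype: PhenotypeDef,
    bundle: Bundle,
    targets: Sequence[str] | None = None,
    environment: EnvironmentSpec | None = None,
) -> ViabilityReport:
    """Solve one production LP per target and AND the per-target feasibility.

    O2-sensitive reactions are removed before solving when the environment
    contains oxygen.  Witness fluxes satisfy the steady-state constraint to
    solver tolerance and are returned for audit.
    """
    tgts = tuple(targets) if targets is not None else default_targets(bundle)
    problem = build_flux_problem(phenotype, bundle, targets=tgts, environment=environment)
    results: dict[str, TargetResult] = {}
    for target in tgts:
        j = problem.col_index("demand", target)
        out = problem.max_flux(j)
        if out is None:
            results[target] = TargetResult(target, False, 0.0, None)
        else:
            val, v = out
            results[target] = TargetResult(target, val >= EPSILON, val,
                                           v if val >= EPSILON else None)
    return ViabilityReport(
        phenotype_id=phenotype.id, targets=results,
        disabled_reactions=problem.disabled_reactions, problem=problem,
    )


def producibility_closure(
    phenotype: PhenotypeDef,
    bundle: Bundle,
    environment: EnvironmentSpec | None = None,
    seed_carriers: bool = True,
) -> frozenset[str]:
    """Fixed point of forward reachability (scope expansion).

    A metabolite is reachable if it is importable from the environment or some
    active reaction whose substrates are all reachable produces it (reverse
    direction included for reversible reactions).  When ``seed_carriers`` is
    true the unloaded forms of conserved carrier pairs touched by the network
    (THF, H4MPT, lipoamide, CoA) are seeded, as is the TCA-loop anchor
    oxaloacetate when the network touches it: carriers and catalytic-cycle
    intermediates cannot bootstrap themselves under forward expansion even
    though the steady-state LP can run them (autocatalytic cycles have no
    forward seed).  With no reactions the closure is exactly the importable
    set.  Reachability is necessary but not sufficient for LP producibility.
    """
    env = environment or phenotype.environment
    rids = sorted(phenotype.reaction_ids(bundle))
    active = [bundle.reactions[r] for r in rids
              if not (env.o2_present and bundle.reactions[r].o2_sensitive)]

    reachable: set[str] = {CARBON_METABOLITE[s] for s in env.inorganic_carbon}
    reachable.update({"nh3", "h2o", "pi"})
    if env.reductant_available:
        reachable.add("red")
    if env.atp_available:
        reachable.add("atp")
    if seed_carriers:
        touched = {m for r in active for m in r.stoichiometry}
        reachable.update(c for c in bundle.carrier_free_ids() if any(
            next(iter(bundle.metabolites[c].formula)) in bundle.metabolites[m].formula
            for m in touched))
        reachable.update(a for a in CYCLE_ANCHORS if a in touched)

    steps = []
    for rxn in active:
        steps.append((rxn.substrates(), rxn.products()))
        if rxn.reversible:
            steps.append((rxn.products(), rxn.substrates()))

    changed = True
    while changed:
        changed = False
        for subs, prods in steps:
            if all(s in reachable for s in subs) and not all(p in reachable for p in prods):
                reachable.update(prods)
                changed = True
    return frozenset(reachable)
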