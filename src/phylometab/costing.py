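"""Biosynthetic cost accounting in ATP and reductant units.

``min_cost`` computes, for a target metabolite in a phenotype context, the
minimum ATP demand at unit target production and then the minimum reductant
demand at that ATP optimum (lexicographic linear programming).  Costs are
reported in ATP hydrolysis units (ATP->AMP counts two, GTP counts as ATP) and
H2 equivalents.  The degree of reduction of the target is an exact lower
bound on the reductant cost; on fully reductive routes the two coincide,
while oxidative glycine synthesis exceeds it by the one H2 equivalent lost in
the discharged surplus C1 unit.

``count_steps`` counts enzymatic steps along a pathway definition, with the
glycine cleavage system counted as its four protein components (P, H, T, L;
the H carrier protein has no EC number of its own).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .knowledge_base import Bundle, EnvironmentSpec, PathwayDef, PhenotypeDef
from .stoich import FLUX_BOUND, Column, build_flux_problem, degree_of_reduction
from .viability import check_viability

__all__ = [
    "CostResult",
    "StepCount",
    "NotProducibleError",
    "min_cost",
    "cost_table",
    "count_steps",
    "GCS_REACTIONS",
    "GCS_COMPONENTS",
]

#: the three glycine-cleavage-system reactions in the knowledge base
GCS_REACTIONS = frozenset({"5", "6", "7"})
#: the GCS is a four-protein complex (P, H, T, L); H has no EC number
GCS_COMPONENTS = 4

ATP_STAGE_TOL = 1e-7
INT_SNAP_TOL = 1e-6


class NotProducibleError(RuntimeError):
    """The requested target cannot be produced in the given context."""


def _snap(value: float) -> tuple[float, bool]:
    near = round(value)
    if abs(value - near) <= INT_SNAP_TOL:
        return float(near), True
    return float(value), False


@dataclass(frozen=True)
class CostResult:
    target: str
    context: str
    atp_cost: float
    reductant_cost: float
    atp_integral: bool
    reductant_integral: bool
    reductant_lower_bound: Fraction | None
    witness: np.ndarray | None

    def cell(self) -> str:
        """Table-style formatting, e.g. ``1 ATP+3 Red``."""
        fmt = lambda x, integral: f"{int(x)}" if integral else f"{x:.6g}"
        return (f"{fmt(self.atp_cost, self.atp_integral)} ATP+"
                f"{fmt(self.reductant_cost, self.reductant_integral)} Red")


def min_cost(
    phenotype: PhenotypeDef,
    bundle: Bundle,
    target: str,
    environment: EnvironmentSpec | None = None,
) -> CostResult:
    """Lexicographic minimum (ATP, then reductant) for unit target production.

    Stage 1 minimizes the ATP import flux subject to the demand flux fixed at
    one unit; stage 2 minimizes the reductant import flux with the ATP import
    capped at its optimum (plus a small tolerance).  Costs within 1e-6 of an
    integer are snapped and flagged integral.
    """
    problem = build_flux_problem(phenotype, bundle, targets=(target,),
                                 environment=environment)
    jd = problem.col_index("demand", target)
    j_atp = problem.col_index("import", "atp")
    j_red = problem.col_index("import", "red")
    ncols = len(problem.columns)

    obj_atp = np.zeros(ncols)
    if j_atp is not None:
        obj_atp[j_atp] = 1.0
    stage1 = problem.solve(obj_atp, extra_lb={jd: 1.0}, extra_ub={jd: 1.0})
    if stage1 is None:
        raise NotProducibleError(
            f"{target} is not producible in context {phenotype.id}; "
            f"viability report: {check_viability(phenotype, bundle, targets=(target,), environment=environment).targets[target]}")
    atp_opt, _ = stage1

    obj_red = np.zeros(ncols)
    if j_red is not None:
        obj_red[j_red] = 1.0
    caps = {jd: 1.0}
    if j_atp is not None:
        caps[j_atp] = atp_opt + ATP_STAGE_TOL
    stage2 = problem.solve(obj_red, extra_lb={jd: 1.0}, extra_ub=caps)
    assert stage2 is not None  # stage 1 witness still feasible
    red_opt, v = stage2

    atp_cost, atp_int = _snap(atp_opt)
    red_cost, red_int = _snap(red_opt)
    try:
        bound = degree_of_reduction(bundle.metabolites[target])
    except ValueError:
        bound = None
    return CostResult(
        target=target, context=phenotype.id,
        atp_cost=atp_cost, reductant_cost=red_cost,
        atp_integral=atp_int, reductant_integral=red_int,
        reductant_lower_bound=bound, witness=v,
    )


def cost_table(
    bundle: Bundle,
    contexts: Sequence[str],
    targets: Sequence[str] = ("glycine", "serine"),
) -> dict[tuple[str, str], CostResult]:
    """Cost matrix over (context phenotype, target) pairs."""
    out: dict[tuple[str, str], CostResult] = {}
    for ctx in contexts:
        phenotype = bundle.phenotypes[ctx]
        for target in targets:
            out[(ctx, target)] = min_cost(phenotype, bundle, target)
    return out


@dataclass(frozen=True)
class StepCount:
    pathway: str
    source: str
    target: str
    steps: int
    reactions_used: frozenset[str]


def count_steps(
    pathway: PathwayDef,
    bundle: Bundle,
    source: str,
    target: str,
) -> StepCount:
    """Count enzymatic steps from source to target along a pathway definition.

    A minimal-total-flux production route is found on the sub-network of the
    pathway's ``step_reactions`` with the source freely importable (plus
    ammonia, reductant, ATP, water, phosphate and the amino-group shuttle);
    the step count is the number of non-GCS reactions in the route's support,
    plus four whenever the glycine cleavage system participates.
    """
    rids = tuple(sorted(pathway.step_reactions))
    env = EnvironmentSpec(inorganic_carbon=frozenset({"CO2"}))
    pheno = PhenotypeDef(id=f"steps_{pathway.id}", name="", modules=(),
                         environment=env, extra_reactions=rids)
    problem = build_flux_problem(pheno, bundle, targets=(target,), environment=env)

    # free the source and the amino-group shuttle (glutamate/2-oxoglutarate):
    # shuttles and the source are boundary conditions of the step count, not steps.
    extra_free = {source, "glu", "akg"}
    rows = [problem.met_index[m] for m in extra_free if m in problem.met_index]
    if rows:
        free_cols = np.zeros((problem.S.shape[0], 2 * len(rows)))
        for k, i in enumerate(rows):
            free_cols[i, 2 * k] = 1.0
            free_cols[i, 2 * k + 1] = -1.0
        problem.S = np.hstack([problem.S, free_cols])
        problem.columns = problem.columns + [
            Column("import", f"free_{k}") for k in range(2 * len(rows))]
        problem.lb = np.concatenate([problem.lb, np.zeros(2 * len(rows))])
        problem.ub = np.concatenate([problem.ub, np.full(2 * len(rows), FLUX_BOUND)])

    jd = problem.col_index("demand", target)
    nrxn = sum(1 for c in problem.columns if c.kind == "rxn")
    obj = np.array([1.0 if c.kind == "rxn" else 0.0 for c in problem.columns])
    sol = problem.solve(obj, extra_lb={jd: 1.0}, extra_ub={jd: 1.0})
    if sol is None:
        raise NotProducibleError(
            f"pathway {pathway.id} does not connect {source} to {target}")
    _, v = sol
    support = {c.target for j, c in enumerate(problem.columns)
               if c.kind == "rxn" and v[j] > 1e-6}
    steps = len(support - GCS_REACTIONS)
    if support & GCS_REACTIONS:
        steps += GCS_COMPONENTS
    return StepCount(pathway=pathway.id, source=source, target=target,
                     steps=steps, reactions_used=frozenset(support))
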