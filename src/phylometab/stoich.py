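"""Stoichiometric matrix construction and element/electron bookkeeping.

The flux problems built here are the data structures behind the viability and
costing analyses: a steady-state constraint ``S v = 0`` over every metabolite,
irreversible flux columns (reversible reactions are split), exchange columns
determined by the environment, and unit-demand columns for production targets.
Degree of reduction (electron content in H2 equivalents relative to the
CO2/H2O/NH3 baseline) provides the exact lower bound on reductant costs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .knowledge_base import (
    Bundle,
    CARBON_METABOLITE,
    EnvironmentSpec,
    MetaboliteRecord,
    PhenotypeDef,
)

__all__ = [
    "Column",
    "FluxProblem",
    "LPError",
    "build_flux_problem",
    "degree_of_reduction",
    "BalanceReport",
    "balance_report",
]

FLUX_BOUND = 1000.0
STEADY_STATE_TOL = 1e-9

#: species that may always leave the system (waste/venting); uptake is
#: environment-controlled, disposal of small inorganics is not.
ALWAYS_EXPORT = ("co2", "formate", "formate_w", "nh3", "h2o", "pi", "red")
#: species exchangeable in both directions regardless of environment
FREE_EXCHANGE = ("h2o", "pi")


class LPError(RuntimeError):
    """The LP solver failed for an infrastructure reason (not infeasibility)."""


@dataclass(frozen=True)
class Column:
    """One flux column: a directed reaction, an exchange, or a demand sink.

    ``kind`` is one of ``rxn`` (direction +1 forward / -1 reverse of the
    reaction as written), ``import``, ``export`` or ``demand``.
    """

    kind: str
    target: str
    direction: int = 1

    def label(self) -> str:
        if self.kind == "rxn":
            return self.target if self.direction > 0 else f"{self.target}__rev"
        return f"{self.kind}__{self.target}"


@dataclass
class FluxProblem:
    """Steady-state flux problem for one phenotype in one environment."""

    phenotype_id: str
    S: np.ndarray
    met_index: dict[str, int]
    columns: list[Column]
    lb: np.ndarray
    ub: np.ndarray
    disabled_reactions: tuple[str, ...]
    dead_ends: tuple[str, ...]
    environment: EnvironmentSpec

    def col_index(self, kind: str, target: str, direction: int = 1) -> int | None:
        for j, col in enumerate(self.columns):
            if col.kind == kind and col.target == target and (
                    kind != "rxn" or col.direction == direction):
                return j
        return None

    def solve(self, objective: np.ndarray, extra_ub: Mapping[int, float] | None = None,
              extra_lb: Mapping[int, float] | None = None) -> tuple[float, np.ndarray] | None:
        """Minimize ``objective . v`` subject to ``S v = 0`` and bounds.

        Returns ``(optimum, v)`` or ``None`` if infeasible.  Raises
        :class:`LPError` on solver failure.
        """
        lb = self.lb.copy()
        ub = self.ub.copy()
        for j, b in (extra_ub or {}).items():
            ub[j] = min(ub[j], b)
        for j, b in (extra_lb or {}).items():
            lb[j] = max(lb[j], b)
        res = linprog(objective, A_eq=self.S, b_eq=np.zeros(self.S.shape[0]),
                      bounds=list(zip(lb, ub)), method="highs")
        if res.status == 2:
            return None
        if res.status != 0:
            raise LPError(f"LP solver failure (status {res.status}): {res.message}")
        return float(res.fun), res.x

    def max_flux(self, j: int, cap: float = 1.0) -> tuple[float, np.ndarray] | None:
        """Maximize flux through column ``j`` (capped for scale-freeness)."""
        obj = np.zeros(len(self.columns))
        obj[j] = -1.0
        out = self.solve(obj, extra_ub={j: cap})
        if out is None:
            return None
        val, v = out
        return -val, v

    def residual(self, v: np.ndarray) -> float:
        """max |S v| over all metabolite rows for a witness flux."""
        return float(np.max(np.abs(self.S @ v))) if len(v) else 0.0


def _carrier_release(met: MetaboliteRecord, bundle: Bundle) -> str | None:
    """Free carrier form released when a carrier-bound target leaves the system."""
    carriers = {next(iter(bundle.metabolites[c].formula)): c
                for c in bundle.carrier_free_ids()}
    for el in met.formula:
        if el in carriers and carriers[el] != met.id:
            return carriers[el]
    return None


def build_flux_problem(
    phenotype: PhenotypeDef,
    bundle: Bundle,
    targets: Sequence[str] = (),
    environment: EnvironmentSpec | None = None,
) -> FluxProblem:
    """Build the steady-state LP for a phenotype.

    Reversible reactions are split into two irreversible columns; O2-sensitive
    reactions are removed when the environment contains oxygen; exchange
    columns are created from the environment (imports) and the fixed waste
    list (exports); each target gets a unit-capacity demand column that
    releases the free carrier when the target is carrier-bound (for example
    acetyl-CoA leaves as the acetyl moiety, returning CoA).
    """
    env = environment or phenotype.environment
    rids = sorted(phenotype.reaction_ids(bundle))
    disabled = tuple(r for r in rids
                     if env.o2_present and bundle.reactions[r].o2_sensitive)
    active = [r for r in rids if r not in disabled]

    columns: list[Column] = []
    for rid in active:
        columns.append(Column("rxn", rid, +1))
        if bundle.reactions[rid].reversible:
            columns.append(Column("rxn", rid, -1))

    imports: set[str] = {CARBON_METABOLITE[s] for s in env.inorganic_carbon}
    imports.add("nh3")
    imports.update(FREE_EXCHANGE)
    if env.reductant_available:
        imports.add("red")
    if env.atp_available:
        imports.add("atp")
    for mid in sorted(imports):
        columns.append(Column("import", mid))
    for mid in ALWAYS_EXPORT + FREE_EXCHANGE:
        if mid not in {c.target for c in columns if c.kind == "export"}:
            columns.append(Column("export", mid))
    for mid in targets:
        if mid not in bundle.metabolites:
            raise KeyError(f"unknown target metabolite {mid!r}")
        columns.append(Column("demand", mid))

    mets = sorted({m for rid in active for m in bundle.reactions[rid].stoichiometry}
                  | {c.target for c in columns if c.kind != "rxn"}
                  | {rel for c in columns if c.kind == "demand"
                     for rel in [_carrier_release(bundle.metabolites[c.target], bundle)]
                     if rel})
    met_index = {m: i for i, m in enumerate(mets)}

    S = np.zeros((len(mets), len(columns)))
    lb = np.zeros(len(columns))
    ub = np.full(len(columns), FLUX_BOUND)
    for j, col in enumerate(columns):
        if col.kind == "rxn":
            for m, coef in bundle.reactions[col.target].stoichiometry.items():
                S[met_index[m], j] += col.direction * float(coef)
        elif col.kind == "import":
            S[met_index[col.target], j] += 1.0
        elif col.kind == "export":
            S[met_index[col.target], j] -= 1.0
        elif col.kind == "demand":
            S[met_index[col.target], j] -= 1.0
            rel = _carrier_release(bundle.metabolites[col.target], bundle)
            if rel:
                S[met_index[rel], j] += 1.0
            ub[j] = 1.0

    produced = {m for m in mets if np.any(S[met_index[m]] > 0)}
    consumed = {m for m in mets if np.any(S[met_index[m]] < 0)}
    dead = tuple(sorted(
        m for m in mets
        if not bundle.metabolites[m].is_exchangeable
        and (m not in produced or m not in consumed)))

    return FluxProblem(
        phenotype_id=phenotype.id, S=S, met_index=met_index, columns=columns,
        lb=lb, ub=ub, disabled_reactions=disabled, dead_ends=dead,
        environment=env,
    )


#: baseline oxidation states: CO2, H2O, NH3 carry zero H2 equivalents
_GAMMA_WEIGHT = {"C": 4, "H": 1, "O": -2, "N": -3}


def degree_of_reduction(metabolite: MetaboliteRecord) -> Fraction:
    """Electron content of a metabolite in H2 equivalents.

    gamma/2 with gamma = 4C + H - 2O - 3N, relative to the CO2/H2O/NH3
    baseline.  Only defined for full C/H/N/O formulas; carrier-bound or
    phosphorylated metabolites raise ``ValueError``.
    """
    if not metabolite.formula:
        raise ValueError(f"{metabolite.id}: no formula; degree of reduction unsupported")
    extra = set(metabolite.formula) - set(_GAMMA_WEIGHT)
    if extra:
        raise ValueError(
            f"{metabolite.id}: degree of reduction undefined for elements {sorted(extra)}")
    gamma = sum(_GAMMA_WEIGHT[el] * n for el, n in metabolite.formula.items())
    return Fraction(gamma, 2)


@dataclass(frozen=True)
class BalanceReport:
    """Element imbalances per reaction and degrees of reduction per metabolite."""

    reaction_imbalance: Mapping[str, Mapping[str, Fraction]]
    metabolite_gamma: Mapping[str, Fraction]


def balance_report(bundle: Bundle) -> BalanceReport:
    imbal: dict[str, dict[str, Fraction]] = {}
    for rid, rxn in bundle.reactions.items():
        bal: dict[str, Fraction] = {}
        complete = True
        for mid, coef in rxn.stoichiometry.items():
            formula = bundle.metabolites[mid].formula
            if not formula:
                complete = False
                break
            for el, n in formula.items():
                bal[el] = bal.get(el, Fraction(0)) + coef * n
        if complete:
            imbal[rid] = {el: v for el, v in bal.items() if v != 0 and el != "H"}
    gammas: dict[str, Fraction] = {}
    for mid, met in bundle.metabolites.items():
        try:
            gammas[mid] = degree_of_reduction(met)
        except ValueError:
            continue
    return BalanceReport(reaction_imbalance=imbal, metabolite_gamma=gammas)
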