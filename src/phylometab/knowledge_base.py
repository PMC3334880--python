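"""Knowledge base: schemas, loading, validation and round-trip serialization.

The knowledge base bundles five tables — reactions, metabolites, pathway-call
definitions, phenotype definitions and per-clade pathway-call counts — that the
rest of the toolkit consumes.  Reactions are EC-annotated stoichiometric
transformations over a metabolite set in which cofactor moieties (THF, H4MPT,
lipoamide, CoA) are conserved carrier pairs and ATP / reductant are tracked
through dedicated pseudo-metabolites (``atp``, one hydrolysis unit; ``red``,
one H2 equivalent = two electrons).  Phenotypes are named reaction-module sets
plus an environment; they are the nodes of the phylometabolic tree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "KBError",
    "ReactionRecord",
    "MetaboliteRecord",
    "PathwayDef",
    "EnvironmentSpec",
    "PhenotypeDef",
    "CladeRow",
    "Bundle",
    "load_knowledge_base",
    "default_knowledge_base",
    "validate_knowledge_base",
    "save_knowledge_base",
]

CARBON_SPECIES = ("none", "CO2", "HCO3", "CO", "formate")
#: inorganic carbon species id in the metabolite table, keyed by flag name
CARBON_METABOLITE = {"CO2": "co2", "HCO3": "hco3", "CO": "co", "formate": "formate"}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]*)(\d*)")


class KBError(ValueError):
    """Schema or cross-reference error in a knowledge-base table."""


def parse_formula(text: str) -> dict[str, int]:
    """Parse an element-count formula such as ``C2H5NO2`` or ``ThfCH2``.

    Multi-letter tokens (``Thf``, ``Mpt``, ``Lip``, ``Coa``) denote conserved
    carrier moieties treated as pseudo-elements.  An empty string denotes an
    abstract metabolite with no formula.
    """
    text = (text or "").strip()
    if not text:
        return {}
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise KBError(f"cannot parse formula {text!r}")
        pos = m.end()
        el, num = m.group(1), m.group(2)
        out[el] = out.get(el, 0) + (int(num) if num else 1)
    if pos != len(text):
        raise KBError(f"cannot parse formula {text!r}")
    return out


def format_formula(formula: Mapping[str, int]) -> str:
    order = sorted(formula, key=lambda e: (len(e) > 1, e != "C", e != "H", e))
    return "".join(f"{el}{formula[el] if formula[el] != 1 else ''}" for el in order)


def parse_equation(text: str) -> dict[str, Fraction]:
    """Parse ``1 co2 + 1 red -> 1 formate`` into signed coefficients.

    Substrates get negative, products positive coefficients.  Coefficients may
    be rationals (``1/2``).
    """
    if "->" not in text:
        raise KBError(f"equation {text!r} lacks '->'")
    lhs, rhs = text.split("->")
    stoich: dict[str, Fraction] = {}

    def _side(side: str, sign: int) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            parts = term.split()
            if len(parts) == 1:
                coef, met = Fraction(1), parts[0]
            elif len(parts) == 2:
                coef, met = Fraction(parts[0]), parts[1]
            else:
                raise KBError(f"cannot parse term {term!r}")
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coef

    _side(lhs, -1)
    _side(rhs, +1)
    return {m: c for m, c in stoich.items() if c != 0}


def format_equation(stoich: Mapping[str, Fraction]) -> str:
    subs = sorted((m for m, c in stoich.items() if c < 0))
    prods = sorted((m for m, c in stoich.items() if c > 0))
    left = " + ".join(f"{-stoich[m]} {m}" for m in subs)
    right = " + ".join(f"{stoich[m]} {m}" for m in prods)
    return f"{left} -> {right}"


@dataclass(frozen=True)
class ReactionRecord:
    """An EC-annotated stoichiometric transformation.

    ``stoichiometry`` is the single source of truth; ``atp_events`` and
    ``reductant_events`` are derived views of the ATP / reductant
    pseudo-metabolite entries (positive = consumed per forward unit flux).
    """

    id: str
    name: str
    ec: str
    stoichiometry: Mapping[str, Fraction]
    reversible: bool
    o2_sensitive: bool
    carbon_species: str
    module: str

    @property
    def atp_events(self) -> Fraction:
        return -self.stoichiometry.get("atp", Fraction(0))

    @property
    def reductant_events(self) -> Fraction:
        return -self.stoichiometry.get("red", Fraction(0))

    def substrates(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.stoichiometry.items() if c < 0)

    def products(self) -> tuple[str, ...]:
        return tuple(m for m, c in self.stoichiometry.items() if c > 0)


@dataclass(frozen=True)
class MetaboliteRecord:
    id: str
    name: str
    formula: Mapping[str, int]
    is_precursor: bool
    is_exchangeable: bool
    carrier_free: bool = False


@dataclass(frozen=True)
class PathwayDef:
    """A pathway call: all ``required_present`` reactions present and all
    ``required_absent`` reactions absent.  ``step_reactions`` is the reaction
    set used for enzymatic step counting (defaults to ``required_present``)."""

    id: str
    required_present: frozenset[str]
    required_absent: frozenset[str] = frozenset()
    step_reactions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.required_present & self.required_absent:
            raise KBError(f"pathway {self.id}: present/absent sets overlap")
        if not self.step_reactions:
            object.__setattr__(self, "step_reactions", self.required_present)


@dataclass(frozen=True)
class EnvironmentSpec:
    """Chemical environment of a phenotype.

    ``inorganic_carbon`` lists the importable carbon species; nitrogen is
    always ammonia; reductant and ATP availability are boolean switches on the
    corresponding exchange fluxes.
    """

    o2_present: bool = False
    inorganic_carbon: frozenset[str] = frozenset({"CO2"})
    nitrogen_source: str = "NH3"
    reductant_available: bool = True
    atp_available: bool = True

    def __post_init__(self) -> None:
        bad = set(self.inorganic_carbon) - set(CARBON_METABOLITE)
        if bad:
            raise KBError(f"unknown inorganic carbon species {sorted(bad)}")


@dataclass(frozen=True)
class PhenotypeDef:
    id: str
    name: str
    modules: tuple[str, ...]
    environment: EnvironmentSpec
    extra_reactions: tuple[str, ...] = ()
    latent_modules: tuple[str, ...] = ()
    observed: bool = True
    observed_in: str = ""

    def reaction_ids(self, bundle: "Bundle", include_latent: bool = False) -> frozenset[str]:
        """Expand modules (minus latent ones unless requested) to reaction ids."""
        mods = set(self.modules)
        if not include_latent:
            mods -= set(self.latent_modules)
        rids: set[str] = set(self.extra_reactions)
        for mod in sorted(mods):
            rids.update(bundle.modules[mod])
        return frozenset(rids)


@dataclass(frozen=True)
class CladeRow:
    clade: str
    n_strains: int
    counts: Mapping[str, int]


@dataclass(frozen=True)
class Bundle:
    """Immutable, cross-reference-checked knowledge base."""

    reactions: Mapping[str, ReactionRecord]
    metabolites: Mapping[str, MetaboliteRecord]
    pathways: Mapping[str, PathwayDef]
    phenotypes: Mapping[str, PhenotypeDef]
    clades: tuple[CladeRow, ...]
    modules: Mapping[str, tuple[str, ...]]

    def precursors(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites.values() if m.is_precursor)

    def carrier_free_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites.values() if m.carrier_free)


def _read_tsv(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    df.columns = [c.strip() for c in df.columns]
    return df


def _as_bool(val: str, where: str) -> bool:
    val = str(val).strip()
    if val in {"0", "1"}:
        return val == "1"
    raise KBError(f"{where}: expected 0/1, got {val!r}")


def data_dir() -> Path:
    """Directory of the packaged fixture tables."""
    return Path(resources.files("phylometab") / "data")


def load_knowledge_base(paths: Mapping[str, str | Path] | None = None) -> Bundle:
    """Load and cross-check a knowledge base.

    ``paths`` may override any of the table locations (keys ``reactions``,
    ``metabolites``, ``pathways``, ``phenotypes``, ``clades``); the packaged
    fixture is used for any table not overridden.
    """
    base = data_dir()
    paths = dict(paths or {})
    loc = {k: Path(paths.get(k, base / f"{k}.tsv"))
           for k in ("reactions", "metabolites", "pathways", "phenotypes", "clades")}

    mets: dict[str, MetaboliteRecord] = {}
    for _, row in _read_tsv(loc["metabolites"]).iterrows():
        mid = row["id"].strip()
        if mid in mets:
            raise KBError(f"duplicate metabolite id {mid!r}")
        mets[mid] = MetaboliteRecord(
            id=mid,
            name=row["name"],
            formula=parse_formula(row["formula"]),
            is_precursor=_as_bool(row["is_precursor"], f"metabolite {mid}"),
            is_exchangeable=_as_bool(row["is_exchangeable"], f"metabolite {mid}"),
            carrier_free=_as_bool(row.get("carrier_free", "0"), f"metabolite {mid}"),
        )

    rxns: dict[str, ReactionRecord] = {}
    modules: dict[str, list[str]] = {}
    for _, row in _read_tsv(loc["reactions"]).iterrows():
        rid = row["id"].strip()
        if rid in rxns:
            raise KBError(f"duplicate reaction id {rid!r}")
        stoich = parse_equation(row["equation"])
        if not stoich:
            raise KBError(f"reaction {rid}: empty stoichiometry")
        for m in stoich:
            if m not in mets:
                raise KBError(f"reaction {rid}: unknown metabolite {m!r}")
        cs = row["carbon_species"].strip() or "none"
        if cs not in CARBON_SPECIES:
            raise KBError(f"reaction {rid}: bad carbon_species {cs!r}")
        rxns[rid] = ReactionRecord(
            id=rid, name=row["name"], ec=row["ec"].strip(),
            stoichiometry=stoich,
            reversible=_as_bool(row["reversible"], f"reaction {rid}"),
            o2_sensitive=_as_bool(row["o2_sensitive"], f"reaction {rid}"),
            carbon_species=cs, module=row["module"].strip(),
        )
        if rxns[rid].module:
            modules.setdefault(rxns[rid].module, []).append(rid)

    paths_tbl: dict[str, PathwayDef] = {}
    for _, row in _read_tsv(loc["pathways"]).iterrows():
        pid = row["id"].strip()
        if pid in paths_tbl:
            raise KBError(f"duplicate pathway id {pid!r}")
        pres = frozenset(x.strip() for x in row["required_present"].split(",") if x.strip())
        absent = frozenset(x.strip() for x in row["required_absent"].split(",") if x.strip())
        steps = frozenset(x.strip() for x in row.get("step_reactions", "").split(",") if x.strip())
        for rid in pres | absent | steps:
            if rid not in rxns:
                raise KBError(f"pathway {pid}: unknown reaction id {rid!r}")
        paths_tbl[pid] = PathwayDef(pid, pres, absent, steps)

    phens: dict[str, PhenotypeDef] = {}
    for _, row in _read_tsv(loc["phenotypes"]).iterrows():
        fid = row["id"].strip()
        if fid in phens:
            raise KBError(f"duplicate phenotype id {fid!r}")
        mods = tuple(x.strip() for x in row["modules"].split(",") if x.strip())
        latent = tuple(x.strip() for x in row.get("latent_modules", "").split(",") if x.strip())
        extra = tuple(x.strip() for x in row.get("extra_reactions", "").split(",") if x.strip())
        for mod in mods + latent:
            if mod not in modules:
                raise KBError(f"phenotype {fid}: unknown module {mod!r}")
        for rid in extra:
            if rid not in rxns:
                raise KBError(f"phenotype {fid}: unknown reaction id {rid!r}")
        env = EnvironmentSpec(
            o2_present=_as_bool(row["env_o2"], f"phenotype {fid}"),
            inorganic_carbon=frozenset(
                x.strip() for x in row["env_carbon"].split("|") if x.strip()),
            reductant_available=_as_bool(row.get("env_reductant", "1"), f"phenotype {fid}"),
            atp_available=_as_bool(row.get("env_atp", "1"), f"phenotype {fid}"),
        )
        phens[fid] = PhenotypeDef(
            id=fid, name=row["name"], modules=mods, environment=env,
            extra_reactions=extra, latent_modules=latent,
            observed=_as_bool(row["observed"], f"phenotype {fid}"),
            observed_in=row.get("observed_in", ""),
        )

    clades: list[CladeRow] = []
    cl_df = _read_tsv(loc["clades"])
    if len(cl_df):
        count_cols = [c for c in cl_df.columns if c not in ("clade", "n_strains")]
        for c in count_cols:
            if c not in paths_tbl:
                raise KBError(f"clades table column {c!r} is not a pathway id")
        for _, row in cl_df.iterrows():
            clades.append(CladeRow(
                clade=row["clade"].strip(),
                n_strains=int(row["n_strains"]),
                counts={c: int(row[c]) for c in count_cols},
            ))

    return Bundle(
        reactions=rxns, metabolites=mets, pathways=paths_tbl,
        phenotypes=phens, clades=tuple(clades),
        modules={k: tuple(v) for k, v in modules.items()},
    )


_DEFAULT: Bundle | None = None


def default_knowledge_base() -> Bundle:
    """The packaged fixture bundle (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_knowledge_base()
    return _DEFAULT


def validate_knowledge_base(bundle: Bundle) -> list[str]:
    """Return diagnostics (empty list iff all invariants hold).

    Checked invariants: exactly five precursor metabolites; every reaction
    stoichiometry names known metabolites and moves mass in both directions
    (no all-positive or all-negative stoichiometries); C, N, O and P are
    conserved by every reaction with fully specified formulas (H is left free
    under the proton/water convention); phenotype reactions resolve; clade
    counts do not exceed clade sizes.
    """
    diags: list[str] = []
    prec = [m.id for m in bundle.metabolites.values() if m.is_precursor]
    if len(prec) != 5:
        diags.append(f"metabolites: expected 5 precursors, found {len(prec)}: {sorted(prec)}")

    for rid, rxn in bundle.reactions.items():
        signs = {1 if c > 0 else -1 for c in rxn.stoichiometry.values()}
        if signs == {1}:
            diags.append(f"reactions/{rid}: mass created (all coefficients positive)")
        if signs == {-1}:
            diags.append(f"reactions/{rid}: mass destroyed (all coefficients negative)")
        balance: dict[str, Fraction] = {}
        complete = True
        for mid, coef in rxn.stoichiometry.items():
            formula = bundle.metabolites[mid].formula
            if not formula:
                complete = False
                break
            for el, n in formula.items():
                balance[el] = balance.get(el, Fraction(0)) + coef * n
        if complete:
            for el in ("C", "N", "O", "P", "S", "Thf", "Mpt", "Lip", "Coa"):
                if balance.get(el, Fraction(0)) != 0:
                    diags.append(f"reactions/{rid}: element {el} imbalance {balance[el]}")

    for fid, ph in bundle.phenotypes.items():
        try:
            rids = ph.reaction_ids(bundle, include_latent=True)
        except KeyError as exc:  # unknown module slipped through
            diags.append(f"phenotypes/{fid}: unresolved module {exc}")
            continue
        for rid in rids:
            if rid not in bundle.reactions:
                diags.append(f"phenotypes/{fid}: unresolved reaction {rid!r}")
        if not ph.environment.inorganic_carbon:
            diags.append(f"phenotypes/{fid}: environment has no inorganic carbon")

    for row in bundle.clades:
        for pid, n in row.counts.items():
            if n > row.n_strains:
                diags.append(f"clades/{row.clade}: count {pid}={n} exceeds n_strains={row.n_strains}")
    return diags


def save_knowledge_base(bundle: Bundle, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a bundle back to the TSV schemas (round-trip stable)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    met_rows = [{
        "id": m.id, "name": m.name, "formula": format_formula(m.formula),
        "is_precursor": int(m.is_precursor), "is_exchangeable": int(m.is_exchangeable),
        "carrier_free": int(m.carrier_free),
    } for m in bundle.metabolites.values()]
    files["metabolites"] = out / "metabolites.tsv"
    pd.DataFrame(met_rows).to_csv(files["metabolites"], sep="\t", index=False)

    rxn_rows = [{
        "id": r.id, "name": r.name, "ec": r.ec, "equation": format_equation(r.stoichiometry),
        "reversible": int(r.reversible), "o2_sensitive": int(r.o2_sensitive),
        "carbon_species": r.carbon_species, "module": r.module,
    } for r in bundle.reactions.values()]
    files["reactions"] = out / "reactions.tsv"
    pd.DataFrame(rxn_rows).to_csv(files["reactions"], sep="\t", index=False)

    pw_rows = [{
        "id": p.id,
        "required_present": ",".join(sorted(p.required_present)),
        "required_absent": ",".join(sorted(p.required_absent)),
        "step_reactions": ",".join(sorted(p.step_reactions)),
    } for p in bundle.pathways.values()]
    files["pathways"] = out / "pathways.tsv"
    pd.DataFrame(pw_rows).to_csv(files["pathways"], sep="\t", index=False)

    ph_rows = [{
        "id": p.id, "name": p.name, "modules": ",".join(p.modules),
        "extra_reactions": ",".join(p.extra_reactions),
        "latent_modules": ",".join(p.latent_modules),
        "env_o2": int(p.environment.o2_present),
        "env_carbon": "|".join(sorted(p.environment.inorganic_carbon)),
        "env_reductant": int(p.environment.reductant_available),
        "env_atp": int(p.environment.atp_available),
        "observed": int(p.observed), "observed_in": p.observed_in,
    } for p in bundle.phenotypes.values()]
    files["phenotypes"] = out / "phenotypes.tsv"
    pd.DataFrame(ph_rows).to_csv(files["phenotypes"], sep="\t", index=False)

    if bundle.clades:
        count_cols = list(bundle.clades[0].counts)
        cl_rows = [{"clade": c.clade, "n_strains": c.n_strains, **c.counts} for c in bundle.clades]
        files["clades"] = out / "clades.tsv"
        pd.DataFrame(cl_rows, columns=["clade", "n_strains", *count_cols]).to_csv(
            files["clades"], sep="\t", index=False)
    return files
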