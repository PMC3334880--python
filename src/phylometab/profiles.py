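"""Pathway calling from enzyme-presence profiles and clade aggregation.

A gene profile is one strain's presence/absence vector over the glycine/serine
pathway reactions.  A pathway is called present when every required reaction
shows up and every reaction in the definition's exclusion set is absent (the
``Red(-2)`` call, for example, requires the seven-reaction form *without* the
ATP-dependent formyl-THF synthase).  Clade summaries reproduce the per-clade
call-count table; a synthetic generator emulates annotation misses with a
per-enzyme drop probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .knowledge_base import Bundle, CladeRow, KBError, PathwayDef

__all__ = [
    "GeneProfile",
    "PathwayCall",
    "CladeSummary",
    "PATHWAY_ORDER",
    "call_pathways",
    "summarize_clades",
    "cooccurrence",
    "generate_profiles",
    "synthesize_clade_profiles",
    "load_profiles",
    "profiles_frame",
]

#: canonical column order of the clade summary table
PATHWAY_ORDER = ("Glx", "Ox", "Red", "Red-2", "GlyC", "FDH")


@dataclass(frozen=True)
class GeneProfile:
    """One strain's enzyme presence vector.

    ``presence`` maps reaction id to True/False; a reaction absent from the
    mapping is treated as absent.  ``unknown`` lists reactions marked ``?`` in
    the input (treated as absent for calling, counted for coverage).
    """

    strain: str
    clade: str
    presence: Mapping[str, bool]
    unknown: frozenset[str] = frozenset()

    def has(self, rid: str) -> bool:
        return bool(self.presence.get(rid, False))


@dataclass(frozen=True)
class PathwayCall:
    strain: str
    pathway: str
    called: bool


@dataclass(frozen=True)
class CladeSummary:
    clade: str
    n_strains: int
    counts: Mapping[str, int]
    caveats: tuple[str, ...] = ()


def _check_profile(profile: GeneProfile, bundle: Bundle | None) -> None:
    if bundle is None:
        return
    unknown = set(profile.presence) - set(bundle.reactions)
    if unknown:
        raise KBError(
            f"profile {profile.strain}: unknown reaction ids {sorted(unknown)}")


def call_pathways(
    profile: GeneProfile,
    defs: Sequence[PathwayDef],
    bundle: Bundle | None = None,
) -> list[PathwayCall]:
    """called = all required_present present AND all required_absent absent."""
    _check_profile(profile, bundle)
    calls = []
    for d in defs:
        ok = (all(profile.has(r) for r in d.required_present)
              and not any(profile.has(r) for r in d.required_absent))
        calls.append(PathwayCall(profile.strain, d.id, ok))
    return calls


def summarize_clades(
    profiles: Sequence[GeneProfile],
    defs: Sequence[PathwayDef],
    bundle: Bundle | None = None,
) -> list[CladeSummary]:
    """Per-clade pathway call counts, clades in first-appearance order."""
    order: list[str] = []
    by_clade: dict[str, list[GeneProfile]] = {}
    for p in profiles:
        if p.clade not in by_clade:
            order.append(p.clade)
        by_clade.setdefault(p.clade, []).append(p)

    out = []
    for clade in order:
        members = by_clade[clade]
        counts = {d.id: 0 for d in defs}
        for p in members:
            for call in call_pathways(p, defs, bundle):
                counts[call.pathway] += int(call.called)
        caveats = ()
        if any(p.unknown for p in members):
            caveats = ("contains '?' (unknown) presence entries",)
        out.append(CladeSummary(clade, len(members), counts, caveats))
    return out


def grand_total(summaries: Sequence[CladeSummary]) -> CladeSummary:
    counts: dict[str, int] = {}
    n = 0
    for s in summaries:
        n += s.n_strains
        for k, v in s.counts.items():
            counts[k] = counts.get(k, 0) + v
    return CladeSummary("All", n, counts)


def cooccurrence(
    profiles: Sequence[GeneProfile],
    defs: Sequence[PathwayDef],
    a: str,
    b: str | Sequence[str],
    bundle: Bundle | None = None,
) -> tuple[int, int, float]:
    """Count n(a AND b), n(a) and the conditional fraction n(a&b)/n(a).

    ``b`` may be a single pathway id or a sequence interpreted as a
    disjunction (e.g. Red-or-Red(-2)).
    """
    b_ids = (b,) if isinstance(b, str) else tuple(b)
    by_id = {d.id: d for d in defs}
    for pid in (a, *b_ids):
        if pid not in by_id:
            raise KeyError(f"pathway {pid!r} not in defs")
    n_a = n_ab = 0
    for p in profiles:
        calls = {c.pathway: c.called for c in call_pathways(p, defs, bundle)}
        if calls[a]:
            n_a += 1
            if any(calls[x] for x in b_ids):
                n_ab += 1
    return n_ab, n_a, (n_ab / n_a if n_a else float("nan"))


def generate_profiles(
    assignments: Mapping[str, Mapping[str, int]],
    defs: Sequence[PathwayDef],
    n_strains: Mapping[str, int] | None = None,
    miss_rate: float = 0.0,
    targeted_misses: Mapping[str, float] | None = None,
    seed: int = 0,
) -> list[GeneProfile]:
    """Synthesize strain profiles from clade -> pathway assignment counts.

    ``assignments[clade][pathway_id]`` strains of each clade receive that
    pathway's full enzyme complement.  Pathway blocks are laid out
    deterministically from strain 0 and may overlap (one strain can carry
    several pathways), except that a pathway whose exclusion set conflicts
    with an earlier pathway's complement (Red versus Red(-2)) is placed on
    the following strains, so that at ``miss_rate`` 0 the calls reproduce the
    assignment exactly.  Each present enzyme is then dropped independently
    with probability ``miss_rate`` (or the targeted per-reaction
    probability), emulating annotation misses.  Deterministic under a fixed
    seed.
    """
    if not 0.0 <= miss_rate <= 1.0:
        raise ValueError(f"miss_rate {miss_rate} outside [0, 1]")
    for rid, p in (targeted_misses or {}).items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"targeted miss rate {rid}={p} outside [0, 1]")
    rng = np.random.default_rng(seed)
    by_id = {d.id: d for d in defs}
    out: list[GeneProfile] = []
    for clade in assignments:
        counts = assignments[clade]
        n = (n_strains or {}).get(clade, max([0, *counts.values()]))
        present_sets: list[set[str]] = [set() for _ in range(n)]
        placed: list[tuple[PathwayDef, int, int]] = []  # (def, start, count)
        for pid in sorted(counts):
            if pid not in by_id:
                raise KeyError(f"pathway {pid!r} not in defs")
            d = by_id[pid]
            start = 0
            for q, q_start, q_count in placed:
                if (d.required_absent & q.required_present
                        or q.required_absent & d.required_present):
                    start = max(start, q_start + q_count)
            if start + counts[pid] > n:
                raise ValueError(
                    f"{clade}: cannot lay out {pid} x{counts[pid]} within n={n}")
            for i in range(start, start + counts[pid]):
                present_sets[i].update(d.required_present)
            placed.append((d, start, counts[pid]))
        for i, present in enumerate(present_sets):
            kept = {}
            for rid in sorted(present):
                p_miss = (targeted_misses or {}).get(rid, miss_rate)
                kept[rid] = bool(rng.random() >= p_miss)
            out.append(GeneProfile(strain=f"{clade}_{i:04d}", clade=clade,
                                   presence=kept))
    return out


def synthesize_clade_profiles(bundle: Bundle) -> list[GeneProfile]:
    """Deterministic strain-level fixture reproducing the packaged clade table.

    The original per-strain genome annotations are not shipped; this
    constructs, for each clade row, a minimal strain set whose pathway calls
    aggregate exactly to the row's counts.  Strains carrying the
    complete reductive pathway get reactions 2-8, the Red(-2) form gets 3-8,
    glycine-cycle-only strains get 5-8; oxidative (9-11), glyoxylate (12) and
    formate-dehydrogenase (1) complements are overlaid starting from the first
    strains of the clade.
    """
    profiles: list[GeneProfile] = []
    red = bundle.pathways["Red"].required_present
    red2 = bundle.pathways["Red-2"].required_present
    glyc = bundle.pathways["GlyC"].required_present
    ox = bundle.pathways["Ox"].required_present
    glx = bundle.pathways["Glx"].required_present
    fdh = bundle.pathways["FDH"].required_present
    for row in bundle.clades:
        c = row.counts
        n = row.n_strains
        n_red, n_red2, n_glyc = c.get("Red", 0), c.get("Red-2", 0), c.get("GlyC", 0)
        if n_red + n_red2 > n_glyc:
            raise KBError(f"{row.clade}: Red+Red-2 exceed GlyC; fixture not constructible")
        sets: list[set[str]] = [set() for _ in range(n)]
        i = 0
        for _ in range(n_red):
            sets[i].update(red); i += 1
        for _ in range(n_red2):
            sets[i].update(red2); i += 1
        for _ in range(n_glyc - n_red - n_red2):
            sets[i].update(glyc); i += 1
        for i in range(c.get("Ox", 0)):
            sets[i].update(ox)
        for i in range(c.get("Glx", 0)):
            sets[i].update(glx)
        for i in range(c.get("FDH", 0)):
            sets[i].update(fdh)
        for i, present in enumerate(sets):
            profiles.append(GeneProfile(
                strain=f"{row.clade}_{i:04d}", clade=row.clade,
                presence={r: True for r in sorted(present)}))
    return profiles


def load_profiles(path: str | Path, bundle: Bundle | None = None) -> list[GeneProfile]:
    """Read a profiles TSV: strain, clade, then one 0/1/? column per reaction."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    rid_cols = [col for col in df.columns if col not in ("strain", "clade")]
    out = []
    for _, row in df.iterrows():
        presence: dict[str, bool] = {}
        unknown: set[str] = set()
        for col in rid_cols:
            val = str(row[col]).strip()
            if val == "?":
                presence[col] = False
                unknown.add(col)
            elif val in {"0", "1", ""}:
                presence[col] = val == "1"
            else:
                raise KBError(f"profile {row['strain']}/{col}: bad value {val!r}")
        p = GeneProfile(strain=row["strain"], clade=row["clade"],
                        presence=presence, unknown=frozenset(unknown))
        _check_profile(p, bundle)
        out.append(p)
    return out


def profiles_frame(profiles: Sequence[GeneProfile],
                   reaction_ids: Sequence[str]) -> pd.DataFrame:
    """Profiles as a strain x reaction 0/1 DataFrame (for TSV export)."""
    rows = [{"strain": p.strain, "clade": p.clade,
             **{r: int(p.has(r)) for r in reaction_ids}} for p in profiles]
    return pd.DataFrame(rows, columns=["strain", "clade", *reaction_ids])
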