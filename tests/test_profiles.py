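"""Pathway calling, clade aggregation and the synthetic profile generator."""

import numpy as np
import pytest

import phylometab as pm
from phylometab.knowledge_base import KBError
from phylometab.profiles import (
    GeneProfile,
    PATHWAY_ORDER,
    call_pathways,
    cooccurrence,
    generate_profiles,
    grand_total,
    load_profiles,
    summarize_clades,
    synthesize_clade_profiles,
)


def _profile(rids, strain="s", clade="c"):
    return GeneProfile(strain=strain, clade=clade,
                       presence={r: True for r in rids})


def test_full_eight_reaction_profile_calls(bundle, pathway_defs):
    """Reactions 1-8 all present: Red, GlyC and FDH called, Red(-2) not."""
    calls = {c.pathway: c.called
             for c in call_pathways(_profile("12345678"), pathway_defs, bundle)}
    assert calls == {"Glx": False, "Ox": False, "Red": True, "Red-2": False,
                     "GlyC": True, "FDH": True}


def test_seven_reaction_form_calls_red_minus_2(bundle, pathway_defs):
    calls = {c.pathway: c.called
             for c in call_pathways(_profile("1345678"), pathway_defs, bundle)}
    assert calls["Red-2"] and not calls["Red"]
    assert calls["GlyC"] and calls["FDH"]


def test_empty_profile_calls_nothing(bundle, pathway_defs):
    calls = call_pathways(_profile(""), pathway_defs, bundle)
    assert not any(c.called for c in calls)


def test_unknown_reaction_id_raises(bundle, pathway_defs):
    with pytest.raises(KBError, match="zz"):
        call_pathways(_profile(["zz"]), pathway_defs, bundle)


def test_red_and_red2_imply_glyc_for_all_fixture_strains(bundle, pathway_defs,
                                                         clade_profiles):
    """Red => GlyC and Red(-2) => GlyC; Red and Red(-2) mutually exclusive."""
    for p in clade_profiles:
        calls = {c.pathway: c.called for c in call_pathways(p, pathway_defs)}
        assert not (calls["Red"] and calls["Red-2"])
        if calls["Red"] or calls["Red-2"]:
            assert calls["GlyC"]


def test_caller_monotone_in_presence(bundle, pathway_defs):
    """Adding a present enzyme never removes a call except via
    required_absent."""
    base = _profile("345678")
    more = _profile("1345678")
    c0 = {c.pathway: c.called for c in call_pathways(base, pathway_defs)}
    c1 = {c.pathway: c.called for c in call_pathways(more, pathway_defs)}
    for pid in c0:
        if not pathway_defs[PATHWAY_ORDER.index(pid)].required_absent:
            assert c1[pid] or not c0[pid]
    # and the exception: adding reaction 2 retracts the Red(-2) call
    c2 = {c.pathway: c.called for c in call_pathways(_profile("12345678"), pathway_defs)}
    assert c0["Red-2"] and not c2["Red-2"]


def test_clade_summaries_reproduce_packaged_table(bundle, pathway_defs,
                                                  clade_profiles):
    summ = summarize_clades(clade_profiles, pathway_defs, bundle)
    by_clade = {s.clade: s for s in summ}
    for row in bundle.clades:
        s = by_clade[row.clade]
        assert s.n_strains == row.n_strains
        for pid, n in row.counts.items():
            assert s.counts[pid] == n, (row.clade, pid)


def test_thermotogae_row(bundle, pathway_defs, clade_profiles):
    summ = summarize_clades(clade_profiles, pathway_defs, bundle)
    t = next(s for s in summ if s.clade == "Thermotogae")
    assert [t.counts[p] for p in PATHWAY_ORDER] == [0, 0, 11, 0, 11, 1]


def test_grand_total_is_column_sum(bundle, pathway_defs, clade_profiles):
    summ = summarize_clades(clade_profiles, pathway_defs, bundle)
    tot = grand_total(summ)
    for pid in PATHWAY_ORDER:
        assert tot.counts[pid] == sum(s.counts[pid] for s in summ)
    assert tot.n_strains == 359


def test_example_profiles_call_as_described(bundle, pathway_defs):
    """The packaged exemplar strains: three full 8-step profiles call Red,
    three 7-reaction profiles call Red(-2)."""
    profs = load_profiles(pm.knowledge_base.data_dir() / "example_profiles.tsv",
                          bundle)
    calls = {p.strain: {c.pathway: c.called
                        for c in call_pathways(p, pathway_defs, bundle)}
             for p in profs}
    for s in ("MTA", "CAG", "NDE"):
        assert calls[s]["Red"] and not calls[s]["Red-2"]
    for s in ("AAE", "CCH", "NPU"):
        assert calls[s]["Red-2"] and not calls[s]["Red"]


def test_cooccurrence_glyc_with_reductive_forms(bundle, pathway_defs,
                                                clade_profiles):
    """On the fixture, all GlyC strains derive from Red/Red(-2)/GlyC-only
    construction; perfect-linkage generation gives fraction 1.0."""
    defs = pathway_defs
    profs = generate_profiles({"c": {"GlyC": 5, "Red": 5}}, defs,
                              n_strains={"c": 5}, miss_rate=0.0, seed=1)
    n_ab, n_a, frac = cooccurrence(profs, defs, "GlyC", ("Red", "Red-2"))
    assert (n_ab, n_a, frac) == (5, 5, 1.0)
    # Lactobacillales lack the glycine cycle entirely
    lacto = [p for p in clade_profiles if p.clade == "Bacilli-Lactobacillales"]
    n_ab, n_a, _ = cooccurrence(lacto, defs, "Ox", "GlyC")
    assert n_a == 16 and n_ab == 0


def test_cooccurrence_independent_rates(bundle, pathway_defs):
    """Independent presence at rates p, q gives conditional fraction ~= q."""
    rng = np.random.default_rng(7)
    p_rate, q_rate, n = 0.6, 0.3, 4000
    profs = []
    for i in range(n):
        pres = {}
        if rng.random() < p_rate:
            pres.update({r: True for r in "5678"})
        if rng.random() < q_rate:
            pres["12"] = True
        profs.append(GeneProfile(f"s{i}", "c", pres))
    n_ab, n_a, frac = cooccurrence(profs, pathway_defs, "GlyC", "Glx")
    se = (q_rate * (1 - q_rate) / n_a) ** 0.5
    assert abs(frac - q_rate) < 4 * se


def test_generator_miss_rate_zero_round_trip(bundle, pathway_defs):
    """generate at miss_rate 0 then summarize reproduces the generating
    assignment exactly."""
    assignments = {row.clade: dict(row.counts) for row in bundle.clades}
    n_strains = {row.clade: row.n_strains for row in bundle.clades}
    profs = generate_profiles(assignments, pathway_defs, n_strains=n_strains,
                              miss_rate=0.0, seed=3)
    summ = summarize_clades(profs, pathway_defs, bundle)
    by_clade = {s.clade: s for s in summ}
    for row in bundle.clades:
        for pid in ("Red", "Red-2", "GlyC", "FDH", "Ox", "Glx"):
            assert by_clade[row.clade].counts[pid] == row.counts[pid], \
                (row.clade, pid)


def test_generator_deterministic_under_seed(pathway_defs):
    a = generate_profiles({"c": {"Red": 10}}, pathway_defs, miss_rate=0.3, seed=42)
    b = generate_profiles({"c": {"Red": 10}}, pathway_defs, miss_rate=0.3, seed=42)
    assert a == b
    c = generate_profiles({"c": {"Red": 10}}, pathway_defs, miss_rate=0.3, seed=43)
    assert a != c


def test_targeted_miss_produces_red2_clade(bundle, pathway_defs):
    """Dropping reaction 2 with probability 1 turns an assigned-Red clade
    into an all-Red(-2) clade (the Aquificales pattern)."""
    profs = generate_profiles({"aq": {"Red": 6, "FDH": 6}}, pathway_defs,
                              n_strains={"aq": 6}, miss_rate=0.0,
                              targeted_misses={"2": 1.0}, seed=5)
    for p in profs:
        calls = {c.pathway: c.called for c in call_pathways(p, pathway_defs)}
        assert calls["Red-2"] and not calls["Red"]


def test_miss_frequency_within_binomial_interval(pathway_defs):
    """Per-enzyme absence frequency at miss_rate 0.1 with 1000 strains falls
    in the 99% binomial interval (0.10 +/- 0.03)."""
    profs = generate_profiles({"c": {"Red": 1000}}, pathway_defs,
                              n_strains={"c": 1000}, miss_rate=0.1, seed=11)
    red = next(d for d in pathway_defs if d.id == "Red")
    for rid in sorted(red.required_present):
        freq = sum(0 if p.has(rid) else 1 for p in profs) / 1000
        assert abs(freq - 0.10) <= 0.03, (rid, freq)


def test_invalid_probability_rejected(pathway_defs):
    with pytest.raises(ValueError):
        generate_profiles({"c": {"Red": 1}}, pathway_defs, miss_rate=1.5, seed=0)


def test_unknown_marker_treated_absent_but_flagged(tmp_path, bundle, pathway_defs):
    p = tmp_path / "p.tsv"
    p.write_text("strain\tclade\t1\t2\t3\ns1\tc\t1\t?\t0\n")
    profs = load_profiles(p, bundle)
    assert profs[0].unknown == frozenset({"2"})
    assert not profs[0].has("2")
    summ = summarize_clades(profs, pathway_defs, bundle)
    assert summ[0].caveats
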