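"""Reporting: composition, satisfaction vs brute-force oracle, search, stats."""

import math

import numpy as np
import pytest

from ihmforge import fixtures, reporting
from ihmforge.reporting import (
    CatalogEntry,
    QueryError,
    SatisfactionPolicy,
    archive_statistics,
    crosslink_satisfaction,
    entry_summary,
    model_composition,
    search_catalog,
)
from conftest import random_config


# -- composition -------------------------------------------------------------


def test_composition_matches_ground_truth_and_conserves():
    rng = np.random.default_rng(9)
    for k in range(8):
        entry, truth = fixtures.generate_entry(random_config(rng, seed=700 + k))
        c = model_composition(entry)
        assert c.residues_total == truth.composition["residues_total"]
        assert c.residues_atomic == truth.composition["residues_atomic"]
        assert c.residues_coarse == truth.composition["residues_coarse"]
        assert c.n_spheres == truth.composition["n_spheres"]
        assert c.n_atoms == truth.composition["n_atoms"]
        # conservation: every residue is atomic, coarse or unmodeled
        assert (c.residues_atomic + c.residues_coarse + c.residues_unmodeled
                == c.residues_total)
        assert c.atomic_fraction == pytest.approx(
            truth.composition["atomic_fraction"]
        )


# -- cross-link satisfaction -------------------------------------------------


def brute_force_satisfaction(entry, ensemble_rule):
    """Naive per-pair/per-model scan, independent of the library code."""

    def point(model, end, granularity):
        aref = end.asym_ref or next(
            (a.id for a in entry.asyms if a.entity_ref == end.entity_ref), None
        )
        if granularity == "by-atom" and end.atom_name:
            for at in model.atoms:
                if (at.asym_ref == aref and at.seq_id == end.seq_id
                        and at.atom_name == end.atom_name):
                    return (at.x, at.y, at.z)
        for at in model.atoms:
            if (at.asym_ref == aref and at.seq_id == end.seq_id
                    and at.atom_name == "CA"):
                return (at.x, at.y, at.z)
        for sp in model.spheres:
            if sp.asym_ref == aref and sp.seq_begin <= end.seq_id <= sp.seq_end:
                return (sp.x, sp.y, sp.z)
        return None

    groups = {}
    for xl in entry.crosslinks:
        groups.setdefault(xl.group_id, []).append(xl)
    per_group = {}
    for gid, members in groups.items():
        if any(x.restraint_form != "upper-bound" for x in members):
            per_group[gid] = None
            continue
        ok_models = 0
        skip = False
        for m in entry.models:
            dists = []
            for xl in members:
                p1 = point(m, xl.end1, xl.granularity)
                p2 = point(m, xl.end2, xl.granularity)
                if p1 is None or p2 is None:
                    skip = True
                    break
                dists.append(math.sqrt(sum((a - b) ** 2
                                           for a, b in zip(p1, p2))))
            if skip:
                break
            combined = (min(dists) if members[0].conditionality == "any"
                        else max(dists))
            if combined <= members[0].threshold:
                ok_models += 1
        if skip:
            per_group[gid] = "skip"
        elif ensemble_rule == "any-model":
            per_group[gid] = ok_models > 0
        else:
            per_group[gid] = ok_models == len(entry.models)
    return per_group


@pytest.mark.parametrize("rule", ["any-model", "all-models"])
def test_satisfaction_equals_brute_force_oracle(rule):
    rng = np.random.default_rng(13)
    for k in range(6):
        entry, truth = fixtures.generate_entry(random_config(rng, seed=300 + k))
        report = crosslink_satisfaction(entry, SatisfactionPolicy(rule))
        oracle = brute_force_satisfaction(entry, rule)
        got = {o.restraint_group_id: o.satisfied for o in report.outcomes}
        want = {g: v for g, v in oracle.items() if isinstance(v, bool)}
        assert got == want
        assert report.summary.n_satisfied == sum(want.values())
        assert report.summary.n_violated == len(want) - sum(want.values())


def test_satisfaction_matches_construction_counts(toy):
    entry, truth = toy
    report = crosslink_satisfaction(entry)
    assert report.summary.n_satisfied == truth.n_satisfied
    assert report.summary.n_violated == truth.n_violated
    for o in report.outcomes:
        assert o.satisfied == truth.group_satisfied[o.restraint_group_id]


def test_non_upper_bound_groups_are_not_evaluated(toy):
    import copy

    entry = copy.deepcopy(toy[0])
    entry.crosslinks[0].restraint_form = "lower-bound"
    gid = entry.crosslinks[0].group_id
    report = crosslink_satisfaction(entry)
    assert gid in report.not_evaluated
    assert all(o.restraint_group_id != gid for o in report.outcomes)


def test_unrepresented_end_yields_finding(toy):
    import copy

    entry = copy.deepcopy(toy[0])
    entry.crosslinks[0].end1.seq_id = entry.crosslinks[0].end1.seq_id  # noop
    # point the end at a residue beyond every representation footprint
    for m in entry.models:
        m.atoms = [a for a in m.atoms if a.seq_id != 1]
        m.spheres = [s for s in m.spheres if not s.seq_begin <= 1 <= s.seq_end]
    entry.crosslinks[0].end1.seq_id = 1
    report = crosslink_satisfaction(entry)
    assert any("unrepresented" in f for f in report.findings)


def test_satisfaction_requires_models_and_links(toy):
    import copy

    empty = copy.deepcopy(toy[0])
    empty.crosslinks = []
    with pytest.raises(ValueError):
        crosslink_satisfaction(empty)
    nomodel = copy.deepcopy(toy[0])
    nomodel.models = []
    with pytest.raises(ValueError):
        crosslink_satisfaction(nomodel)


# -- catalog, stats, search --------------------------------------------------


def _cards():
    return [
        CatalogEntry("PDBDEV_00000001", "Nuclear pore complex scaffold",
                     "multi-scale model", ["CX-MS", "3DEM"], ["IMP"],
                     ["Doe, J."], multi_scale=True),
        CatalogEntry("PDBDEV_00000002", "Chromatin remodeler dynamics",
                     "two-state ensemble", ["CX-MS", "SAS"], ["IMP", "MODELLER"],
                     ["Roe, R."], multi_state=True),
        CatalogEntry("PDBDEV_00000003", "Kinetochore assembly pathway",
                     "ordered process", ["FRET"], ["Rosetta"],
                     ["Doe, J.", "Poe, E."], ordered=True),
    ]


def test_entry_summary_flags(toy):
    entry, truth = toy
    card = entry_summary(entry, accession="PDBDEV_00000009")
    assert card.accession == "PDBDEV_00000009"
    assert card.multi_scale  # both atomic and sphere segments
    assert not card.multi_state and not card.ordered
    assert card.data_types == ["CX-MS", "SAS"]
    assert card.software_names == ["IMP"]
    multi = fixtures.generate_entry(
        fixtures.ToyConfig(seed=2, n_states=3, n_models=3, ordered=True)
    )[0]
    card2 = entry_summary(multi)
    assert card2.multi_state and card2.ordered


def test_archive_statistics_sums():
    stats = archive_statistics(_cards())
    assert stats.n_entries == 3
    assert stats.counts_by_data_type == {"CX-MS": 2, "3DEM": 1, "SAS": 1, "FRET": 1}
    assert stats.counts_by_software == {"IMP": 2, "MODELLER": 1, "Rosetta": 1}
    # each entry counted once per distinct value it carries
    assert sum(stats.counts_by_data_type.values()) == sum(
        len(set(c.data_types)) for c in _cards()
    )


def test_search_terms_operators_and_wildcards():
    cards = _cards()
    assert search_catalog(cards, "chromatin") == ["PDBDEV_00000002"]
    assert search_catalog(cards, "imp") == [
        "PDBDEV_00000001", "PDBDEV_00000002",
    ]
    assert search_catalog(cards, "imp AND 3dem") == ["PDBDEV_00000001"]
    assert search_catalog(cards, "imp OR fret") == [
        "PDBDEV_00000001", "PDBDEV_00000002", "PDBDEV_00000003",
    ]
    assert search_catalog(cards, "NOT imp") == ["PDBDEV_00000003"]
    assert search_catalog(cards, "chrom*") == ["PDBDEV_00000002"]
    assert search_catalog(cards, "(imp OR fret) AND NOT sas") == [
        "PDBDEV_00000001", "PDBDEV_00000003",
    ]
    # implicit conjunction: juxtaposed terms all must match
    assert search_catalog(cards, "imp sas") == ["PDBDEV_00000002"]
    # case-insensitive terms, case-sensitive operators
    assert search_catalog(cards, "IMP AND SAS") == ["PDBDEV_00000002"]


def test_search_de_morgan_duality():
    cards = _cards()
    for q1, q2 in [
        ("NOT (imp OR fret)", "NOT imp AND NOT fret"),
        ("NOT (imp AND sas)", "NOT imp OR NOT sas"),
    ]:
        assert search_catalog(cards, q1) == search_catalog(cards, q2)
    # complement partitions the catalog
    hits = set(search_catalog(cards, "imp"))
    rest = set(search_catalog(cards, "NOT imp"))
    assert hits | rest == {c.accession for c in cards} and not hits & rest


def test_search_facets():
    cards = _cards()
    assert search_catalog(cards, "PDBDEV_*", {"multi_state": True}) == [
        "PDBDEV_00000002",
    ]
    assert search_catalog(cards, "PDBDEV_*", {"data_type": "CX-MS"}) == [
        "PDBDEV_00000001", "PDBDEV_00000002",
    ]
    assert search_catalog(cards, "PDBDEV_*", {"software": "Rosetta"}) == [
        "PDBDEV_00000003",
    ]
    with pytest.raises(QueryError):
        search_catalog(cards, "PDBDEV_*", {"shoe_size": 42})


@pytest.mark.parametrize("bad", ["", "(imp", "imp)", "AND imp", "imp OR", "NOT"])
def test_search_query_errors(bad):
    with pytest.raises(QueryError):
        search_catalog(_cards(), bad)


def test_catalog_entry_dict_roundtrip():
    for card in _cards():
        assert CatalogEntry.from_dict(card.to_dict()) == card
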