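"""Domain graph: invariants, integrity, (de)serialization, fact derivation."""

import copy

import numpy as np
import pytest

from ihmforge import cif, fixtures
from ihmforge.model import (
    Assembly,
    AsymUnit,
    Atom,
    CrossLinkEnd,
    CrossLinkRestraint,
    Ensemble,
    Entity,
    Entry,
    ModelError,
    ModelGroup,
    OrderedProcess,
    RepresentationSegment,
    Sphere,
    State,
    StructModel,
    derive_entry_facts,
    entry_from_document,
    entry_to_document,
    validate_referential_integrity,
)
from conftest import random_config


# -- invariants --------------------------------------------------------------


def test_type_invariants_reject_bad_values():
    with pytest.raises(ModelError):
        Entity("e1", "polymer", [])  # empty polymer sequence
    with pytest.raises(ModelError):
        Entity("e1", "nonpolymer", ["ATP", "ADP"])  # exactly one component
    with pytest.raises(ModelError):
        Entity("e1", "gas", ["ALA"])  # bad kind
    with pytest.raises(ModelError):
        Sphere("A", 1, 5, 0.0, 0.0, 0.0, radius=0.0)  # radius > 0
    with pytest.raises(ModelError):
        Atom("A", 1, "CA", "C", float("nan"), 0.0, 0.0)  # finite coords
    with pytest.raises(ModelError):
        RepresentationSegment("A", 1, 5, "atomic", "by-feature")
    with pytest.raises(ModelError):
        State("s1", [])  # needs a model group
    with pytest.raises(ModelError):
        State("s1", ["g1"], population_fraction=1.5)
    with pytest.raises(ModelError):
        OrderedProcess("o1", "time", [("g1", "g2", 2)])  # indices 1..n
    with pytest.raises(ModelError):
        Ensemble("e1", "g1", num_models_total=1, num_models_deposited=2)
    with pytest.raises(ModelError):
        CrossLinkRestraint(
            "1", "g1", CrossLinkEnd("e1", 1), CrossLinkEnd("e1", 2),
            "DSS", threshold=-1.0,
        )
    with pytest.raises(ModelError):
        CrossLinkRestraint(
            "1", "g1", CrossLinkEnd("e1", 1), CrossLinkEnd("e1", 2),
            "DSS", threshold=10.0, granularity="by-atom",
        )


def test_referential_integrity_reports_each_dangling_reference():
    entry = Entry(id="x")
    entry.entities.append(Entity("e1", "polymer", ["ALA", "GLY"]))
    entry.asyms.append(AsymUnit("A", "nope"))  # dangling entity
    entry.assemblies.append(Assembly("a1", [("B", 1, 2)]))  # dangling asym
    entry.models.append(StructModel("m1", "a1", "missing_rep"))
    entry.model_groups.append(ModelGroup("g1", ["m1", "m2"]))  # m2 dangling
    findings = validate_referential_integrity(entry)
    targets = {(f.field, f.target) for f in findings}
    assert ("entity_ref", "nope") in targets
    assert ("asym_ref", "B") in targets
    assert ("representation_ref", "missing_rep") in targets
    assert ("model_refs", "m2") in targets
    assert len(findings) == 4


def test_entry_to_document_refuses_broken_entry(toy):
    entry, _ = toy
    broken = copy.deepcopy(entry)
    broken.models[0].atoms[0].asym_ref = "ZZ"
    with pytest.raises(ModelError, match="ZZ"):
        entry_to_document(broken)


# -- round trip --------------------------------------------------------------


def test_entry_document_roundtrip_is_identity_across_configs():
    rng = np.random.default_rng(2024)
    for k in range(8):
        entry, _ = fixtures.generate_entry(random_config(rng, seed=900 + k))
        doc = entry_to_document(entry)
        entry2 = entry_from_document(doc)
        doc2 = entry_to_document(entry2)
        result = cif.documents_equal(doc, doc2)
        assert result, f"config {k}: {result.difference}"
        # serialization is deterministic byte-for-byte
        assert cif.write_document(doc) == cif.write_document(doc2)


def test_unknown_categories_roundtrip_through_extras(toy):
    entry, _ = toy
    doc = entry_to_document(entry)
    extra = cif.CifCategory("my_custom_scores", ["model_id", "score"])
    extra.append(["m1", "0.5"])
    doc.sole_block.add(extra)
    entry2 = entry_from_document(doc)
    assert [c.name for c in entry2.extras] == ["my_custom_scores"]
    doc2 = entry_to_document(entry2)
    assert cif.documents_equal(doc, doc2)


def test_deserialization_errors_carry_location(toy):
    entry, _ = toy
    doc = entry_to_document(entry)
    bad = copy.deepcopy(doc)
    cat = bad.sole_block.find("atom_site")
    cat.rows[3][cat.item_names.index("x")] = cif.value_of("oops")
    with pytest.raises(ModelError) as exc:
        entry_from_document(bad)
    msg = str(exc.value)
    assert "atom_site" in msg and "x" in msg and "row 3" in msg and "oops" in msg


def test_entry_from_document_requires_models_and_entities(toy):
    entry, _ = toy
    doc = entry_to_document(entry)
    no_coords = copy.deepcopy(doc)
    no_coords.sole_block.categories = [
        c for c in no_coords.sole_block.categories
        if c.name not in ("atom_site", "sphere")
    ]
    with pytest.raises(ModelError, match="no models"):
        entry_from_document(no_coords)
    no_entity = copy.deepcopy(doc)
    no_entity.sole_block.categories = [
        c for c in no_entity.sole_block.categories if c.name != "entity"
    ]
    with pytest.raises(ModelError, match="entity"):
        entry_from_document(no_entity)


# -- derived facts -----------------------------------------------------------


def test_derive_facts_match_ground_truth():
    rng = np.random.default_rng(77)
    for k in range(6):
        config = random_config(rng, seed=500 + k)
        entry, truth = fixtures.generate_entry(config)
        facts = derive_entry_facts(entry_to_document(entry))
        assert facts.n_models == truth.n_models
        assert facts.asym_ids == truth.asym_ids
        assert facts.sequences_three == truth.sequences_three
        assert facts.has_atoms == (config.n_atomic > 0)
        assert facts.has_spheres == (config.n_atomic < config.chain_length)
        for aid in truth.asym_ids:
            assert facts.modeled_ranges[aid] == [(1, config.chain_length)]


def test_derive_facts_reconstructs_sequence_from_atoms():
    src = """\
data_m
loop_
_atom_site.model_id
_atom_site.asym_id
_atom_site.seq_id
_atom_site.comp_id
_atom_site.atom_id
_atom_site.type_symbol
_atom_site.x
_atom_site.y
_atom_site.z
1 A 1 MET CA C 0.0 0.0 0.0
1 A 2 ALA CA C 3.8 0.0 0.0
1 A 4 GLY CA C 7.6 0.0 0.0
2 A 1 MET CA C 0.1 0.0 0.0
"""
    facts = derive_entry_facts(cif.parse_document(src))
    assert facts.n_models == 2
    assert facts.asym_ids == ["A"]
    assert facts.sequences_three["A"] == ["MET", "ALA", "UNK", "GLY"]
    assert facts.sequences_one["A"] == "MAXG"
    assert facts.modeled_ranges["A"] == [(1, 2), (4, 4)]


def test_derive_facts_rejects_undeclared_asym(toy):
    entry, _ = toy
    doc = entry_to_document(entry)
    bad = copy.deepcopy(doc)
    cat = bad.sole_block.find("atom_site")
    cat.rows[0][cat.item_names.index("asym_id")] = cif.value_of("Q")
    with pytest.raises(ModelError, match="undeclared"):
        derive_entry_facts(bad)


def test_modeled_ranges_merge_adjacent_and_overlapping():
    from ihmforge.model import _merge_ranges

    assert _merge_ranges([(5, 9), (1, 4), (12, 14)]) == [(1, 9), (12, 14)]
    assert _merge_ranges([(1, 3), (2, 6)]) == [(1, 6)]
    assert _merge_ranges([]) == []
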