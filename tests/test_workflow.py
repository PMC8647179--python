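"""Deposition workflow: state machine, file integrity, metadata, CSV, submit."""

import itertools

import numpy as np
import pytest

from ihmforge import cif, fixtures, workflow
from ihmforge.workflow import (
    ALLOWED_TRANSITIONS,
    CROSSLINK_COLUMNS,
    NotFoundError,
    Submission,
    SubmissionStore,
    WorkflowError,
    WorkflowStatus,
    create_submission,
    get_snapshot,
    ingest_restraint_csv,
    load_submission,
    process_model_upload,
    read_file,
    record_metadata,
    save_submission,
    store_file,
    submit,
    transition,
)
from ihmforge.model import entry_to_document
from conftest import random_config


def _model_text(seed=21, **kw) -> tuple[str, object, object]:
    entry, truth = fixtures.generate_entry(fixtures.ToyConfig(seed=seed, **kw))
    text = cif.write_document(fixtures.coordinates_only_document(entry))
    return text, entry, truth


def _annotated(seed=21, **kw):
    text, entry, truth = _model_text(seed, **kw)
    sub = create_submission("dep1")
    store_file(sub, "model", "model.cif", text.encode())
    process_model_upload(sub)
    assert sub.status == WorkflowStatus.ANNOT
    return sub, entry, truth


# -- state machine -----------------------------------------------------------


def test_transition_table_is_enforced_exhaustively():
    for a, b in itertools.product(WorkflowStatus, repeat=2):
        sub = create_submission("d")
        sub.status = a
        if (a, b) in ALLOWED_TRANSITIONS:
            transition(sub, b, "test")
            assert sub.status == b
            assert sub.status_history[-1].to_status == b
        else:
            with pytest.raises(WorkflowError):
                transition(sub, b, "test")
            assert sub.status == a


def _simple_paths(start, end):
    paths = []

    def walk(node, seen, path):
        if node == end:
            paths.append(list(path))
            return
        for a, b in ALLOWED_TRANSITIONS:
            if a == node and b not in seen:
                walk(b, seen | {b}, path + [b])

    walk(start, {start}, [start])
    return paths


def test_no_path_reaches_submit_without_processing():
    for path in _simple_paths(WorkflowStatus.DRAFT, WorkflowStatus.SUBMIT):
        assert WorkflowStatus.PROC in path
    # every escape from ERROR goes through reprocessing
    for path in _simple_paths(WorkflowStatus.ERROR, WorkflowStatus.SUBMIT):
        assert path[1] == WorkflowStatus.PROC
    # and release is unreachable without submission
    for path in _simple_paths(WorkflowStatus.DRAFT, WorkflowStatus.REL):
        assert WorkflowStatus.SUBMIT in path


# -- files -------------------------------------------------------------------


def test_file_versioning_and_hash_integrity():
    sub = create_submission("d")
    store_file(sub, "model", "m.cif", b"data_x\n_a.v 1\n")
    f2 = store_file(sub, "model", "m.cif", b"data_x\n_a.v 2\n")
    assert [f.version for f in sub.file_versions("m.cif", "model")] == [1, 2]
    assert read_file(sub, "m.cif", "model") == b"data_x\n_a.v 2\n"
    assert read_file(sub, "m.cif", "model", version=1) == b"data_x\n_a.v 1\n"
    # single-byte corruption is detected on read
    corrupted = bytearray(f2.content)
    corrupted[5] ^= 0x01
    f2.content = bytes(corrupted)
    with pytest.raises(WorkflowError, match="integrity"):
        read_file(sub, "m.cif", "model")
    with pytest.raises(NotFoundError):
        read_file(sub, "ghost.cif", "model")


def test_processing_failure_sets_error_and_reupload_recovers():
    sub = create_submission("d")
    store_file(sub, "model", "m.cif", b"this is not mmCIF at all")
    process_model_upload(sub)
    assert sub.status == WorkflowStatus.ERROR
    assert sub.status_history[-1].note  # the parse error is recorded
    text, _, _ = _model_text()
    store_file(sub, "model", "m.cif", text.encode())
    process_model_upload(sub)
    assert sub.status == WorkflowStatus.ANNOT
    assert sub.derived_facts is not None
    # the full history is retained
    seq = [ev.to_status for ev in sub.status_history]
    assert seq == [
        WorkflowStatus.DRAFT, WorkflowStatus.PROC, WorkflowStatus.ERROR,
        WorkflowStatus.PROC, WorkflowStatus.ANNOT,
    ]


# -- metadata records --------------------------------------------------------


def test_metadata_versions_and_snapshots(dictionary):
    sub, _, _ = _annotated()
    rv1, f = record_metadata(
        sub, "citations",
        {"id": "c1", "title": "First title", "journal": "J"}, dictionary,
    )
    assert rv1 is not None and not f
    rv2, _ = record_metadata(
        sub, "citations",
        {"id": "c1", "title": "Corrected title", "journal": "J"}, dictionary,
    )
    assert rv2.version == 2
    assert get_snapshot(sub, rv1.record_id, 1)["title"] == "First title"
    assert get_snapshot(sub, rv1.record_id, 2)["title"] == "Corrected title"
    with pytest.raises(NotFoundError):
        get_snapshot(sub, rv1.record_id, 3)
    # a rejected payload stores nothing
    bad, findings = record_metadata(sub, "citations", {"journal": "J"}, dictionary)
    assert bad is None and findings
    assert len(sub.metadata_records[rv1.record_id]) == 2


def test_metadata_requires_annot_status(dictionary):
    sub = create_submission("d")
    with pytest.raises(WorkflowError):
        record_metadata(sub, "citations", {"id": "c", "title": "t"}, dictionary)
    with pytest.raises(WorkflowError):
        record_metadata(sub, "nonsense", {}, dictionary)


def test_dataset_metadata_validation(dictionary):
    sub, _, _ = _annotated()
    ok, f = record_metadata(sub, "dataset_refs", {
        "id": "d9", "data_type": "SAS", "db_name": "SASBDB", "accession": "S1",
    }, dictionary)
    assert ok is not None and not f
    bad, f = record_metadata(sub, "dataset_refs", {
        "id": "d9", "data_type": "guesswork", "db_name": "SASBDB",
        "accession": "S1",
    }, dictionary)
    assert bad is None and any("data_type" == x.location.item for x in f)


# -- restraint CSVs ----------------------------------------------------------


def test_csv_roundtrip_reproduces_restraints():
    sub, entry, truth = _annotated()
    text = fixtures.generate_crosslink_csv(entry, truth)
    got, findings = ingest_restraint_csv(sub, "crosslink", text)
    assert not findings
    want = entry.crosslinks
    assert len(got) == len(want)
    for g, w in zip(got, want):
        assert (
            g.group_id, g.end1.entity_ref, g.end1.seq_id,
            g.end2.entity_ref, g.end2.seq_id, g.linker, g.threshold,
            g.restraint_form, g.conditionality, g.dataset_ref,
        ) == (
            w.group_id, w.end1.entity_ref, w.end1.seq_id,
            w.end2.entity_ref, w.end2.seq_id, w.linker, w.threshold,
            w.restraint_form, w.conditionality, w.dataset_ref,
        )


def test_csv_ingestion_is_atomic_and_locates_errors():
    sub, entry, truth = _annotated()
    lines = fixtures.generate_crosslink_csv(entry, truth).splitlines()
    # corrupt line 3: bad threshold; line 5: out-of-range seq id
    parts = lines[2].split(",")
    parts[CROSSLINK_COLUMNS.index("threshold_A")] = "wide"
    lines[2] = ",".join(parts)
    parts = lines[4].split(",")
    parts[CROSSLINK_COLUMNS.index("seq_id_1")] = "9999"
    lines[4] = ",".join(parts)
    got, findings = ingest_restraint_csv(sub, "crosslink", "\n".join(lines))
    assert got == [] and sub.restraints == []
    assert sorted(f.line for f in findings) == [3, 5]
    assert any("threshold" in f.message for f in findings)
    assert any("seq_id" in f.message for f in findings)


def test_csv_rejects_wrong_header_and_comp_mismatch():
    sub, entry, truth = _annotated()
    with pytest.raises(WorkflowError, match="template header"):
        ingest_restraint_csv(sub, "crosslink", "a,b,c\n1,2,3\n")
    with pytest.raises(WorkflowError, match="unknown restraint kind"):
        ingest_restraint_csv(sub, "torsion", "x\n")
    lines = fixtures.generate_crosslink_csv(entry, truth).splitlines()
    parts = lines[1].split(",")
    comp_col = CROSSLINK_COLUMNS.index("comp_id_1")
    parts[comp_col] = "TRP" if parts[comp_col] != "TRP" else "GLY"
    lines[1] = ",".join(parts)
    got, findings = ingest_restraint_csv(sub, "crosslink", "\n".join(lines))
    assert got == [] and len(findings) == 1 and "disagrees" in findings[0].message


def test_csv_accepts_tab_delimiter():
    sub, entry, truth = _annotated()
    text = fixtures.generate_crosslink_csv(entry, truth).replace(",", "\t")
    got, findings = ingest_restraint_csv(sub, "crosslink", text)
    assert not findings and len(got) == len(entry.crosslinks)


# -- submission --------------------------------------------------------------


def _record_minimum(sub, dictionary):
    record_metadata(sub, "citations", {
        "id": "c1", "title": "A study", "journal": "J", "authors": ["Doe, J."],
    }, dictionary)
    record_metadata(sub, "dataset_refs", {
        "id": "d1", "data_type": "CX-MS", "db_name": "ProteomeXchange",
        "accession": "PXD000001",
    }, dictionary)


def test_submit_aggregates_and_validates(dictionary):
    sub, entry, truth = _annotated()
    _record_minimum(sub, dictionary)
    ingest_restraint_csv(
        sub, "crosslink", fixtures.generate_crosslink_csv(entry, truth)
    )
    sub, aggregate = submit(sub, dictionary)
    assert sub.status == WorkflowStatus.SUBMIT
    assert sub.compliance_report.compliant
    block = aggregate.sole_block
    assert block.find("citation") is not None
    assert block.find("crosslink") is not None
    assert len(block.find("crosslink").rows) == len(entry.crosslinks)
    # the aggregate is stored with the other files
    agg = sub.latest_file("aggregate")
    assert agg is not None and agg.verify()


def test_submit_requires_mandatory_metadata(dictionary):
    sub, _, _ = _annotated()
    with pytest.raises(WorkflowError, match="citations"):
        submit(sub, dictionary)


def test_submit_bypass_for_complete_upload(dictionary):
    """A complete, compliant upload needs no separately recorded metadata."""
    entry, _ = fixtures.generate_entry(fixtures.ToyConfig(seed=33))
    text = cif.write_document(entry_to_document(entry))
    sub = create_submission("d")
    store_file(sub, "model", "full.cif", text.encode())
    process_model_upload(sub)
    sub, aggregate = submit(sub, dictionary)
    assert sub.status == WorkflowStatus.SUBMIT
    assert sub.compliance_report.compliant


def test_submit_with_dangling_dataset_goes_to_error(dictionary):
    sub, entry, truth = _annotated()
    record_metadata(sub, "citations", {"id": "c1", "title": "T"}, dictionary)
    ingest_restraint_csv(
        sub, "crosslink", fixtures.generate_crosslink_csv(entry, truth)
    )  # references dataset d1, never recorded
    sub, aggregate = submit(sub, dictionary)
    assert sub.status == WorkflowStatus.ERROR
    assert "integrity" in sub.status_history[-1].note


def test_submit_requires_annot(dictionary):
    sub = create_submission("d")
    with pytest.raises(WorkflowError):
        submit(sub, dictionary)


# -- store and persistence ---------------------------------------------------


def test_store_access_control():
    store = SubmissionStore()
    sub = create_submission("alice")
    store.add(sub)
    assert store.get(sub.entry_id, "alice").entry_id == sub.entry_id
    with pytest.raises(WorkflowError):
        store.get(sub.entry_id, "mallory")
    assert store.get(sub.entry_id, "any", role="curator") is sub
    with pytest.raises(NotFoundError):
        store.get("nope", "alice")
    assert store.list_for("mallory") == []
    assert store.list_for("x", role="admin") == [sub]


def test_save_load_roundtrip(tmp_path, dictionary):
    sub, entry, truth = _annotated()
    _record_minimum(sub, dictionary)
    save_submission(sub, str(tmp_path))
    loaded = load_submission(str(tmp_path), sub.entry_id)
    assert loaded.status == sub.status
    assert loaded.derived_facts.n_models == sub.derived_facts.n_models
    assert [f.content_hash for f in loaded.files] == [
        f.content_hash for f in sub.files
    ]
    assert {r for r in loaded.metadata_records} == {r for r in sub.metadata_records}
    assert len(loaded.status_history) == len(sub.status_history)
    # and the loaded submission is still operable
    ingest_restraint_csv(
        loaded, "crosslink", fixtures.generate_crosslink_csv(entry, truth)
    )
    loaded, _ = submit(loaded, dictionary)
    assert loaded.status == WorkflowStatus.SUBMIT
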