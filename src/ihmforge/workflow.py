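"""The data-harvesting workflow: an auditable deposition state machine.

A deposition ("entry") moves through a fixed status vocabulary:

    DRAFT  -- created, nothing processed yet
    PROC   -- an automated agent is processing uploaded files
    ERROR  -- processing or validation failed; depositor attention needed
    ANNOT  -- coordinates processed; metadata and restraints being collected
    SUBMIT -- final submission accepted; aggregate file built and compliant
    HOLD   -- curated, kept on hold for the associated publication
    REL    -- publicly released

Every status change is an append-only StatusEvent; stored files carry
SHA-256 content hashes and per-(name, role) version numbers; metadata
records are immutable versioned snapshots addressable by a persistent id.
"""

from __future__ import annotations

import copy
import csv as csv_mod
import hashlib
import io
import itertools
import json
import os
import time
import uuid
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .cif import CifDocument, parse_document, write_document
from .dictionary import DictionaryModel, Finding, FindingKind, Location, validate_row
from .model import (
    Citation,
    CrossLinkEnd,
    CrossLinkRestraint,
    Dataset,
    DbReference,
    DerivedFacts,
    DoiReference,
    Entry,
    ModelError,
    ProtocolStep,
    SeqReference,
    derive_entry_facts,
    entry_from_document,
    entry_to_document,
)


class WorkflowError(RuntimeError):
    """Invalid state transition or unmet workflow precondition."""


class NotFoundError(KeyError):
    pass


class WorkflowStatus(str, Enum):
    DRAFT = "DRAFT"
    PROC = "PROC"
    ERROR = "ERROR"
    ANNOT = "ANNOT"
    SUBMIT = "SUBMIT"
    HOLD = "HOLD"
    REL = "REL"


#: The complete transition table.  PROC, ERROR and SUBMIT are the statuses
#: the archive vocabulary names; DRAFT, ANNOT, HOLD and REL close the
#: lifecycle (creation, annotation, hold-for-publication, release).
ALLOWED_TRANSITIONS: frozenset[tuple[WorkflowStatus, WorkflowStatus]] = frozenset({
    (WorkflowStatus.DRAFT, WorkflowStatus.PROC),
    (WorkflowStatus.PROC, WorkflowStatus.ANNOT),
    (WorkflowStatus.PROC, WorkflowStatus.ERROR),
    (WorkflowStatus.ERROR, WorkflowStatus.PROC),
    (WorkflowStatus.ANNOT, WorkflowStatus.PROC),
    (WorkflowStatus.ANNOT, WorkflowStatus.SUBMIT),
    (WorkflowStatus.ANNOT, WorkflowStatus.ERROR),
    (WorkflowStatus.SUBMIT, WorkflowStatus.HOLD),
    (WorkflowStatus.SUBMIT, WorkflowStatus.REL),
    (WorkflowStatus.HOLD, WorkflowStatus.REL),
})

_clock = itertools.count(1)


def _now() -> float:
    # wall time plus a strictly monotone tiebreaker for same-instant events
    return time.time() + next(_clock) * 1e-9


@dataclass
class StoredFile:
    name: str
    role: str  # model | starting-model | restraint-csv | aggregate
    content: bytes
    content_hash: str
    size_bytes: int
    version: int
    stored_at: float

    def verify(self) -> bool:
        return hashlib.sha256(self.content).hexdigest() == self.content_hash


@dataclass
class RecordVersion:
    record_id: str
    version: int
    snapshot: dict
    created_at: float


@dataclass
class StatusEvent:
    from_status: Optional[WorkflowStatus]
    to_status: WorkflowStatus
    actor: str  # depositor | curator | system
    note: str
    at: float


@dataclass
class Submission:
    entry_id: str
    depositor_id: str
    status: WorkflowStatus
    created_at: float
    files: list[StoredFile] = field(default_factory=list)
    metadata_records: dict[str, list[RecordVersion]] = field(default_factory=dict)
    status_history: list[StatusEvent] = field(default_factory=list)
    derived_facts: Optional[DerivedFacts] = None
    restraints: list[CrossLinkRestraint] = field(default_factory=list)
    accession: Optional[str] = None
    release_date: Optional[float] = None
    compliance_report: Optional[object] = None  # ComplianceReport after submit

    def latest_file(self, role: str, name: Optional[str] = None) -> Optional[StoredFile]:
        candidates = [
            f for f in self.files
            if f.role == role and (name is None or f.name == name)
        ]
        if not candidates:
            return None
        return max(candidates, key=lambda f: (f.stored_at, f.version))

    def file_versions(self, name: str, role: str) -> list[StoredFile]:
        return sorted(
            (f for f in self.files if f.name == name and f.role == role),
            key=lambda f: f.version,
        )

    def records_for_section(self, section: str) -> list[RecordVersion]:
        """Latest version of every record in a metadata section."""
        out = []
        prefix = f"{self.entry_id}:{section}:"
        for rid, versions in self.metadata_records.items():
            if rid.startswith(prefix):
                out.append(versions[-1])
        out.sort(key=lambda rv: rv.created_at)
        return out


def transition(
    sub: Submission, to: WorkflowStatus, actor: str, note: str = ""
) -> None:
    """Apply one status change, enforcing the transition table."""
    pair = (sub.status, to)
    if pair not in ALLOWED_TRANSITIONS:
        raise WorkflowError(
            f"invalid transition {sub.status.value} -> {to.value}"
        )
    sub.status_history.append(
        StatusEvent(sub.status, to, actor, note, _now())
    )
    sub.status = to


# ---------------------------------------------------------------------------
# Operations


def create_submission(depositor_id: str) -> Submission:
    if not depositor_id:
        raise WorkflowError("depositor id must be non-empty")
    now = _now()
    sub = Submission(
        entry_id=uuid.uuid4().hex[:12],
        depositor_id=depositor_id,
        status=WorkflowStatus.DRAFT,
        created_at=now,
    )
    sub.status_history.append(
        StatusEvent(None, WorkflowStatus.DRAFT, "depositor", "created", now)
    )
    return sub


def store_file(sub: Submission, role: str, name: str, content: bytes) -> StoredFile:
    """Store (a new version of) a file; SHA-256 guards its integrity."""
    if sub.status == WorkflowStatus.REL:
        raise WorkflowError("cannot store files in a released submission")
    prior = sub.file_versions(name, role)
    f = StoredFile(
        name=name,
        role=role,
        content=bytes(content),
        content_hash=hashlib.sha256(content).hexdigest(),
        size_bytes=len(content),
        version=prior[-1].version + 1 if prior else 1,
        stored_at=_now(),
    )
    sub.files.append(f)
    return f


def read_file(
    sub: Submission, name: str, role: str, version: Optional[int] = None
) -> bytes:
    """Retrieve stored content, re-verifying the cryptographic hash."""
    versions = sub.file_versions(name, role)
    if not versions:
        raise NotFoundError(f"no file {name!r} with role {role!r}")
    if version is None:
        f = versions[-1]
    else:
        matches = [v for v in versions if v.version == version]
        if not matches:
            raise NotFoundError(f"no version {version} of {name!r}")
        f = matches[0]
    if not f.verify():
        raise WorkflowError(
            f"integrity check failed for {name!r} v{f.version}: stored hash "
            "does not match content"
        )
    return f.content


def process_model_upload(sub: Submission) -> Submission:
    """Automated agent pass over the uploaded coordinates.

    On success the derivable facts (model count, chains, sequences) are
    populated and the entry moves to ANNOT; failures move it to ERROR with
    the message recorded in the status event, and a fixed file may be
    re-uploaded and reprocessed.
    """
    model_file = sub.latest_file("model")
    if model_file is None:
        raise WorkflowError("no model file uploaded")
    transition(sub, WorkflowStatus.PROC, "system", f"processing {model_file.name}")
    try:
        doc = parse_document(model_file.content.decode("utf-8"))
        sub.derived_facts = derive_entry_facts(doc)
    except Exception as exc:  # noqa: BLE001 - failures become ERROR state
        transition(sub, WorkflowStatus.ERROR, "system", str(exc))
        return sub
    transition(
        sub, WorkflowStatus.ANNOT, "system",
        f"derived {sub.derived_facts.n_models} models, "
        f"{len(sub.derived_facts.asym_ids)} chains",
    )
    return sub


METADATA_SECTIONS = ("authors", "citations", "protocols", "seq_refs", "dataset_refs")
MANDATORY_SECTIONS = ("citations",)

_SECTION_ID_KEY = {
    "authors": "ordinal",
    "citations": "id",
    "protocols": "step_index",
    "seq_refs": "entity_id",
    "dataset_refs": "id",
}


def _validate_section_payload(
    dictionary: DictionaryModel, section: str, payload: dict
) -> list[Finding]:
    str_payload = {
        k: (None if v is None else str(v)) for k, v in payload.items()
    }
    if section == "authors":
        return validate_row(dictionary, "audit_author", str_payload)
    if section == "citations":
        sub = {k: v for k, v in str_payload.items() if k != "authors"}
        return validate_row(dictionary, "citation", sub)
    if section == "protocols":
        return validate_row(dictionary, "protocol_step", {
            k: v for k, v in str_payload.items() if k != "dataset_ids"
        })
    if section == "seq_refs":
        return validate_row(dictionary, "seq_ref", str_payload)
    if section == "dataset_refs":
        findings = validate_row(dictionary, "dataset", {
            "id": str_payload.get("id"),
            "data_type": str_payload.get("data_type"),
        })
        if str_payload.get("doi"):
            findings += [
                f for f in validate_row(dictionary, "dataset_doi_ref", {
                    "dataset_id": str_payload.get("id"),
                    "doi": str_payload.get("doi"),
                    "file_path": str_payload.get("file_path"),
                }) if f.severity == "error"
            ]
        else:
            findings += [
                f for f in validate_row(dictionary, "dataset_db_ref", {
                    "dataset_id": str_payload.get("id"),
                    "db_name": str_payload.get("db_name"),
                    "accession": str_payload.get("accession"),
                }) if f.severity == "error"
            ]
        return findings
    raise WorkflowError(f"unknown metadata section {section!r}")


def record_metadata(
    sub: Submission,
    section: str,
    payload: dict,
    dictionary: DictionaryModel,
) -> tuple[Optional[RecordVersion], list[Finding]]:
    """Store one metadata record as a new immutable version.

    The payload is validated against the section's dictionary rules
    (mandatory items, types, controlled vocabularies, bounds); a rejected
    payload leaves the store unchanged and the findings are returned.
    """
    if section not in METADATA_SECTIONS:
        raise WorkflowError(f"unknown metadata section {section!r}")
    if sub.status != WorkflowStatus.ANNOT:
        raise WorkflowError(
            f"metadata can only be recorded in ANNOT (status is {sub.status.value})"
        )
    findings = _validate_section_payload(dictionary, section, payload)
    if any(f.severity == "error" for f in findings):
        return None, findings
    id_key = _SECTION_ID_KEY[section]
    local_id = str(payload.get(id_key, "1"))
    record_id = f"{sub.entry_id}:{section}:{local_id}"
    versions = sub.metadata_records.setdefault(record_id, [])
    rv = RecordVersion(
        record_id=record_id,
        version=len(versions) + 1,
        snapshot=copy.deepcopy(payload),
        created_at=_now(),
    )
    versions.append(rv)
    return rv, findings


def get_snapshot(sub: Submission, record_id: str, version: int) -> dict:
    """Point-in-time snapshot of a metadata record (versions run 1..n)."""
    versions = sub.metadata_records.get(record_id)
    if not versions:
        raise NotFoundError(f"unknown record {record_id!r}")
    if not 1 <= version <= len(versions):
        raise NotFoundError(f"record {record_id!r} has no version {version}")
    return copy.deepcopy(versions[version - 1].snapshot)


# ---------------------------------------------------------------------------
# Restraint CSV ingestion

CROSSLINK_COLUMNS = [
    "group_id", "entity_id_1", "seq_id_1", "comp_id_1", "atom_id_1",
    "entity_id_2", "seq_id_2", "comp_id_2", "atom_id_2", "linker",
    "threshold_A", "restraint_form", "conditionality", "dataset_id",
]
DISTANCE_COLUMNS = [c for c in CROSSLINK_COLUMNS if c != "linker"]


@dataclass
class CsvFinding:
    line: int
    message: str

    def __str__(self) -> str:
        return f"line {self.line}: {self.message}"


def _sniff_delimiter(text: str) -> str:
    first = text.splitlines()[0] if text.splitlines() else ""
    return "\t" if first.count("\t") > first.count(",") else ","


def ingest_restraint_csv(
    sub: Submission, kind: str, csv_text: str
) -> tuple[list[CrossLinkRestraint], list[CsvFinding]]:
    """Parse a restraint CSV/TSV against the documented template.

    Ingestion is atomic: if any row is malformed, findings are returned and
    no restraints are stored.  Component codes are cross-checked against the
    derived entity sequence at the referenced position.
    """
    if kind not in ("crosslink", "distance"):
        raise WorkflowError(f"unknown restraint kind {kind!r}")
    if sub.status != WorkflowStatus.ANNOT:
        raise WorkflowError(
            f"restraints can only be ingested in ANNOT (status is {sub.status.value})"
        )
    expected = CROSSLINK_COLUMNS if kind == "crosslink" else DISTANCE_COLUMNS
    delim = _sniff_delimiter(csv_text)
    reader = csv_mod.reader(io.StringIO(csv_text), delimiter=delim)
    rows = list(reader)
    if not rows:
        raise WorkflowError("empty restraint file")
    header = [h.strip() for h in rows[0]]
    if header != expected:
        raise WorkflowError(
            f"unexpected {kind} template header; expected columns: "
            + ", ".join(expected)
        )
    sequences = sub.derived_facts.sequences_three if sub.derived_facts else {}

    restraints: list[CrossLinkRestraint] = []
    findings: list[CsvFinding] = []
    for lineno, raw in enumerate(rows[1:], start=2):
        if not raw or all(not c.strip() for c in raw):
            continue
        if len(raw) != len(expected):
            findings.append(CsvFinding(
                lineno, f"expected {len(expected)} fields, got {len(raw)}"
            ))
            continue
        rec = dict(zip(expected, (c.strip() for c in raw)))
        try:
            threshold = float(rec["threshold_A"])
        except ValueError:
            findings.append(CsvFinding(
                lineno, f"malformed threshold {rec['threshold_A']!r}"
            ))
            continue
        if threshold <= 0:
            findings.append(CsvFinding(
                lineno, f"threshold must be positive, got {threshold}"
            ))
            continue
        ok = True
        ends = []
        for suffix in ("1", "2"):
            try:
                seq_id = int(rec[f"seq_id_{suffix}"])
            except ValueError:
                findings.append(CsvFinding(
                    lineno, f"malformed seq_id_{suffix} {rec['seq_id_' + suffix]!r}"
                ))
                ok = False
                break
            entity_id = rec[f"entity_id_{suffix}"]
            comp_id = rec[f"comp_id_{suffix}"]
            seq = sequences.get(entity_id)
            if seq is not None:
                if not 1 <= seq_id <= len(seq):
                    findings.append(CsvFinding(
                        lineno,
                        f"seq_id_{suffix} {seq_id} outside entity {entity_id} "
                        f"sequence (length {len(seq)})",
                    ))
                    ok = False
                    break
                if comp_id and seq[seq_id - 1] != comp_id:
                    findings.append(CsvFinding(
                        lineno,
                        f"comp_id_{suffix} {comp_id!r} disagrees with entity "
                        f"{entity_id} sequence at {seq_id} "
                        f"({seq[seq_id - 1]!r})",
                    ))
                    ok = False
                    break
            ends.append(CrossLinkEnd(
                entity_ref=entity_id,
                seq_id=seq_id,
                asym_ref=None,
                atom_name=rec[f"atom_id_{suffix}"] or None,
            ))
        if not ok:
            continue
        if rec["restraint_form"] not in ("upper-bound", "lower-bound", "harmonic"):
            findings.append(CsvFinding(
                lineno, f"bad restraint_form {rec['restraint_form']!r}"
            ))
            continue
        if rec["conditionality"] not in ("any", "all"):
            findings.append(CsvFinding(
                lineno, f"bad conditionality {rec['conditionality']!r}"
            ))
            continue
        granularity = (
            "by-atom" if ends[0].atom_name and ends[1].atom_name else "by-residue"
        )
        restraints.append(CrossLinkRestraint(
            id=str(len(restraints) + 1),
            group_id=rec["group_id"],
            end1=ends[0],
            end2=ends[1],
            linker=rec.get("linker", "") or ("." if kind == "distance" else ""),
            threshold=threshold,
            restraint_form=rec["restraint_form"],
            granularity=granularity,
            conditionality=rec["conditionality"],
            dataset_ref=rec["dataset_id"] or None,
        ))
    if findings:
        return [], findings
    sub.restraints.extend(restraints)
    return restraints, []


# ---------------------------------------------------------------------------
# Final submission


def _merge_metadata(entry: Entry, sub: Submission) -> Entry:
    for rv in sub.records_for_section("authors"):
        name = str(rv.snapshot.get("name", ""))
        if name and name not in entry.authors:
            entry.authors.append(name)
    existing_cit = {c.id for c in entry.citations}
    for rv in sub.records_for_section("citations"):
        p = rv.snapshot
        cid = str(p.get("id", "1"))
        if cid in existing_cit:
            continue
        entry.citations.append(Citation(
            id=cid, title=str(p.get("title", "")),
            journal=str(p.get("journal", "") or ""),
            authors=[str(a) for a in p.get("authors", [])],
            doi=p.get("doi"), pmid=p.get("pmid"),
        ))
    existing_ds = {d.id for d in entry.datasets}
    for rv in sub.records_for_section("dataset_refs"):
        p = rv.snapshot
        did = str(p.get("id"))
        if did in existing_ds:
            continue
        if p.get("doi"):
            source = DoiReference(str(p["doi"]), p.get("file_path"))
        else:
            source = DbReference(str(p.get("db_name")), str(p.get("accession")))
        entry.datasets.append(Dataset(did, str(p.get("data_type")), source))
    existing_steps = {(s.protocol_id, s.step_index) for s in entry.protocol_steps}
    for rv in sub.records_for_section("protocols"):
        p = rv.snapshot
        key = (str(p.get("protocol_id", "1")), int(p.get("step_index", 1)))
        if key in existing_steps:
            continue
        entry.protocol_steps.append(ProtocolStep(
            protocol_id=key[0], step_index=key[1],
            method_name=str(p.get("method_name", "")),
            num_models_begin=int(p.get("num_models_begin", 0)),
            num_models_end=int(p.get("num_models_end", 0)),
            multi_scale=bool(p.get("multi_scale") in (True, "YES")),
            multi_state=bool(p.get("multi_state") in (True, "YES")),
            ordered=bool(p.get("ordered") in (True, "YES")),
            software_ref=p.get("software_id"),
            dataset_refs=[str(d) for d in p.get("dataset_ids", [])],
        ))
    for rv in sub.records_for_section("seq_refs"):
        p = rv.snapshot
        entry.seq_refs.append(SeqReference(
            entity_ref=str(p.get("entity_id")), db=str(p.get("db")),
            accession=str(p.get("accession")),
            model_begin=int(p.get("model_begin")), model_end=int(p.get("model_end")),
            ref_begin=int(p.get("ref_begin")), ref_end=int(p.get("ref_end")),
            identity_percent=float(p.get("identity_percent")),
        ))
    return entry


def _merge_restraints(entry: Entry, sub: Submission) -> Entry:
    existing = {
        (x.group_id, x.end1.entity_ref, x.end1.seq_id,
         x.end2.entity_ref, x.end2.seq_id)
        for x in entry.crosslinks
    }
    next_id = len(entry.crosslinks) + 1
    for xl in sub.restraints:
        key = (xl.group_id, xl.end1.entity_ref, xl.end1.seq_id,
               xl.end2.entity_ref, xl.end2.seq_id)
        if key in existing:
            continue
        xl.id = str(next_id)
        next_id += 1
        # resolve chain: default to the first chain of the entity
        for end in (xl.end1, xl.end2):
            if end.asym_ref is None:
                for a in entry.asyms:
                    if a.entity_ref == end.entity_ref:
                        end.asym_ref = a.id
                        break
        entry.crosslinks.append(xl)
    return entry


def submit(
    sub: Submission, dictionary: DictionaryModel
) -> tuple[Submission, Optional[CifDocument]]:
    """Final submission: aggregate everything into one complete mmCIF entry.

    The uploaded coordinates, collected metadata records and ingested
    restraints are merged into a single Entry, serialized, stored as the
    aggregate file and validated against the dictionary.  A compliant
    aggregate moves the entry to SUBMIT; a non-compliant one to ERROR with
    the compliance report attached.  An uploaded file that is already a
    complete compliant entry passes through without recorded metadata.
    """
    from .dictionary import validate_document

    if sub.status != WorkflowStatus.ANNOT:
        raise WorkflowError(
            f"submission requires ANNOT status (status is {sub.status.value})"
        )
    if sub.derived_facts is None:
        raise WorkflowError("model file has not been processed")
    model_file = sub.latest_file("model")
    if model_file is None:
        raise WorkflowError("no model file uploaded")

    doc = parse_document(model_file.content.decode("utf-8"))
    entry = entry_from_document(doc)

    for section in MANDATORY_SECTIONS:
        has_records = bool(sub.records_for_section(section))
        already_complete = bool(entry.citations) if section == "citations" else False
        if not has_records and not already_complete:
            raise WorkflowError(
                f"mandatory metadata section {section!r} is missing"
            )

    entry = _merge_metadata(entry, sub)
    entry = _merge_restraints(entry, sub)
    if not entry.title:
        entry.title = f"Integrative structure {sub.entry_id}"

    try:
        aggregate = entry_to_document(entry)
    except ModelError as exc:
        transition(
            sub, WorkflowStatus.ERROR, "system",
            f"aggregate failed referential integrity: {exc}",
        )
        return sub, None
    text = write_document(aggregate)
    store_file(sub, "aggregate", f"{sub.entry_id}.cif", text.encode("utf-8"))

    report = validate_document(aggregate, dictionary)
    sub.compliance_report = report
    if report.compliant:
        transition(sub, WorkflowStatus.SUBMIT, "depositor", "final submission")
        return sub, aggregate
    transition(
        sub, WorkflowStatus.ERROR, "system",
        f"aggregate failed dictionary validation with {len(report.errors)} errors",
    )
    return sub, aggregate


# ---------------------------------------------------------------------------
# Access control and persistence


ROLES = ("depositor", "curator", "admin")


@dataclass
class SubmissionStore:
    """A registry of submissions with the archive's access rule:
    depositors see only their own entries; curators and admins see all."""

    submissions: dict[str, Submission] = field(default_factory=dict)

    def add(self, sub: Submission) -> None:
        self.submissions[sub.entry_id] = sub

    def get(self, entry_id: str, actor_id: str, role: str = "depositor") -> Submission:
        if role not in ROLES:
            raise WorkflowError(f"unknown role {role!r}")
        sub = self.submissions.get(entry_id)
        if sub is None:
            raise NotFoundError(f"no submission {entry_id!r}")
        if role == "depositor" and sub.depositor_id != actor_id:
            raise WorkflowError(
                f"depositor {actor_id!r} cannot access entry {entry_id!r}"
            )
        return sub

    def list_for(self, actor_id: str, role: str = "depositor") -> list[Submission]:
        if role in ("curator", "admin"):
            return sorted(self.submissions.values(), key=lambda s: s.created_at)
        return sorted(
            (s for s in self.submissions.values() if s.depositor_id == actor_id),
            key=lambda s: s.created_at,
        )


def save_submission(sub: Submission, directory: str) -> None:
    """Persist a submission as a directory of text files plus a JSON index."""
    root = os.path.join(directory, sub.entry_id)
    files_dir = os.path.join(root, "files")
    os.makedirs(files_dir, exist_ok=True)
    for f in sub.files:
        path = os.path.join(files_dir, f"{f.role}__{f.name}__v{f.version}")
        with open(path, "wb") as fh:
            fh.write(f.content)
    index = {
        "entry_id": sub.entry_id,
        "depositor_id": sub.depositor_id,
        "status": sub.status.value,
        "created_at": sub.created_at,
        "accession": sub.accession,
        "files": [
            {
                "name": f.name, "role": f.role, "hash": f.content_hash,
                "size": f.size_bytes, "version": f.version,
                "stored_at": f.stored_at,
            }
            for f in sub.files
        ],
        "metadata_records": {
            rid: [
                {"version": rv.version, "snapshot": rv.snapshot,
                 "created_at": rv.created_at}
                for rv in versions
            ]
            for rid, versions in sub.metadata_records.items()
        },
        "status_history": [
            {
                "from": ev.from_status.value if ev.from_status else None,
                "to": ev.to_status.value, "actor": ev.actor,
                "note": ev.note, "at": ev.at,
            }
            for ev in sub.status_history
        ],
    }
    with open(os.path.join(root, "index.json"), "w") as fh:
        json.dump(index, fh, indent=1)


def load_submission(directory: str, entry_id: str) -> Submission:
    root = os.path.join(directory, entry_id)
    with open(os.path.join(root, "index.json")) as fh:
        index = json.load(fh)
    sub = Submission(
        entry_id=index["entry_id"],
        depositor_id=index["depositor_id"],
        status=WorkflowStatus(index["status"]),
        created_at=index["created_at"],
        accession=index.get("accession"),
    )
    for f in index["files"]:
        path = os.path.join(root, "files", f"{f['role']}__{f['name']}__v{f['version']}")
        with open(path, "rb") as fh:
            content = fh.read()
        sub.files.append(StoredFile(
            name=f["name"], role=f["role"], content=content,
            content_hash=f["hash"], size_bytes=f["size"],
            version=f["version"], stored_at=f["stored_at"],
        ))
    for rid, versions in index["metadata_records"].items():
        sub.metadata_records[rid] = [
            RecordVersion(rid, rv["version"], rv["snapshot"], rv["created_at"])
            for rv in versions
        ]
    for ev in index["status_history"]:
        sub.status_history.append(StatusEvent(
            WorkflowStatus(ev["from"]) if ev["from"] else None,
            WorkflowStatus(ev["to"]), ev["actor"], ev["note"], ev["at"],
        ))
    model_file = sub.latest_file("model")
    if model_file is not None and sub.status in (
        WorkflowStatus.ANNOT, WorkflowStatus.SUBMIT,
        WorkflowStatus.HOLD, WorkflowStatus.REL,
    ):
        try:
            sub.derived_facts = derive_entry_facts(
                parse_document(model_file.content.decode("utf-8"))
            )
        except Exception:  # noqa: BLE001 - facts are re-derivable later
            pass
    return sub
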