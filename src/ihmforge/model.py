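"""Domain model for integrative/hybrid structures.

An :class:`Entry` is the complete object graph behind one archive deposition:
molecular entities and their placed chains, multi-scale representations
(atomic regions plus coarse-grained sphere beads), models grouped into
states and ordered processes, experimental datasets and restraints, starting
models, modeling protocols and bibliographic metadata.

The category layout used for mmCIF serialization is documented in
``docs/format.md``; :func:`entry_to_document` and :func:`entry_from_document`
are mutually inverse on that layout, and unknown categories round-trip
opaquely through ``Entry.extras``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

from Bio.SeqUtils import seq1

from . import cif
from .cif import (
    INAPPLICABLE,
    CifCategory,
    CifDocument,
    CifBlock,
    CifValue,
    value_of,
)

DATA_TYPES = (
    "CX-MS", "3DEM", "2DEM", "SAS", "NMR", "X-ray", "FRET", "EPR",
    "HDX-MS", "other",
)
DB_NAMES = (
    "PDB", "BMRB", "EMDB", "EMPIAR", "SASBDB", "ProteomeXchange",
    "ModelArchive",
)
SEQ_DBS = ("UniProt", "INSDC")


class ModelError(ValueError):
    """Structural problem in an entry or its serialized form."""


# ---------------------------------------------------------------------------
# Types


@dataclass
class Entity:
    id: str
    kind: str  # polymer | nonpolymer | water
    sequence: list[str]  # 3-letter component codes
    polymer_type: Optional[str] = None  # protein | RNA | DNA | other
    description: str = ""

    def __post_init__(self):
        if self.kind == "polymer":
            if len(self.sequence) < 1:
                raise ModelError(f"entity {self.id}: empty polymer sequence")
        elif self.kind in ("nonpolymer", "water"):
            if len(self.sequence) != 1:
                raise ModelError(
                    f"entity {self.id}: non-polymer needs exactly one component"
                )
        else:
            raise ModelError(f"entity {self.id}: bad kind {self.kind!r}")


@dataclass
class AsymUnit:
    id: str
    entity_ref: str


@dataclass
class Assembly:
    id: str
    components: list[tuple[str, int, int]]  # (asym_ref, seq_begin, seq_end)


@dataclass
class RepresentationSegment:
    asym_ref: str
    seq_begin: int
    seq_end: int
    mode: str  # atomic | sphere
    granularity: str  # by-residue | by-feature
    is_rigid: bool = False
    starting_model_ref: Optional[str] = None

    def __post_init__(self):
        if self.granularity == "by-feature" and self.mode != "sphere":
            raise ModelError("by-feature granularity requires sphere mode")


@dataclass
class Representation:
    id: str
    segments: list[RepresentationSegment]


@dataclass
class Atom:
    asym_ref: str
    seq_id: int
    atom_name: str
    element: str
    x: float
    y: float
    z: float

    def __post_init__(self):
        if not all(math.isfinite(c) for c in (self.x, self.y, self.z)):
            raise ModelError("non-finite atom coordinates")


@dataclass
class Sphere:
    asym_ref: str
    seq_begin: int
    seq_end: int
    x: float
    y: float
    z: float
    radius: float
    rmsf: Optional[float] = None

    def __post_init__(self):
        if self.radius <= 0:
            raise ModelError("sphere radius must be positive")
        if self.rmsf is not None and self.rmsf < 0:
            raise ModelError("sphere rmsf must be non-negative")


@dataclass
class StructModel:
    id: str
    assembly_ref: str
    representation_ref: str
    protocol_ref: Optional[str] = None
    atoms: list[Atom] = field(default_factory=list)
    spheres: list[Sphere] = field(default_factory=list)


@dataclass
class ModelGroup:
    id: str
    model_refs: list[str]
    name: str = ""


@dataclass
class State:
    id: str
    group_refs: list[str]
    name: str = ""
    population_fraction: Optional[float] = None

    def __post_init__(self):
        if not self.group_refs:
            raise ModelError(f"state {self.id}: needs at least one model group")
        pf = self.population_fraction
        if pf is not None and not 0.0 <= pf <= 1.0:
            raise ModelError(f"state {self.id}: population fraction {pf} outside [0,1]")


@dataclass
class StateGroup:
    id: str
    state_refs: list[str]


@dataclass
class OrderedProcess:
    id: str
    ordered_by: str  # time | other
    steps: list[tuple[str, str, int]]  # (from_group_ref, to_group_ref, step_index)

    def __post_init__(self):
        indices = [s[2] for s in self.steps]
        if indices != list(range(1, len(indices) + 1)):
            raise ModelError(
                f"ordered process {self.id}: step indices must run 1..n"
            )


@dataclass
class Ensemble:
    id: str
    group_ref: str
    num_models_total: int
    num_models_deposited: int
    clustering_method: Optional[str] = None

    def __post_init__(self):
        if self.num_models_deposited < 0 or self.num_models_total < self.num_models_deposited:
            raise ModelError(f"ensemble {self.id}: bad model counts")


@dataclass
class DbReference:
    db_name: str
    accession: str

    def __post_init__(self):
        if self.db_name not in DB_NAMES:
            raise ModelError(f"unknown database {self.db_name!r}")
        if not self.accession:
            raise ModelError("empty accession")


@dataclass
class DoiReference:
    doi: str
    file_path: Optional[str] = None

    def __post_init__(self):
        if not self.doi.startswith("10."):
            raise ModelError(f"malformed DOI {self.doi!r}")


@dataclass
class Dataset:
    id: str
    data_type: str
    source: DbReference | DoiReference

    def __post_init__(self):
        if self.data_type not in DATA_TYPES:
            raise ModelError(f"unknown data type {self.data_type!r}")


@dataclass
class StartingModel:
    id: str
    asym_ref: str
    seq_begin: int
    seq_end: int
    source_type: str  # experimental | comparative | ab-initio | other
    dataset_ref: Optional[str] = None

    def __post_init__(self):
        if self.source_type not in ("experimental", "comparative", "ab-initio", "other"):
            raise ModelError(f"bad starting-model source {self.source_type!r}")


@dataclass
class CrossLinkEnd:
    entity_ref: str
    seq_id: int
    asym_ref: Optional[str] = None
    atom_name: Optional[str] = None


@dataclass
class CrossLinkRestraint:
    id: str
    group_id: str
    end1: CrossLinkEnd
    end2: CrossLinkEnd
    linker: str
    threshold: float  # Angstrom
    restraint_form: str = "upper-bound"  # upper-bound | lower-bound | harmonic
    granularity: str = "by-residue"  # by-residue | by-atom
    conditionality: str = "any"  # any | all
    dataset_ref: Optional[str] = None

    def __post_init__(self):
        if self.threshold <= 0:
            raise ModelError(f"cross-link {self.id}: threshold must be positive")
        if self.granularity == "by-atom" and not (
            self.end1.atom_name and self.end2.atom_name
        ):
            raise ModelError(
                f"cross-link {self.id}: by-atom granularity needs atom names"
            )


@dataclass
class FitMetric:
    restraint_kind: str  # 3DEM | 2DEM | SAS | EPR
    dataset_ref: str
    model_ref: str
    metric_name: str
    metric_value: float

    def __post_init__(self):
        if not math.isfinite(self.metric_value):
            raise ModelError("non-finite fit metric")


@dataclass
class ProtocolStep:
    protocol_id: str
    step_index: int
    method_name: str
    num_models_begin: int = 0
    num_models_end: int = 0
    multi_scale: bool = False
    multi_state: bool = False
    ordered: bool = False
    software_ref: Optional[str] = None
    dataset_refs: list[str] = field(default_factory=list)


@dataclass
class Software:
    id: str
    name: str
    classification: str = ""
    version: Optional[str] = None
    location: Optional[str] = None


@dataclass
class Citation:
    id: str
    title: str
    journal: str = ""
    authors: list[str] = field(default_factory=list)
    doi: Optional[str] = None
    pmid: Optional[str] = None


@dataclass
class SeqReference:
    entity_ref: str
    db: str
    accession: str
    model_begin: int
    model_end: int
    ref_begin: int
    ref_end: int
    identity_percent: float

    def __post_init__(self):
        if self.db not in SEQ_DBS:
            raise ModelError(f"unknown sequence database {self.db!r}")
        if self.model_end < self.model_begin or self.ref_end < self.ref_begin:
            raise ModelError("inverted alignment span")
        if not 0.0 <= self.identity_percent <= 100.0:
            raise ModelError("identity percent outside [0,100]")


@dataclass
class Entry:
    id: str
    title: str = ""
    summary: Optional[str] = None
    entities: list[Entity] = field(default_factory=list)
    asyms: list[AsymUnit] = field(default_factory=list)
    assemblies: list[Assembly] = field(default_factory=list)
    representations: list[Representation] = field(default_factory=list)
    models: list[StructModel] = field(default_factory=list)
    model_groups: list[ModelGroup] = field(default_factory=list)
    states: list[State] = field(default_factory=list)
    state_groups: list[StateGroup] = field(default_factory=list)
    ordered_processes: list[OrderedProcess] = field(default_factory=list)
    ensembles: list[Ensemble] = field(default_factory=list)
    datasets: list[Dataset] = field(default_factory=list)
    starting_models: list[StartingModel] = field(default_factory=list)
    crosslinks: list[CrossLinkRestraint] = field(default_factory=list)
    fit_metrics: list[FitMetric] = field(default_factory=list)
    protocol_steps: list[ProtocolStep] = field(default_factory=list)
    software: list[Software] = field(default_factory=list)
    citations: list[Citation] = field(default_factory=list)
    authors: list[str] = field(default_factory=list)
    seq_refs: list[SeqReference] = field(default_factory=list)
    extras: list[CifCategory] = field(default_factory=list)

    # convenience lookups -------------------------------------------------
    def entity(self, eid: str) -> Optional[Entity]:
        return next((e for e in self.entities if e.id == eid), None)

    def asym(self, aid: str) -> Optional[AsymUnit]:
        return next((a for a in self.asyms if a.id == aid), None)

    def entity_for_asym(self, aid: str) -> Optional[Entity]:
        a = self.asym(aid)
        return self.entity(a.entity_ref) if a else None


# ---------------------------------------------------------------------------
# Referential integrity


@dataclass
class RefFinding:
    referrer: str  # e.g. "StructModel m1"
    field: str
    target: str

    def __str__(self) -> str:
        return f"{self.referrer}: field {self.field} -> missing target {self.target!r}"


def validate_referential_integrity(entry: Entry) -> list[RefFinding]:
    """One finding per dangling reference; empty list iff closure holds."""
    findings: list[RefFinding] = []
    entity_ids = {e.id for e in entry.entities}
    asym_ids = {a.id for a in entry.asyms}
    assembly_ids = {a.id for a in entry.assemblies}
    rep_ids = {r.id for r in entry.representations}
    model_ids = {m.id for m in entry.models}
    group_ids = {g.id for g in entry.model_groups}
    state_ids = {s.id for s in entry.states}
    dataset_ids = {d.id for d in entry.datasets}
    sm_ids = {s.id for s in entry.starting_models}
    sw_ids = {s.id for s in entry.software}
    protocol_ids = {p.protocol_id for p in entry.protocol_steps}

    def check(referrer: str, fieldname: str, ref: Optional[str], pool: set[str]):
        if ref is not None and ref not in pool:
            findings.append(RefFinding(referrer, fieldname, ref))

    for a in entry.asyms:
        check(f"AsymUnit {a.id}", "entity_ref", a.entity_ref, entity_ids)
    for asm in entry.assemblies:
        for aref, _, _ in asm.components:
            check(f"Assembly {asm.id}", "asym_ref", aref, asym_ids)
    for rep in entry.representations:
        for seg in rep.segments:
            check(f"Representation {rep.id}", "asym_ref", seg.asym_ref, asym_ids)
            check(
                f"Representation {rep.id}", "starting_model_ref",
                seg.starting_model_ref, sm_ids,
            )
    for m in entry.models:
        check(f"StructModel {m.id}", "assembly_ref", m.assembly_ref, assembly_ids)
        check(f"StructModel {m.id}", "representation_ref", m.representation_ref, rep_ids)
        check(f"StructModel {m.id}", "protocol_ref", m.protocol_ref, protocol_ids)
        for at in m.atoms:
            check(f"StructModel {m.id} atom", "asym_ref", at.asym_ref, asym_ids)
        for sp in m.spheres:
            check(f"StructModel {m.id} sphere", "asym_ref", sp.asym_ref, asym_ids)
    for g in entry.model_groups:
        for mref in g.model_refs:
            check(f"ModelGroup {g.id}", "model_refs", mref, model_ids)
    for s in entry.states:
        for gref in s.group_refs:
            check(f"State {s.id}", "group_refs", gref, group_ids)
    for sg in entry.state_groups:
        for sref in sg.state_refs:
            check(f"StateGroup {sg.id}", "state_refs", sref, state_ids)
    for op in entry.ordered_processes:
        for fr, to, idx in op.steps:
            check(f"OrderedProcess {op.id} step {idx}", "from_group_ref", fr, group_ids)
            check(f"OrderedProcess {op.id} step {idx}", "to_group_ref", to, group_ids)
    for en in entry.ensembles:
        check(f"Ensemble {en.id}", "group_ref", en.group_ref, group_ids)
    for sm in entry.starting_models:
        check(f"StartingModel {sm.id}", "asym_ref", sm.asym_ref, asym_ids)
        check(f"StartingModel {sm.id}", "dataset_ref", sm.dataset_ref, dataset_ids)
    for xl in entry.crosslinks:
        for endname, end in (("end1", xl.end1), ("end2", xl.end2)):
            check(f"CrossLink {xl.id}", f"{endname}.entity_ref", end.entity_ref, entity_ids)
            check(f"CrossLink {xl.id}", f"{endname}.asym_ref", end.asym_ref, asym_ids)
        check(f"CrossLink {xl.id}", "dataset_ref", xl.dataset_ref, dataset_ids)
    for fm in entry.fit_metrics:
        check("FitMetric", "dataset_ref", fm.dataset_ref, dataset_ids)
        check("FitMetric", "model_ref", fm.model_ref, model_ids)
    for ps in entry.protocol_steps:
        check(
            f"ProtocolStep {ps.protocol_id}.{ps.step_index}", "software_ref",
            ps.software_ref, sw_ids,
        )
        for dref in ps.dataset_refs:
            check(
                f"ProtocolStep {ps.protocol_id}.{ps.step_index}", "dataset_refs",
                dref, dataset_ids,
            )
    for sr in entry.seq_refs:
        check("SeqReference", "entity_ref", sr.entity_ref, entity_ids)
    return findings


# ---------------------------------------------------------------------------
# Serialization

#: Categories owned by the layout, in write order; anything else round-trips
#: through Entry.extras.
KNOWN_CATEGORIES = (
    "struct", "audit_author", "citation", "citation_author", "software",
    "entity", "entity_seq", "struct_asym", "assembly", "representation",
    "starting_model", "dataset", "dataset_db_ref", "dataset_doi_ref",
    "model_list", "atom_site", "sphere", "model_group", "model_group_link",
    "state", "state_link", "state_group", "state_group_link",
    "ordered_process", "ordered_step", "ensemble", "crosslink",
    "angle_restraint", "torsion_restraint", "fit_metric",
    "protocol_step", "protocol_step_dataset", "seq_ref",
)


def _opt(v) -> CifValue:
    return INAPPLICABLE if v in (None, "") else value_of(v)


def _cat(block: CifBlock, name: str, items: list[str]) -> CifCategory:
    return block.add(CifCategory(name, items))


def entry_to_document(entry: Entry) -> CifDocument:
    """Serialize an entry into its (single-block) mmCIF document.

    Raises ModelError listing all findings if referential integrity fails.
    Deterministic: repeated calls yield byte-identical text.
    """
    findings = validate_referential_integrity(entry)
    if findings:
        raise ModelError(
            "entry fails referential integrity:\n"
            + "\n".join(str(f) for f in findings)
        )
    block = CifBlock(entry.id)

    c = _cat(block, "struct", ["entry_id", "title", "summary"])
    c.rows.append([value_of(entry.id), value_of(entry.title), _opt(entry.summary)])

    if entry.authors:
        c = _cat(block, "audit_author", ["ordinal", "name"])
        for i, name in enumerate(entry.authors, 1):
            c.append([i, name])

    if entry.citations:
        c = _cat(block, "citation", ["id", "title", "journal", "doi", "pmid"])
        ca = _cat(block, "citation_author", ["citation_id", "ordinal", "name"])
        for cit in entry.citations:
            c.rows.append([
                value_of(cit.id), value_of(cit.title), _opt(cit.journal),
                _opt(cit.doi), _opt(cit.pmid),
            ])
            for i, name in enumerate(cit.authors, 1):
                ca.append([cit.id, i, name])
        if not ca.rows:
            block.categories.remove(ca)

    if entry.software:
        c = _cat(block, "software", ["id", "name", "classification", "version", "location"])
        for sw in entry.software:
            c.rows.append([
                value_of(sw.id), value_of(sw.name), _opt(sw.classification),
                _opt(sw.version), _opt(sw.location),
            ])

    c = _cat(block, "entity", ["id", "kind", "polymer_type", "description"])
    cs = _cat(block, "entity_seq", ["entity_id", "num", "comp_id"])
    for e in entry.entities:
        c.rows.append([
            value_of(e.id), value_of(e.kind), _opt(e.polymer_type),
            _opt(e.description),
        ])
        for i, comp in enumerate(e.sequence, 1):
            cs.append([e.id, i, comp])

    if entry.asyms:
        c = _cat(block, "struct_asym", ["id", "entity_id"])
        for a in entry.asyms:
            c.append([a.id, a.entity_ref])

    if entry.assemblies:
        c = _cat(block, "assembly", ["id", "asym_id", "seq_begin", "seq_end"])
        for asm in entry.assemblies:
            for aref, b, e in asm.components:
                c.append([asm.id, aref, b, e])

    if entry.representations:
        c = _cat(block, "representation", [
            "id", "asym_id", "seq_begin", "seq_end", "mode", "granularity",
            "is_rigid", "starting_model_id",
        ])
        for rep in entry.representations:
            for seg in rep.segments:
                c.rows.append([
                    value_of(rep.id), value_of(seg.asym_ref),
                    value_of(seg.seq_begin), value_of(seg.seq_end),
                    value_of(seg.mode), value_of(seg.granularity),
                    value_of(seg.is_rigid), _opt(seg.starting_model_ref),
                ])

    if entry.starting_models:
        c = _cat(block, "starting_model", [
            "id", "asym_id", "seq_begin", "seq_end", "source_type", "dataset_id",
        ])
        for sm in entry.starting_models:
            c.rows.append([
                value_of(sm.id), value_of(sm.asym_ref), value_of(sm.seq_begin),
                value_of(sm.seq_end), value_of(sm.source_type), _opt(sm.dataset_ref),
            ])

    if entry.datasets:
        c = _cat(block, "dataset", ["id", "data_type"])
        cdb = _cat(block, "dataset_db_ref", ["dataset_id", "db_name", "accession"])
        cdoi = _cat(block, "dataset_doi_ref", ["dataset_id", "doi", "file_path"])
        for d in entry.datasets:
            c.append([d.id, d.data_type])
            if isinstance(d.source, DbReference):
                cdb.append([d.id, d.source.db_name, d.source.accession])
            else:
                cdoi.rows.append([
                    value_of(d.id), value_of(d.source.doi), _opt(d.source.file_path),
                ])
        for maybe_empty in (cdb, cdoi):
            if not maybe_empty.rows:
                block.categories.remove(maybe_empty)

    if entry.models:
        c = _cat(block, "model_list", ["id", "assembly_id", "representation_id", "protocol_id"])
        for m in entry.models:
            c.rows.append([
                value_of(m.id), value_of(m.assembly_ref),
                value_of(m.representation_ref), _opt(m.protocol_ref),
            ])
        atoms = _cat(block, "atom_site", [
            "model_id", "asym_id", "seq_id", "comp_id", "atom_id",
            "type_symbol", "x", "y", "z",
        ])
        spheres = _cat(block, "sphere", [
            "model_id", "asym_id", "seq_begin", "seq_end", "x", "y", "z",
            "radius", "rmsf",
        ])
        for m in entry.models:
            for at in m.atoms:
                ent = entry.entity_for_asym(at.asym_ref)
                comp = (
                    ent.sequence[at.seq_id - 1]
                    if ent and 1 <= at.seq_id <= len(ent.sequence)
                    else "UNK"
                )
                atoms.append([
                    m.id, at.asym_ref, at.seq_id, comp, at.atom_name,
                    at.element, repr(at.x), repr(at.y), repr(at.z),
                ])
            for sp in m.spheres:
                spheres.rows.append([
                    value_of(m.id), value_of(sp.asym_ref), value_of(sp.seq_begin),
                    value_of(sp.seq_end), value_of(repr(sp.x)), value_of(repr(sp.y)),
                    value_of(repr(sp.z)), value_of(repr(sp.radius)),
                    _opt(None if sp.rmsf is None else repr(sp.rmsf)),
                ])
        for maybe_empty in (atoms, spheres):
            if not maybe_empty.rows:
                block.categories.remove(maybe_empty)

    if entry.model_groups:
        c = _cat(block, "model_group", ["id", "name"])
        cl = _cat(block, "model_group_link", ["group_id", "model_id"])
        for g in entry.model_groups:
            c.rows.append([value_of(g.id), _opt(g.name)])
            for mref in g.model_refs:
                cl.append([g.id, mref])

    if entry.states:
        c = _cat(block, "state", ["id", "name", "population_fraction"])
        cl = _cat(block, "state_link", ["state_id", "group_id"])
        for s in entry.states:
            c.rows.append([
                value_of(s.id), _opt(s.name),
                _opt(None if s.population_fraction is None else repr(s.population_fraction)),
            ])
            for gref in s.group_refs:
                cl.append([s.id, gref])

    if entry.state_groups:
        c = _cat(block, "state_group", ["id"])
        cl = _cat(block, "state_group_link", ["state_group_id", "state_id"])
        for sg in entry.state_groups:
            c.append([sg.id])
            for sref in sg.state_refs:
                cl.append([sg.id, sref])

    if entry.ordered_processes:
        c = _cat(block, "ordered_process", ["id", "ordered_by"])
        cl = _cat(block, "ordered_step", [
            "process_id", "step_index", "from_group_id", "to_group_id",
        ])
        for op in entry.ordered_processes:
            c.append([op.id, op.ordered_by])
            for fr, to, idx in op.steps:
                cl.append([op.id, idx, fr, to])

    if entry.ensembles:
        c = _cat(block, "ensemble", [
            "id", "group_id", "num_models_total", "num_models_deposited",
            "clustering_method",
        ])
        for en in entry.ensembles:
            c.rows.append([
                value_of(en.id), value_of(en.group_ref),
                value_of(en.num_models_total), value_of(en.num_models_deposited),
                _opt(en.clustering_method),
            ])

    if entry.crosslinks:
        c = _cat(block, "crosslink", [
            "id", "group_id", "entity_id_1", "asym_id_1", "seq_id_1", "atom_id_1",
            "entity_id_2", "asym_id_2", "seq_id_2", "atom_id_2", "linker",
            "threshold", "restraint_form", "granularity", "conditionality",
            "dataset_id",
        ])
        for xl in entry.crosslinks:
            c.rows.append([
                value_of(xl.id), value_of(xl.group_id),
                value_of(xl.end1.entity_ref), _opt(xl.end1.asym_ref),
                value_of(xl.end1.seq_id), _opt(xl.end1.atom_name),
                value_of(xl.end2.entity_ref), _opt(xl.end2.asym_ref),
                value_of(xl.end2.seq_id), _opt(xl.end2.atom_name),
                value_of(xl.linker), value_of(repr(xl.threshold)),
                value_of(xl.restraint_form), value_of(xl.granularity),
                value_of(xl.conditionality), _opt(xl.dataset_ref),
            ])

    if entry.fit_metrics:
        c = _cat(block, "fit_metric", [
            "restraint_kind", "dataset_id", "model_id", "metric_name",
            "metric_value",
        ])
        for fm in entry.fit_metrics:
            c.append([
                fm.restraint_kind, fm.dataset_ref, fm.model_ref, fm.metric_name,
                repr(fm.metric_value),
            ])

    if entry.protocol_steps:
        c = _cat(block, "protocol_step", [
            "protocol_id", "step_index", "method_name", "num_models_begin",
            "num_models_end", "multi_scale", "multi_state", "ordered",
            "software_id",
        ])
        cl = _cat(block, "protocol_step_dataset", [
            "protocol_id", "step_index", "dataset_id",
        ])
        for ps in entry.protocol_steps:
            c.rows.append([
                value_of(ps.protocol_id), value_of(ps.step_index),
                value_of(ps.method_name), value_of(ps.num_models_begin),
                value_of(ps.num_models_end), value_of(ps.multi_scale),
                value_of(ps.multi_state), value_of(ps.ordered),
                _opt(ps.software_ref),
            ])
            for dref in ps.dataset_refs:
                cl.append([ps.protocol_id, ps.step_index, dref])
        if not cl.rows:
            block.categories.remove(cl)

    if entry.seq_refs:
        c = _cat(block, "seq_ref", [
            "entity_id", "db", "accession", "model_begin", "model_end",
            "ref_begin", "ref_end", "identity_percent",
        ])
        for sr in entry.seq_refs:
            c.append([
                sr.entity_ref, sr.db, sr.accession, sr.model_begin,
                sr.model_end, sr.ref_begin, sr.ref_end,
                repr(sr.identity_percent),
            ])

    for extra in entry.extras:
        block.add(
            CifCategory(extra.name, list(extra.item_names), [list(r) for r in extra.rows])
        )
    return CifDocument([block])


# -- deserialization helpers ------------------------------------------------


class _Loc:
    def __init__(self, block: str):
        self.block = block

    def fail(self, category: str, item: str, row: int, why: str):
        raise ModelError(
            f"block {self.block}, category {category}, item {item}, "
            f"row {row}: {why}"
        )


def _text(v: Optional[CifValue], default: str = "") -> str:
    if v is None or v.is_sentinel:
        return default
    return v.text


def _opt_text(v: Optional[CifValue]) -> Optional[str]:
    if v is None or v.is_sentinel:
        return None
    return v.text


def _int(loc: _Loc, cat: str, item: str, row: int, v: Optional[CifValue]) -> int:
    s = _opt_text(v)
    if s is None:
        loc.fail(cat, item, row, "missing integer")
    try:
        return int(s)
    except ValueError:
        loc.fail(cat, item, row, f"malformed integer {s!r}")


def _float(loc: _Loc, cat: str, item: str, row: int, v: Optional[CifValue]) -> float:
    s = _opt_text(v)
    if s is None:
        loc.fail(cat, item, row, "missing number")
    try:
        return float(s)
    except ValueError:
        loc.fail(cat, item, row, f"malformed number {s!r}")


def _opt_float(loc: _Loc, cat: str, item: str, row: int, v: Optional[CifValue]) -> Optional[float]:
    if v is None or v.is_sentinel:
        return None
    return _float(loc, cat, item, row, v)


def _bool(v: Optional[CifValue]) -> bool:
    return _text(v).upper() in ("YES", "Y", "1", "TRUE")


def entry_from_document(doc: CifDocument) -> Entry:
    """Reconstruct an Entry from its serialized form.

    Inverse of :func:`entry_to_document` on its image.  Categories outside
    the documented layout are kept in ``extras`` and re-emitted on write.
    """
    block = doc.sole_block
    loc = _Loc(block.name)

    def rows(name: str):
        cat = block.find(name)
        return list(enumerate(cat.iter_dicts())) if cat else []

    if block.find("entity") is None:
        raise ModelError("missing structurally required category 'entity'")
    if block.find("atom_site") is None and block.find("sphere") is None:
        raise ModelError("no models found (no atom_site or sphere category)")

    entry = Entry(id=block.name)
    for _, r in rows("struct"):
        entry.id = _text(r.get("entry_id"), block.name)
        entry.title = _text(r.get("title"))
        entry.summary = _opt_text(r.get("summary"))

    entry.authors = [
        _text(r.get("name")) for _, r in rows("audit_author")
    ]

    cit_authors: dict[str, list[str]] = {}
    for _, r in rows("citation_author"):
        cit_authors.setdefault(_text(r.get("citation_id")), []).append(
            _text(r.get("name"))
        )
    for _, r in rows("citation"):
        cid = _text(r.get("id"))
        entry.citations.append(Citation(
            id=cid, title=_text(r.get("title")), journal=_text(r.get("journal")),
            authors=cit_authors.get(cid, []), doi=_opt_text(r.get("doi")),
            pmid=_opt_text(r.get("pmid")),
        ))

    for _, r in rows("software"):
        entry.software.append(Software(
            id=_text(r.get("id")), name=_text(r.get("name")),
            classification=_text(r.get("classification")),
            version=_opt_text(r.get("version")), location=_opt_text(r.get("location")),
        ))

    seqs: dict[str, list[tuple[int, str]]] = {}
    for i, r in rows("entity_seq"):
        eid = _text(r.get("entity_id"))
        num = _int(loc, "entity_seq", "num", i, r.get("num"))
        seqs.setdefault(eid, []).append((num, _text(r.get("comp_id"))))
    for _, r in rows("entity"):
        eid = _text(r.get("id"))
        seq = [c for _, c in sorted(seqs.get(eid, []))]
        entry.entities.append(Entity(
            id=eid, kind=_text(r.get("kind")), sequence=seq,
            polymer_type=_opt_text(r.get("polymer_type")),
            description=_text(r.get("description")),
        ))

    for _, r in rows("struct_asym"):
        entry.asyms.append(AsymUnit(_text(r.get("id")), _text(r.get("entity_id"))))

    assemblies: dict[str, Assembly] = {}
    for i, r in rows("assembly"):
        aid = _text(r.get("id"))
        asm = assemblies.setdefault(aid, Assembly(aid, []))
        asm.components.append((
            _text(r.get("asym_id")),
            _int(loc, "assembly", "seq_begin", i, r.get("seq_begin")),
            _int(loc, "assembly", "seq_end", i, r.get("seq_end")),
        ))
    entry.assemblies = list(assemblies.values())

    reps: dict[str, Representation] = {}
    for i, r in rows("representation"):
        rid = _text(r.get("id"))
        rep = reps.setdefault(rid, Representation(rid, []))
        rep.segments.append(RepresentationSegment(
            asym_ref=_text(r.get("asym_id")),
            seq_begin=_int(loc, "representation", "seq_begin", i, r.get("seq_begin")),
            seq_end=_int(loc, "representation", "seq_end", i, r.get("seq_end")),
            mode=_text(r.get("mode")), granularity=_text(r.get("granularity")),
            is_rigid=_bool(r.get("is_rigid")),
            starting_model_ref=_opt_text(r.get("starting_model_id")),
        ))
    entry.representations = list(reps.values())

    for i, r in rows("starting_model"):
        entry.starting_models.append(StartingModel(
            id=_text(r.get("id")), asym_ref=_text(r.get("asym_id")),
            seq_begin=_int(loc, "starting_model", "seq_begin", i, r.get("seq_begin")),
            seq_end=_int(loc, "starting_model", "seq_end", i, r.get("seq_end")),
            source_type=_text(r.get("source_type")),
            dataset_ref=_opt_text(r.get("dataset_id")),
        ))

    db_refs: dict[str, DbReference] = {}
    doi_refs: dict[str, DoiReference] = {}
    for _, r in rows("dataset_db_ref"):
        db_refs[_text(r.get("dataset_id"))] = DbReference(
            _text(r.get("db_name")), _text(r.get("accession"))
        )
    for _, r in rows("dataset_doi_ref"):
        doi_refs[_text(r.get("dataset_id"))] = DoiReference(
            _text(r.get("doi")), _opt_text(r.get("file_path"))
        )
    for i, r in rows("dataset"):
        did = _text(r.get("id"))
        source = db_refs.get(did) or doi_refs.get(did)
        if source is None:
            loc.fail("dataset", "id", i, f"dataset {did} has no source reference")
        entry.datasets.append(Dataset(did, _text(r.get("data_type")), source))

    models: dict[str, StructModel] = {}
    for _, r in rows("model_list"):
        mid = _text(r.get("id"))
        models[mid] = StructModel(
            id=mid, assembly_ref=_text(r.get("assembly_id")),
            representation_ref=_text(r.get("representation_id")),
            protocol_ref=_opt_text(r.get("protocol_id")),
        )
    for i, r in rows("atom_site"):
        mid = _text(r.get("model_id"))
        m = models.setdefault(mid, StructModel(mid, "", ""))
        m.atoms.append(Atom(
            asym_ref=_text(r.get("asym_id")),
            seq_id=_int(loc, "atom_site", "seq_id", i, r.get("seq_id")),
            atom_name=_text(r.get("atom_id")), element=_text(r.get("type_symbol")),
            x=_float(loc, "atom_site", "x", i, r.get("x")),
            y=_float(loc, "atom_site", "y", i, r.get("y")),
            z=_float(loc, "atom_site", "z", i, r.get("z")),
        ))
    for i, r in rows("sphere"):
        mid = _text(r.get("model_id"))
        m = models.setdefault(mid, StructModel(mid, "", ""))
        m.spheres.append(Sphere(
            asym_ref=_text(r.get("asym_id")),
            seq_begin=_int(loc, "sphere", "seq_begin", i, r.get("seq_begin")),
            seq_end=_int(loc, "sphere", "seq_end", i, r.get("seq_end")),
            x=_float(loc, "sphere", "x", i, r.get("x")),
            y=_float(loc, "sphere", "y", i, r.get("y")),
            z=_float(loc, "sphere", "z", i, r.get("z")),
            radius=_float(loc, "sphere", "radius", i, r.get("radius")),
            rmsf=_opt_float(loc, "sphere", "rmsf", i, r.get("rmsf")),
        ))
    entry.models = list(models.values())

    groups: dict[str, ModelGroup] = {}
    for _, r in rows("model_group"):
        gid = _text(r.get("id"))
        groups[gid] = ModelGroup(gid, [], name=_text(r.get("name")))
    for _, r in rows("model_group_link"):
        groups[_text(r.get("group_id"))].model_refs.append(_text(r.get("model_id")))
    entry.model_groups = list(groups.values())

    state_links: dict[str, list[str]] = {}
    for _, r in rows("state_link"):
        state_links.setdefault(_text(r.get("state_id")), []).append(
            _text(r.get("group_id"))
        )
    for i, r in rows("state"):
        sid = _text(r.get("id"))
        entry.states.append(State(
            id=sid, group_refs=state_links.get(sid, []), name=_text(r.get("name")),
            population_fraction=_opt_float(
                loc, "state", "population_fraction", i, r.get("population_fraction")
            ),
        ))

    sg_links: dict[str, list[str]] = {}
    for _, r in rows("state_group_link"):
        sg_links.setdefault(_text(r.get("state_group_id")), []).append(
            _text(r.get("state_id"))
        )
    for _, r in rows("state_group"):
        sgid = _text(r.get("id"))
        entry.state_groups.append(StateGroup(sgid, sg_links.get(sgid, [])))

    op_steps: dict[str, list[tuple[str, str, int]]] = {}
    for i, r in rows("ordered_step"):
        op_steps.setdefault(_text(r.get("process_id")), []).append((
            _text(r.get("from_group_id")), _text(r.get("to_group_id")),
            _int(loc, "ordered_step", "step_index", i, r.get("step_index")),
        ))
    for _, r in rows("ordered_process"):
        oid = _text(r.get("id"))
        steps = sorted(op_steps.get(oid, []), key=lambda s: s[2])
        entry.ordered_processes.append(
            OrderedProcess(oid, _text(r.get("ordered_by")), steps)
        )

    for i, r in rows("ensemble"):
        entry.ensembles.append(Ensemble(
            id=_text(r.get("id")), group_ref=_text(r.get("group_id")),
            num_models_total=_int(loc, "ensemble", "num_models_total", i, r.get("num_models_total")),
            num_models_deposited=_int(loc, "ensemble", "num_models_deposited", i, r.get("num_models_deposited")),
            clustering_method=_opt_text(r.get("clustering_method")),
        ))

    for i, r in rows("crosslink"):
        entry.crosslinks.append(CrossLinkRestraint(
            id=_text(r.get("id")), group_id=_text(r.get("group_id")),
            end1=CrossLinkEnd(
                entity_ref=_text(r.get("entity_id_1")),
                seq_id=_int(loc, "crosslink", "seq_id_1", i, r.get("seq_id_1")),
                asym_ref=_opt_text(r.get("asym_id_1")),
                atom_name=_opt_text(r.get("atom_id_1")),
            ),
            end2=CrossLinkEnd(
                entity_ref=_text(r.get("entity_id_2")),
                seq_id=_int(loc, "crosslink", "seq_id_2", i, r.get("seq_id_2")),
                asym_ref=_opt_text(r.get("asym_id_2")),
                atom_name=_opt_text(r.get("atom_id_2")),
            ),
            linker=_text(r.get("linker")),
            threshold=_float(loc, "crosslink", "threshold", i, r.get("threshold")),
            restraint_form=_text(r.get("restraint_form"), "upper-bound"),
            granularity=_text(r.get("granularity"), "by-residue"),
            conditionality=_text(r.get("conditionality"), "any"),
            dataset_ref=_opt_text(r.get("dataset_id")),
        ))

    for i, r in rows("fit_metric"):
        entry.fit_metrics.append(FitMetric(
            restraint_kind=_text(r.get("restraint_kind")),
            dataset_ref=_text(r.get("dataset_id")),
            model_ref=_text(r.get("model_id")),
            metric_name=_text(r.get("metric_name")),
            metric_value=_float(loc, "fit_metric", "metric_value", i, r.get("metric_value")),
        ))

    step_datasets: dict[tuple[str, int], list[str]] = {}
    for i, r in rows("protocol_step_dataset"):
        key = (
            _text(r.get("protocol_id")),
            _int(loc, "protocol_step_dataset", "step_index", i, r.get("step_index")),
        )
        step_datasets.setdefault(key, []).append(_text(r.get("dataset_id")))
    for i, r in rows("protocol_step"):
        pid = _text(r.get("protocol_id"))
        idx = _int(loc, "protocol_step", "step_index", i, r.get("step_index"))
        entry.protocol_steps.append(ProtocolStep(
            protocol_id=pid, step_index=idx, method_name=_text(r.get("method_name")),
            num_models_begin=_int(loc, "protocol_step", "num_models_begin", i, r.get("num_models_begin")),
            num_models_end=_int(loc, "protocol_step", "num_models_end", i, r.get("num_models_end")),
            multi_scale=_bool(r.get("multi_scale")),
            multi_state=_bool(r.get("multi_state")),
            ordered=_bool(r.get("ordered")),
            software_ref=_opt_text(r.get("software_id")),
            dataset_refs=step_datasets.get((pid, idx), []),
        ))

    for i, r in rows("seq_ref"):
        entry.seq_refs.append(SeqReference(
            entity_ref=_text(r.get("entity_id")), db=_text(r.get("db")),
            accession=_text(r.get("accession")),
            model_begin=_int(loc, "seq_ref", "model_begin", i, r.get("model_begin")),
            model_end=_int(loc, "seq_ref", "model_end", i, r.get("model_end")),
            ref_begin=_int(loc, "seq_ref", "ref_begin", i, r.get("ref_begin")),
            ref_end=_int(loc, "seq_ref", "ref_end", i, r.get("ref_end")),
            identity_percent=_float(loc, "seq_ref", "identity_percent", i, r.get("identity_percent")),
        ))

    for cat in block.categories:
        if cat.name not in KNOWN_CATEGORIES:
            entry.extras.append(
                CifCategory(cat.name, list(cat.item_names), [list(r) for r in cat.rows])
            )
    return entry


# ---------------------------------------------------------------------------
# Derived facts


@dataclass
class DerivedFacts:
    n_models: int
    asym_ids: list[str]
    sequences_three: dict[str, list[str]]  # entity id -> 3-letter codes
    sequences_one: dict[str, str]  # entity id -> one-letter string
    has_atoms: bool
    has_spheres: bool
    modeled_ranges: dict[str, list[tuple[int, int]]]  # asym id -> merged ranges


def _merge_ranges(ranges: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for b, e in sorted(ranges):
        if merged and b <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((b, e))
    return merged


def derive_entry_facts(doc: CifDocument) -> DerivedFacts:
    """Facts recoverable from an uploaded coordinate file.

    Counts distinct model ids across atom and sphere records, collects the
    declared chains, and reads the polymeric sequences; when no explicit
    sequence categories are present, the sequence is reconstructed from
    per-residue atom records with gaps marked as UNK.
    """
    block = doc.sole_block
    atom_cat = block.find("atom_site")
    sphere_cat = block.find("sphere")
    if atom_cat is None and sphere_cat is None:
        raise ModelError("no models found (no coordinate categories)")

    asym_cat = block.find("struct_asym")
    declared_asyms = (
        [r["id"].as_str() for r in asym_cat.iter_dicts()] if asym_cat else []
    )
    asym_entity = (
        {r["id"].as_str(): r["entity_id"].as_str() for r in asym_cat.iter_dicts()}
        if asym_cat else {}
    )

    model_ids: set[str] = set()
    modeled: dict[str, list[tuple[int, int]]] = {}
    atom_comps: dict[str, dict[int, str]] = {}  # entity -> seq_id -> comp
    seen_asyms: set[str] = set()
    loc = _Loc(block.name)

    if atom_cat:
        for i, r in enumerate(atom_cat.iter_dicts()):
            aid = r["asym_id"].as_str()
            seen_asyms.add(aid)
            model_ids.add(r["model_id"].as_str())
            seq = _int(loc, "atom_site", "seq_id", i, r.get("seq_id"))
            modeled.setdefault(aid, []).append((seq, seq))
            comp = r.get("comp_id")
            eid = asym_entity.get(aid, aid)
            if comp is not None and not comp.is_sentinel:
                atom_comps.setdefault(eid, {})[seq] = comp.text
    if sphere_cat:
        for i, r in enumerate(sphere_cat.iter_dicts()):
            aid = r["asym_id"].as_str()
            seen_asyms.add(aid)
            model_ids.add(r["model_id"].as_str())
            b = _int(loc, "sphere", "seq_begin", i, r.get("seq_begin"))
            e = _int(loc, "sphere", "seq_end", i, r.get("seq_end"))
            modeled.setdefault(aid, []).append((b, e))

    if declared_asyms:
        undeclared = seen_asyms - set(declared_asyms)
        if undeclared:
            raise ModelError(
                "coordinate rows reference undeclared asym ids: "
                + ", ".join(sorted(undeclared))
            )
        asym_ids = declared_asyms
    else:
        asym_ids = sorted(seen_asyms)

    sequences_three: dict[str, list[str]] = {}
    seq_cat = block.find("entity_seq")
    if seq_cat:
        tmp: dict[str, list[tuple[int, str]]] = {}
        for i, r in enumerate(seq_cat.iter_dicts()):
            eid = r["entity_id"].as_str()
            num = _int(loc, "entity_seq", "num", i, r.get("num"))
            tmp.setdefault(eid, []).append((num, r["comp_id"].as_str()))
        sequences_three = {
            eid: [c for _, c in sorted(v)] for eid, v in tmp.items()
        }
    else:
        # reconstruct from per-residue records; gaps marked UNK
        for aid in asym_ids:
            eid = asym_entity.get(aid, aid)
            comps = atom_comps.get(eid, {})
            top = 0
            for b, e in modeled.get(aid, []):
                top = max(top, e)
            if top:
                sequences_three[eid] = [
                    comps.get(i, "UNK") for i in range(1, top + 1)
                ]

    sequences_one = {
        eid: "".join(seq1(c) if len(c) == 3 else "X" for c in seq)
        for eid, seq in sequences_three.items()
    }

    return DerivedFacts(
        n_models=len(model_ids),
        asym_ids=asym_ids,
        sequences_three=sequences_three,
        sequences_one=sequences_one,
        has_atoms=bool(atom_cat and atom_cat.rows),
        has_spheres=bool(sphere_cat and sphere_cat.rows),
        modeled_ranges={a: _merge_ranges(r) for a, r in modeled.items()},
    )
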