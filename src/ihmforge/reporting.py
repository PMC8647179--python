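"""Validation-report payloads, archive statistics and catalog search.

Model composition counts residues by how they are represented: a residue is
*atomic* if any atom with its sequence position exists in any model, and
*coarse* if it is covered by a sphere bead but not atomic; residues covered
by neither are unmodeled.  Cross-link satisfaction evaluates upper-bound
distance restraints against representative points (the named atom, else the
residue's CA, else the center of the covering sphere); restraints sharing a
group id form one ambiguity group whose member distances combine by the
group's conditionality (any -> minimum, all -> maximum).
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

from .model import Entry, StructModel


@dataclass
class CompositionSummary:
    n_entities: int
    n_asyms: int
    n_models: int
    n_states: int
    n_model_groups: int
    residues_total: int
    residues_atomic: int
    residues_coarse: int
    atomic_fraction: float
    n_spheres: int
    n_atoms: int

    @property
    def residues_modeled(self) -> int:
        return self.residues_atomic + self.residues_coarse

    @property
    def residues_unmodeled(self) -> int:
        return self.residues_total - self.residues_modeled

    def to_dict(self) -> dict:
        return {
            "n_entities": self.n_entities, "n_asyms": self.n_asyms,
            "n_models": self.n_models, "n_states": self.n_states,
            "n_model_groups": self.n_model_groups,
            "residues_total": self.residues_total,
            "residues_atomic": self.residues_atomic,
            "residues_coarse": self.residues_coarse,
            "residues_unmodeled": self.residues_unmodeled,
            "atomic_fraction": self.atomic_fraction,
            "n_spheres": self.n_spheres, "n_atoms": self.n_atoms,
        }


def model_composition(entry: Entry) -> CompositionSummary:
    """Composition of the modeled system across all deposited models.

    Sphere and atom site counts are distinct footprints: two models placing
    the same bead differently still contribute one sphere site.
    """
    atomic: dict[str, set[int]] = {}
    coarse_cover: dict[str, set[int]] = {}
    atom_sites: set[tuple[str, int, str]] = set()
    sphere_sites: set[tuple[str, int, int]] = set()
    for m in entry.models:
        for at in m.atoms:
            atomic.setdefault(at.asym_ref, set()).add(at.seq_id)
            atom_sites.add((at.asym_ref, at.seq_id, at.atom_name))
        for sp in m.spheres:
            cover = coarse_cover.setdefault(sp.asym_ref, set())
            cover.update(range(sp.seq_begin, sp.seq_end + 1))
            sphere_sites.add((sp.asym_ref, sp.seq_begin, sp.seq_end))

    residues_total = 0
    residues_atomic = 0
    residues_coarse = 0
    for asym in entry.asyms:
        ent = entry.entity(asym.entity_ref)
        if ent is None:
            continue
        residues_total += len(ent.sequence)
        a = atomic.get(asym.id, set())
        residues_atomic += len(a)
        residues_coarse += len(coarse_cover.get(asym.id, set()) - a)

    modeled = residues_atomic + residues_coarse
    return CompositionSummary(
        n_entities=len(entry.entities),
        n_asyms=len(entry.asyms),
        n_models=len(entry.models),
        n_states=len(entry.states),
        n_model_groups=len(entry.model_groups),
        residues_total=residues_total,
        residues_atomic=residues_atomic,
        residues_coarse=residues_coarse,
        atomic_fraction=residues_atomic / max(modeled, 1),
        n_spheres=len(sphere_sites),
        n_atoms=len(atom_sites),
    )


# ---------------------------------------------------------------------------
# Cross-link satisfaction


@dataclass
class SatisfactionPolicy:
    ensemble_rule: str = "any-model"  # any-model | all-models

    def __post_init__(self):
        if self.ensemble_rule not in ("any-model", "all-models"):
            raise ValueError(f"bad ensemble rule {self.ensemble_rule!r}")


@dataclass
class CrosslinkOutcome:
    restraint_group_id: str
    min_distance: float  # minimum group distance over models, Angstrom
    satisfied: bool
    best_model_ref: str


@dataclass
class SatisfactionSummary:
    n_groups: int
    n_satisfied: int
    n_violated: int
    threshold_policy: str

    def to_dict(self) -> dict:
        return {
            "n_groups": self.n_groups, "n_satisfied": self.n_satisfied,
            "n_violated": self.n_violated,
            "threshold_policy": self.threshold_policy,
        }


@dataclass
class SatisfactionReport:
    summary: SatisfactionSummary
    outcomes: list[CrosslinkOutcome]
    not_evaluated: list[str]  # group ids with non-upper-bound forms
    findings: list[str]  # unrepresented ends etc.


def _representative_point(
    entry: Entry, model: StructModel, asym_ref: Optional[str],
    entity_ref: str, seq_id: int, atom_name: Optional[str],
) -> Optional[tuple[float, float, float]]:
    if asym_ref is None:
        for a in entry.asyms:
            if a.entity_ref == entity_ref:
                asym_ref = a.id
                break
    if asym_ref is None:
        return None
    if atom_name:
        for at in model.atoms:
            if (at.asym_ref == asym_ref and at.seq_id == seq_id
                    and at.atom_name == atom_name):
                return (at.x, at.y, at.z)
    for at in model.atoms:
        if at.asym_ref == asym_ref and at.seq_id == seq_id and at.atom_name == "CA":
            return (at.x, at.y, at.z)
    for sp in model.spheres:
        if sp.asym_ref == asym_ref and sp.seq_begin <= seq_id <= sp.seq_end:
            return (sp.x, sp.y, sp.z)
    return None


def crosslink_satisfaction(
    entry: Entry, policy: SatisfactionPolicy | None = None
) -> SatisfactionReport:
    """Evaluate cross-link distance restraints over the deposited ensemble.

    Only upper-bound restraints are evaluated; lower-bound and harmonic
    groups are listed as not evaluated.  A group is satisfied in a model iff
    its combined distance is within the threshold, and satisfied overall per
    the ensemble rule (default: satisfied in at least one model).
    """
    policy = policy or SatisfactionPolicy()
    if not entry.models:
        raise ValueError("entry has no models")
    if not entry.crosslinks:
        raise ValueError("entry has no cross-links")

    groups: dict[str, list] = {}
    for xl in entry.crosslinks:
        groups.setdefault(xl.group_id, []).append(xl)

    outcomes: list[CrosslinkOutcome] = []
    not_evaluated: list[str] = []
    findings: list[str] = []
    n_satisfied = n_violated = 0

    for gid in groups:
        members = groups[gid]
        if any(xl.restraint_form != "upper-bound" for xl in members):
            not_evaluated.append(gid)
            continue
        conditionality = members[0].conditionality
        threshold = members[0].threshold
        per_model: list[tuple[str, float]] = []
        unrepresented = False
        for m in entry.models:
            dists = []
            for xl in members:
                p1 = _representative_point(
                    entry, m, xl.end1.asym_ref, xl.end1.entity_ref,
                    xl.end1.seq_id, xl.end1.atom_name if xl.granularity == "by-atom" else None,
                )
                p2 = _representative_point(
                    entry, m, xl.end2.asym_ref, xl.end2.entity_ref,
                    xl.end2.seq_id, xl.end2.atom_name if xl.granularity == "by-atom" else None,
                )
                if p1 is None or p2 is None:
                    which = "1" if p1 is None else "2"
                    findings.append(
                        f"unrepresented cross-link end: group {gid}, "
                        f"restraint {xl.id}, end {which}, model {m.id}"
                    )
                    unrepresented = True
                    break
                dists.append(math.dist(p1, p2))
            if unrepresented:
                break
            combined = min(dists) if conditionality == "any" else max(dists)
            per_model.append((m.id, combined))
        if unrepresented:
            continue
        satisfied_models = [mid for mid, d in per_model if d <= threshold]
        if policy.ensemble_rule == "any-model":
            satisfied = bool(satisfied_models)
        else:
            satisfied = len(satisfied_models) == len(per_model)
        best_model, min_dist = min(per_model, key=lambda t: t[1])
        outcomes.append(CrosslinkOutcome(
            restraint_group_id=gid, min_distance=min_dist,
            satisfied=satisfied, best_model_ref=best_model,
        ))
        if satisfied:
            n_satisfied += 1
        else:
            n_violated += 1

    summary = SatisfactionSummary(
        n_groups=n_satisfied + n_violated,
        n_satisfied=n_satisfied,
        n_violated=n_violated,
        threshold_policy=(
            f"upper-bound thresholds; per-group conditionality any=min/all=max; "
            f"ensemble rule {policy.ensemble_rule}"
        ),
    )
    return SatisfactionReport(summary, outcomes, not_evaluated, findings)


# ---------------------------------------------------------------------------
# Catalog, statistics and search


@dataclass
class CatalogEntry:
    accession: str
    title: str
    summary: str
    data_types: list[str] = field(default_factory=list)
    software_names: list[str] = field(default_factory=list)
    authors: list[str] = field(default_factory=list)
    multi_scale: bool = False
    multi_state: bool = False
    ordered: bool = False

    def to_dict(self) -> dict:
        return {
            "accession": self.accession, "title": self.title,
            "summary": self.summary, "data_types": self.data_types,
            "software_names": self.software_names, "authors": self.authors,
            "multi_scale": self.multi_scale, "multi_state": self.multi_state,
            "ordered": self.ordered,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CatalogEntry":
        return cls(**d)


def entry_summary(entry: Entry, accession: Optional[str] = None) -> CatalogEntry:
    """Condense a curated entry into its catalog card.

    Flags: multi-scale iff both atomic and sphere segments exist; multi-state
    iff at least two states; ordered iff an ordered process is present.
    """
    modes = {
        seg.mode for rep in entry.representations for seg in rep.segments
    }
    data_types = sorted({d.data_type for d in entry.datasets})
    software_names = sorted({s.name for s in entry.software})
    descriptions = [e.description for e in entry.entities if e.description]
    parts = [entry.title] if entry.title else []
    if descriptions:
        parts.append("Components: " + ", ".join(descriptions) + ".")
    if software_names:
        parts.append("Modeled with " + ", ".join(software_names) + ".")
    if data_types:
        parts.append("Restraints from " + ", ".join(data_types) + " data.")
    return CatalogEntry(
        accession=accession or entry.id,
        title=entry.title,
        summary=entry.summary or " ".join(parts),
        data_types=data_types,
        software_names=software_names,
        authors=list(entry.authors),
        multi_scale=("atomic" in modes and "sphere" in modes),
        multi_state=len(entry.states) >= 2,
        ordered=bool(entry.ordered_processes),
    )


@dataclass
class ArchiveStats:
    n_entries: int
    counts_by_data_type: dict[str, int]
    counts_by_software: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_entries": self.n_entries,
            "counts_by_data_type": self.counts_by_data_type,
            "counts_by_software": self.counts_by_software,
        }


def archive_statistics(catalog: list[CatalogEntry]) -> ArchiveStats:
    """Holdings statistics: per-entry distinct contribution to each bucket,
    ordered by descending count then name."""
    by_type: Counter = Counter()
    by_software: Counter = Counter()
    for e in catalog:
        for t in set(e.data_types):
            by_type[t] += 1
        for s in set(e.software_names):
            by_software[s] += 1

    def ordered(c: Counter) -> dict[str, int]:
        return dict(sorted(c.items(), key=lambda kv: (-kv[1], kv[0])))

    return ArchiveStats(
        n_entries=len(catalog),
        counts_by_data_type=ordered(by_type),
        counts_by_software=ordered(by_software),
    )


# -- query language ---------------------------------------------------------


class QueryError(ValueError):
    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class _QueryParser:
    """Terms, AND/OR/NOT (uppercase), parentheses, trailing ``*`` wildcard."""

    def __init__(self, query: str):
        self.tokens = [(m.group(0), m.start()) for m in _TOKEN_RE.finditer(query)]
        self.pos = 0
        self.length = len(query)

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, self.length)

    def next(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self):
        node = self.parse_or()
        tok, at = self.peek()
        if tok is not None:
            raise QueryError(f"unexpected token {tok!r}", at)
        return node

    def parse_or(self):
        node = self.parse_and()
        while self.peek()[0] == "OR":
            self.next()
            node = ("or", node, self.parse_and())
        return node

    def parse_and(self):
        node = self.parse_unary()
        while True:
            tok, _ = self.peek()
            if tok == "AND":
                self.next()
                node = ("and", node, self.parse_unary())
            elif tok is not None and tok not in ("OR", ")"):
                # juxtaposition is an implicit conjunction
                node = ("and", node, self.parse_unary())
            else:
                return node

    def parse_unary(self):
        tok, at = self.peek()
        if tok is None:
            raise QueryError("unexpected end of query", at)
        if tok == "NOT":
            self.next()
            return ("not", self.parse_unary())
        if tok == "(":
            self.next()
            node = self.parse_or()
            tok2, at2 = self.next()
            if tok2 != ")":
                raise QueryError("unbalanced parentheses", at)
            return node
        if tok == ")":
            raise QueryError("unbalanced parentheses", at)
        if tok in ("AND", "OR"):
            raise QueryError(f"operator {tok} needs operands", at)
        self.next()
        return ("term", tok)


def _entry_words(e: CatalogEntry) -> set[str]:
    words: set[str] = set()
    for text in (
        [e.title, e.summary, e.accession]
        + e.authors + e.software_names + e.data_types
    ):
        for w in re.findall(r"[^\s,;:.()\[\]]+", text):
            words.add(w.lower())
    return words


def _term_matches(term: str, words: set[str]) -> bool:
    t = term.lower()
    if t.endswith("*"):
        prefix = t[:-1]
        return any(w.startswith(prefix) for w in words)
    return t in words


def _eval_query(node, e: CatalogEntry, words: set[str]) -> bool:
    op = node[0]
    if op == "term":
        return _term_matches(node[1], words)
    if op == "not":
        return not _eval_query(node[1], e, words)
    if op == "and":
        return _eval_query(node[1], e, words) and _eval_query(node[2], e, words)
    if op == "or":
        return _eval_query(node[1], e, words) or _eval_query(node[2], e, words)
    raise AssertionError(op)


_FLAG_FACETS = ("multi_scale", "multi_state", "ordered")


def search_catalog(
    catalog: list[CatalogEntry],
    query: str = "",
    facets: Optional[dict] = None,
) -> list[str]:
    """Search the released-entry catalog; returns accessions in order.

    The free-text query supports Boolean operators (uppercase AND/OR/NOT),
    parentheses and trailing-``*`` wildcards, matched case-insensitively
    against title, summary, authors, software and data types.  Facets
    (data_type, software, or a multi_scale/multi_state/ordered flag)
    intersect with the query results.
    """
    facets = facets or {}
    if not query and not facets:
        raise QueryError("empty query and no facets", 0)
    tree = _QueryParser(query).parse() if query.strip() else None
    hits = []
    for e in catalog:
        if tree is not None and not _eval_query(tree, e, _entry_words(e)):
            continue
        ok = True
        for key, wanted in facets.items():
            if key in _FLAG_FACETS:
                want_bool = wanted in (True, "true", "True", "1", "yes")
                if getattr(e, key) != want_bool:
                    ok = False
            elif key == "data_type":
                if str(wanted) not in e.data_types:
                    ok = False
            elif key == "software":
                if str(wanted) not in e.software_names:
                    ok = False
            else:
                raise QueryError(f"unknown facet {key!r}", 0)
        if ok:
            hits.append(e.accession)
    return sorted(hits)
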