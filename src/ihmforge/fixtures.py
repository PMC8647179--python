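"""Deterministic synthetic-entry generator.

Builds complete integrative-structure entries with known ground truth so
that every pipeline stage is testable without downloads: multi-scale chains
(an atomic N-terminal region as CA atoms on an approximately self-avoiding
walk, the remainder as coarse-grained sphere beads), multiple models and
states, optional ordered processes, and cross-link restraints placed *by
construction* at half (satisfied) or one-and-a-half (violated) times their
threshold in every model.

Also provides the seeded-violation corruptor used to test the compliance
validator, and a random-document generator for serialization stress tests.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import cif
from .cif import CifCategory, CifDocument, UNKNOWN, value_of
from .dictionary import Finding, FindingKind, Location
from .model import (
    Assembly,
    AsymUnit,
    Atom,
    Citation,
    CrossLinkEnd,
    CrossLinkRestraint,
    Dataset,
    DbReference,
    Ensemble,
    Entity,
    Entry,
    ModelGroup,
    OrderedProcess,
    ProtocolStep,
    Representation,
    RepresentationSegment,
    Software,
    Sphere,
    State,
    StateGroup,
    StructModel,
    entry_to_document,
)

_AA3 = [
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
]


@dataclass
class ToyConfig:
    n_entities: int = 1
    chain_length: int = 100
    n_models: int = 3
    atomic_fraction: float = 0.3
    sphere_residues_per_bead: int = 10
    n_states: int = 1
    ordered: bool = False
    n_crosslinks_satisfied: int = 15
    n_crosslinks_violated: int = 5
    crosslink_threshold: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.n_entities < 1 or self.chain_length < 1 or self.n_models < 1:
            raise ValueError("n_entities, chain_length and n_models must be >= 1")
        if not 0.0 <= self.atomic_fraction <= 1.0:
            raise ValueError("atomic_fraction must be within [0, 1]")
        if self.sphere_residues_per_bead < 1:
            raise ValueError("sphere_residues_per_bead must be >= 1")
        if self.n_states < 1:
            raise ValueError("n_states must be >= 1")
        if self.n_crosslinks_satisfied < 0 or self.n_crosslinks_violated < 0:
            raise ValueError("cross-link counts must be >= 0")
        if self.crosslink_threshold <= 0:
            raise ValueError("crosslink_threshold must be positive")
        if self.ordered and self.n_states < 2:
            raise ValueError("an ordered process needs at least 2 states")

    @property
    def n_atomic(self) -> int:
        return int(math.floor(self.atomic_fraction * self.chain_length))

    @property
    def n_beads(self) -> int:
        coarse = self.chain_length - self.n_atomic
        return -(-coarse // self.sphere_residues_per_bead)  # ceil


@dataclass
class GroupSpec:
    group_id: str
    satisfied: bool
    conditionality: str  # any | all
    pairs: list[tuple[int, int, float]]  # (site_x, site_y, distance)


@dataclass
class GroundTruth:
    config: ToyConfig
    sequences_three: dict[str, list[str]]
    asym_ids: list[str]
    n_models: int
    composition: dict
    n_crosslink_groups: int
    n_satisfied: int
    n_violated: int
    group_satisfied: dict[str, bool]
    group_specs: list[GroupSpec] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "config": self.config.__dict__,
            "asym_ids": self.asym_ids,
            "n_models": self.n_models,
            "composition": self.composition,
            "n_crosslink_groups": self.n_crosslink_groups,
            "n_satisfied": self.n_satisfied,
            "n_violated": self.n_violated,
            "group_satisfied": self.group_satisfied,
        }


# ---------------------------------------------------------------------------
# Geometry helpers


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    while True:
        v = rng.normal(size=3)
        norm = float(np.linalg.norm(v))
        if norm > 1e-9:
            return v / norm


def _walk(
    rng: np.random.Generator, n: int, step: float, min_sep: float = 2.0
) -> np.ndarray:
    """Approximately self-avoiding random walk: rejection up to 100 tries,
    then the clash is accepted."""
    pts = np.zeros((n, 3))
    for i in range(1, n):
        for _ in range(100):
            cand = pts[i - 1] + step * _random_unit(rng)
            if i < 2 or np.min(np.linalg.norm(pts[: i - 1] - cand, axis=1)) >= min_sep:
                pts[i] = cand
                break
        else:
            pts[i] = cand
    return pts


# ---------------------------------------------------------------------------
# Entry generation


def generate_entry(config: ToyConfig) -> tuple[Entry, GroundTruth]:
    """Build a synthetic entry plus its ground truth; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    L = config.chain_length
    n_atomic = config.n_atomic
    bead = config.sphere_residues_per_bead

    # bead footprints (shared by all chains)
    bead_ranges: list[tuple[int, int]] = []
    pos = n_atomic + 1
    while pos <= L:
        bead_ranges.append((pos, min(pos + bead - 1, L)))
        pos += bead

    # cross-link site plan on the first chain: atomic residues then beads
    sites: list[tuple[str, int]] = [("atom", i) for i in range(1, n_atomic + 1)]
    sites += [("bead", bi) for bi in range(len(bead_ranges))]
    t = config.crosslink_threshold
    group_specs: list[GroupSpec] = []
    total_pairs = 0
    order = [(True, i) for i in range(config.n_crosslinks_satisfied)]
    order += [(False, i) for i in range(config.n_crosslinks_violated)]
    for gi, (satisfied, _) in enumerate(order, start=1):
        conditionality = str(rng.choice(["any", "all"]))
        n_pairs = int(rng.choice([1, 2], p=[0.7, 0.3]))
        if satisfied:
            # any: min must be inside; all: every pair inside
            dists = [0.5 * t] + (
                [1.5 * t] if (n_pairs == 2 and conditionality == "any") else
                [0.5 * t] * (n_pairs - 1)
            )
        else:
            dists = [1.5 * t] + (
                [0.5 * t] if (n_pairs == 2 and conditionality == "all") else
                [1.5 * t] * (n_pairs - 1)
            )
        group_specs.append(GroupSpec(f"g{gi}", satisfied, conditionality,
                                     [(0, 0, d) for d in dists]))
        total_pairs += n_pairs
    if total_pairs and total_pairs + 1 > len(sites):
        raise ValueError(
            f"too many cross-links for chain length: need {total_pairs + 1} "
            f"sites, have {len(sites)}"
        )
    perm = list(rng.permutation(len(sites)))
    y_sites = perm[:total_pairs]
    anchor_pool = perm[total_pairs:]
    yi = 0
    for spec in group_specs:
        resolved = []
        for _, _, d in spec.pairs:
            x = anchor_pool[int(rng.integers(len(anchor_pool)))]
            resolved.append((x, y_sites[yi], d))
            yi += 1
        spec.pairs = resolved

    # entities and chains
    entry = Entry(
        id=f"toy{config.seed}",
        title=f"Synthetic multi-scale complex (seed {config.seed})",
    )
    asym_ids = [chr(ord("A") + i) for i in range(config.n_entities)]
    sequences: dict[str, list[str]] = {}
    for i in range(config.n_entities):
        eid = f"e{i + 1}"
        seq = [
            _AA3[int(k)] for k in rng.integers(0, len(_AA3), size=L)
        ]
        sequences[eid] = seq
        entry.entities.append(Entity(
            id=eid, kind="polymer", sequence=seq, polymer_type="protein",
            description=f"Synthetic subunit {i + 1}",
        ))
        entry.asyms.append(AsymUnit(asym_ids[i], eid))

    entry.assemblies.append(Assembly(
        "a1", [(aid, 1, L) for aid in asym_ids]
    ))

    segments: list[RepresentationSegment] = []
    for aid in asym_ids:
        if n_atomic >= 1:
            segments.append(RepresentationSegment(
                asym_ref=aid, seq_begin=1, seq_end=n_atomic,
                mode="atomic", granularity="by-residue",
            ))
        if bead_ranges:
            segments.append(RepresentationSegment(
                asym_ref=aid, seq_begin=bead_ranges[0][0], seq_end=L,
                mode="sphere", granularity="by-feature",
            ))
    entry.representations.append(Representation("r1", segments))

    entry.software.append(Software("s1", "IMP", classification="integrative modeling"))
    entry.citations.append(Citation(
        id="c1", title="Synthetic integrative structure study",
        journal="J. Synth. Struct. Biol.", authors=["Doe, J.", "Roe, R."],
    ))
    entry.authors = ["Doe, J.", "Roe, R."]
    entry.datasets.append(Dataset(
        "d1", "CX-MS", DbReference("ProteomeXchange", "PXD000001")
    ))
    entry.datasets.append(Dataset(
        "d2", "SAS", DbReference("SASBDB", "SASDA11")
    ))
    entry.protocol_steps.append(ProtocolStep(
        protocol_id="p1", step_index=1, method_name="replica exchange sampling",
        num_models_begin=0, num_models_end=config.n_models * 100,
        multi_scale=bool(bead_ranges) and n_atomic >= 1,
        multi_state=config.n_states >= 2, ordered=config.ordered,
        software_ref="s1", dataset_refs=["d1", "d2"],
    ))

    bead_radius = 2.3 * bead ** (1.0 / 3.0)

    def site_anchor_seq(site: tuple[str, int]) -> int:
        kind, idx = site
        return idx if kind == "atom" else bead_ranges[idx][0]

    # models
    for mi in range(1, config.n_models + 1):
        model = StructModel(
            id=f"m{mi}", assembly_ref="a1", representation_ref="r1",
            protocol_ref="p1",
        )
        offsets = {aid: np.array([60.0 * i, 0.0, 0.0])
                   for i, aid in enumerate(asym_ids)}
        chain_points: dict[str, np.ndarray] = {}
        for aid in asym_ids:
            pts = _walk(rng, n_atomic + len(bead_ranges), 3.8) + offsets[aid]
            chain_points[aid] = pts
        # move cross-link partner sites on the first chain to exact distances
        first = asym_ids[0]
        pts = chain_points[first]
        for spec in group_specs:
            for x, y, d in spec.pairs:
                pts[y] = pts[x] + d * _random_unit(rng)
        for aid in asym_ids:
            pts = chain_points[aid]
            for i in range(1, n_atomic + 1):
                p = pts[i - 1]
                model.atoms.append(Atom(
                    asym_ref=aid, seq_id=i, atom_name="CA", element="C",
                    x=float(p[0]), y=float(p[1]), z=float(p[2]),
                ))
            for bi, (b, e) in enumerate(bead_ranges):
                p = pts[n_atomic + bi]
                model.spheres.append(Sphere(
                    asym_ref=aid, seq_begin=b, seq_end=e,
                    x=float(p[0]), y=float(p[1]), z=float(p[2]),
                    radius=float(bead_radius * (e - b + 1) ** (1.0 / 3.0) / bead ** (1.0 / 3.0)),
                ))
        entry.models.append(model)

    # groups, states, optional ordered process
    n_groups = config.n_states
    model_ids = [m.id for m in entry.models]
    for gi in range(n_groups):
        members = [model_ids[j] for j in range(len(model_ids)) if j % n_groups == gi]
        if not members:
            members = [model_ids[0]]
        entry.model_groups.append(
            ModelGroup(f"mg{gi + 1}", members, name=f"cluster {gi + 1}")
        )
    for si in range(config.n_states):
        entry.states.append(State(
            id=f"st{si + 1}", group_refs=[f"mg{si + 1}"],
            name=f"state {si + 1}",
            population_fraction=round(1.0 / config.n_states, 6),
        ))
    entry.state_groups.append(
        StateGroup("sg1", [s.id for s in entry.states])
    )
    if config.ordered:
        steps = [
            (f"mg{i + 1}", f"mg{i + 2}", i + 1)
            for i in range(n_groups - 1)
        ]
        entry.ordered_processes.append(OrderedProcess("op1", "time", steps))
    entry.ensembles.append(Ensemble(
        "en1", "mg1", num_models_total=config.n_models,
        num_models_deposited=config.n_models, clustering_method="centroid",
    ))

    # cross-link restraints
    first_entity = entry.entities[0].id
    first_asym = asym_ids[0]
    xid = 0
    for spec in group_specs:
        for x, y, _d in spec.pairs:
            xid += 1
            s1 = site_anchor_seq(sites[x])
            s2 = site_anchor_seq(sites[y])
            entry.crosslinks.append(CrossLinkRestraint(
                id=str(xid), group_id=spec.group_id,
                end1=CrossLinkEnd(first_entity, s1, asym_ref=first_asym),
                end2=CrossLinkEnd(first_entity, s2, asym_ref=first_asym),
                linker="DSS", threshold=t, restraint_form="upper-bound",
                granularity="by-residue", conditionality=spec.conditionality,
                dataset_ref="d1",
            ))

    truth = GroundTruth(
        config=config,
        sequences_three=sequences,
        asym_ids=asym_ids,
        n_models=config.n_models,
        composition={
            "residues_total": config.n_entities * L,
            "residues_atomic": config.n_entities * n_atomic,
            "residues_coarse": config.n_entities * (L - n_atomic),
            "n_spheres": config.n_entities * len(bead_ranges),
            "n_atoms": config.n_entities * n_atomic,
            "atomic_fraction": (
                (config.n_entities * n_atomic) / max(config.n_entities * L, 1)
            ),
        },
        n_crosslink_groups=len(group_specs),
        n_satisfied=config.n_crosslinks_satisfied,
        n_violated=config.n_crosslinks_violated,
        group_satisfied={s.group_id: s.satisfied for s in group_specs},
        group_specs=group_specs,
    )
    return entry, truth


def coordinates_only_document(entry: Entry) -> CifDocument:
    """The document a depositor's modeling software would upload: structure
    and coordinates, no bibliographic metadata or restraints."""
    keep = {
        "struct", "entity", "entity_seq", "struct_asym", "assembly",
        "representation", "model_list", "atom_site", "sphere",
    }
    doc = entry_to_document(entry)
    block = doc.sole_block
    block.categories = [c for c in block.categories if c.name in keep]
    # model_list references protocols/assemblies that stay; drop protocol col refs
    ml = block.find("model_list")
    if ml and "protocol_id" in ml.item_names:
        idx = ml.item_names.index("protocol_id")
        for row in ml.rows:
            row[idx] = cif.INAPPLICABLE
    return doc


# ---------------------------------------------------------------------------
# Restraint CSV


def generate_crosslink_csv(entry: Entry, truth: Optional[GroundTruth] = None) -> str:
    """Emit the entry's cross-links in the harvest CSV template; ingesting
    the result reproduces the restraint set."""
    from .workflow import CROSSLINK_COLUMNS

    lines = [",".join(CROSSLINK_COLUMNS)]
    for xl in entry.crosslinks:
        def comp(end: CrossLinkEnd) -> str:
            ent = entry.entity(end.entity_ref)
            return ent.sequence[end.seq_id - 1] if ent else ""

        lines.append(",".join([
            xl.group_id,
            xl.end1.entity_ref, str(xl.end1.seq_id), comp(xl.end1),
            xl.end1.atom_name or "",
            xl.end2.entity_ref, str(xl.end2.seq_id), comp(xl.end2),
            xl.end2.atom_name or "",
            xl.linker, repr(xl.threshold), xl.restraint_form,
            xl.conditionality, xl.dataset_ref or "",
        ]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Seeded violations

SEEDABLE_KINDS = (
    FindingKind.MISSING_MANDATORY_CATEGORY,
    FindingKind.MISSING_MANDATORY_ITEM,
    FindingKind.BAD_TYPE,
    FindingKind.ENUM_VIOLATION,
    FindingKind.RANGE_VIOLATION,
    FindingKind.PARENT_MISSING,
    FindingKind.DUPLICATE_KEY,
    FindingKind.UNKNOWN_CATEGORY,
    FindingKind.UNKNOWN_ITEM,
)


def seed_violation(
    doc: CifDocument, kind: FindingKind, rng_seed: int = 0
) -> tuple[CifDocument, Finding]:
    """Inject exactly one violation of the requested kind at a random
    eligible location; returns the corrupted copy and the expected finding."""
    rng = np.random.default_rng(rng_seed)
    doc = copy.deepcopy(doc)
    block = doc.sole_block

    def pick_row(cat_name: str) -> int:
        cat = block.find(cat_name)
        if cat is None or not cat.rows:
            raise ValueError(f"no eligible location: category {cat_name} empty")
        return int(rng.integers(len(cat.rows)))

    def set_cell(cat_name: str, item: str, row: int, value) -> None:
        cat = block.find(cat_name)
        cat.rows[row][cat.item_names.index(item)] = (
            value if isinstance(value, cif.CifValue) else value_of(value)
        )

    if kind == FindingKind.MISSING_MANDATORY_CATEGORY:
        cat = block.find("struct")
        if cat is None:
            raise ValueError("no eligible location: struct absent")
        block.categories.remove(cat)
        return doc, Finding(
            "error", kind, Location(block.name, "struct"),
            "mandatory category struct is absent",
        )

    if kind == FindingKind.MISSING_MANDATORY_ITEM:
        row = pick_row("citation")
        set_cell("citation", "title", row, UNKNOWN)
        return doc, Finding(
            "error", kind, Location(block.name, "citation", "title", row),
            "mandatory item left unknown (?)",
        )

    if kind == FindingKind.BAD_TYPE:
        for cat_name in ("atom_site", "sphere"):
            if block.find(cat_name) and block.find(cat_name).rows:
                row = pick_row(cat_name)
                set_cell(cat_name, "x", row, "not-a-number")
                return doc, Finding(
                    "error", kind, Location(block.name, cat_name, "x", row),
                    "value 'not-a-number' is not a valid float",
                )
        raise ValueError("no eligible location for BAD_TYPE")

    if kind == FindingKind.ENUM_VIOLATION:
        row = pick_row("entity")
        set_cell("entity", "kind", row, "blob")
        return doc, Finding(
            "error", kind, Location(block.name, "entity", "kind", row),
            "value 'blob' not in the controlled vocabulary",
        )

    if kind == FindingKind.RANGE_VIOLATION:
        for cat_name, item in (("sphere", "radius"), ("crosslink", "threshold")):
            if block.find(cat_name) and block.find(cat_name).rows:
                row = pick_row(cat_name)
                set_cell(cat_name, item, row, "-1.0")
                return doc, Finding(
                    "error", kind, Location(block.name, cat_name, item, row),
                    "value -1.0 outside allowed range",
                )
        raise ValueError("no eligible location for RANGE_VIOLATION")

    if kind == FindingKind.PARENT_MISSING:
        for cat_name in ("atom_site", "sphere"):
            if block.find(cat_name) and block.find(cat_name).rows:
                row = pick_row(cat_name)
                set_cell(cat_name, "asym_id", row, "zz9")
                return doc, Finding(
                    "error", kind, Location(block.name, cat_name, "asym_id", row),
                    "value 'zz9' has no parent in _struct_asym.id",
                )
        raise ValueError("no eligible location for PARENT_MISSING")

    if kind == FindingKind.DUPLICATE_KEY:
        cat = block.find("entity_seq")
        if cat is None or not cat.rows:
            raise ValueError("no eligible location: entity_seq empty")
        row = int(rng.integers(len(cat.rows)))
        cat.rows.append(list(cat.rows[row]))
        return doc, Finding(
            "error", kind,
            Location(block.name, "entity_seq", None, len(cat.rows) - 1),
            "duplicate key tuple",
        )

    if kind == FindingKind.UNKNOWN_CATEGORY:
        extra = CifCategory("zz_custom", ["x"])
        extra.append(["1"])
        block.add(extra)
        return doc, Finding(
            "warning", kind, Location(block.name, "zz_custom"),
            "category zz_custom not defined in dictionary",
        )

    if kind == FindingKind.UNKNOWN_ITEM:
        cat = block.find("citation")
        if cat is None or not cat.rows:
            raise ValueError("no eligible location: citation empty")
        cat.item_names.append("zz_extra")
        for r in cat.rows:
            r.append(value_of("1"))
        return doc, Finding(
            "warning", kind, Location(block.name, "citation", "zz_extra"),
            "item zz_extra not defined in dictionary",
        )

    raise ValueError(f"kind {kind} is not seedable")


# ---------------------------------------------------------------------------
# Random documents for serialization stress


_STRESS_VALUES = [
    "plain", "two words", "it's quoted", 'say "hi"', "both ' and \" marks",
    "multi\nline\nvalue", "?", ".", "", "data_block", "loop_", "_underscore",
    "#hash", "tab\there", "ends with space ", " leading", "semi; colon",
    "line1\nline2 with 'quotes'", "unicode-αβγ", "5.5", "-3", "1e-5",
]


def random_document(rng: np.random.Generator) -> CifDocument:
    """A random document exercising quoting, fencing and loop layouts."""
    doc = CifDocument()
    n_blocks = int(rng.integers(1, 3))
    for bi in range(n_blocks):
        block = cif.CifBlock(f"blk{bi}_{int(rng.integers(1000))}")
        n_cats = int(rng.integers(1, 5))
        for ci in range(n_cats):
            n_items = int(rng.integers(1, 11))
            n_rows = int(rng.integers(1, 51))
            items = [f"item{k}" for k in range(n_items)]
            cat = CifCategory(f"cat{ci}", items)
            for _ in range(n_rows):
                row = []
                for _ in range(n_items):
                    choice = int(rng.integers(len(_STRESS_VALUES) + 2))
                    if choice == len(_STRESS_VALUES):
                        row.append(cif.UNKNOWN)
                    elif choice == len(_STRESS_VALUES) + 1:
                        row.append(cif.INAPPLICABLE)
                    else:
                        row.append(value_of(_STRESS_VALUES[choice]))
                cat.rows.append(row)
            block.add(cat)
        doc.blocks.append(block)
    return doc
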