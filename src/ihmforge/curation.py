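"""Curation procedures: reference-sequence matching, small-molecule
nomenclature, accession issuance and the release step.

Reference sequences are matched with an exact semi-global dynamic-programming
aligner (the model sequence is aligned end-to-end; overhangs of the reference
cost nothing), which is deterministic and adequate at archive-entry scale.
Component nomenclature is checked against a Chemical Component Dictionary
table; a small bundled subset ships with the package and a full CCD file can
be supplied by the user.
"""

from __future__ import annotations

import json
import os
import re
import tempfile
import time
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .cif import parse_document
from .model import Entry, SeqReference


class CurationError(ValueError):
    pass


@dataclass
class CurationFinding:
    kind: str  # UNKNOWN_COMP | NAME_MISMATCH | SEQUENCE_MISMATCH
    subject: str
    message: str

    def __str__(self) -> str:
        return f"{self.kind} ({self.subject}): {self.message}"


# ---------------------------------------------------------------------------
# Sequence alignment


@dataclass
class Scoring:
    match: int = 1
    mismatch: int = -1
    gap: int = -2


@dataclass
class AlignmentResult:
    score: int
    identity_percent: float
    model_begin: int
    model_end: int
    ref_begin: int
    ref_end: int
    n_matches: int
    n_mismatches: int
    n_gaps: int


def align_to_reference(
    model_seq: str, ref_seq: str, scoring: Scoring | None = None
) -> AlignmentResult:
    """Optimal semi-global alignment of a modeled sequence to a reference.

    The model sequence is aligned in full; unaligned overhangs of the
    reference at either end are free.  Linear gap penalty.  Ties during
    traceback break deterministically: diagonal, then up (gap in the
    reference), then left (gap in the model); among equally scoring end
    positions the leftmost is taken.
    """
    if not model_seq or not ref_seq:
        raise CurationError("empty sequence")
    if not (model_seq.isalpha() and ref_seq.isalpha()):
        raise CurationError("sequences must be A-Z letters")
    sc = scoring or Scoring()
    a, b = model_seq.upper(), ref_seq.upper()
    m, n = len(a), len(b)

    # dp[i][j]: best score with a[:i] fully aligned, ref consumed up to j;
    # the unaligned ref prefix is free (row 0 all zero).
    dp = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(1, m + 1):
        dp[i][0] = i * sc.gap
    for i in range(1, m + 1):
        ai = a[i - 1]
        row, prev = dp[i], dp[i - 1]
        for j in range(1, n + 1):
            diag = prev[j - 1] + (sc.match if ai == b[j - 1] else sc.mismatch)
            up = prev[j] + sc.gap
            left = row[j - 1] + sc.gap
            row[j] = max(diag, up, left)

    end_j = 0
    best = dp[m][0]
    for j in range(n + 1):
        if dp[m][j] > best:
            best = dp[m][j]
            end_j = j
    score = best

    i, j = m, end_j
    n_matches = n_mismatches = n_gaps = 0
    while i > 0:
        if j > 0:
            diag = dp[i - 1][j - 1] + (
                sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            )
            if dp[i][j] == diag:
                if a[i - 1] == b[j - 1]:
                    n_matches += 1
                else:
                    n_mismatches += 1
                i, j = i - 1, j - 1
                continue
        if dp[i][j] == dp[i - 1][j] + sc.gap:
            n_gaps += 1
            i -= 1
            continue
        n_gaps += 1
        j -= 1

    denom = n_matches + n_mismatches + n_gaps
    return AlignmentResult(
        score=score,
        identity_percent=100.0 * n_matches / denom if denom else 0.0,
        model_begin=1,
        model_end=m,
        ref_begin=j + 1 if end_j else 1,
        ref_end=end_j,
        n_matches=n_matches,
        n_mismatches=n_mismatches,
        n_gaps=n_gaps,
    )


DEFAULT_MIN_IDENTITY = 95.0


def annotate_reference(
    entry: Entry,
    entity_ref: str,
    db: str,
    accession: str,
    result: AlignmentResult,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[CurationFinding]:
    """Attach a database reference to an entity if the alignment is good.

    A SeqReference is appended when identity >= min_identity; otherwise a
    sequence-mismatch finding is returned and the entry is left unchanged.
    """
    if entry.entity(entity_ref) is None:
        raise CurationError(f"no entity {entity_ref!r} in entry {entry.id}")
    if result.identity_percent < min_identity:
        return [CurationFinding(
            "SEQUENCE_MISMATCH", f"entity {entity_ref}",
            f"identity {result.identity_percent:.1f}% below "
            f"threshold {min_identity:.1f}% for {db}:{accession}",
        )]
    entry.seq_refs.append(SeqReference(
        entity_ref=entity_ref, db=db, accession=accession,
        model_begin=result.model_begin, model_end=result.model_end,
        ref_begin=result.ref_begin, ref_end=result.ref_end,
        identity_percent=result.identity_percent,
    ))
    return []


# ---------------------------------------------------------------------------
# Chemical components


@dataclass
class ChemCompDef:
    comp_id: str
    name: str
    formula: str = ""
    comp_type: str = ""

    def __post_init__(self):
        if not re.match(r"^[A-Z0-9]{1,5}$", self.comp_id):
            raise CurationError(f"bad component id {self.comp_id!r}")


def load_ccd(source: str) -> dict[str, ChemCompDef]:
    """Load component definitions from an mmCIF-dialect CCD file."""
    doc = parse_document(source)
    comps: dict[str, ChemCompDef] = {}
    for block in doc.blocks:
        cat = block.find("chem_comp")
        if cat is None:
            continue
        for r in cat.iter_dicts():
            cid = r["id"].as_str()
            comps[cid] = ChemCompDef(
                comp_id=cid,
                name=r["name"].as_str() if "name" in r else "",
                formula=r["formula"].as_str() if "formula" in r else "",
                comp_type=r["type"].as_str() if "type" in r else "",
            )
    return comps


def builtin_ccd() -> dict[str, ChemCompDef]:
    """The bundled mini-CCD (standard residues plus common ligands)."""
    text = resources.files("ihmforge.data").joinpath("mini_ccd.cif").read_text()
    return load_ccd(text)


def check_chem_comp(
    entry: Entry, ccd: dict[str, ChemCompDef]
) -> list[CurationFinding]:
    """Nomenclature check against a Chemical Component Dictionary.

    One UNKNOWN_COMP finding per component code absent from the CCD; one
    NAME_MISMATCH per non-polymer entity whose description differs
    (case-insensitively) from the CCD component name.
    """
    findings: list[CurationFinding] = []
    seen: set[str] = set()
    for ent in entry.entities:
        for comp in ent.sequence:
            if comp in seen:
                continue
            seen.add(comp)
            if comp not in ccd:
                findings.append(CurationFinding(
                    "UNKNOWN_COMP", comp,
                    "component not present in the Chemical Component Dictionary",
                ))
    for ent in entry.entities:
        if ent.kind == "polymer":
            continue
        comp = ent.sequence[0]
        ref = ccd.get(comp)
        if ref is None or not ent.description:
            continue
        if ent.description.strip().lower() != ref.name.strip().lower():
            findings.append(CurationFinding(
                "NAME_MISMATCH", comp,
                f"entry name {ent.description!r} differs from CCD name {ref.name!r}",
            ))
    return findings


# ---------------------------------------------------------------------------
# Accession codes

ACCESSION_PATTERN = re.compile(r"^PDBDEV_\d{8}$")


@dataclass
class AccessionRecord:
    code: str
    entry_ref: str
    issued_at: float

    def __post_init__(self):
        if not ACCESSION_PATTERN.match(self.code):
            raise CurationError(f"bad accession code {self.code!r}")


@dataclass
class AccessionRegistry:
    """Sequential accession issuer, optionally persisted as a JSON file.

    Codes are PDBDEV_ followed by a zero-padded 8-digit integer, strictly
    increasing and never reused; issuance is idempotent per entry.
    """

    path: Optional[str] = None
    next_number: int = 1
    records: dict[str, AccessionRecord] = field(default_factory=dict)

    @classmethod
    def load(cls, path: str) -> "AccessionRegistry":
        if not os.path.exists(path):
            return cls(path=path)
        with open(path) as fh:
            raw = json.load(fh)
        reg = cls(path=path, next_number=raw["next_number"])
        for entry_ref, rec in raw["records"].items():
            reg.records[entry_ref] = AccessionRecord(
                code=rec["code"], entry_ref=entry_ref, issued_at=rec["issued_at"]
            )
        return reg

    def _persist(self) -> None:
        if self.path is None:
            return
        payload = {
            "next_number": self.next_number,
            "records": {
                ref: {"code": r.code, "issued_at": r.issued_at}
                for ref, r in self.records.items()
            },
        }
        dirname = os.path.dirname(os.path.abspath(self.path))
        fd, tmp = tempfile.mkstemp(dir=dirname, suffix=".tmp")
        try:
            with os.fdopen(fd, "w") as fh:
                json.dump(payload, fh, indent=1)
            os.replace(tmp, self.path)
        except BaseException:
            if os.path.exists(tmp):
                os.unlink(tmp)
            raise


def issue_accession(registry: AccessionRegistry, entry_ref: str) -> AccessionRecord:
    """Issue (or return the already-issued) accession code for an entry.

    The registry is persisted before the in-memory counter advances, so a
    failed write consumes no code.
    """
    existing = registry.records.get(entry_ref)
    if existing is not None:
        return existing
    code = f"PDBDEV_{registry.next_number:08d}"
    record = AccessionRecord(code=code, entry_ref=entry_ref, issued_at=time.time())
    old_next, old_records = registry.next_number, dict(registry.records)
    registry.records[entry_ref] = record
    registry.next_number += 1
    try:
        registry._persist()
    except BaseException:
        registry.next_number, registry.records = old_next, old_records
        raise
    return record


# ---------------------------------------------------------------------------
# Release


def release_entry(submission, mode: str, publication_released: bool = False):
    """Move a curated submission toward public release.

    ``immediate`` releases right away; ``on_publication`` parks the entry on
    HOLD until the associated publication appears, after which it is
    released.
    """
    from . import workflow  # local import; workflow does not import curation

    if mode not in ("immediate", "on_publication"):
        raise CurationError(f"bad release mode {mode!r}")
    status = submission.status
    if status == workflow.WorkflowStatus.SUBMIT:
        if mode == "immediate":
            workflow.transition(
                submission, workflow.WorkflowStatus.REL, "curator", "released"
            )
        elif publication_released:
            workflow.transition(
                submission, workflow.WorkflowStatus.REL, "curator",
                "released with publication",
            )
        else:
            workflow.transition(
                submission, workflow.WorkflowStatus.HOLD, "curator",
                "kept on hold for publication",
            )
    elif status == workflow.WorkflowStatus.HOLD:
        if not publication_released:
            raise workflow.WorkflowError(
                "entry on hold: publication not yet released"
            )
        workflow.transition(
            submission, workflow.WorkflowStatus.REL, "curator",
            "publication released",
        )
    else:
        raise workflow.WorkflowError(
            f"cannot release from status {status.value}"
        )
    return submission
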