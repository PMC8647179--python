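"""Curation: alignment vs independent oracles, CCD checks, accessions."""

import os
import string

import numpy as np
import pytest

from ihmforge import curation, fixtures
from ihmforge.curation import (
    AccessionRegistry,
    CurationError,
    Scoring,
    align_to_reference,
    annotate_reference,
    builtin_ccd,
    check_chem_comp,
    issue_accession,
    load_ccd,
    release_entry,
)


# -- oracles -----------------------------------------------------------------


def oracle_enumerate(a: str, b: str, sc: Scoring):
    """Exhaustive enumeration of every semi-global alignment (free end gaps
    on the reference only).  Returns the best score and the set of
    (matches, mismatches, gaps) triples achieved by co-optimal alignments."""
    m, n = len(a), len(b)
    best = [None]
    stats = [set()]

    def rec(i, j, score, ma, mi, ga):
        if i == m:  # remaining reference suffix is free
            if best[0] is None or score > best[0]:
                best[0], stats[0] = score, {(ma, mi, ga)}
            elif score == best[0]:
                stats[0].add((ma, mi, ga))
            return
        if j < n:
            eq = a[i] == b[j]
            rec(i + 1, j + 1, score + (sc.match if eq else sc.mismatch),
                ma + eq, mi + (not eq), ga)
            rec(i, j + 1, score + sc.gap, ma, mi, ga + 1)
        rec(i + 1, j, score + sc.gap, ma, mi, ga + 1)

    for j0 in range(n + 1):  # free reference prefix
        rec(0, j0, 0, 0, 0, 0)
    return best[0], stats[0]


def oracle_memo(a: str, b: str, sc: Scoring) -> int:
    """Top-down memoized recursion; structurally independent of the DP."""
    from functools import lru_cache

    m, n = len(a), len(b)

    @lru_cache(maxsize=None)
    def f(i, j):
        if i == m:
            return 0  # reference suffix free
        opts = [f(i + 1, j) + sc.gap]
        if j < n:
            opts.append(f(i + 1, j + 1)
                        + (sc.match if a[i] == b[j] else sc.mismatch))
            opts.append(f(i, j + 1) + sc.gap)
        return max(opts)

    return max(f(0, j0) for j0 in range(n + 1))


def oracle_dp2(a: str, b: str, sc: Scoring) -> int:
    """Independent second implementation: row-rolling arrays."""
    m, n = len(a), len(b)
    prev = [0] * (n + 1)
    for i in range(1, m + 1):
        cur = [i * sc.gap] + [0] * n
        for j in range(1, n + 1):
            cur[j] = max(
                prev[j - 1] + (sc.match if a[i - 1] == b[j - 1] else sc.mismatch),
                prev[j] + sc.gap,
                cur[j - 1] + sc.gap,
            )
        prev = cur
    return max(prev)


def _random_seq(rng, max_len, min_len=1, alphabet="ACDEG"):
    k = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(list(alphabet), size=k))


def test_alignment_equals_exhaustive_enumeration():
    rng = np.random.default_rng(1)
    for _ in range(40):
        a = _random_seq(rng, 6)
        b = _random_seq(rng, 6)
        r = align_to_reference(a, b)
        score, stat_set = oracle_enumerate(a, b, Scoring())
        assert r.score == score, (a, b)
        assert (r.n_matches, r.n_mismatches, r.n_gaps) in stat_set, (a, b)


def test_alignment_equals_memoized_recursion_oracle():
    rng = np.random.default_rng(2)
    for _ in range(100):
        a = _random_seq(rng, 12)
        b = _random_seq(rng, 12)
        sc = Scoring(
            match=int(rng.integers(1, 4)),
            mismatch=int(rng.integers(-3, 0)),
            gap=int(rng.integers(-4, -1)),
        )
        r = align_to_reference(a, b, sc)
        assert r.score == oracle_memo(a, b, sc), (a, b, sc)
        # the reported stats must reproduce the reported score exactly
        assert (sc.match * r.n_matches + sc.mismatch * r.n_mismatches
                + sc.gap * r.n_gaps) == r.score


def test_alignment_equals_second_dp_up_to_length_50():
    rng = np.random.default_rng(3)
    letters = list(string.ascii_uppercase[:20])
    for _ in range(60):
        a = _random_seq(rng, 50, alphabet=letters)
        b = _random_seq(rng, 50, alphabet=letters)
        r = align_to_reference(a, b)
        assert r.score == oracle_dp2(a, b, Scoring()), (a, b)


def test_alignment_known_cases():
    r = align_to_reference("AAA", "GGAAAGG")
    assert (r.score, r.identity_percent) == (3, 100.0)
    assert (r.ref_begin, r.ref_end) == (3, 5)
    # identical sequences
    r2 = align_to_reference("ACDEG", "ACDEG")
    assert r2.identity_percent == 100.0 and r2.n_gaps == 0
    # model longer than reference forces gaps
    r3 = align_to_reference("AAAA", "AA")
    assert r3.n_gaps == 2
    with pytest.raises(CurationError):
        align_to_reference("", "AA")
    with pytest.raises(CurationError):
        align_to_reference("A-A", "AA")


def test_annotate_reference_threshold(toy):
    entry, _ = toy
    # align the entity's own sequence against itself: 100% identity
    from Bio.SeqUtils import seq1 as bio_seq1

    one = "".join(bio_seq1(c) for c in entry.entities[0].sequence)
    good = align_to_reference(one, one)
    findings = annotate_reference(entry, "e1", "UniProt", "P00001", good)
    assert findings == []
    assert entry.seq_refs[-1].accession == "P00001"
    assert entry.seq_refs[-1].identity_percent == 100.0
    # a poor alignment is rejected and leaves the entry unchanged
    n_before = len(entry.seq_refs)
    bad = align_to_reference(one, one[::-1])
    findings = annotate_reference(entry, "e1", "UniProt", "P00002", bad)
    assert len(findings) == 1 and findings[0].kind == "SEQUENCE_MISMATCH"
    assert len(entry.seq_refs) == n_before
    with pytest.raises(CurationError):
        annotate_reference(entry, "ghost", "UniProt", "P1", good)


# -- chemical components -----------------------------------------------------


def test_builtin_ccd_covers_standard_amino_acids():
    ccd = builtin_ccd()
    for aa in ("ALA", "GLY", "TRP", "HIS", "MET"):
        assert aa in ccd
    assert "HOH" in ccd and "ATP" in ccd


def test_check_chem_comp_flags_unknown_and_name_mismatch(toy):
    import copy

    entry, _ = copy.deepcopy(toy[0]), toy[1]
    ccd = builtin_ccd()
    assert check_chem_comp(entry, ccd) == []
    entry.entities[0].sequence[0] = "QQQ"
    entry.entities[0].sequence[5] = "QQQ"
    findings = check_chem_comp(entry, ccd)
    assert len(findings) == 1  # deduplicated per code
    assert findings[0].kind == "UNKNOWN_COMP" and findings[0].subject == "QQQ"


def test_check_chem_comp_additivity(toy):
    """Findings for a two-entity entry equal the union over single entities."""
    import copy
    from ihmforge.model import AsymUnit, Entity

    entry = copy.deepcopy(toy[0])
    entry.entities.append(Entity("e9", "nonpolymer", ["ZZZ"], description="x"))
    entry.asyms.append(AsymUnit("Z", "e9"))
    ccd = builtin_ccd()
    both = {(f.kind, f.subject) for f in check_chem_comp(entry, ccd)}
    solo = copy.deepcopy(entry)
    solo.entities = [e for e in solo.entities if e.id == "e9"]
    only_bad = {(f.kind, f.subject) for f in check_chem_comp(solo, ccd)}
    assert only_bad <= both and only_bad


def test_load_ccd_roundtrip():
    text = """\
data_ccd
loop_
_chem_comp.id
_chem_comp.name
_chem_comp.type
XYZ 'my compound' non-polymer
"""
    ccd = load_ccd(text)
    assert ccd["XYZ"].name == "my compound"


# -- accessions --------------------------------------------------------------


def test_accession_sequential_idempotent_and_persistent(tmp_path):
    path = os.fspath(tmp_path / "registry.json")
    reg = AccessionRegistry.load(path)
    codes = [issue_accession(reg, f"entry{i}").code for i in range(5)]
    assert codes == [f"PDBDEV_{i:08d}" for i in range(1, 6)]
    # idempotent per entry
    assert issue_accession(reg, "entry2").code == "PDBDEV_00000003"
    # strictly increasing, never reused, across a reload
    reg2 = AccessionRegistry.load(path)
    assert issue_accession(reg2, "entry2").code == "PDBDEV_00000003"
    assert issue_accession(reg2, "new").code == "PDBDEV_00000006"


def test_accession_rollback_on_persist_failure(tmp_path):
    path = os.fspath(tmp_path / "sub" / "registry.json")
    reg = AccessionRegistry.load(path)  # parent dir does not exist
    with pytest.raises(OSError):
        issue_accession(reg, "e1")
    assert reg.next_number == 1 and not reg.records
    os.makedirs(os.path.dirname(path))
    assert issue_accession(reg, "e1").code == "PDBDEV_00000001"


# -- release -----------------------------------------------------------------


def _submitted():
    from ihmforge import workflow

    sub = workflow.create_submission("dep")
    sub.status = workflow.WorkflowStatus.SUBMIT
    return sub


def test_release_paths():
    from ihmforge.workflow import WorkflowError, WorkflowStatus

    sub = _submitted()
    release_entry(sub, "immediate")
    assert sub.status == WorkflowStatus.REL

    sub = _submitted()
    release_entry(sub, "on_publication")
    assert sub.status == WorkflowStatus.HOLD
    with pytest.raises(WorkflowError):
        release_entry(sub, "on_publication")  # publication still pending
    release_entry(sub, "on_publication", publication_released=True)
    assert sub.status == WorkflowStatus.REL

    with pytest.raises(CurationError):
        release_entry(_submitted(), "whenever")
    from ihmforge import workflow

    draft = workflow.create_submission("dep")
    with pytest.raises(WorkflowError):
        release_entry(draft, "immediate")
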