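# Methods and conventions

This document records the precise semantics implemented by each module —
the details a user or reviewer needs to predict the toolkit's behaviour
without reading the source.

## 1. mmCIF subset (`ihmforge.cif`)

The parser accepts the STAR subset used by PDBx/mmCIF data files:

- `data_<name>` blocks containing key–value pairs
  (`_category.item value`) and `loop_` constructs.
- Values may be bare, single-quoted, double-quoted, or multi-line
  semicolon-fenced (`;` in column 1 opens and closes the fence).
- `?` is *unknown* and `.` is *inapplicable*; they are distinct sentinel
  objects (`CifValue.UNKNOWN` / `CifValue.INAPPLICABLE`) and a quoted
  `'?'` is an ordinary two-character string.
- `#` comments run to end of line; CRLF / CR line endings are normalized
  to LF before tokenization.
- `save_`, `global_` and `stop_` are rejected with a `CifSyntaxError`
  carrying a line number, as are: values before any block, loops with a
  header but no values, value counts not divisible by the column count,
  unterminated quotes or fences, and duplicate categories in one block.

The writer emits one canonical style — single-row categories as aligned
key–value pairs, multi-row categories as `loop_` — choosing the minimal
quoting for each value and refusing (CifWriteError) the one unwritable
case: a multi-line value with a line starting `;`. Key–value categories
keep the position of their first appearance, so `write ∘ parse` is
byte-stable.

**Semantic equality** (`documents_equal`) ignores style, item order
within a category and category order within a block; it distinguishes
block order, row order, and the two sentinels. The result carries a
human-readable `difference` string for the first discrepancy.

## 2. Entry model (`ihmforge.model`)

`Entry` aggregates entities, asymmetric units, assemblies, multi-scale
representations (atomic and sphere segments), models with atoms and/or
coarse spheres, model groups, states, state groups, ordered processes,
ensembles, datasets, starting models, cross-link restraints, protocols,
software, citations and sequence-reference annotations. Dataclass
`__post_init__` checks enforce local invariants (positive lengths and
radii, non-empty ids, valid enumerations); `validate_referential_integrity`
returns one finding per dangling cross-reference.

`entry_to_document` refuses to serialize an entry with integrity
failures and produces a single-block document; `entry_from_document`
reports failures as "block …, category …, item …, row …".
`derive_entry_facts` reconstructs per-entity one- and three-letter
sequences from coordinates (unseen positions become `UNK` only when
within a modeled range gap) and merges modeled residue ranges.

## 3. Dictionary validation (`ihmforge.dictionary`)

Dictionaries are themselves mmCIF documents using three categories:
`_dictionary` (title, version), `_category_def` (name, mandatory,
space-separated key items) and `_item_def` (category, name, type_code,
mandatory, comma-separated enum, range bounds with open/closed flags,
parent links, description). Type codes: `int`, `float` (scientific
notation accepted), `text`, `code` (no whitespace), `yyyy-mm-dd`.

`validate_document` reports nine finding kinds, each with an exact
`Location(block, category, item, row)`:

| kind | severity | location convention |
|---|---|---|
| MISSING_MANDATORY_CATEGORY | error | block + category |
| MISSING_MANDATORY_ITEM | error | item; row when a sentinel occupies a mandatory cell |
| BAD_TYPE | error | offending cell |
| ENUM_VIOLATION | error | offending cell |
| RANGE_VIOLATION | error | offending cell |
| PARENT_MISSING | error | referring cell |
| DUPLICATE_KEY | error | second occurrence, item = None |
| UNKNOWN_CATEGORY | warning | block + category |
| UNKNOWN_ITEM | warning | category + item |

A document is *compliant* when it has no errors (warnings allowed).
The built-in integrative-modeling dictionary
(`ihm_dictionary.builtin_dictionary`) defines 33 categories, of which
`struct`, `citation`, `entity`, `entity_seq` and `struct_asym` are
mandatory.

## 4. Sequence alignment (`ihmforge.curation`)

`align_to_reference` is a semi-global dynamic program: the model
sequence must be aligned end to end, while leading and trailing
reference residues are free (`dp[0][j] = 0`, final score is the row
maximum). Default `Scoring(match=1, mismatch=-1, gap=-2)`; interior
gaps on either sequence cost `gap`. The traceback tie-breaks
diagonal → up → left, and the invariant

```
score = match·n_matches + mismatch·n_mismatches + gap·n_gaps
```

always holds. Identity is `100·matches / (matches+mismatches+gaps)`.
`annotate_reference` attaches a database reference to an entity only
when identity meets the threshold (default 95 %); otherwise it returns
findings and leaves the entry untouched.

`check_chem_comp` reports each residue code absent from the chemical
component dictionary once, with the code as the finding subject.
`AccessionRegistry` issues sequential `PDBDEV_%08d` codes idempotently
per entry, persisting atomically with rollback on write failure.
`release_entry` implements the policy: `immediate` releases from
SUBMIT; `on_publication` holds (SUBMIT → HOLD) until the publication
trigger releases (HOLD → REL).

## 5. Deposition workflow (`ihmforge.workflow`)

Seven statuses with exactly ten allowed transitions:

```
DRAFT → PROC → ANNOT → SUBMIT → {HOLD, REL},  HOLD → REL
PROC → ERROR,  ANNOT → {PROC, ERROR},  ERROR → PROC
```

Consequences, verified by exhaustive path enumeration: every route
DRAFT → SUBMIT passes processing; every recovery from ERROR re-enters
PROC first; nothing leaves REL and nothing re-enters DRAFT.

Files are stored with version numbers and SHA-256 checksums that are
re-verified on read. `process_model_upload` parses and validates the
uploaded model; failures transition to ERROR with the reason in the
status history, and a corrected re-upload recovers through PROC.
Metadata records (`authors`, `citations`, `protocols`, `seq_refs`,
`dataset_refs`) are versioned with retrievable snapshots; `citations`
is mandatory for submission. Restraint CSVs (cross-link or distance)
are ingested atomically — any malformed line rejects the whole file
with per-line findings — with delimiter sniffing, exact header checks
and residue-code cross-checks against the uploaded model. `submit`
assembles the aggregate entry, validates it against the dictionary,
stores it, and turns referential-integrity failures into an ERROR
transition instead of an exception.

## 6. Reporting (`ihmforge.reporting`)

`model_composition` classifies every residue of every chain as atomic,
coarse or unmodeled from the representation footprint (conservation:
the three counts sum to the total). `crosslink_satisfaction` evaluates
upper-bound restraint groups: the representative point of an end is the
named atom (by-atom granularity), else the CA atom, else the covering
sphere center; group distance is the min (`any` conditionality) or max
(`all`) over member pairs; a group is satisfied under `any-model` if
some model satisfies it, under `all-models` if every model does.
Groups with non-upper-bound forms are listed in `not_evaluated`;
unrepresented ends produce findings. Catalog search supports terms,
`AND`/`OR`/`NOT` (uppercase), parentheses, trailing-`*` wildcards,
implicit conjunction, and facet filters (`multi_scale`, `multi_state`,
`ordered`, `data_type`, `software`).

## 7. Fixtures (`ihmforge.fixtures`)

`generate_entry(ToyConfig)` builds a complete, dictionary-compliant
entry plus a `GroundTruth` that is exact by construction:

- Chains are self-avoiding random walks (3.8 Å steps, 2 Å minimum
  separation). The first `atomic_fraction·L` residues are atomic (CA
  atoms), the remainder coarse beads of `sphere_residues_per_bead`.
- Cross-link groups each get fresh, disjoint sites on the first chain;
  in every model the second site of each pair is re-placed at exactly
  `0.5·threshold` (satisfied) or `1.5·threshold` (violated), so group
  satisfaction is known, not sampled. Infeasible plans (more pairs than
  sites) raise `ValueError`.
- `seed_violation(doc, kind)` injects exactly one violation of any of
  the nine finding kinds and returns the expected `Finding`, leaving
  the input untouched. `random_document(rng)` produces quoting- and
  fence-stress documents for round-trip testing.

Generation is byte-deterministic per seed, and every generated file
stays far below 64 KiB of plain text.

## 8. Acceptance

`scripts/acceptance.py --seed N --out out.json` recomputes, with
oracles reimplemented inside the script (a memoized alignment
recursion, an independent second DP, a naive per-pair/per-model
cross-link scan), the rates reported in the JSON: round-trip success,
exact violation detection, clean-entry error count, alignment and
cross-link oracle agreement, ground-truth recovery, workflow closure
and aggregate compliance, and the end-to-end deposition outcome
(100 % identity annotation, clean CCD check, first accession
`PDBDEV_00000001`, HOLD then REL). `tests/test_acceptance.py` holds the
same seven properties as pytest tests.
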