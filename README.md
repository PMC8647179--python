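# ihmforge

A self-contained toolkit for archiving **integrative / hybrid structural
models**: a strict PDBx/mmCIF reader–writer, an in-memory model of an
integrative-modeling entry, a dictionary-driven validator, curation tools
(sequence annotation, chemical-component checks, accession issuing,
release policy), a deposition workflow engine, reporting (composition,
cross-link satisfaction, archive search), and a deterministic synthetic
fixture generator with exact ground truth.

Everything is plain text in and plain text out; the only runtime
dependencies are `numpy`, `click`, and `biopython`.

## Package layout

| module | contents |
|---|---|
| `ihmforge.cif` | mmCIF (STAR subset) parser, writer, semantic equality |
| `ihmforge.model` | `Entry` object model, (de)serialization, derived facts |
| `ihmforge.dictionary` | dictionary loader, `validate_document`, `ComplianceReport` |
| `ihmforge.ihm_dictionary` | the built-in integrative-modeling dictionary |
| `ihmforge.curation` | semi-global alignment, reference annotation, CCD check, accessions, release policy |
| `ihmforge.workflow` | submissions, file store with checksums, status graph, restraint CSV ingestion, submit |
| `ihmforge.reporting` | composition, cross-link satisfaction, catalog search and statistics |
| `ihmforge.fixtures` | `ToyConfig` → entry + `GroundTruth`, violation seeding, random stress documents |
| `ihmforge.cli` | the `ihmforge` command-line tool |

## Worked example

Generate a synthetic entry (100 residues, 30 % atomic, 3 models, 20
cross-link groups of which exactly 15 are satisfied by construction):

```sh
$ ihmforge fixture --seed 7 --out fx
wrote entry.cif, crosslinks.csv, truth.json to fx

$ ihmforge validate fx/entry.cif
compliant: yes
findings: 0 (0 errors, 0 warnings)

$ ihmforge report fx/entry.cif
{
 "entry_id": "toy7",
 "title": "Synthetic multi-scale complex (seed 7)",
 "composition": {
  "n_entities": 1,
  "n_asyms": 1,
  "n_models": 3,
  ...
  "residues_total": 100,
  "residues_atomic": 30,
  "residues_coarse": 70,
  "atomic_fraction": 0.3,
  "n_spheres": 7,
  "n_atoms": 30
 },
 "crosslinks": {
  "n_groups": 20,
  "n_satisfied": 15,
  "n_violated": 5,
  ...
 }
}
```

Run a full deposition — upload, processing, restraint ingestion,
submission, release:

```sh
$ S=$(ihmforge harvest create --store st --depositor alice)
$ ihmforge harvest upload --store st --entry $S fx/entry.cif
status: ANNOT
$ ihmforge harvest restraints --store st --entry $S fx/crosslinks.csv
ingested 28 restraints
$ ihmforge harvest submit --store st --entry $S
status: SUBMIT
$ ihmforge harvest release --store st --entry $S --mode immediate
status: REL
$ ihmforge harvest status --store st --entry $S
entry     46979aa5a3e4
status    REL
depositor alice
       - -> DRAFT  [depositor] created
   DRAFT -> PROC   [system] processing entry.cif
    PROC -> ANNOT  [system] derived 3 models, 1 chains
   ANNOT -> SUBMIT [depositor] final submission
  SUBMIT -> REL    [curator] released
```

Align a model sequence against a reference (semi-global: the model is
fully aligned, reference overhangs are free):

```sh
$ ihmforge align MKTAYIAK GGMKTAYIAKGG
score     8
identity  100.00%
ref span  3..10
matches   8  mismatches 0  gaps 0
```

Other commands: `roundtrip`, `facts`, `chem-check`, `accession`,
`stats`, `search`, `random-doc`; `ihmforge COMMAND --help` for details.

## Library use

```python
from ihmforge import fixtures, cif, reporting
from ihmforge.model import entry_to_document
from ihmforge.dictionary import validate_document
from ihmforge.ihm_dictionary import builtin_dictionary

entry, truth = fixtures.generate_entry(fixtures.ToyConfig(seed=7))
doc = entry_to_document(entry)
assert validate_document(doc, builtin_dictionary()).compliant
report = reporting.crosslink_satisfaction(entry)
assert report.summary.n_satisfied == truth.n_satisfied  # exactly 15
text = cif.write_document(doc)                          # round-trips losslessly
```

## Tests and acceptance

```sh
python -m pytest -o addopts= -p no:cacheprovider -q tests/
python scripts/acceptance.py --seed 1 --out acceptance.json
```

The acceptance script recomputes the headline quantities (round-trip
success rate, exact violation-detection rate, alignment and cross-link
oracle agreement, ground-truth recovery, workflow closure, end-to-end
deposition outcome) against independently implemented oracles and writes
them as JSON. See `docs/methods.md` for the algorithms and conventions.
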