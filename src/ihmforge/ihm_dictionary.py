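"""The bundled mini-IHM dictionary.

Definitions for every category of the entry layout (see ``docs/format.md``):
data types, mandatory flags, controlled vocabularies, numeric bounds, key
items and parent-child links.  The dictionary is held here as a table and
rendered to the documented mmCIF-dialect text form on demand, so the shipped
definitions and the loader are exercised together.
"""

from __future__ import annotations

from functools import lru_cache

from .cif import CifBlock, CifCategory, CifDocument, write_document, value_of, INAPPLICABLE
from .dictionary import DictionaryModel, load_dictionary

_ENTITY_KINDS = "polymer,nonpolymer,water"
_POLYMER_TYPES = "protein,RNA,DNA,other"
_YESNO = "YES,NO"
_DATA_TYPES = "CX-MS,3DEM,2DEM,SAS,NMR,X-ray,FRET,EPR,HDX-MS,other"
_DB_NAMES = "PDB,BMRB,EMDB,EMPIAR,SASBDB,ProteomeXchange,ModelArchive"

# (name, mandatory, keys)
CATEGORIES = [
    ("struct", True, ""),
    ("audit_author", False, "ordinal"),
    ("citation", True, "id"),
    ("citation_author", False, "citation_id ordinal"),
    ("software", False, "id"),
    ("entity", True, "id"),
    ("entity_seq", True, "entity_id num"),
    ("struct_asym", True, "id"),
    ("assembly", False, "id asym_id seq_begin"),
    ("representation", False, "id asym_id seq_begin"),
    ("starting_model", False, "id"),
    ("dataset", False, "id"),
    ("dataset_db_ref", False, "dataset_id"),
    ("dataset_doi_ref", False, "dataset_id"),
    ("model_list", False, "id"),
    ("atom_site", False, "model_id asym_id seq_id atom_id"),
    ("sphere", False, "model_id asym_id seq_begin"),
    ("model_group", False, "id"),
    ("model_group_link", False, "group_id model_id"),
    ("state", False, "id"),
    ("state_link", False, "state_id group_id"),
    ("state_group", False, "id"),
    ("state_group_link", False, "state_group_id state_id"),
    ("ordered_process", False, "id"),
    ("ordered_step", False, "process_id step_index"),
    ("ensemble", False, "id"),
    ("crosslink", False, "id"),
    ("angle_restraint", False, "id"),
    ("torsion_restraint", False, "id"),
    ("fit_metric", False, ""),
    ("protocol_step", False, "protocol_id step_index"),
    ("protocol_step_dataset", False, "protocol_id step_index dataset_id"),
    ("seq_ref", False, "entity_id db accession"),
]

# (category, item, type, mandatory, enum, (min, max, min_open, max_open), (parent_cat, parent_item))
_R = None  # no range
_P = None  # no parent
ITEMS = [
    ("struct", "entry_id", "code", True, None, _R, _P),
    ("struct", "title", "text", True, None, _R, _P),
    ("struct", "summary", "text", False, None, _R, _P),

    ("audit_author", "ordinal", "int", True, None, (1, None, False, False), _P),
    ("audit_author", "name", "text", True, None, _R, _P),

    ("citation", "id", "code", True, None, _R, _P),
    ("citation", "title", "text", True, None, _R, _P),
    ("citation", "journal", "text", False, None, _R, _P),
    ("citation", "doi", "text", False, None, _R, _P),
    ("citation", "pmid", "code", False, None, _R, _P),
    ("citation_author", "citation_id", "code", True, None, _R, ("citation", "id")),
    ("citation_author", "ordinal", "int", True, None, (1, None, False, False), _P),
    ("citation_author", "name", "text", True, None, _R, _P),

    ("software", "id", "code", True, None, _R, _P),
    ("software", "name", "text", True, None, _R, _P),
    ("software", "classification", "text", False, None, _R, _P),
    ("software", "version", "text", False, None, _R, _P),
    ("software", "location", "text", False, None, _R, _P),

    ("entity", "id", "code", True, None, _R, _P),
    ("entity", "kind", "code", True, _ENTITY_KINDS, _R, _P),
    ("entity", "polymer_type", "code", False, _POLYMER_TYPES, _R, _P),
    ("entity", "description", "text", False, None, _R, _P),
    ("entity_seq", "entity_id", "code", True, None, _R, ("entity", "id")),
    ("entity_seq", "num", "int", True, None, (1, None, False, False), _P),
    ("entity_seq", "comp_id", "code", True, None, _R, _P),

    ("struct_asym", "id", "code", True, None, _R, _P),
    ("struct_asym", "entity_id", "code", True, None, _R, ("entity", "id")),

    ("assembly", "id", "code", True, None, _R, _P),
    ("assembly", "asym_id", "code", True, None, _R, ("struct_asym", "id")),
    ("assembly", "seq_begin", "int", True, None, (1, None, False, False), _P),
    ("assembly", "seq_end", "int", True, None, (1, None, False, False), _P),

    ("representation", "id", "code", True, None, _R, _P),
    ("representation", "asym_id", "code", True, None, _R, ("struct_asym", "id")),
    ("representation", "seq_begin", "int", True, None, (1, None, False, False), _P),
    ("representation", "seq_end", "int", True, None, (1, None, False, False), _P),
    ("representation", "mode", "code", True, "atomic,sphere", _R, _P),
    ("representation", "granularity", "code", True, "by-residue,by-feature", _R, _P),
    ("representation", "is_rigid", "code", True, _YESNO, _R, _P),
    ("representation", "starting_model_id", "code", False, None, _R, ("starting_model", "id")),

    ("starting_model", "id", "code", True, None, _R, _P),
    ("starting_model", "asym_id", "code", True, None, _R, ("struct_asym", "id")),
    ("starting_model", "seq_begin", "int", True, None, (1, None, False, False), _P),
    ("starting_model", "seq_end", "int", True, None, (1, None, False, False), _P),
    ("starting_model", "source_type", "code", True,
     "experimental,comparative,ab-initio,other", _R, _P),
    ("starting_model", "dataset_id", "code", False, None, _R, ("dataset", "id")),

    ("dataset", "id", "code", True, None, _R, _P),
    ("dataset", "data_type", "code", True, _DATA_TYPES, _R, _P),
    ("dataset_db_ref", "dataset_id", "code", True, None, _R, ("dataset", "id")),
    ("dataset_db_ref", "db_name", "code", True, _DB_NAMES, _R, _P),
    ("dataset_db_ref", "accession", "code", True, None, _R, _P),
    ("dataset_doi_ref", "dataset_id", "code", True, None, _R, ("dataset", "id")),
    ("dataset_doi_ref", "doi", "text", True, None, _R, _P),
    ("dataset_doi_ref", "file_path", "text", False, None, _R, _P),

    ("model_list", "id", "code", True, None, _R, _P),
    ("model_list", "assembly_id", "code", True, None, _R, ("assembly", "id")),
    ("model_list", "representation_id", "code", True, None, _R, ("representation", "id")),
    ("model_list", "protocol_id", "code", False, None, _R, ("protocol_step", "protocol_id")),

    ("atom_site", "model_id", "code", True, None, _R, ("model_list", "id")),
    ("atom_site", "asym_id", "code", True, None, _R, ("struct_asym", "id")),
    ("atom_site", "seq_id", "int", True, None, (1, None, False, False), _P),
    ("atom_site", "comp_id", "code", True, None, _R, _P),
    ("atom_site", "atom_id", "code", True, None, _R, _P),
    ("atom_site", "type_symbol", "code", True, None, _R, _P),
    ("atom_site", "x", "float", True, None, _R, _P),
    ("atom_site", "y", "float", True, None, _R, _P),
    ("atom_site", "z", "float", True, None, _R, _P),

    ("sphere", "model_id", "code", True, None, _R, ("model_list", "id")),
    ("sphere", "asym_id", "code", True, None, _R, ("struct_asym", "id")),
    ("sphere", "seq_begin", "int", True, None, (1, None, False, False), _P),
    ("sphere", "seq_end", "int", True, None, (1, None, False, False), _P),
    ("sphere", "x", "float", True, None, _R, _P),
    ("sphere", "y", "float", True, None, _R, _P),
    ("sphere", "z", "float", True, None, _R, _P),
    ("sphere", "radius", "float", True, None, (0, None, True, False), _P),
    ("sphere", "rmsf", "float", False, None, (0, None, False, False), _P),

    ("model_group", "id", "code", True, None, _R, _P),
    ("model_group", "name", "text", False, None, _R, _P),
    ("model_group_link", "group_id", "code", True, None, _R, ("model_group", "id")),
    ("model_group_link", "model_id", "code", True, None, _R, ("model_list", "id")),

    ("state", "id", "code", True, None, _R, _P),
    ("state", "name", "text", False, None, _R, _P),
    ("state", "population_fraction", "float", False, None, (0, 1, False, False), _P),
    ("state_link", "state_id", "code", True, None, _R, ("state", "id")),
    ("state_link", "group_id", "code", True, None, _R, ("model_group", "id")),
    ("state_group", "id", "code", True, None, _R, _P),
    ("state_group_link", "state_group_id", "code", True, None, _R, ("state_group", "id")),
    ("state_group_link", "state_id", "code", True, None, _R, ("state", "id")),

    ("ordered_process", "id", "code", True, None, _R, _P),
    ("ordered_process", "ordered_by", "code", True, "time,other", _R, _P),
    ("ordered_step", "process_id", "code", True, None, _R, ("ordered_process", "id")),
    ("ordered_step", "step_index", "int", True, None, (1, None, False, False), _P),
    ("ordered_step", "from_group_id", "code", True, None, _R, ("model_group", "id")),
    ("ordered_step", "to_group_id", "code", True, None, _R, ("model_group", "id")),

    ("ensemble", "id", "code", True, None, _R, _P),
    ("ensemble", "group_id", "code", True, None, _R, ("model_group", "id")),
    ("ensemble", "num_models_total", "int", True, None, (0, None, False, False), _P),
    ("ensemble", "num_models_deposited", "int", True, None, (0, None, False, False), _P),
    ("ensemble", "clustering_method", "text", False, None, _R, _P),

    ("crosslink", "id", "code", True, None, _R, _P),
    ("crosslink", "group_id", "code", True, None, _R, _P),
    ("crosslink", "entity_id_1", "code", True, None, _R, ("entity", "id")),
    ("crosslink", "asym_id_1", "code", False, None, _R, ("struct_asym", "id")),
    ("crosslink", "seq_id_1", "int", True, None, (1, None, False, False), _P),
    ("crosslink", "atom_id_1", "code", False, None, _R, _P),
    ("crosslink", "entity_id_2", "code", True, None, _R, ("entity", "id")),
    ("crosslink", "asym_id_2", "code", False, None, _R, ("struct_asym", "id")),
    ("crosslink", "seq_id_2", "int", True, None, (1, None, False, False), _P),
    ("crosslink", "atom_id_2", "code", False, None, _R, _P),
    ("crosslink", "linker", "code", True, None, _R, _P),
    ("crosslink", "threshold", "float", True, None, (0, None, True, False), _P),
    ("crosslink", "restraint_form", "code", True,
     "upper-bound,lower-bound,harmonic", _R, _P),
    ("crosslink", "granularity", "code", True, "by-residue,by-atom", _R, _P),
    ("crosslink", "conditionality", "code", True, "any,all", _R, _P),
    ("crosslink", "dataset_id", "code", False, None, _R, ("dataset", "id")),

    # declared for completeness; no computational support (distance-type only)
    ("angle_restraint", "id", "code", True, None, _R, _P),
    ("angle_restraint", "dataset_id", "code", False, None, _R, ("dataset", "id")),
    ("angle_restraint", "angle_target", "float", False, None, _R, _P),
    ("torsion_restraint", "id", "code", True, None, _R, _P),
    ("torsion_restraint", "dataset_id", "code", False, None, _R, ("dataset", "id")),
    ("torsion_restraint", "torsion_target", "float", False, None, _R, _P),

    ("fit_metric", "restraint_kind", "code", True, "3DEM,2DEM,SAS,EPR", _R, _P),
    ("fit_metric", "dataset_id", "code", True, None, _R, ("dataset", "id")),
    ("fit_metric", "model_id", "code", True, None, _R, ("model_list", "id")),
    ("fit_metric", "metric_name", "text", True, None, _R, _P),
    ("fit_metric", "metric_value", "float", True, None, _R, _P),

    ("protocol_step", "protocol_id", "code", True, None, _R, _P),
    ("protocol_step", "step_index", "int", True, None, (1, None, False, False), _P),
    ("protocol_step", "method_name", "text", True, None, _R, _P),
    ("protocol_step", "num_models_begin", "int", True, None, (0, None, False, False), _P),
    ("protocol_step", "num_models_end", "int", True, None, (0, None, False, False), _P),
    ("protocol_step", "multi_scale", "code", True, _YESNO, _R, _P),
    ("protocol_step", "multi_state", "code", True, _YESNO, _R, _P),
    ("protocol_step", "ordered", "code", True, _YESNO, _R, _P),
    ("protocol_step", "software_id", "code", False, None, _R, ("software", "id")),
    ("protocol_step_dataset", "protocol_id", "code", True, None, _R,
     ("protocol_step", "protocol_id")),
    ("protocol_step_dataset", "step_index", "int", True, None, (1, None, False, False), _P),
    ("protocol_step_dataset", "dataset_id", "code", True, None, _R, ("dataset", "id")),

    ("seq_ref", "entity_id", "code", True, None, _R, ("entity", "id")),
    ("seq_ref", "db", "code", True, "UniProt,INSDC", _R, _P),
    ("seq_ref", "accession", "code", True, None, _R, _P),
    ("seq_ref", "model_begin", "int", True, None, (1, None, False, False), _P),
    ("seq_ref", "model_end", "int", True, None, (1, None, False, False), _P),
    ("seq_ref", "ref_begin", "int", True, None, (1, None, False, False), _P),
    ("seq_ref", "ref_end", "int", True, None, (1, None, False, False), _P),
    ("seq_ref", "identity_percent", "float", True, None, (0, 100, False, False), _P),
]


def builtin_dictionary_text() -> str:
    """Render the mini-IHM dictionary in its mmCIF-dialect file form."""
    block = CifBlock("mini_ihm")
    head = CifCategory("dictionary", ["title", "version"])
    head.append(["mini-IHM dictionary", "1.0"])
    block.add(head)
    cats = CifCategory("category_def", ["name", "mandatory", "keys"])
    for name, mandatory, keys in CATEGORIES:
        cats.rows.append([
            value_of(name), value_of("yes" if mandatory else "no"),
            value_of(keys) if keys else INAPPLICABLE,
        ])
    block.add(cats)
    items = CifCategory("item_def", [
        "category", "name", "type_code", "mandatory", "enum",
        "range_min", "range_max", "min_open", "max_open",
        "parent_category", "parent_item", "description",
    ])
    for cat, name, tc, mandatory, enum, rng, parent in ITEMS:
        rmin, rmax, omin, omax = rng if rng else (None, None, False, False)
        items.rows.append([
            value_of(cat), value_of(name), value_of(tc),
            value_of("yes" if mandatory else "no"),
            value_of(enum) if enum else INAPPLICABLE,
            value_of(rmin) if rmin is not None else INAPPLICABLE,
            value_of(rmax) if rmax is not None else INAPPLICABLE,
            value_of("yes" if omin else "no"), value_of("yes" if omax else "no"),
            value_of(parent[0]) if parent else INAPPLICABLE,
            value_of(parent[1]) if parent else INAPPLICABLE,
            INAPPLICABLE,
        ])
    block.add(items)
    return write_document(CifDocument([block]))


@lru_cache(maxsize=1)
def builtin_dictionary() -> DictionaryModel:
    """Load the bundled mini-IHM dictionary."""
    return load_dictionary(builtin_dictionary_text())
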