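group_id,entity_id_1,seq_id_1,comp_id_1,atom_id_1,entity_id_2,seq_id_2,comp_id_2,atom_id_2,linker,threshold_A,restraint_form,conditionality,dataset_id
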