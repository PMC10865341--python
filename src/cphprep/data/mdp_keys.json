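{
    "master_switch": "lambda-dynamics",
    "simulation_ph": "lambda-dynamics-simulation-ph",
    "lambda_mass": "lambda-dynamics-lambda-particle-mass",
    "lambda_tau": "lambda-dynamics-tau",
    "update_nst": "lambda-dynamics-update-nst",
    "charge_constraints": "lambda-dynamics-charge-constraints",
    "calibration": "lambda-dynamics-calibration",
    "n_group_types": "lambda-dynamics-number-lambda-group-types",
    "n_atom_sets": "lambda-dynamics-number-atom-collections",
    "type_name": "lambda-dynamics-group-type{i}-name",
    "type_n_states": "lambda-dynamics-group-type{i}-n-states",
    "type_common_charges": "lambda-dynamics-group-type{i}-state-0-charges",
    "type_state_charges": "lambda-dynamics-group-type{i}-state-{j}-charges",
    "type_state_pka": "lambda-dynamics-group-type{i}-state-{j}-reference-pka",
    "type_state_dvdl": "lambda-dynamics-group-type{i}-state-{j}-dvdl-coefficients",
    "set_name": "lambda-dynamics-atom-set{k}-name",
    "set_index_group": "lambda-dynamics-atom-set{k}-index-group-name",
    "set_initial_lambda": "lambda-dynamics-atom-set{k}-initial-lambda",
    "set_barrier": "lambda-dynamics-atom-set{k}-barrier",
    "set_charge_restraint_group": "lambda-dynamics-atom-set{k}-charge-restraint-group-index",
    "set_buffer_residue": "lambda-dynamics-atom-set{k}-buffer-residue",
    "set_buffer_multiplier": "lambda-dynamics-atom-set{k}-buffer-residue-multiplier"
}
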