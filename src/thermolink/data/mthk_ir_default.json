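{
  "schema_version": 1,
  "model_type": "four_state",
  "description": "Default four-state binary-elements parameter set for MthK IR calcium-dependent gating. Units: L0 and all theta couplings dimensionless; K_Ca in 1/M; van't Hoff dH in J/mol, dS in J/(mol*K).",
  "parameters": {
    "L0": {"value": 0.1},
    "K_Ca": {"value": 20000.0, "unit": "1/M"},
    "theta_UC": {"value": 150.0},
    "theta_UO": {"value": 18.0},
    "theta_BC": {"value": 8.0},
    "theta_BO": {"value": 8.0}
  },
  "vant_hoff_variants": {
    "theta_UC": {"dH_J_per_mol": -71000.0, "dS_J_per_mol_K": -220.0},
    "theta_UO": {"dH_J_per_mol": 80000.0, "dS_J_per_mol_K": 300.0},
    "theta_BC": {"dH_J_per_mol": -71000.0, "dS_J_per_mol_K": -220.0},
    "theta_BO": {"dH_J_per_mol": 81000.0, "dS_J_per_mol_K": 310.0}
  },
  "notes": "Published listings of this parameter set are partially ambiguous (the static theta_BC entry in particular); the assignment theta_BC = 8 and the per-coupling dH/dS pairs above are configuration choices of this package, not asserted author values. The vant_hoff_variants block gives the enthalpy/entropy pair to substitute for a coupling when simulating its temperature dependence; couplings not substituted keep their static value."
}
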