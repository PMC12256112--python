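{
  "format_version": 1,
  "comment": "Default kinetic parameter sets per proteasome variant / ligand condition. Rates marked representative=true are not printed numerically in the source study and encode its qualitative statements; all others are the printed values.",
  "acquisition": {
    "frame_interval_s": 0.0517,
    "n_frames": 2000,
    "total_intensity": 1000.0,
    "noise_sd": 60.0,
    "background": 20.0,
    "donor_bleach_mean_s": 80.0,
    "acceptor_bleach_mean_s": 80.0
  },
  "fret_levels": {"E_s1": 0.4, "E_ns1": 0.8},
  "titration": {
    "K_D_app_uM": 3.1,
    "k_f_apo": 1.45,
    "k_f_sat": 0.30,
    "default_conc_grid_uM": [0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0]
  },
  "dynamics": {
    "WT": {"k_f": 1.45, "k_b": 5.8, "ligand_conc_uM": 0.0},
    "WT+Ub4": {"k_f": 0.45, "k_b": 5.8, "ligand_conc_uM": 10.0},
    "dUIM": {"k_f": 1.45, "k_b": 5.8, "ligand_conc_uM": 0.0, "representative": true},
    "dUIM+Ub4": {"k_f": 1.15, "k_b": 5.8, "ligand_conc_uM": 10.0, "representative": true},
    "ARR-Pru-dUIM": {"k_f": 1.45, "k_b": 5.8, "ligand_conc_uM": 0.0, "representative": true},
    "ARR-Pru-dUIM+Ub4": {"k_f": 1.25, "k_b": 5.8, "ligand_conc_uM": 10.0, "representative": true},
    "ARR-Pru-dUIM-A89F": {"k_f": 1.45, "k_b": 5.8, "ligand_conc_uM": 0.0, "representative": true},
    "ARR-Pru-dUIM-A89F+Ub4": {"k_f": 0.50, "k_b": 5.8, "ligand_conc_uM": 10.0, "representative": true},
    "Rpn10-EKK": {"k_f": 0.87, "k_b": 6.2, "ligand_conc_uM": 0.0}
  },
  "processing": {
    "WT": {"p_success": 0.037, "tau_ins_mean_s": 1.64},
    "WT+Ub4": {"p_success": 0.078, "tau_ins_mean_s": 1.39},
    "ARR-Pru-dUIM": {"p_success": 0.037, "tau_ins_mean_s": 1.64, "representative": true},
    "ARR-Pru-dUIM+Ub4": {"p_success": 0.037, "tau_ins_mean_s": 1.64, "representative": true},
    "ARR-Pru-dUIM-A89F": {"p_success": 0.037, "tau_ins_mean_s": 1.64, "representative": true},
    "ARR-Pru-dUIM-A89F+Ub4": {"p_success": 0.078, "tau_ins_mean_s": 1.39, "representative": true}
  },
  "bulk_degradation": {
    "enzyme_conc_nM": 50.0,
    "substrate_conc_uM": 10.0,
    "fp_intact_mP": 200.0,
    "fp_degraded_mP": 50.0,
    "fp_noise_sd_mP": 1.0,
    "sample_interval_min": 0.5,
    "duration_min": 60.0,
    "conditions": {
      "GS/SspB-dReceptor": {"rate_per_enzyme": 0.25},
      "Ub-GS/SspB-dReceptor": {"rate_per_enzyme": 1.0},
      "GS/SspB-dReceptor-fig5": {"rate_per_enzyme": 0.21},
      "monoUb-GS/SspB-dReceptor": {"rate_per_enzyme": 0.38},
      "monoUb-GS/SspB-dReceptor-A89F": {"rate_per_enzyme": 0.42},
      "GS/SspB-dReceptor-A89F": {"rate_per_enzyme": 0.21},
      "monoUb-GS/SspB-dReceptor-A89I": {"rate_per_enzyme": 0.38},
      "GS/SspB-dReceptor-A89I": {"rate_per_enzyme": 0.22},
      "monoUb-GS/SspB-dReceptor-L132R": {"rate_per_enzyme": 0.25},
      "GS/SspB-dReceptor-L132R": {"rate_per_enzyme": 0.23},
      "titin/ARR-Pru-dUIM-A89F": {"rate_per_enzyme": 1.25},
      "titin/ARR-Pru-dUIM-A89F+Ub4": {"rate_per_enzyme": 1.51}
    }
  },
  "dub_assay": {
    "enzyme_conc_nM": 500.0,
    "substrate_conc_uM": 100.0,
    "fp_intact_mP": 200.0,
    "fp_degraded_mP": 50.0,
    "fp_noise_sd_mP": 1.0,
    "sample_interval_min": 0.2,
    "duration_min": 30.0,
    "conditions": {
      "Rpn11-WT": {"rate_per_enzyme": 1.0},
      "Rpn11-A89F": {"rate_per_enzyme": 1.3},
      "Rpn11-A89I": {"rate_per_enzyme": 10.0},
      "Rpn11-L132R": {"rate_per_enzyme": 0.0}
    }
  }
}
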