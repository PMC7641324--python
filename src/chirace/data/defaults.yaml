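# Packaged default configuration.
# Every key is documented; unknown keys are rejected by the loader.
schema_version: 1

kinetics:
  # Motor rate-law constants, kinetic mode.  Km and Ki (uM) are solved from
  # the two-condition IC50 pair below; RecD's Ki is 7.3x RecB's (the
  # predicted binding-affinity ratio), so RecD slows less than RecB.
  # v_max in nt/ms; the RecD scale makes nt and ms interchangeable.
  recB: { v_max: 0.8, km_atp: 416.6667, ki_inh: 9.434 }
  recD: { v_max: 1.0, km_atp: 416.6667, ki_inh: 68.87 }

swing:
  # Nuclease-swing timing: fast after Chi, slow after an end stop.
  tau_chi_ms: 1.0
  tau_stop_ms: 250.0
  cv: 0.2
  chi_offset_nt: 5

enzyme:
  p_chi_recognition: 1.0
  k_sens_uM: 75.0

# Direct inhibitor -> (velocity ratio, swing advance) lookup, the default
# mode for reproducing the published per-concentration fits.
calibration:
  - { inhibitor_uM: 0, ratio: 0.80, advance_nt: 0 }
  - { inhibitor_uM: 25, ratio: 0.70, advance_nt: 250 }
  - { inhibitor_uM: 50, ratio: 0.60, advance_nt: 250 }
  - { inhibitor_uM: 100, ratio: 0.50, advance_nt: 370 }
  - { inhibitor_uM: 200, ratio: 0.40, advance_nt: 290 }
  - { inhibitor_uM: 400, ratio: 0.30, advance_nt: 200 }

gel:
  a_mm: 120.0
  b_mm: 30.0
  sigma_mm: 0.8
  min_length_nt: 100
  max_length_nt: 5000

markers_nt: [4350, 2270, 1340, 1000, 500, 250, 100]

substrates:
  # 5'-end-labeled duplexes; entry from the right puts Chi in its active
  # orientation, with the label on the distal (left) end.
  lengths_nt: [4350, 2270, 1340]
  chi_cut_from_label_nt: 970

# The two-condition nuclease-assay IC50 pair used to solve (Ki, Km).
ic50_observations:
  - { atp_uM: 25, ic50_uM: 10 }
  - { atp_uM: 4000, ic50_uM: 100 }

# Settings of the standard-condition solubilization assay generator.
nuclease_assay:
  atp_uM: 25
  ic50_uM: 6.3
  concentrations_uM: [0, 2.5, 5, 10, 20, 40, 60, 80]
  replicates: 3
  noise_cv: 0.05

experiment:
  concentrations_uM: [0, 25, 50, 100, 200, 400]
  n_molecules: 2000
  noise: { band_jitter_mm: 0.0, activity_cv: 0.05 }
  seed: 0
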