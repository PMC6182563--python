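# Non-agglomerative progression (Mucor-like): large lemon-shaped spores
# swell dramatically, each germling grows into its own loose pellet; no
# agglomeration stage. Includes occasional multicore pellets late.
name: non-agglomerative
description: large elongated spores -> strong swelling -> germination -> loose single-germling pellets
timepoints:
  - time_hr: 0
    stage: spores
    width: 600
    height: 600
    calibration: 0.1
    objects:
      - {kind: spore, count: 10, diameter_um: 8.0, diameter_sd_um: 0.6, axis_ratio: 2.0}
  - time_hr: 5
    stage: swelling
    width: 600
    height: 600
    calibration: 0.2
    objects:
      - {kind: swollen_spore, count: 14, diameter_um: 14.0, diameter_sd_um: 1.0, axis_ratio: 1.5}
  - time_hr: 12
    stage: germination
    width: 800
    height: 800
    calibration: 0.5
    objects:
      - {kind: germinating_spore, count: 10, diameter_um: 16.0, tube_length_um: 60.0, tube_width_px: 4}
      - {kind: clump, count: 3, n_steps: 45, step_px: 4.0, width_px: 4.0, branch_prob: 0.03}
  - time_hr: 24
    stage: loose_pellets
    width: 1000
    height: 1000
    calibration: 2.0
    objects:
      - {kind: hairy_pellet, count: 3, core_radius_um: 160.0, n_filaments: 25,
         filament_length_um: 120.0, filament_width_px: 3}
      - {kind: multicore_pellet, count: 1, core_radius_um: 100.0, n_cores: 3,
         n_filaments: 30, filament_length_um: 80.0, filament_width_px: 3}
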