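# Perithecia-seeded progression (Chaetomium-like): spores germinate into
# hyphae; flask-shaped fruiting bodies later act as agglomeration centers,
# yielding core-shell pellets covered with long filaments.
name: perithecia-seeded
description: spores -> germination -> hyphae -> perithecium-centered core-shell pellets
timepoints:
  - time_hr: 0
    stage: spores
    width: 600
    height: 600
    calibration: 0.1
    objects:
      - {kind: spore, count: 25, diameter_um: 5.0, diameter_sd_um: 0.4, axis_ratio: 1.1}
  - time_hr: 5
    stage: germination
    width: 800
    height: 800
    calibration: 0.2
    objects:
      - {kind: germinating_spore, count: 6, diameter_um: 6.0, tube_length_um: 15.0, tube_width_px: 3}
  - time_hr: 10
    stage: hyphal_growth
    width: 1000
    height: 1000
    calibration: 0.5
    objects:
      - {kind: branched_hypha, count: 6, n_steps: 45, step_px: 4.0, width_px: 3.0, branch_prob: 0.1}
  - time_hr: 24
    stage: core_shell_pellets
    width: 1200
    height: 1200
    calibration: 2.0
    objects:
      - {kind: core_shell_pellet, count: 2, core_radius_um: 200.0, n_filaments: 60,
         filament_length_um: 300.0, filament_width_px: 3}
      - {kind: clump, count: 2, n_steps: 50, step_px: 4.0, width_px: 3.0, branch_prob: 0.05}
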