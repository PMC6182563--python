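# Hyphal-agglomerative progression (Penicillium-like): slightly elongated
# spores germinate first, dispersed hyphae and clumps dominate, and the
# germlings then agglomerate into ellipsoid hairy pellets while dispersed
# mycelium persists to the end.
name: agglomerative-hyphal
description: elongated spores -> early germination -> hyphae/clumps -> hyphal agglomerates -> ellipsoid pellets
timepoints:
  - time_hr: 0
    stage: spores
    width: 600
    height: 600
    calibration: 0.05
    objects:
      - {kind: spore, count: 12, diameter_um: 3.2, diameter_sd_um: 0.2, axis_ratio: 1.15}
  - time_hr: 5
    stage: germination
    width: 600
    height: 600
    calibration: 0.1
    objects:
      - {kind: germinating_spore, count: 8, diameter_um: 5.0, tube_length_um: 12.0, tube_width_px: 3}
      - {kind: spore, count: 6, diameter_um: 4.0, diameter_sd_um: 0.3}
  - time_hr: 10
    stage: hyphal_growth
    width: 800
    height: 800
    calibration: 0.5
    objects:
      - {kind: branched_hypha, count: 5, n_steps: 45, step_px: 4.0, width_px: 3.0, branch_prob: 0.1}
      - {kind: clump, count: 3, n_steps: 50, step_px: 4.0, width_px: 3.0, branch_prob: 0.05}
  - time_hr: 17
    stage: hyphal_agglomeration
    width: 1000
    height: 1000
    calibration: 1.0
    objects:
      - {kind: hairy_pellet, count: 2, core_radius_um: 80.0, n_filaments: 50,
         filament_length_um: 50.0, filament_width_px: 3}
      - {kind: clump, count: 4, n_steps: 50, step_px: 4.0, width_px: 3.0, branch_prob: 0.08}
  - time_hr: 24
    stage: pellets_with_dispersed
    width: 1000
    height: 1000
    calibration: 2.0
    objects:
      - {kind: hairy_pellet, count: 3, core_radius_um: 150.0, n_filaments: 50,
         filament_length_um: 80.0, filament_width_px: 3}
      - {kind: clump, count: 3, n_steps: 50, step_px: 4.0, width_px: 3.0, branch_prob: 0.08}
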