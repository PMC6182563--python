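# Spore-agglomerative progression (Aspergillus-like): spores swell,
# agglomerate while still ungerminated, germinate from the agglomerate
# surface, and mature into hairy pellets. Calibration changes between
# timepoints mirror the objective switching needed as objects grow by
# orders of magnitude. Sizes are qualitative geometric stand-ins.
name: agglomerative-spore
description: spore swelling -> spore agglomeration -> germination -> hairy pellets
timepoints:
  - time_hr: 0
    stage: spores
    width: 600
    height: 600
    calibration: 0.1
    objects:
      - {kind: spore, count: 30, diameter_um: 4.0, diameter_sd_um: 0.3}
  - time_hr: 5
    stage: swelling
    width: 600
    height: 600
    calibration: 0.1
    objects:
      - {kind: swollen_spore, count: 25, diameter_um: 6.0, diameter_sd_um: 0.4}
  - time_hr: 8
    stage: agglomeration
    width: 600
    height: 600
    calibration: 1.0
    objects:
      - {kind: agglomerate, count: 3, n_members: 150, member_diameter_um: 26.0, overlap: 0.35}
      - {kind: agglomerate, count: 4, n_members: 5, member_diameter_um: 16.0, overlap: 0.35}
  - time_hr: 12
    stage: germination
    width: 1000
    height: 1000
    calibration: 1.0
    objects:
      - {kind: hairy_pellet, count: 3, core_radius_um: 65.0, n_filaments: 20,
         filament_length_um: 60.0, filament_width_px: 3}
      - {kind: clump, count: 4, n_steps: 50, step_px: 4.0, width_px: 3.0, branch_prob: 0.05}
  - time_hr: 18
    stage: pellet_formation
    width: 1000
    height: 1000
    calibration: 1.0
    objects:
      - {kind: hairy_pellet, count: 4, core_radius_um: 70.0, n_filaments: 40,
         filament_length_um: 40.0, filament_width_px: 3}
      - {kind: clump, count: 2, n_steps: 50, step_px: 4.0, width_px: 3.0, branch_prob: 0.05}
  - time_hr: 24
    stage: pellets
    width: 800
    height: 800
    calibration: 2.0
    objects:
      - {kind: hairy_pellet, count: 4, core_radius_um: 180.0, n_filaments: 40,
         filament_length_um: 60.0, filament_width_px: 3}
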