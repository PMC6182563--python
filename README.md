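# mycomorph

Quantitative morphometry of filamentous fungi in submerged culture.

Micrographs of shake-flask or bioreactor samples show mycelial objects that
span four orders of magnitude over a single cultivation — spores of a few
μm² swell, agglomerate, germinate and mature into hairy pellets of up to
millimeters — and the productivity of many fungal bioprocesses depends on
which of these morphologies dominates (microparticle-enhanced cultivation,
MPEC, deliberately steers it). `mycomorph` provides the image-analysis
pipeline such studies rely on: segmentation of dark mycelial objects on a
bright phase-contrast background, per-object size and shape descriptors,
debris filtering, two-size-class statistics, plus a synthetic micrograph
generator with exact ground truth so every stage is testable without
microscopy data.

## The pipeline and its descriptors

1. green plane of the RGB capture → median filter (smooths edges without
   changing object size or shape) → Sobel gradient magnitude;
2. edge-based segmentation: Otsu (or fixed) threshold on the gradient,
   morphological closing, hole filling, one-pixel halo compensation,
   8-connected labeling;
3. rule-based removal of debris and invalid objects (minimum/maximum
   projected area, circularity, border exclusion, optional polygonal areas
   of interest) — e.g. ~10 μm angular mineral microparticles in MPEC
   samples;
4. per-object descriptors, with μm/px calibration per objective:

   | symbol | descriptor | definition |
   |---|---|---|
   | A | projected area | pixel count × calibration², μm² |
   | D | mean diameter | chord through the center of gravity, averaged over 180 directions |
   | Dmax | maximum diameter | maximum Feret diameter (boundary-to-boundary), μm |
   | E | elongation | (σ_longitudinal/σ_transversal)² of pixel coordinates along the principal axis; 1 = circle |
   | R (S) | roughness / solidity | A / convex-hull area; 1 = smooth convex |
   | — | circularity | 4πA/P² |
   | Mo | morphology number | **Mo = 2·√(A·S) / (√π · Dmax · E)** |

   Mo is 1 for an ideal disk, stays ≥ 0.6 for circular objects
   (ungerminated spores, ideal pellets) and falls below 0.5 once
   filamentous morphology evolves;
5. statistics: per time × condition × size-class means, sample SD and
   Student-t confidence bands (α = 0.05 by default), with the small/large
   split at a projected-area threshold (10⁴ μm² by default, 10⁵ μm² for
   strongly pelleting cultures).

## Worked example

```python
from mycomorph import generate_spore_field, render, records_to_frame
from mycomorph.config import RunConfig
from mycomorph.pipeline import analyze_image
from mycomorph.partition_stats import summarize_table

# a synthetic spore image: 12 slightly elongated spores + 8 microparticles
scene, truth = generate_spore_field(12, diameter_um=4.0, axis_ratio=1.3,
                                    calibration=0.1, seed=42,
                                    n_microparticles=8,
                                    width=900, height=900)
cfg = RunConfig(calibration=0.1,
                filters=[{"kind": "min_circularity", "threshold": 0.7},
                         {"kind": "border_exclusion", "threshold": 1.0}])
result = analyze_image(render(scene), cfg)
print(f"{result.n_detected} objects detected, "
      f"{len(result.removals)} removed as debris, "
      f"{len(result.records)} kept")
```

```
20 objects detected, 8 removed as debris, 12 kept
```

All 8 angular microparticles fail the circularity ≥ 0.7 rule; all 12 spores
survive. The per-object table and the summary:

```python
table = records_to_frame(result.records, image="demo", time_hr=0.0,
                         condition="standard")
print(table[["object_id", "A_um2", "D_um", "E", "R", "Mo"]].head(3).round(3))
print(summarize_table(table, parameters=("A_um2", "Mo"), threshold=1e4))
```

```
 object_id  A_um2  D_um     E   R    Mo
         1  15.47 4.396 1.699 1.0 0.521
         2  10.03 3.537 1.668 1.0 0.529
         3  13.57 4.114 1.692 1.0 0.522

 time_hr condition class parameter  n    mean     sd  ci_half_width
     0.0  standard   all     A_um2 12 12.6917 2.0282         1.2887
     0.0  standard   all        Mo 12  0.5234 0.0061         0.0039
```

Spores of 4 μm nominal diameter measure ~3.5–4.4 μm across with A ≈ 10–15
μm²; the axis ratio of 1.3 gives E ≈ 1.7 (= 1.3²) and pushes Mo to ~0.52,
i.e. visibly away from the ideal-circle value of 1. The summary row reports
the mean, sample SD and the t-based 95 % confidence half-width over the 12
surviving objects.

The same chain is available from the shell:

```sh
mycomorph simulate --profile agglomerative-spore --out sim/ --seed 1
mycomorph analyze sim/ --out results/ --config config.yaml
mycomorph summarize results/objects.csv --out summary.csv --threshold 1e4
```

`simulate` ships four editable timecourse presets (`agglomerative-spore`,
`agglomerative-hyphal`, `perithecia-seeded`, `non-agglomerative`) emulating
the canonical pellet-formation routes.

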