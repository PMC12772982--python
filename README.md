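# cervhsi

Hyperspectral cervical-tissue analysis pipeline: multi-examiner annotation
consensus, landmark-based homography transfer of annotations into the
hyperspectral (HSI) frame, band-ratio tissue indices (TWI, THI, StO2, NIR)
and paired nonparametric inference — plus a seeded synthetic phantom
generator so the whole chain is testable without any clinical data.

## What it does

1. **synthetic_data** — renders Beer–Lambert reflectance phantoms
   (a "cervix" disc with lesion polygons carrying elevated hemoglobin/water
   absorption), a perspective-distorted higher-resolution second view with
   noisy landmark pairs, and imperfect multi-examiner annotations.
2. **consensus** — per-pixel consensus maps (fraction of examiners marking a
   pixel), pairwise IoU matrices averaged across subjects, consensus
   thresholding (default ≥ 50%) for lesion classes, and the healthy-union
   reference mask.
3. **registration** — homography estimation from ≥ 4 landmark pairs
   (normalized DLT + least-squares refinement of the back-projection error),
   point projection and nearest-neighbor binary-mask warping.
4. **spectral** — wavelength grids, ENVI/portable cube I/O, absorbance,
   masked mean spectra, z-scoring, and configurable two-window band-ratio
   index maps clipped to [0, 1].
5. **stats** — Wilcoxon signed-rank (exact by enumeration for tie-free
   n ≤ 25, tie/continuity-corrected normal approximation otherwise),
   Hodges–Lehmann estimate (median of Walsh averages), seeded percentile
   bootstrap CIs, effect size r = |Z|/√n.
6. **pipeline** — per-subject and cohort orchestration, consensus-threshold
   sensitivity analysis, deterministic JSON/CSV outputs.

## CLI

```bash
# simulate a seeded phantom cohort (ENVI cubes, PNG masks, landmark CSVs)
cervhsi simulate --config examples/cohort.yaml --seed 1 --out scratch/cohort

# full cohort analysis; add repeated --tau for a sensitivity run
cervhsi run --manifest scratch/cohort/cohort_manifest.json --seed 1 --out scratch/results
cervhsi run --manifest scratch/cohort/cohort_manifest.json --tau 0.5 --tau 0.75 \
    --seed 1 --out scratch/results_sens

# individual stages
cervhsi consensus --annotations scratch/cohort/subject-01_annotations.json --tau 0.5 --out scratch/c
cervhsi register  --landmarks scratch/cohort/subject-01_landmarks.csv --out scratch/H.json
cervhsi warp      --h scratch/H.json --mask mask.png --shape 72x72 --out warped.png
cervhsi indices   --cube scratch/cohort/subject-01_cube.hdr --out scratch/idx
cervhsi stats     --table paired_table.csv --b 10000 --seed 1 --out scratch/stats
```

Analysis configuration (consensus threshold, index band definitions and
scales, wavelength window, bootstrap settings) is a YAML file; see
`cervhsi.pipeline.AnalysisConfig.from_dict` for the schema.

## Layout

```
src/cervhsi/
  spectral.py        # grids, cubes, absorbance, band-ratio indices
  synthetic_data.py  # phantom scenes with known ground truth
  consensus.py       # consensus maps, IoU, reference masks
  registration.py    # homography estimation / projection / warping
  stats.py           # signed-rank, Hodges–Lehmann, bootstrap, effect size
  pipeline.py        # subject/cohort orchestration
  io.py              # ENVI, PNG masks, landmark CSV, manifests
  cli.py             # click entry points
```
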