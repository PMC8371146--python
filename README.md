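# corridorprobe

Virtual bore-probe feasibility analysis of transpubic screw corridors in CT
Hounsfield-unit volumes.

Given a 3D HU volume (NIfTI or MetaImage) and entry/exit landmarks in world
millimetres, the package places a straight cylindrical bore probe (default
diameter 7.5 mm) between the landmarks, samples trilinearly interpolated HU
over the probe cross-section in 1 mm steps, and decides whether the corridor
is *accessible*: no station's disc maximum may exceed the cortical threshold
(default 400 HU) except in the contiguous cortical runs containing the entry
and exit stations.  Inaccessible corridors are classified by perforation
site (pubic ramus / acetabulum / both).  Cohort-level outputs include
length-normalized mean HU profiles, length summary tables, perforation-group
tallies, and Mann-Whitney U / Pearson chi-square tests.

A parametric phantom generator produces curved tubular bone phantoms
(cortical shell, trabecular interior, periacetabular zone, dense exit
cortex, optional acetabular wall) with analytically known accessibility and
length, so the whole pipeline is testable end to end without clinical data.

## Layout

| module | role |
| --- | --- |
| `corridorprobe.volume_geometry` | volume I/O (NIfTI via nibabel, minimal MetaImage reader/writer), world/index transforms, trilinear interpolation, station and disc sample geometry |
| `corridorprobe.corridor_probe` | bore-probe sampling, cortical-run detection, accessibility verdicts, perforation-site grouping, region maps |
| `corridorprobe.phantom_gen` | phantom specs, voxelization, analytic ground truth, cohort sampling |
| `corridorprobe.cohort_profiles` | profile normalization/aggregation, cohort summary tables |
| `corridorprobe.stats_report` | Mann-Whitney U (exact ≤ 8 per group, tie-corrected normal otherwise), Pearson chi-square, end-to-end pipeline + report bundle |

## CLI

```sh
# write a synthetic cohort (volumes, landmarks, region maps, ground truth)
corridorprobe synth --n 20 --seed 1 --out out/synth

# probe one volume along landmark pairs
corridorprobe run --volume vol.nii --landmarks landmarks.csv \
    --regions regions.yaml --out out/run

# aggregate per-specimen results into cohort tables and statistics
corridorprobe report --results out/run/results.json \
    --covariates covariates.csv --out out/report

# synthetic end-to-end run in memory
corridorprobe pipeline --n 50 --seed 1 --out out/pipe
```

Landmark CSVs use the header
`specimen_id,side,entry_x,entry_y,entry_z,exit_x,exit_y,exit_z` (world mm);
an equivalent JSON list is accepted.  Analysis parameters (probe diameter,
step, threshold, cross-section sampling density) come from a YAML file
mirroring `AnalysisConfig`.

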