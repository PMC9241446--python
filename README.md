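# bscb-mark

Quantitative MRI/IHC biomarker pipeline for blood–spinal-cord-barrier (BSCB)
disruption and white-matter integrity in a focal spinal-cord lesion model:

- **`bscbmark.dti`** — log-linear diffusion-tensor fitting, FA/AD/RD maps,
  binarization-threshold calibration against a target white-matter area
  fraction (~55% of the cord cross-section at the injection level), and the
  %FA-positive / %AD-positive / %RD-negative area scores (default thresholds
  FA ≥ 0.55, AD ≥ 1.4 µm²/ms, RD ≤ 0.5 µm²/ms, inclusive comparisons).
- **`bscbmark.dce`** — relative enhancement from serial post-contrast scans
  (1 baseline + 6 scans over 10 min), the per-slice Gd influx rate Kp (OLS
  slope of enhancement vs time), the whole-cord leakage score (sum over
  slices), and percent normalization against a reference-day value.
- **`bscbmark.ihc`** — vessel segmentation from the CD31 channel (Canny
  edges + hole filling + half-maximum boundary refinement), marker
  (e.g. P-selectin) high-intensity area within vessels, perivascular
  collagen area (collagen⁺ in a dilated vessel neighborhood minus the part
  inside vessels), and triplicate-per-region averaging per animal.
- **`bscbmark.stats`** — per-timepoint Spearman/Pearson correlations with
  strength bands (0.2/0.4/0.7 boundaries), standardized partial multiple
  regression of clinical score on the MRI parameters, and the input→output
  prediction model whose regression effect size (r²) is read as predictive
  power of acute Gd leakage for later %RD-negative area.
- **`bscbmark.synthetic`** — phantoms and cohorts with known ground truth:
  a disk-cord DWI phantom with a 55% white-matter annulus and optional
  lesion wedge, linear-enhancement DCE series, annular vessel images with
  marker coverage and collagen halos, and a latent-severity longitudinal
  cohort whose population correlations are available in closed form.
- **`bscbmark.pipeline` / `bscbmark.cli`** — end-to-end orchestration with
  YAML config, per-stage seed substreams and a deterministic run directory.

## CLI

```sh
# full synthetic demo run (phantoms -> quantification -> statistics)
bscb-mark all --seed 0 --out runs/demo

# print / edit the demo config
bscb-mark demo-config > my_config.yaml
bscb-mark all --config my_config.yaml --out runs/custom

# real-data style stage invocations
bscb-mark dti --dwi dwi.nii.gz --bval bval.txt --bvec bvec.txt \
    --cord-mask cord.nii.gz --calibrate-wm-fraction 0.55 --out out/
bscb-mark dce --scans scans.nii.gz --times times.csv --roi roi.nii.gz --out out/
bscb-mark ihc --image fov1.tif --channels cd31,p_selectin,collagen1 --region epicenter
bscb-mark stats --cohort cohort.csv --analysis predict --dpi 14
```

A run directory contains `maps/` (NIfTI scalar maps + masks), `curves/`
(enhancement CSV), `ihc/` (phantom TIFF), `stats/` (all result CSVs),
`report.md`, `config.yaml` (frozen snapshot) and `run.log`. Re-running with
the same config and seed reproduces every output byte for byte.

## Cohort CSV schema

`animal_id, group, dpi, gd_leakage, pct_fa, pct_ad, pct_rd, clinical_score`
with one row per animal × timepoint (7/14/21 days), groups in
`{naive, isotype_control, anti_rgma}` and clinical scores on the ordinal
scale `{0, 0.5, 1, 1.5, 2, 3, 4, 5}`. Missing values are allowed and
handled pairwise-complete in correlations, listwise in regression.
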