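# lesionpipe

Subject-specific white-matter lesionometry for diffusion MRI, with a fully
synthetic phantom + cohort generator so the entire pipeline is testable
offline.

The pipeline:

1. **phantom** — simulates two-shell diffusion acquisitions (10 b=0 + 64
   directions at b=1500 and b=3000 s/mm², 1.7 mm isotropic) over small 3-D
   grids containing fiber bundles, gray-matter-like and CSF-like regions and
   spherical white-matter-hyperintensity (WMH) lesions; generates a
   two-timepoint cohort (ages 58–81, sex, GrimAge, brain/WMH volumes) with a
   planted effect structure linking age-adjusted epigenetic age
   (AgeAccelGrim) to WMH volume and to perilesional microstructure, plus a
   deliberately null whole-brain change and missing-completely-at-random
   follow-up dropout.
2. **csd** — estimates WM/GM/CSF response functions and performs single-shell
   3-tissue constrained spherical deconvolution (b=0 + outermost shell),
   yielding a white-matter fiber orientation distribution (FOD, even real
   spherical harmonics, lmax 8) and per-voxel signal fractions
   (f_ECI, f_ICI, f_ICA) that sum to 1.
3. **tracking** — probabilistic whole-volume streamline tractography on the
   FOD field (bidirectional, cone-restricted sampling proportional to FOD
   amplitude, 2.6 mm minimum length), exact segment–voxel traversal / track
   density maps, and SIFT-style greedy pruning that ties streamline density
   to FOD magnitude.
4. **lesionometry** — selects streamlines traversing WMH voxels, builds the
   per-subject ROI of voxels crossed by ≥ 10 distinct lesioned streamlines
   (excluding the WMH itself), and computes ROI fraction means and lesion
   load (WMH volume / ROI volume).
5. **stats** — AgeAccelGrim (OLS residual of GrimAge on age), cross-sectional
   GLMs with planned covariates (age at scan, sex, a volumetric term),
   change-score longitudinal models on complete pairs, and
   missing-completely-at-random t-tests.
6. **io / pipeline / cli** — NIfTI, FSL bvals/bvecs, TCK and TSV formats,
   YAML configuration, seeded orchestration with a checksummed run manifest.

## Command line

```bash
lesionpipe --help
lesionpipe simulate --out out/sim --seed 1            # synthetic cohort
lesionpipe fit-microstructure --dwi dwi.nii --bvals bvals --bvecs bvecs \
    --wm-mask wm.nii --gm-mask gm.nii --csf-mask csf.nii --out out/fit
lesionpipe track --fod out/fit/fod.nii --mask mask.nii --count 20000 \
    --seed 1 --out tracks.tck
lesionpipe sift --tracks tracks.tck --fod out/fit/fod.nii --keep 4000 \
    --out sifted.tck
lesionpipe lesionometry --tracks sifted.tck --wmh wmh.nii \
    --fractions out/fit --min-tracts 10 --out out/les
lesionpipe stats --cohort cohort.tsv --roi-stats roi.tsv --out out/stats
lesionpipe run-all --out out/run --seed 1             # full synthetic run
```

Real-data entry points accept NIfTI volumes with FSL-style `bvals`/`bvecs`
text files, NIfTI masks, TCK tractograms and TSV cohort tables.

## Notes

- All randomness is seeded; pipeline runs are bit-reproducible (the manifest
  records per-stage seeds and output checksums).
- Desk-scale defaults (20³ grids, 10⁵→2×10⁴ streamline pruning ratio) stand
  in for acquisition-scale settings; every count is configurable.
- Cohort runs share one reference response function across subjects and
  timepoints to keep compartment decompositions comparable between scans.
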