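# trabec-bvtv

Trabecular bone volume fraction (BV/TV) estimation from dual-echo
ultrashort-echo-time (UTE) MRI, with a complete synthetic validation
pipeline against a microCT reference arm.

## The method

Bone bound water has an apparent transverse relaxation time (T2\*) of a
few hundred microseconds; marrow water and fat relax over tens of
milliseconds. A dual-echo UTE acquisition at TE₁ = 0.032 ms and
TE₂ = 2.2 ms (fat–water in phase at 3 T) therefore sees bone + marrow at
the first echo and marrow alone at the second, and the fractional signal
loss estimates the bone volume fraction per voxel:

```
BVTV_MR = (S_UTE − S_echo2) / S_UTE
```

No trabecular-level morphology or threshold choice is involved, so the
estimator works at clinical resolution (0.5 mm) where individual
trabeculae (~0.1 mm) are far below the voxel size. The reference standard
is microCT at 50 µm: bone is segmented by local adaptive thresholding in
~3 mm windows and BVTV is the bone voxel count over the total voxel count.

This package provides, as composable library modules with a CLI on top:

- `phantom` — seeded Gaussian-random-field trabecular microstructures
  with exact target bone fraction, and exact partial-volume downsampling;
- `mri` — the two-compartment dual-echo signal model with Rician noise;
- `uct` — the microCT forward model (two levels, Gaussian PSF, noise);
- `bvtv` — the dual-echo estimator, clamp policy and ROI means;
- `segmentation` — partial-volume-matched local adaptive thresholding
  and voxel counting;
- `registration` — corner-landmark similarity registration (least-squares,
  equal to the closed-form Procrustes fit) and 1-MR-slice-to-10-microCT-slice
  pairing;
- `stats` — Lilliefors-style normality check, exact/tie-corrected Wilcoxon
  rank-sum, Spearman correlation with a specimen-level (cluster) bootstrap
  CI, and difference/residual bias summaries;
- `study` — end-to-end orchestration with a single seed and a hashed
  artifact manifest.

See `docs/methods.md` for the models, their assumptions and limitations.

## Worked example

Run a full synthetic study — six specimens with true BVTV spanning
0.15–0.45, each imaged with both modalities, registered, paired and
compared:

```python
from trabec_bvtv import StudyConfig, run_study

result = run_study(StudyConfig(seed=1), out_dir="study_out")
print(result.report.summary())
```

prints

```
Paired BVTV comparison over 60 (specimen, slice) ROIs from 6 specimens
  BVTV MR   : 30.5 +/- 8.9 %
  BVTV microCT: 31.7 +/- 10.4 %
  Wilcoxon rank-sum two-sided p = 0.436
  Spearman r = 0.99 [0.94-0.99] (95% cluster-bootstrap CI, 1000 iterations)
  Difference (microCT - MR): 1.2 +/- 2.3 % [-4.4-6.1]
  Residuals about fit line : -0.0 +/- 1.6 % [-3.2-3.0]
```

Reading the numbers: the microCT arm tracks ground truth to ~10⁻³ on
average, and the MR estimate correlates almost perfectly with it across
the 60 (specimen, slice) regions because specimen-to-specimen spread
dominates measurement noise. The MR mean sits below the microCT mean: the
higher proton density per unit volume of fatty marrow (ratio 1.3 in the
model) deflates the estimator — in the idealized signal limit to
f/(f + 1.3(1−f)) — while marrow T2\* decay between the echoes partially
compensates, leaving a net ~1 percentage-point deficit at these defaults.
`study_out/` contains the paired table (`pairs.csv`), per-slice ground
truth, the JSON report, scatter and box plots, and a manifest with a
SHA-256 hash per artifact; rerunning the same config is bit-identical.

The same stages are available as subcommands on real NIfTI/TIFF data:

```
trabec-bvtv phantom --target-bvtv 0.3 --shape 128 128 128 --seed 1 --out phantom.nii.gz
trabec-bvtv simulate-mr --phantom phantom.nii.gz --noise 0.06 --out mr
trabec-bvtv simulate-uct --phantom phantom.nii.gz --noise 0.1125 --out uct.nii.gz
trabec-bvtv bvtv-mr --echo1 mr_echo1.nii.gz --echo2 mr_echo2.nii.gz \
    --slices 2 12 --bounds 2 8 2 8 --out mr_means.csv
trabec-bvtv segment-uct --uct uct.nii.gz --window-mm 3 --out uct_means.csv
trabec-bvtv stats --pairs pairs.csv --n-boot 1000 --seed 7 --out report/
trabec-bvtv run-study --seed 1 --out study_out/
```

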