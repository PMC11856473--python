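# Methods

## The measurement problem

Trabecular bone volume fraction (BV/TV) is the single best structural
predictor of bone strength, but its reference measurement — microCT at
~50 µm — requires an excised specimen. Dual-echo ultrashort-echo-time
(UTE) MRI offers a non-invasive surrogate: at an ultrashort first echo
(TE₁ ≈ 0.03 ms) both bone bound water and marrow contribute signal; by the
second echo (TE₂ = 2.2 ms, where fat and water are in phase at 3 T) the
bone signal, whose T2\* is a few hundred microseconds, has fully decayed
while marrow, with T2\* of tens of milliseconds, persists. The fractional
signal loss

    BVTV_MR = (S_UTE − S_echo2) / S_UTE

therefore estimates the bone volume fraction per voxel without resolving
individual trabeculae. This package implements that estimator together
with a complete synthetic validation pipeline — specimen phantoms, forward
models for both modalities, the microCT reference arm, registration and
pairing, and the paired statistical comparison — so the estimator's
accuracy, bias direction and correlation behaviour can be exercised end to
end on known ground truth.

## Signal model

Each MR voxel with true bone fraction *f* produces the noiseless
two-compartment signal

    S(TE) = ρ_b · f · exp(−TE/T2*_b) + ρ_m · (1−f) · exp(−TE/T2*_m)

| parameter | default | meaning |
|---|---|---|
| TE₁, TE₂ | 0.032, 2.2 ms | echo times; TE₁ must be ≤ 0.1 ms (ultrashort) |
| T2\*_b | 0.35 ms | bone bound-water apparent transverse relaxation |
| T2\*_m | 30 ms | lumped marrow (water + fat) relaxation |
| ρ_b, ρ_m | 1.0, 1.3 | relative proton densities per unit volume |
| mr_voxel | 0.5 mm | MR voxel size (10 × the fine-grid voxel) |

Marrow water and fat are lumped into one compartment: at TE₂ = 2.2 ms at
3 T they are in phase, so no fat–water cancellation needs modelling. The
density ratio ρ_m/ρ_b > 1 encodes the higher proton density per unit
volume of fatty marrow; it makes the estimator *underestimate* BVTV. In
the idealized limit (TE₁ ≪ T2\*_b ≪ TE₂ ≪ T2\*_m, equal densities) the
estimator is exact; with a density ratio ρ it converges to
f / (f + ρ(1−f)), which is strictly below f — the systematic
underestimation seen when the method is compared against microCT. With
the realistic defaults above, marrow decay between the echoes
(1 − e^(−2.2/30) ≈ 7%) adds a compensating positive term, so the net bias
of a simulated study is smaller than the idealized algebra suggests.

Simulation is image-domain only: the analysis consumes reconstructed
magnitude images, so k-space trajectories, coils and steady-state T1/TR
weighting (which scales both echoes equally and cancels in the ratio) are
out of scope. Noise is Rician (magnitude reconstruction), per voxel per
echo, seeded; a Gaussian option exists for analytic tests. Partial-volume
mixing is exact block averaging of the fine binary microstructure — the
standard linearity assumption for proton-density-weighted magnitude
signals.

## Phantoms

Specimens are level sets of a Gaussian random field: white noise smoothed
with an isotropic Gaussian of sigma `feature_scale` (default 0.2 mm at
0.05 mm voxels) and thresholded at an empirical quantile, which pins the
realised bone fraction to the target within ~0.005. The default
construction keeps the voxels nearest the field's *zero isosurface*
("plates"): this yields plate-like trabeculae and, crucially, a connected
network (largest component > 97% of bone voxels) across the whole
physiological range 0.15–0.45. A plain upper-tail excursion set ("rods")
is also available but fragments below a bone fraction of about 0.2 — the
excursion-set percolation threshold of smooth Gaussian fields sits near
0.16, so a rods phantom at BVTV 0.15 is necessarily a suspension of
disconnected blobs, which real trabecular bone is not. Anisotropy and
morphometric realism (plate/rod mix, trabecular thickness distributions)
are deliberately not modelled: the measurand is the volume fraction, and
the estimator under test explicitly avoids trabecular-level morphology.

## MicroCT arm

The microCT forward model maps the binary microstructure to two
attenuation levels (marrow 0.1, bone 1.0, arbitrary units), blurs with a
Gaussian PSF (default 0.05 mm = 1 voxel, mirror-padded so edges are not
darkened), adds Gaussian noise, and clamps at zero. Contrast-to-noise
ratio (CNR) is (µ_bone − µ_marrow)/σ.

Segmentation uses local adaptive gray-level thresholding in overlapping
~3 mm cubic windows (50% overlap; per-window thresholds blended into a
smooth per-voxel threshold field with triangular distance weights). The
per-window criterion is **partial-volume matched** rather than Otsu's:
because the PSF preserves the window mean, the window's bone fraction is
recoverable by linearly unmixing the mean between the marrow and bone
intensity levels, and the threshold is placed at the order statistic that
reproduces that fraction. Plain per-window Otsu (retained as an option)
systematically over-segments blurred thin trabeculae — the partial-volume
halo drags the between-class optimum below the level midpoint — by +0.02
to +0.13 in bone fraction at the default feature scale, which would
swamp a 0.02 accuracy requirement.

The level estimators are the fragile part and are built for robustness:

- **Marrow level** — median of *raw* intensities over an eroded marrow
  region (3 erosion iterations strip the partial-volume halo bordering
  trabeculae; the median is immune to the scanner's zero clamp, which
  biases the mean at low CNR).
- **Bone level** — mean of raw intensities over the top 0.1% of a median
  filter whose footprint excludes the centre voxel, so that the selection
  is independent of the averaged noise. Selection is restricted to the
  array interior: reflective padding folds a border voxel's own value
  into its neighbourhood, and extreme-quantile selection otherwise
  concentrates exactly there. A global top-0.01% vs top-0.1% difference
  corrects the residual plateau deficit of thin plates (at BVTV 0.15 even
  the brightest voxels are only ~95% bone-occupied).
- **Fallbacks** — windows whose contrast is below 25% of the regional
  contrast or below 2.5 estimated noise SDs take the region-global
  threshold; if the whole region lacks credible contrast, nothing is
  segmented as bone (no 50/50 hallucination on pure marrow).
- The final threshold is clipped into the mid-band (20–80%) between the
  levels, which makes segmentation of clean bimodal inputs exact even
  when the unmixed fraction is off by a few counts.

Measured accuracy at the defaults: per-slice error ≤ 0.02 for CNR ≥ 4
across BVTV 0.15–0.45; zero voxel errors on noiseless two-level input.
Under strong smooth shading the count degrades gracefully and remains
better than a global threshold. BVTV itself is exact integer counting of
the mask; no morphological cleanup is applied by default.

## Registration and pairing

MR analysis regions are rectangles on the central slices, inset two MR
voxels from the specimen boundary (a deterministic stand-in for an
analyst drawing a global ROI that avoids specimen edges). They are mapped
to microCT space by a least-squares similarity transform (rotation +
isotropic scale + translation) fitted to matched corner landmarks; the
linear (a, b, t_x, t_y) parametrisation is solved by `lstsq` and equals
the closed-form Procrustes solution (verified to 1e-9 against an
independent SVD implementation). A similarity is deliberately minimal: a
rigid cube imaged by two calibrated scanners needs rotation and
translation plus a scale safety factor; a full affine would be
under-constrained by a handful of corners. Mapped corners are snapped to
an axis-aligned bounding box (keeps downstream grids rectangular; the
slight growth under rotation is symmetric across modalities in synthetic
mode). A transform whose landmark RMSE exceeds 0.25 mm (half an MR voxel)
is refused.

In synthetic mode the landmarks are the specimen corners (plus edge
midpoints when more than four are requested) with seeded Gaussian jitter
(default 0.05 mm) replacing the human picking step. Jitter propagation is
closed-form: the mapped-centre displacement is Rayleigh with per-axis SD
jitter/√n, so sub-voxel placement (< 0.05 mm) holds with probability
1 − e^(−n/2) — 86.5% with 4 landmarks, 98.2% with 8.

Through-plane, each 0.5 mm MR slice maps to k = 10 consecutive 0.05 mm
microCT slices; the microCT value paired with an MR slice is the mean of
its k per-slice bone fractions. A default study yields 6 specimens × 10
central slices = 60 paired measurements.

## Statistics

All computations use fractions internally; reports print percent.

- **Normality** — one-sample KS statistic against a normal with estimated
  mean/SD. Because parameters are estimated, the classical null is wrong;
  p-values come from a seeded Monte-Carlo null (Lilliefors convention,
  default 2000 simulations, memoised per sample size). Power caveat:
  KS-type tests are weak against flat symmetric alternatives (~35%
  against uniform at n = 60) though near-perfect against skewed ones.
- **Modality difference** — two-sided Wilcoxon rank-sum, as named (the
  pairing is deliberately ignored; a signed-rank option exists but is not
  the default). Groups of ≤ 10 each use full enumeration of rank
  assignments, which handles ties exactly; larger groups use the
  tie-corrected normal approximation with continuity correction.
- **Agreement** — Spearman rank correlation with a 95% percentile CI from
  a cluster bootstrap that resamples whole specimens with replacement,
  keeping each sampled specimen's full slice block. Resampling specimens
  is the standard way to respect within-specimen dependence among slices;
  percentile rather than BCa because acceleration estimates are unstable
  with six clusters. Resamples with zero rank variance are redrawn
  (counted, capped). Known limitation: with six clusters the percentile
  interval undercovers — on a Gaussian-copula population with a shared
  specimen effect at ICC 0.5, measured coverage of the population Spearman
  is ~78% rather than 95%, driven partly by the small-sample bias of the
  rank correlation itself on clustered designs (intra-cluster pairs have
  lower concordance than inter-cluster ones). CIs from six specimens
  should be read as descriptive.
- **Bias** — per-pair (microCT − MR) differences (mean, SD, range) and
  residuals of the OLS line of MR on microCT (mean zero by construction,
  asserted; SD and range reported).

## Study sizes and runtimes

The default synthetic study is scaled down from the full specimen
geometry so a complete run takes seconds rather than minutes: per
specimen, 140 × 100 × 100 fine voxels (7 × 5 × 5 mm at 50 µm) giving 14
MR slices of 10 × 10 voxels, with the central 10 analysed; the full-size
40-slice, 20 mm cube geometry is reachable through the same config. The
correlation-recovery experiments use a further reduced 100 × 80 × 80 grid
(largest in-plane size below 96 divisible by the 10:1 voxel ratio).
Reducing grid size shrinks the ROI (36 voxels per slice at defaults) and
therefore raises the noise on per-slice ROI means; it does not change any
estimator.

## What the synthetic pipeline does and does not show

Passing tests demonstrate that the estimator, segmentation, registration
and statistics are implemented correctly and behave as the underlying
physics and algebra predict under the stated forward models. They do not
validate the forward models against real tissue: real marrow has spatially
heterogeneous fat fraction (here a single effective density), real bone
T2\* varies with porosity and field (here fixed), susceptibility effects
at trabecular interfaces, chemical-shift artifacts and air inclusions are
absent, and the microCT model omits beam hardening and ring artifacts.
The synthetic correlation (r ≈ 0.95–0.99) is therefore an upper bound of
sorts: it reflects a study in which specimen-to-specimen spread dominates
measurement noise and every nuisance not modelled is absent.
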