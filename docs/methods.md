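# Methods

`locusfoci` quantifies fluorescently labeled genomic loci (FP-tagged DNA,
e.g. LacI/LacO or ParB/ParS foci) in 3D confocal stacks of *Drosophila*
imaginal-disc tissue. It implements four measurements — per-spot
signal-to-noise ratio (SNR), labeling efficiency, dual-color 3D focus
localization, and inter-locus distance distributions — together with the
statistical layer used to compare experimental groups, and a synthetic-data
generator that makes every stage testable against known ground truth.

## The measurements

### Per-spot SNR

For a seed voxel marking a candidate focus, a 40×40-pixel, 13-slice ROI is
extracted (even windows use the half-open convention `[s−20, s+20)`, so the
seed sits at local index 20; the Z window is truncated at stack boundaries,
while XY border seeds are rejected). The Z plane with maximal pixel-intensity
skewness — the population moment form `m3 / m2^{3/2}`, the convention ImageJ's
"Skewness" measure uses — locates the spot's central slice. In that slice the
maximum pixel is found, a 14×14 box centered on it is deleted by setting it to
zero, and the mean and sample (n−1) SD of the strictly positive pixels of the
28×28 box with the same center give the background, so that

    SNR = (MAX − background mean) / background SD.

Implementing "deletion" as zeroing followed by excluding zero-valued pixels
means genuinely zero background pixels are excluded too; with realistic
camera offsets this set is empty, and the behavior is kept because it is the
mechanism the thresholding step defines. The estimator assumes the 28×28
neighborhood is statistically homogeneous background. In tissue where nuclei
tile the field this holds; in sparse synthetic fields a box straddling the
nuclear boundary mixes two background levels and inflates the SD, biasing SNR
downward. Calibration is therefore validated on homogeneous-background
simulations, where the mean estimate stays within 25% of the analytic value
across SNR 5–50 (the residual positive bias at low SNR comes from
max-statistics: the reported MAX is the maximum of many noisy pixels).

### Labeling efficiency

A stack is divided into consecutive 10-slice subsections (plus a remainder
subsection when the depth is not divisible by 10); each subsection is
MAX-projected; nuclei are segmented on the DAPI projection
(Gaussian-smoothed Otsu threshold, hole filling, distance-transform
watershed, minimum-area filter); and each nucleus is scored spot-positive
when its brightest in-mask FP pixel reaches `median + k_sigma × SD` of its
own pixel distribution, with the SD estimated robustly as 1.4826 × MAD and
floored at one count (default `k_sigma = 6`). Each projection contributes one
spot+/total ratio. The k-sigma rule is an explicit automated stand-in for a
manual spot call; it reproduces the procedure's shape, not any particular
curator's counts, and `k_sigma` is surfaced in configuration and outputs.

Note one consequence of projection-based counting: a nucleus spanning two
subsections is counted in both, but its focus appears in only one, so pooled
ratios from a thin monolayer underestimate the labeling probability unless
the subsection covers whole nuclei. Validation fields are therefore 10-slice
monolayers; deep-tissue stacks, where each subsection samples a different
cell layer, are the intended use.

### 3D localization and inter-locus distances

Two detectors are implemented. The **object counter** thresholds a 15-slice,
40×40 ROI at 0.7× its global maximum, labels 26-connected components,
discards components smaller than 20 voxels, and reports the
intensity-weighted centroid of the component containing the global maximum.
The 0.7 fraction is applied to the global substack maximum (thresholding the
whole volume); the per-slice maximum step in the original procedure only
located the spot's central plane. The **DoG detector** computes a
difference-of-Gaussians response with `σ1 = diameter/(2√3)`, `σ2 = 1.6 σ1`
(11-pixel estimated diameter; axial sigmas divided by the voxel aspect
dz/dx), takes local maxima above `median + 5×MAD` of the response, and
refines each coordinate by a three-point quadratic fit. Reported distances
default to object-counter centroids, with DoG as the concordance check; on
the same simulated ROIs the two detectors' pairwise distances agree within
one voxel diagonal.

Distances are measured green-seed-first: seeds are picked in the green
channel, a 15-slice ROI is cut from both channels around each seed, foci are
localized per channel, and centroids are grouped per nucleus when a label
mask is available (per ROI otherwise). Groups with two same-color foci are
excluded as replicated (sister-chromatid) nuclei; groups missing a color are
excluded as unpaired. Two refinements make the replication screen as
sensitive as manual curation: the two-spot count includes objects down to 5
voxels (a second focus shrunk below the 20-voxel filter by its brighter
neighbor raising the 0.7×max threshold is still a visible spot), and a
single object larger than ~60 voxels — about twice a focus — is treated as
two fused foci, the call a curator makes on a dumbbell-shaped blob. Only
objects of at least 20 voxels ever anchor a reported centroid.

Sub-voxel coordinates are converted to nm by the voxel calibration and pair
distances computed as `√(Δx² + Δy² + Δz²)`. Pairs at or above 750 nm are
flagged (strictly-below keeps), not deleted: that threshold removes focus
pairs spanning neighboring nuclei. When several red candidates share an ROI
and no mask resolves them, the ROI is excluded rather than silently taking
the nearest — matching the conservatism of manual exclusion.

### Group statistics

Two groups: pooled-variance two-sided Student's t. More than two: one-way
ANOVA followed by Tukey's multiple-comparisons test at α = 0.05 in the
Tukey–Kramer form for unbalanced groups,
`q = |mean_i − mean_j| / √(MSW/2 · (1/n_i + 1/n_j))`, with adjusted p values
from the studentized range distribution (k groups, within-group df). Box
summaries follow the Tukey convention with type-7 (linear-interpolation)
quartiles — the plotting-tool default — and whiskers at the most extreme data
within 1.5×IQR. Fold change is `max(means)/min(means)` over strictly positive
group means. p values are reported to 4 significant figures with the usual
ns/*/**/***/**** labeling at α = 0.05.

The studentized-range tail probabilities come from `scipy.stats`; the test
suite checks them against an independent double-numerical-integration of the
defining CDF at (k, df) ∈ {(3,6), (4,20), (6,100)} to 1e-4, and a
2000-replicate null simulation confirms the ANOVA rejects at 5% ± 1.5% with
Tukey's family-wise error at nominal level.

## The synthetic-data generator

`generate_field` renders non-overlapping spherical nuclei (rejection
sampling, up to 1000 attempts per nucleus, then an error naming the violated
dimension) with a diffuse nuclear FP background, a dimmer cytoplasmic
background, and a solid DAPI fill. Per FP channel each nucleus carries a
focus with the labeling probability; in dual-label mode a labeled nucleus
carries one green and one red focus separated by a draw from the configured
separation (fixed, uniform, or normal). Foci are anisotropic 3D Gaussians
evaluated at voxel centers and accumulated before a single quantization:
Poisson resampling of expected counts, Gaussian read noise, offset, rounding,
and clipping to 16-bit (clipping is counted and logged). One root seed feeds
fixed-offset streams per stage and channel, so adding a channel never
perturbs existing draws, and identical configurations produce bit-identical
stacks and manifests.

Defaults — chosen once as the simulated study conditions:

| parameter | default | rationale |
|---|---|---|
| voxel size (dz, dy, dx) | (200, 65, 65) nm | typical Airyscan sampling; all distance math reads calibration from config |
| nucleus radius | 1000 ± 100 nm | imaginal-disc-scale nuclei that fit a 10–16-slice stack |
| nuclear background | 100 ± 10 counts | diffuse unbound FP pool; per-nucleus level varies |
| cytoplasm background | 20 counts | dim extra-nuclear signal |
| spot amplitude | 300 counts | analytic SNR ≈ 27, inside the 5–54 range the labeling systems span |
| spot σ lateral / axial | 150 / 400 nm | the 0.7×max support is ~25 voxels, consistent with a ~20-voxel object size and ~11 px apparent diameter |
| noise | Poisson + read SD 5 | photon-counting detection |
| doublet separation | 500 nm | resolvable sister-chromatid spacing |

Sister-chromatid doublets are placed at the configured separation in a
uniformly random **lateral** direction: at 500 nm with a 400 nm axial PSF
sigma, an axially displaced doublet renders as a single blob (the midpoint
intensity exceeds 0.7 of the peak), so an axial doublet is unobservable by
construction — the simulator models the doublets curation can actually see.

What the generator does not emulate: optical aberrations, depth-dependent
attenuation, chromatic offset between channels (channels are co-registered
by construction), nuclear-shape irregularity, tissue curvature, cell-cycle
structure, or motion. Passing tests therefore demonstrate that the
*procedures* are implemented correctly and recover known ground truth under
idealized imaging; they do not certify performance on aberrated or densely
packed real data.

`expected_snr` provides the analytic companion used only as an oracle curve:
amplitude / √(background mean + read SD²) under Poisson noise, amplitude /
read SD otherwise.

## Numerical choices and degenerate inputs

* All voxel indices are 0-based, `(z, y, x)`-ordered, half-open everywhere;
  physical coordinates are nm, `(x, y, z)`-ordered in the distance formula.
* Skewness of a zero-variance plane is defined as 0; max-skew ties take the
  lowest slice.
* Object-counter components use 26-connectivity and intensity-weighted
  centroids (recorded in output metadata); an all-zero substack yields no
  detection, with a warning.
* The DoG sub-pixel offset is clamped to ±0.5 voxel and skipped at volume
  borders.
* SNR raises "degenerate background" on zero background SD and "background
  exhausted" below 10 surviving pixels; batch operation logs and skips
  failures.
* The quadratic-fit, MAD-threshold and k-sigma constants are keyword
  arguments, not hidden constants; every run serializes its resolved
  configuration next to its outputs.

## Validation problem sizes

The shipped tests and the reproduction script size their simulations for a
single CPU: distance recovery uses ten 16×400×400-voxel fields of 12 nuclei
per true separation (~110 recovered pairs each at 260/400/600 nm),
efficiency recovery pools ~1000 nuclei from 10-slice 512×512 monolayers, the
null-calibration simulation runs 2000 three-group replicates, and the
detector-equivalence check runs 100 randomized 9×40×40 volumes against a
pure-Python flood-fill oracle. Median localization error under the default
conditions is ~10 nm per pair distance — well inside the one-lateral-voxel
(65 nm) acceptance bound.

## Known limitations

* The SNR background model is 2D (max-skew slice only), by design; no 3D
  background option exists in paper-mode geometry.
* The spot-positive call and the seed-finding gate are automated stand-ins
  for manual steps; their thresholds shape absolute efficiencies, so
  cross-condition comparisons should hold them fixed.
* The merged-doublet volume rule assumes the default amplitude-to-background
  regime; very dim foci enlarge single-spot support and could trip it.
* No chromatic-aberration registration between channels; a future affine
  hook is out of scope.
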