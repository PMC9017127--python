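# locusfoci

Quantification of fluorescently labeled genomic loci in 3D microscopy
stacks: per-spot signal-to-noise ratio, labeling efficiency, dual-color
sub-voxel focus localization with inter-locus 3D distances, and the group
statistics used to compare conditions — validated end to end on synthetic
fields with known ground truth.

## Who this is for

Labs using FP labeling systems (LacI/LacO, ParB/ParS "DNA dot" systems) to
visualize genomic regions of interest as diffraction-limited nuclear foci —
for example to measure enhancer–promoter or inter-allelic distances in
*Drosophila* imaginal discs — and who need a reproducible, scriptable
version of the standard FIJI-macro workflow: pick spots, extract fixed
ROIs, quantify SNR, count spot-positive nuclei, localize foci in two
channels, and compare distance distributions across tissues or constructs.

## The measurements

**SNR** of a focus is computed on the max-skew Z slice of a 40×40-pixel,
13-slice ROI around a seed: the maximum pixel is located, a 14×14 box
around it is deleted, and the strictly positive pixels of the 28×28 box
with the same center give the background, so

    SNR = (MAX − mean_bg) / SD_bg .

**Labeling efficiency** divides the stack into 10-slice subsections,
MAX-projects each, segments nuclei on the DAPI projection and scores each
nucleus spot-positive from its own pixel distribution (median + k·MAD
rule); every projection contributes one spot+/total ratio.

**Distances**: foci are localized in 3D per channel in 15-slice ROIs —
threshold at 0.7 × max, 26-connected objects of ≥ 20 voxels,
intensity-weighted centroid (a DoG detector with sub-pixel refinement is
the built-in cross-check) — then paired per nucleus, with nuclei showing
two same-color foci excluded as replicated, converted to nm with the voxel
calibration, and filtered at 750 nm:

    d = sqrt(Δx² + Δy² + Δz²) .

**Statistics**: pooled-variance Student's t for two groups; one-way ANOVA
with Tukey–Kramer multiple comparisons (adjusted p from the studentized
range, α = 0.05) for more; Tukey box summaries; fold change of group means.

A first-class synthetic module simulates multi-channel stacks of nuclei
with diffuse FP background, Poisson + read noise, anisotropic voxels,
tunable labeling probability, sister-chromatid doublets, and dual-color
pairs at a configurable true separation, with a full ground-truth manifest.
See `docs/methods.md` for models, parameters and limitations.

## Worked example

Simulate a dual-label field of 8 nuclei with a true pair separation of
400 nm and run the whole pipeline:

```python
from locusfoci.io import run_pipeline

summary = run_pipeline(
    {
        "simulation": {
            "n_nuclei": 8, "rng_seed": 42, "stack_dims": [10, 300, 300],
            "channels": ["green", "red", "dapi"], "dual_label": True,
            "pair_separation_nm": 400.0,
        }
    },
    "demo_out",
)
print(summary)
```

prints

```
{'n_nuclei': 8,
 'median_snr': 10.023425208704332,
 'pooled_efficiency': 1.0,
 'distance_median_nm': 394.232101979459,
 'distance_q1_nm': 392.98309874775384,
 'distance_q3_nm': 401.50926183298213,
 'n_kept_pairs': 7}
```

All 8 nuclei carry a green/red pair (labeling probability defaults to 1,
hence pooled efficiency 1.0); 7 pairs survive pairing and the 750 nm
filter, and their median recovered distance, 394 nm, sits within one-tenth
of a lateral voxel (65 nm) of the simulated 400 nm truth. The median SNR of
~10 reflects the seeds this field's green channel yields under the default
amplitude and noise. `demo_out/` contains the TIFF stacks, the ground-truth
manifest, `snr.csv`, `efficiency.csv`, `distances.csv`, `exclusions.csv`
and the resolved configuration that regenerates the run exactly.

The same stages are available from the shell:

```bash
locusfoci simulate --config cfg.json --out sim/ --seed 42
locusfoci snr --stack sim/green.tif --out snr.csv
locusfoci efficiency --fp sim/green.tif --dapi sim/dapi.tif --out eff.csv
locusfoci distance --green sim/green.tif --red sim/red.tif \
    --mask sim/nuclei_labels.tif --out dist/
locusfoci stats --input dist/distances.csv --value-col distance_nm \
    --group-col group_id --out stats.json
```

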