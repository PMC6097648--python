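# gfquant

Quantification of mixed electrical/chemical synaptic inputs onto the
*Drosophila* giant fiber (GF) from confocal image stacks.

Auditory Johnston's Organ neurons (JONs) contact the GF dendrite through
both cholinergic chemical synapses and Shaking-B (ShakB) innexin gap
junctions. Experiments that manipulate ShakB isoforms or the transcription
factor Engrailed in JON subsets ask whether gap junctions instruct the
formation of chemical synapses; answering that requires measuring, per
animal and genotype group, from multi-channel 8-bit confocal stacks:

* **dye coupling** — mean cross-sectional area of retrograde Neurobiotin
  (NB) label over a ~10 µm window centered on the anterior tip of the GF
  dendrite;
* **putative active zones (AZ)** — volume of voxelwise overlap (AND)
  between thresholded Brp-short puncta and the dye-filled GF dendrite;
* **dendrite surface area** — volume of a single-pixel outline of the GF
  mask divided by the pixel size (0.22 µm), split into a medial
  compartment beyond a plane 5 µm (23 px) medial of the dendrite center;
* **gap-junction plaques and colocalization** — ShakB plaque volume inside
  manually traced JO-A/JO-B axon territories and the percentage of ShakB
  overlapping Brp.

Each channel is binarized with the histogram auto-threshold method suited
to its signal (Intermodes for Brp, IsoData/"Default" for dye fill and NB,
Rényi entropy for ShakB) on the pooled stack histogram with saturated
white excluded. Before thresholding, large non-specific Brp-short
agglomerations are removed with a white top-hat: a radius-3 disc minimum
then maximum filter per slice, subtracted from the original, which erases
blob interiors exactly while leaving sub-micron puncta untouched. Groups
are compared per measure with one-way ANOVA followed by Tukey–Kramer HSD
(`*` p ≤ 0.05, `**` p ≤ 0.01, `***` p ≤ 0.001; N = animals).

Because raw microscopy data for this preparation are not deposited, the
package ships a synthetic phantom generator (`gfquant.phantom`) that
renders the same structures — tubular dendrite with medial branches, ~1 µm
ShakB plaques, sub-micron Brp puncta, agglomeration blobs, NB-filled
axons — at the acquisition scale (0.22 µm pixels, 1 µm slices), with
Gaussian PSF, Poisson + read noise, 8-bit quantization, and exact ground
truth, so the entire pipeline and its statistics are testable end to end.

## Worked example

```python
from gfquant import PhantomSpec, generate_phantom, PipelineConfig, run_specimen

spec = PhantomSpec(seed=1)                       # 128 x 128 x 60 phantom
channels, truth = generate_phantom(spec, channels=("GF", "NB", "Brp", "ShB"))
summary = run_specimen(PipelineConfig(), channels, region_masks=truth.region_masks)
print(f"AZ on GF dendrite : {summary.az_on_gf_volume:.1f} um^3")
print(f"GF surface area   : {summary.gf_surface_area:.0f} um^2")
print(f"NB coupling area  : {summary.nb_coupling_area:.2f} um^2")
print(f"ShB JO-A / JO-B   : {summary.shb_volume_by_region['JO-A']:.1f}"
      f" / {summary.shb_volume_by_region['JO-B']:.1f} um^3")
```

prints

```
AZ on GF dendrite : 2.8 um^3
GF surface area   : 359 um^2
NB coupling area  : 4.50 um^2
ShB JO-A / JO-B   : 14.7 / 3.1 um^3
```

i.e. this control phantom carries ~2.8 µm³ of putative active zones apposed
to the dendrite, a dye-coupling cross-section of ~4.5 µm² at the dendrite
tip, and roughly 4-fold more gap-junction plaque volume in the JO-A than
the JO-B territory — the control asymmetry the generator is built around
(ground truth for this seed: 13.4 / 2.8 µm³, so the plaque volumes are
recovered to within about 10%).

Batch analysis runs over a manifest CSV (`specimen_id, group, dx, dy, dz,
ap_axis, medial_direction` plus `channel:<name>` / `mask:<name>` path
columns):

```sh
gfquant synth --out study/ --n-per-group 4 --seed 0
gfquant run --manifest study/manifest.csv --out-dir results/
```

`results/report.json` then holds, per measure, group means ± SEM,
Shapiro–Wilk normality p per group, the ANOVA F and p, and the Tukey
pairwise table with star codes.

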