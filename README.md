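# canaliq

Canalicular histomorphometry for DAB-immunostained liver micrographs.

Bile canaliculi — the channels between apical hepatocyte membranes —
are highlighted in brown by CD10-type immunohistochemistry (DAB
chromogen over a hematoxylin counterstain). `canaliq` quantifies their
morphology from ordinary RGB brightfield photomicrographs: it isolates
the DAB signal, segments each canalicular profile, and measures a
panel of shape and intensity parameters per profile, per field, and
per patient, ending in a two-group statistical comparison. A
ground-truthed synthetic field generator makes the entire chain
verifiable without clinical material.

Intended users: liver pathology and image-cytometry researchers who
want a scripted, parameter-transparent replacement for a manual
ImageJ workflow.

## Method

For each calibrated field (µm/px supplied per manifest row):

1. **Stain separation** — Beer–Lambert color deconvolution with the
   Ruifrok–Johnston H-DAB basis. A pixel is IHC-positive when the DAB
   share of its total optical density exceeds 0.5 and total OD is above
   0.05; everything else is forced to white.
2. **8-bit conversion** — unweighted channel mean, so stained pixels
   are *dark* on a white background.
3. **Thresholding** — explicit 8-bit cut (default 200; Otsu-on-signal
   available as `auto`), recorded in every output.
4. **ROI morphometry** — 8-connected components; components under
   10 px are discarded as artefacts. Per ROI:
   - area `A = n·s²` (µm²),
   - perimeter `P` (corner-corrected boundary walk, µm),
   - Feret diameter `F = (X + Y)/2`, the mean of the projections onto
     the image axes (µm),
   - **perimeter-to-Feret ratio `P/F`** — the branching index:
     side branches lengthen the outline much faster than they extend
     the projections, so `P/F` rises with branching
     (≈ π for a disk, ≈ 4 for a filled square),
   - solidity (area / convex-hull area),
   - mean gray value `MGV` and corrected `cMGV = 255 − MGV`
     (absorbance-like: darker staining → higher cMGV).
5. **Thickness** — 2-D local thickness (largest-inscribed-disk
   diameter, the trabecular-thickness definition), averaged over the
   whole field's mask.
6. **Statistics** — fields are averaged per patient (default unit);
   groups are described as mean ± SD and compared with a two-sided
   pooled-variance Student's t-test (Welch optional). Subgroup tables
   are descriptive only.

## Worked example

```python
from canaliq import SyntheticSpec, generate_field, process_field, RunConfig

field, truth = generate_field(SyntheticSpec(seed=42), sample_id="demo",
                              group_label="control")
records, row, stain_mask, thickness = process_field(field, RunConfig())
print(f"{len(records)} ROIs, threshold {stain_mask.threshold_used}")
for r in records[:3]:
    print(f"roi {r.roi_id}: area {r.area:.2f} um2, P {r.perimeter:.2f} um, "
          f"F {r.feret:.2f} um, P/F {r.pf_ratio:.2f}, "
          f"solidity {r.solidity:.2f}, cMGV {r.cmgv:.1f}")
print(f"field mean P/F {row['pf_ratio']:.2f}, "
      f"mean thickness {row['thickness']:.2f} um")
```

prints

```
3 ROIs, threshold 200
roi 1: area 3.97 um2, P 17.85 um, F 3.95 um, P/F 4.52, solidity 0.45, cMGV 153.0
roi 2: area 9.77 um2, P 27.75 um, F 6.05 um, P/F 4.59, solidity 0.43, cMGV 152.8
roi 3: area 4.62 um2, P 19.56 um, F 4.95 um, P/F 3.95, solidity 0.40, cMGV 153.2
field mean P/F 4.35, mean thickness 0.50 um
```

Three branching tubular profiles were found at the default threshold.
Their `P/F` values (≈ 4–4.6) sit well above the convex-shape range
(π–4), as expected for branched tubes; solidity ≈ 0.4 reflects the same
concavity. cMGV ≈ 153 corresponds to the rendered DAB optical density,
and the 0.50 µm mean thickness recovers the generated 5 px tube width
at 0.1 µm/px.

The same chain runs from the shell:

```bash
canaliq simulate --spec study.yaml --out fixture/   # synthetic study
canaliq measure fixture/manifest.csv --out results/ # per-ROI + per-field CSVs
canaliq compare results/fields.csv --out results/   # group comparison CSV/JSON
```

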