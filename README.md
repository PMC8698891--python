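# vitreoct

Quantitative analysis of **vitreous parainflammation in OCT B-scans**.

In chronic glaucoma (and other retinal disease), innate immune cells —
hyalocytes, the vitreous-resident macrophages — appear in optical coherence
tomography images as small **hyperreflective opacities** floating above the
internal limiting membrane (ILM). Because the vitreous is optically almost
empty, these cells can be detected and measured non-invasively, giving an
imaging window on neuroinflammation that histology can only reach by
sacrifice. `vitreoct` implements the full analysis pipeline for such data:

- **Layer segmentation** — per-A-scan detection of the ILM and the inner and
  outer boundaries of the retinal pigment epithelium (RPE), yielding vitreous
  and RPE masks.
- **VIT/RPE relative intensity** — mean vitreous intensity divided by mean
  RPE intensity per B-scan, averaged over an eye's 61-scan series; a
  turbidity/inflammation proxy.
- **Opacity detection** — a 3×3 vertical-gradient (horizontal-edge) filter,
  Otsu binarization of the rectified response, 8-connected components
  restricted to the vitreous, and a denoising step that keeps only regions
  whose mean intensity is a Tukey upper outlier (Q3 + 1.5·IQR) relative to
  the speckle background.
- **Equivalent-ellipse morphometry** — per region: area
  (`n_pixels × 3.815 µm²` at the default 1536 × 496 px / 3 × 0.969 mm scan
  geometry), mean intensity, eccentricity `√(1 − (b/a)²)` and orientation
  (degrees in (−90°, 90°]) from the second central moments with the 1/12
  pixel-extent correction.
- **Soma-size activation classes** — isolated (<10 µm²), non-activated
  ([10, 50) µm²), activated ([50, 250] µm²) and cell complexes (>250 µm²).
- **Longitudinal cohort statistics** — KS/Lilliefors normality screening,
  one-way ANOVA with Tukey HSD post-hoc, Pearson correlations, Bonferroni
  correction.
- **A synthetic B-scan generator** with exact planted ground truth (layered
  anatomy, elliptical opacities, multiplicative gamma speckle, multi-group
  longitudinal cohorts), used to validate every stage by recovery.

Input is an eye's B-scan series as an AVI video (the device export format;
an uncompressed-AVI reader/writer is included) or a PNG/TIFF image stack.
Output is tidy CSV tables per opacity and per eye.

## Worked example

```python
import vitreoct as vo

scene = vo.make_scene((496, 1536), speckle_shape=10.0)  # default anatomy + speckle
bscan, truth = vo.render_bscan(scene, vo.default_calibration(), seed=0)

boundaries, masks = vo.segment(bscan)
ratio = vo.vit_rpe_relative_intensity(bscan, masks)
opacities = vo.detect_opacities(bscan, masks, bscan.calibration)
```

Running `python examples/01_render_and_segment.py` prints:

```
planted ILM row:      198
recovered ILM rows:   198..198
planted RPE band:     422..429
recovered RPE band:   421..429
VIT/RPE relative intensity: 0.1184
```

The segmentation recovers the planted boundaries to within a pixel and the
VIT/RPE ratio of ≈0.12 reflects a dark, quiet vitreous against the bright
RPE reference. `examples/02_detect_opacities.py` plants five tilted
elliptical opacities and prints their measured vs. planted morphometry:

```
planted 5 opacities, detected 5
 area um2 (true)   ecc (true)  orient deg (true)  class
  209.8 ( 209.8) 0.877 (0.877)   -63.7 (  -63.7)  activated
  209.8 ( 209.8) 0.877 (0.877)   -26.3 (  -26.3)  activated
  ...
```

Every planted region is found with exact area (55 px × 3.815 µm² =
209.8 µm², "activated" class) and matching eccentricity/orientation.
`examples/03_cohort_statistics.py` simulates a control-vs-glaucoma cohort
(10–20 vs. ≈70 opacities per B-scan), analyses each eye end-to-end and
rejects group equality by ANOVA at p ≈ 5×10⁻⁸.

## Command line

A thin CLI wraps the library for batch use:

```bash
vitreoct analyze --input eye.avi --animal-id r01 --side RE --group MEPI \
    --sex male --week 6 --outdir out/          # real data → CSV tables
vitreoct simulate  --eyes 3 --outdir sim/      # synthetic cohort + truth
vitreoct benchmark --eyes 2 --outdir bench/    # detection vs planted truth
vitreoct stats out/summaries.csv --outdir out/ # group statistics report
```

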