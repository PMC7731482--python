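# shgfb

Forward/backward second-harmonic-generation (SHG) scattering-ratio analysis of
tumor collagen, with downstream metastasis-free-survival stratification.

## The problem

Fibrillar collagen produces an intrinsic second-harmonic signal whose
scattering directionality depends on fiber internal structure (fibril
diameter, spacing, packing disorder). The ratio of forward- to
backward-scattered SHG intensity (**F/B**) summarizes that structure per
pixel, and the mean F/B of a region of interest is a candidate prognostic
imaging biomarker in breast cancer: tumors whose tumor–stroma interface shows
*low* F/B tend to have worse metastasis-free survival (MFS). Because tumor
collagen is spatially heterogeneous, the region sampled (cellular tumor bulk
vs the collagen-rich tumor–stroma interface) matters as much as the
measurement itself.

This package implements the full measurement-and-analysis chain for studies of
that kind, for image analysts and biostatisticians working with paired F/B SHG
micrographs and patient outcome tables:

1. **Masking** (`shgfb.masking`) — select collagen-fiber pixels three ways:
   a per-image manual intensity threshold, Otsu's histogram threshold scaled
   by 0.6, and an adaptive local-mean threshold whose window size is chosen
   automatically so no window fits wholly inside collagen-free background.
   F- and B-channel masks are combined by elementwise product.
2. **Quantification** (`shgfb.quant`) — background subtraction, per-pixel
   F/B ratio image, masked-mean F/B per ROI, per-session FITC calibration,
   3-ROI region averaging, and false-color heatmap rendering.
3. **Survival statistics** (`shgfb.survival`) — quartile assignment on
   ln F/B (Q1 = lowest), Kaplan–Meier product-limit curves with censoring
   marks, Cox proportional-hazards fits (Newton–Raphson on the Efron partial
   likelihood) with partial likelihood ratio tests, paired bulk-vs-interface
   t comparison, and the S-ODX (21-gene recurrence score) dichotomization at
   the TAILORx cutoff of 26.
4. **Risk tree** (`shgfb.tree`) — a relative-risk survival regression tree
   (one-step full-likelihood method): Nelson–Aalen baseline fixed at the
   root, per-node constant relative risk `theta = sum(d_i) / sum(L(t_i))`,
   deviance-based exhaustive cutpoint search over S-ODX plus the six F/B
   inputs (2 regions x 3 masking methods).
5. **Synthetic data** (`shgfb.synthetic`) — fiber phantoms with planted
   per-pixel F/B and cohorts with planted proportional-hazards (or
   three-risk-group step) structure, so the whole chain is testable against
   known ground truth.
6. **Pipeline + CLI** (`shgfb.pipeline`, `shgfb` command) — manifest-driven
   end-to-end runs: TIFF pairs → masks → calibrated F/B table → survival
   analyses → serialized tree, all deterministic under a fixed seed.

## Worked example

```python
import numpy as np
from shgfb import synthetic, survival, tree

# a synthetic 300-patient cohort with a protective interface-F/B effect
cohort = synthetic.generate_cohort(300, seed=7)
fit = survival.cox_fit(
    cohort.mfs_time, cohort.event, cohort.ln_fb_interface,
    covariate_names=("ln_fb_interface",),
)
print(f"interface ln F/B coefficient: {fit.coefficients[0]:+.3f} (SE {fit.std_errors[0]:.3f})")
print(f"partial likelihood ratio test: chi2 = {fit.lrt_statistic:.1f}, p = {fit.lrt_p:.2e}")

assignment = survival.quartile_assign(cohort.ln_fb_interface, cohort.patient_id)
print("quartile sizes:", assignment.group_sizes)
print("quartile boundaries (ln F/B):", [round(b, 2) for b in assignment.boundaries])

# three-risk-group recovery by the relative-risk tree
step = synthetic.generate_tree_cohort(300, seed=7)
fitted = tree.grow_tree(
    step, ["ln_fb_interface", "ln_fb_bulk", "sodx"],
    tree.TreeControls(min_node_size=20, min_events=5, max_depth=2),
)
print(tree.render_tree(fitted))
```

prints

```
interface ln F/B coefficient: -0.779 (SE 0.211)
partial likelihood ratio test: chi2 = 13.6, p = 2.27e-04
quartile sizes: (75, 75, 75, 75)
quartile boundaries (ln F/B): [2.62, 2.86, 3.09]
ln_fb_interface < 2.646  (n=300, improvement=92.6)
  yes: leaf: n=80, events=73, relative risk=3.34
  no:  sodx < 25.4  (n=220, improvement=24.7)
    yes: leaf: n=143, events=53, relative risk=0.463
    no:  leaf: n=77, events=52, relative risk=1.25
```

The Cox coefficient recovers the planted log hazard ratio of −0.8 per unit
ln F/B (risk falls as interface F/B rises), and the tree recovers the planted
structure: the low-F/B quarter of patients forms the highest-risk group
(relative risk 3.3), while the higher-F/B branch is subdivided by the
21-gene score near its planted cutoff of 25.5.

A complete run on disk — TIFF phantoms, manifest, calibration table, masks,
heatmaps, KM tables, Cox summaries, and the serialized tree:

```sh
shgfb demo ./demo_run --seed 0 --n-patients 12
```

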