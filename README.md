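# lvcoreg

Co-registration and morphometry of in-vivo and ex-vivo cardiac MR of
infarcted left ventricles.

## The problem

High-resolution ex-vivo MR of an excised, arrested heart resolves infarct
scar far better than in-vivo late gadolinium enhancement (LGE) imaging, but
the excised ventricle changes shape: the cavity collapses and the unloaded
healthy myocardium thickens much more than stiff scar. Comparing the two
acquisitions voxel-by-voxel or node-by-node therefore requires explicit
co-registration. `lvcoreg` implements the full analysis chain as a tested
Python library for imaging scientists who need to validate in-vivo scar
measurements against ex-vivo reference data:

1. **Scar segmentation** inside a given myocardial mask — in-vivo by the
   full-width-at-half-maximum rule (scar = wall voxels with
   SI ≥ ½ · SI_max of the seeded enhancing region), ex-vivo by
   SI_scar = mean(ROI) − 1·SD(ROI), both followed by a seeded
   connected-component filter.
2. **Registration** of the (downsampled) ex-vivo segmentation onto the
   in-vivo grid: landmark-based rigid fit (orthogonal Procrustes), then
   image-based rigid → affine → multi-level cubic B-spline free-form
   deformation (FFD) minimizing a sum-of-squared-differences metric on
   Gaussian-smoothed per-label indicator channels with a bending-energy
   penalty.
3. **Mesh morphometry** — marching-cubes endo/epicardial surfaces, wall
   thickness as the segment length from each endocardial node to its
   nearest epicardial node, scar transmurality as the fraction of segment
   samples inside scar voxels, nodal-wise scar DICE between paired meshes,
   and voxel-wise DICE, LV dimensions and compartment volumes.
4. **Statistics** — paired ratio tests on the log scale, one-way ANOVA
   with Tukey HSD, simple regression and Shapiro–Wilk, aggregated over
   replicates.

Because no paired animal data ship with the package, a first-class
**synthetic phantom** generates paired in-vivo/ex-vivo left ventricles with
a *known analytic deformation*: a truncated thick-walled ellipsoid whose
cavity scales by 0.83 (long axis) / 0.81 (short axes) and whose wall
thickness multiplies by 1.29 / 1.05 / 0.98 in healthy, 0–50 % and 50–100 %
transmural regions. Every downstream operator can therefore be tested as a
parameter-recovery problem. See `docs/methods.md` for the model details.

## Worked example

```bash
python examples/03_registration_chain.py
```

prints, for the default phantom pair (seed 1):

```
landmark rigid fit: residual RMS 3.30 mm (non-zero because the true change includes scaling)
landmark : wall DICE 0.721  cavity DICE 0.708
rigid    : wall DICE 0.778  cavity DICE 0.710
affine   : wall DICE 0.831  cavity DICE 0.855
ffd      : wall DICE 0.983  cavity DICE 0.992
```

The landmark fit aligns pose but cannot represent the cavity shrinkage; the
affine stage captures the global anisotropic scaling; only the non-rigid
FFD recovers the regionally varying wall-thickness change, lifting the
myocardial wall overlap above 0.93. `examples/04_morphometry.py` shows the
morphometric read-back on the same pair:

```
in-vivo endocardium: 7764 nodes, healthy wall thickness 9.92 mm (generator: 9.95 mm)
transmurality vs ground truth: mean absolute error 0.009
proportional thickness change by transmurality bin (%):
healthy  6841  27.3   low  654  6.1   high  269  0.4
```

i.e. the projection morphometry recovers the generator's imposed +29 % /
+5 % / −2 % regional thickness changes to within the mesh/voxel
discretization. The other examples cover phantom generation, both scar
segmentation rules, and the replicated group statistics.

A thin CLI mirrors the library (`lvcoreg simulate | segment | register |
morphometry | stats | run`); `lvcoreg run --out out/ --replicates 7`
executes the full replicated experiment and writes NIfTI volumes, VTK/CSV
meshes, JSON transforms, a JSON report and a run manifest.

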