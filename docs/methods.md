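# Methods

## Phantom model

The in-vivo left ventricle is modelled as a truncated thick-walled
ellipsoid. The endocardial surface is an axis-aligned ellipsoid with the
long axis on world *z* (apex at negative *z*), semiaxes (60, 25, 25) mm by
default; the wall is the *outward normal offset* of that surface by a
uniform thickness T = 9.95 mm; everything is cut at a flat mitral-valve
(MV) disc plane through the ellipsoid center, which is stored as metadata
in every label map and defines the truncation for all dimension and mesh
operations. An antero-septal scar sector (90° circumferential extent, 40 %
of the long axis, centered mid-ventricle) carries a stepped transmural
profile: the inner half of the sector (in both the angular and
longitudinal coordinate) is fully transmural (τ = 1), the surrounding rim
has τ = 0.5. Scar occupies the subendocardial fraction τ of the local wall.
Compartments are labelled background 0 / myocardium 1 / cavity 2 / scar 3
/ aorta 4, with scar superseding myocardium in storage (wall = 1 ∪ 3).

Papillary muscles are omitted by default; an optional flag adds two
endocardial bumps in the in-vivo condition only, mirroring the
segmentation convention that keeps them in the cavity compartment ex-vivo.

### Ground-truth deformation

The ex-vivo condition is produced by an analytic map in shell coordinates
(endocardial foot point **p** + normal offset d):

* cavity points scale anisotropically about the cavity centroid by
  (0.81, 0.81, 0.83) — the measured short/long-axis shrinkage ratios;
* a wall point **p** + d·**n**(**p**) maps to **p**′ + d·m(**p**)·**n**′(**p**′),
  where **p**′ is the scaled foot point, **n**′ the scaled surface's
  outward normal, and m the regional thickness multiplier — 1.29 over
  healthy tissue, 1.05 where τ ∈ (0, 0.5], 0.98 where τ ∈ (0.5, 1] —
  blended with a smoothstep over a 5 mm band across region boundaries
  (the real smoothness of the transition is unknown; 5 mm is a declared
  choice, varied freely without affecting the recovery targets beyond
  their tolerances).

Outward normal offsets of a convex surface cannot cross, so the map is
bijective on the cavity exterior with positive Jacobian throughout the
wall, and its inverse is again a closed-form foot-point decomposition
against the *scaled* ellipsoid (solved by safeguarded Newton iteration on
the standard one-dimensional root problem, to ~1e-12 mm). Ex-vivo labels
are computed by exact geometric membership of the inverse-mapped voxel
center — no label interpolation — which removes resampling bias from the
recovery targets.

### Grids, intensities, noise

In-vivo volumes use 1.2 mm isotropic voxels, ex-vivo 0.4 mm, matching the
two acquisitions the phantom emulates; both grids are snapped to a common
world frame in multiples of the in-vivo voxel so that the 3:1 integer
downsampling lands ex-vivo voxel centers exactly on in-vivo centers —
overlap metrics then measure anatomy rather than grid phase. (At even
downsampling ratios the majority vote ties on half the boundary and the
fixed tie priority resolves the ties with a systematic bias; the default
odd ratio avoids this.)

Intensities are drawn per compartment (in-vivo LGE: bright blood pool and
scar, dark remote myocardium; ex-vivo T1w: bright saline bath and scar,
dark myocardium) plus Gaussian acquisition noise with σ = 5 % of the
wall–scar contrast (a Rician option exists). Scar receives a smooth
*lognormal* enhancement texture (amplitude 15, log-σ 0.5 in-vivo;
30 / 0.7 ex-vivo; correlation ≈ 2 voxels). The positive skew matters: on a
homogeneous Gaussian scar a mean − 1 SD threshold captures exactly
Φ(1) ≈ 84 % of scar voxels regardless of the noise scale, whereas real
ex-vivo scar signal is right-skewed (heterogeneous gadolinium
accumulation), which places the mean − SD threshold near the dim edge of
the scar distribution and lets the rule recover nearly the whole scar.
The phantom reproduces that property by construction, not by tuning to any
measured outcome.

What the phantom does **not** emulate: real trabeculation and papillary
anatomy, right ventricle, intensity bias fields, partial-volume mixtures at
compartment boundaries, motion or reconstruction artifacts, and actual
biomechanics of unloading. Passing the recovery suite therefore shows the
*operators* are correct and the pipeline is self-consistent under the
imposed deformation; it does not validate the biological accuracy of the
deformation model itself.

## Segmentation

Both scar rules operate inside a given wall mask (myocardium segmentation
is taken as given, as in the manual workflow). The FWHM reference maximum
is the 99th-percentile intensity among wall voxels within 6 mm of the
seeds — a robust maximum, since a single hot voxel should not set the
threshold. The ex-vivo threshold is mean − k·SD of a scar ROI (k = 1).
Connected-component filtering (26-connectivity by default; the choice is a
declared default) keeps only components containing a seed. Manual voxel
deletion is replaced by an optional exclusion mask; no voxels are ever
added. `auto_seed_and_rois` emulates the observer deterministically:
enhancing candidates are wall voxels above Otsu's threshold, the largest
candidate component is the infarct, the seed is its brightest voxel after
2 mm smoothing, the scar ROI is the 8 mm ball of wall voxels around the
component's central voxel (a representative patch of the infarct core
rather than the hottest spot), and the remote ROI collects wall voxels
≥ 15 mm from any candidate.

Downsampling to the in-vivo grid uses an exact per-block majority vote for
integer ratios (world-space box averaging of indicator fractions
otherwise) with the fixed tie priority scar > cavity > myocardium > aorta
> background.

## Registration

All transforms map fixed-space (in-vivo) world points to moving-space
(downsampled ex-vivo) points, so only forward resampling is needed. The
similarity metric is the mean SSD over Gaussian-smoothed (σ = 1.5 mm)
indicator channels for wall, cavity and scar, equally weighted; smoothing
turns binary masks into images with usable gradients. The chain is

1. landmark rigid: closed-form Procrustes fit with reflection correction
   over shared landmark names (≥ 3, non-collinear);
2. image rigid (6 parameters) and affine (12 parameters): L-BFGS-B with
   numerical gradients on an image pyramid (factors 4, 2 by default, plus
   a short full-resolution polish for the affine); parameterized about the
   image center with matrix entries scaled so a unit parameter step moves
   points ≈ 1 mm; a stage never returns a transform worse than its
   initialization;
3. FFD: cubic B-spline displacement lattices at control spacings 20, 10,
   5 mm paired with pyramid factors 4, 2, 1. The total transform is the
   affine plus the *sum* of per-level displacement fields, optimized level
   by level with analytic gradients (adjoint B-spline scatter) and a
   bending-energy penalty λ = 1e-3 computed from second differences of
   the control coefficients (normalized per control point; exactly zero
   for any affine field). Folding is discouraged by the penalty only; a
   Jacobian check is available but not enforced, matching classic FFD
   practice. The optimization is fully deterministic — no stochastic
   sampling is used, so the config seed is inert in the default setup.

Metric voxels are restricted to the dilated union support of the fixed
channels, which cuts cost without changing the optimum. Label maps are
resampled by per-label indicator interpolation + priority argmax; scalar
volumes trilinearly. `FFDTransform.invert_points` provides fixed-point
numeric inversion when points must travel moving → fixed.

MIRTK-style settings (metric, spacing schedule, regularization weight) are
declared defaults of this implementation, not values inferred from any
particular prior toolchain.

## Morphometry

Surfaces are marching-cubes iso-surfaces (level 0.5 on the binary
indicator) of the cavity (endocardium) and cavity ∪ wall (epicardium),
truncated at the MV plane (faces within ¾ voxel of the plane dropped) and
smoothed by exactly 5 uniform Laplacian iterations (λ = 0.5) with the
boundary ring fixed — fixed iteration count keeps results deterministic.
"Projection" is interpreted literally as the straight segment from each
endocardial node to its nearest epicardial node: thickness = segment
length; samples every 0.5 × voxel (endpoints included, half-open voxel
boxes) give scar_flag (≥ 1 sample in scar) and transmurality (fraction of
samples in scar). Zero-length segments get transmurality 0 with the flag
from the single sample. Nodal scar DICE pairs each node of one mesh with
its nearest node of the other; both-empty returns 1 with a warning.

LV dimensions: long axis = distance from the cavity voxel farthest below
the MV plane to that plane; the two short-axis diameters are the principal
extents of the cavity cross-section in the one-voxel slab at 25 % of the
long axis below the MV plane (the basal level is a declared choice — the
original measurement is a manual view selection).

Transmurality bins for group statistics: healthy = scar_flag false; low =
τ ∈ (0, 0.5]; high = τ ∈ (0.5, 1] — τ = 0.5 is assigned to the low bin by
declaration.

## Statistics

Paired ratio comparisons run on log-ratios (symmetric in the two
conditions), reporting the geometric mean ratio with a 95 % t-interval;
identical inputs follow a defined degenerate path (ratio 1, p = NaN with a
warning). One-way ANOVA + Tukey HSD, simple linear regression and
Shapiro–Wilk delegate to scipy.stats, with an explicit F = 0, p = 1 path
for all-constant input. All p-values are two-tailed at α = 0.05.

## Pipeline and reproducibility

`run_experiment` runs n replicates (default 7); replicate i uses seed
(global seed + i) for the phantom and for geometric jitter (± 10 % on
semiaxes, wall thickness and scar extent) that emulates inter-animal
variability — the deformation ratios themselves are never jittered, since
they are the quantity under recovery. Reports exclude wall-clock timings
(those live in the manifest), so identical configurations produce
bit-identical report JSON; the manifest records config hash, package
version, per-file SHA-256 checksums and per-stage timings.

## Problem sizes

The default phantom uses ≈ 92×92×85 in-vivo voxels (1.2 mm) and
≈ 168×168×168 ex-vivo voxels (0.4 mm). The test suite exercises most
operators on a geometrically similar scaled-down phantom (2.0 / 1.0 mm
grids) and reserves the full-size pair for the end-to-end recovery checks;
the acceptance script uses seven full-size pairs for the dimension ratios
and one full segment–register–measure replicate for the remaining
quantities.

## Known limitations

* The FFD has no diffeomorphism guarantee; extreme regularization-free
  configurations can fold.
* The dimension operator assumes the cavity cross-section at the basal
  level is roughly convex (principal-extent diameters).
* The native thickness comparison pairs nodes by nearest neighbour after
  landmark rigid alignment; with large rotations about the long axis this
  pairing, like any geometric pairing without texture information, can
  slip circumferentially.
* Segmentation assumes the wall mask is correct; errors in the given
  myocardium segmentation propagate unchecked.
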