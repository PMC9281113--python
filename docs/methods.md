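# Methods

## Signal model and phantom

The generator emulates a multi-slice 2-D gradient-echo acquisition of a
mouse brain: a uniform-tissue ellipse (semi-axes 45% of the in-plane field,
so the section covers ~64% of the field of view) on an air background,
imaged at an ascending ladder of echo times under mono-exponential decay
`S(TE) = S0·exp(−R2*·TE)`. Defaults follow the target protocol: 256×256
in-plane matrix at 0.0625 mm (16 mm FOV / 256), 22 slices of 0.5 mm,
echoes at 10/20/30/40 ms. Tissue `S0 = 100` (arbitrary units) and
`R2* = 0.04 ms⁻¹` (T2* = 25 ms, a typical cortical value at high field).
Four echoes are the minimum comfortable basis for a decay fit while keeping
the largest TE (40 ms) in the regime where tissue still has signal but a
labeled plaque does not.

**Plaques** are spheres that add `ΔR2*` to the decay rate. Their diameters
(0.16–0.30 mm in the reference study) sit at or below the voxel scale, so
boundary voxels are rendered with fractional fill: each voxel's added rate
is `ΔR2*` scaled by the fraction of the voxel inside the sphere, evaluated
on a midpoint sub-grid fine enough (sub-cell ≈ radius/6, at least 4 per
axis) that the summed fraction reproduces the analytic sphere volume to
better than 2%. Partial volume, not edge blur, is the dominant effect at
this scale, and it is what makes through-plane quantification hard (below).

**Contrast calibration.** The reference phantom (`study_phantom_spec`)
draws radii uniformly from 0.08–0.15 mm and places centers uniformly in a
margin-shrunk brain ellipse with ≥ 1.2 mm separation (so each plaque's
annulus statistics are uncontaminated by neighbors). Each plaque's `ΔR2*`
is set so that its *darkest rendered voxel* has a contrast ratio of 0.4 to
tissue at the 10 ms detection echo — the iron load is defined by the
contrast it produces, which is how SPIO-labeled plaques present in vivo,
and 0.4 leaves a comfortable margin below the 0.6 detection threshold under
2% noise. A corollary worth knowing: a sphere straddling a slice boundary
splits its fill fraction between two slices, so hitting the same observed
contrast implies roughly twice the iron; such plaques are genuinely
"heavier" and their apparent (threshold) volume overshoots.

**Noise** is Rician with `σ = 0.02·S0` per channel: Gaussian noise is added
to the clean signal in both quadrature channels and the magnitude taken,
reproducing the Rayleigh floor in air and the signal-dependent bias near
zero. The generator is a pure function of its spec (including the seed):
identical specs give bit-identical volumes.

What the phantom does **not** emulate: k-space sampling, B0 inhomogeneity
and susceptibility blooming beyond the sphere boundary, coil sensitivity
profiles, motion, vessels and other dark structures, partial-brain slices,
or spatially varying tissue T2*. Passing recovery tests therefore
demonstrates correctness of the measurement chain under the stated physics,
not robustness to every in vivo confound — in particular the long-TE filter
is only challenged by single-echo artifacts, not by veins, which also decay.

## Detection

"Darker than the surrounding tissue" is operationalized per slice as
`I(v) < alpha · median(annulus(v))`, with a 7×7 window minus the central
3×3 (the core is excluded so a plaque does not raise its own background
estimate) and `alpha = 0.6`. The annulus holds an even number of voxels;
the median is the rank-`n//2` order statistic, chosen to match the
separable rank filter exactly so the scanning and per-site paths agree to
the bit. 8-connected seeds merge into one candidate anchored at the darkest
voxel (ties broken lexicographically). Detection is per-slice because the
acquisition is multi-slice 2-D; merging across slices happens after
resampling, in component labeling.

**Long-TE filter.** A candidate survives iff (a) its site-mean/annulus
contrast at the largest TE is at most its detection-TE contrast minus
`depth_margin = 0.05`, and (b) the log-linear fit of its site means against
TE has r² ≥ `min_r2 = 0.9`. For (b) the fit excludes echoes whose site mean
has fallen below 2× the air noise floor (the median magnitude outside the
brain mask): the Rician floor flattens the tail of a genuinely decaying
series and would otherwise reject true plaques; truncating at the floor is
standard in R2* estimation. At least the first two echoes are always kept,
so a single-echo artifact — dark at the detection echo, ordinary elsewhere
— still presents a non-monotone series and fails both conditions.

## Resampling and segmentation

The detection-echo volume is resampled to 0.0625 × 0.0625 × 0.1 mm by
trilinear interpolation under a shared corner-origin, center-of-voxel
convention (voxel *i* is centered at `(i+0.5)·spacing`); sampling points
beyond the outermost input centers clamp to the edge. The implementation
(one `map_coordinates` call) is tested against an independent per-voxel
trilinear evaluator to 1e-9.

Segmentation region-grows (26-connectivity) from each kept candidate over
voxels darker than `alpha_seg` times the local in-plane annulus median on
the resampled image, computed on patches around each seed (exact, since the
annulus is local). A global threshold would bleed into any dark background
structure; seeding restricts segments to vetted sites. `alpha_seg` was
**calibrated on phantoms with known truth**: 0.6 inflates total volume by
~+21% (the threshold crosses far down the through-plane interpolation
ramp), 0.55 deflates by ~−20%; 0.57 zeroes the bias and is the default.
On real data no such truth exists — the calibration transfers only insofar
as the contrast-depth distribution does.

## Volumetry and reported metrics

Connected components of the segmented mask (26-connectivity by default;
regions under `min_voxels = 2` resampled voxels are discarded as speckle
and counted separately) are ordered by their lexicographically smallest
voxel. Volume is voxel count × voxel volume (3.90625×10⁻⁴ mm³ on the
default grid); 3-D sizes are reported as sphere-equivalent diameters
`10³·(6V/π)^(1/3)` µm, 2-D areas as circle-equivalent diameters `2·√(A/π)`.
Per-slice metrics (8-connected 2-D components, areas in µm², percent of the
brain section occupied) mirror slice-wise reading of in vivo scans; slices
without brain are flagged undefined and excluded from averages. Labeling is
verified against brute-force flood fill on random masks at 6, 18 and 26
connectivity.

**Accuracy limits.** On the reference conditions (ten noise realizations),
the pipeline recovers ~100% of plaques with no false positives, and total
volume to ~10% mean absolute error. Per-plaque volumes carry ~33% mean
absolute error, and this is *not* noise: the noiseless error is the same.
A 0.16–0.30 mm sphere inside a 0.5 mm slice darkens the whole voxel column
by its fill fraction; after trilinear resampling its apparent through-plane
extent is governed by the slice grid (≈0.33–0.8 mm depending on where the
sphere sits relative to slice boundaries), not by the sphere. No voxel-
counting threshold estimator can recover sub-slice extents; the errors
largely cancel in the total but scatter ~2× on individual plaques, with
slice-straddling plaques biased high. Finer native slices, not
post-processing, are the remedy.

## Relaxometry

`fit_decay` is log-linear least squares on `ln S` vs TE — deterministic, no
initialization, exact on noiseless exponentials, and reduces to the
two-point closed form at n = 2. Non-positive intensities are floored at
`1e-6·max` and flagged. r² of constant data is defined as 1 (a flat line is
a perfect fit; the no-decay case is handled by the depth condition, not the
fit quality). Monte Carlo at 1% noise recovers the generating rate within
0.3% in the mean. `fit_relaxivity` is ordinary least squares of relaxation
rate (s⁻¹) against iron concentration (mM) over a dilution series; rates
convert at the interface (`1000/T2[ms]`, or `−ln(S/S0)/TE·1000` from a
single-TE intensity). Rates are ms⁻¹ internally on the imaging side and
s⁻¹ in relaxivity tables.

## Formulation arithmetic

Closed forms, all in percent: loading rate = drug in nanoparticles /
nanoparticle mass; encapsulation rate = drug in nanoparticles / drug fed;
hemolysis = (As−An)/(Ap−An), reported unclipped with an out-of-range flag;
theoretical component fraction = target part / sum of ratio parts (the
parts-over-total reading reproduces both canonical anchors, 50% at 1:1 and
25% at 2:2:2:1:1). Reports round to one decimal; full precision is kept
internally.

## Determinism and problem sizes

All randomness flows from explicit integer seeds (`numpy` PCG64); repeated
runs with a fixed input and config produce byte-identical report JSON
(sorted keys, fixed layout). The validation studies use ten full-protocol
phantoms (256×256×22, four echoes, 30 plaques each) — large enough that
sensitivity and volume means stabilize to the percent level, small enough
to run in ~1.5 minutes on one CPU. Recovery is scored by matching component
centroids to truth centers within 0.5 mm, unambiguous at the enforced
1.2 mm minimum plaque separation.
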