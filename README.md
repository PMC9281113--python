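# plaquevol

Detection, counting and volume measurement of SPIO-labeled amyloid plaques
on multi-echo T2\*-weighted MRI of the rodent brain — with a physics-based
synthetic phantom generator for validating every stage against known ground
truth.

Superparamagnetic iron oxide (SPIO) contrast agents bound near amyloid
plaques shorten the local effective transverse relaxation time T2\*
(equivalently raise the rate R2\* = 1/T2\*), so labeled plaques appear as
small dark foci on gradient-echo images, and the hypointensity deepens with
echo time TE as `S(TE) = S0 · exp(−R2*·TE)`. `plaquevol` turns that physics
into a quantification pipeline:

1. **Brain masking** — Otsu two-class split, largest connected component,
   slice-wise hole filling and closing.
2. **Candidate detection** on the shortest-TE echo — a voxel seeds a
   candidate when its intensity falls below `alpha` (default 0.6) times the
   median of its surrounding in-plane annulus (window 7, 3×3 core removed);
   8-connected seeds merge per slice.
3. **Long-TE false-positive elimination** — a genuine SPIO focus deepens
   with TE (contrast ratio ∝ `exp(−ΔR2*·TE)`), single-echo noise does not.
   Candidates are kept only if their contrast at the largest TE is deeper
   than at the detection TE by `depth_margin` and their site-mean intensity
   series is mono-exponential-consistent (r² ≥ `min_r2`, fit truncated at
   the Rician noise floor).
4. **Semi-3D resampling** — trilinear interpolation of the anisotropic
   multi-slice stack onto a 0.0625 × 0.0625 × 0.1 mm grid, so plaques
   spanning adjacent thick slices become single 3-D objects.
5. **Seeded threshold segmentation** — region growing from each surviving
   candidate over voxels darker than `alpha_seg` (default 0.57, calibrated
   on phantoms with known truth) times the local annulus median.
6. **3-D connected-component volumetry** — one component per plaque
   (26-connectivity), volume = voxel count × voxel volume, sphere-equivalent
   diameters, plus per-slice 2-D counts, areas (circle-equivalent diameter
   `2·√(A/π)`) and percent of the brain section occupied.

The package also provides the supporting relaxometry (log-linear R2\*
fitting; relaxivity r2 in s⁻¹·mM⁻¹ as the OLS slope of relaxation rate
against iron concentration over a dilution series) and the closed-form
nanoparticle formulation arithmetic (loading rate, encapsulation rate,
hemolysis ratio, theoretical composition fractions).

## Worked example

Generate the reference phantom — 30 disjoint spherical plaques (radius
0.08–0.15 mm, darkest-voxel contrast ratio 0.4 at TE 10 ms) in an
elliptical brain imaged at TE 10/20/30/40 ms with 2% Rician noise — and
quantify it:

```python
from plaquevol import study_phantom_spec, generate_phantom, quantify

spec = study_phantom_spec(n_plaques=30, seed=0)
mev, truths = generate_phantom(spec)
report = quantify(mev)
print(f"detected        : {report.total_count}")
print(f"measured volume : {report.total_volume_mm3:.4f} mm^3")
```

prints

```
planted plaques : 30
true volume     : 0.2113 mm^3
detected        : 30
measured volume : 0.2078 mm^3
candidates      : 35 (35 kept)
largest plaque  : 0.0195 mm^3 (sphere-equivalent diameter 334.1 um)
```

All 30 planted plaques are recovered with no false positives, and the
total measured volume agrees with the planted volume to within a few
percent. Per-plaque volumes are less certain: these plaques are thinner
than the 0.5 mm native slice, so an individual apparent volume depends on
where the sphere falls relative to the slice grid (see
`docs/methods.md`).

The same pipeline is available from the shell:

```bash
plaquevol simulate --n-plaques 30 --seed 0 --out-dir sim/
plaquevol quantify --echo sim/echo_te10ms.nii --te 10 \
                   --echo sim/echo_te20ms.nii --te 20 \
                   --echo sim/echo_te30ms.nii --te 30 \
                   --echo sim/echo_te40ms.nii --te 40 \
                   --out-dir results/
plaquevol relaxivity --table dilution.csv --out r2.json
plaquevol formulation --table masses.csv --out formulation.json
```

`quantify` writes `report.json` (canonical, byte-stable), `components.csv`,
`slices.csv` and the segmentation mask as NIfTI.

### Conventions

In-memory arrays are indexed `(slice, row, col)`; spacing tuples are
`(row, col, slice)` in mm; world coordinates are mm from the volume corner
with voxel centers at `(i + 0.5) · spacing`; voxel indices are 0-based.
NIfTI files store axes `(row, col, slice)` with spacing on the affine
diagonal. Decay rates are ms⁻¹ on the imaging side and s⁻¹ in relaxivity
tables (×1000 at the interface).

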