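import math
from collections import deque

import numpy as np
import pytest
from scipy import ndimage

from plaquevol.config import PipelineConfig
from plaquevol.phantom import PhantomSpec, PlaqueTruth, generate_phantom
from plaquevol.volumetry import (
    PipelineStageError,
    circle_equivalent_diameter,
    label_components,
    map_index_to_grid,
    quantify,
    resample_semi3d,
    segment_threshold,
    slice_metrics,
    sphere_equivalent_diameter,
)
from tests.conftest import SMALL_KW, SMALL_PLAQUES

OUT_SP = (0.0625, 0.0625, 0.1)


def brute_force_trilinear(vol, in_spacing, out_spacing):
    """Per-voxel trilinear evaluation under the center-of-voxel convention,
    clamped to edge values; independent of the implementation path."""
    in_sp = (in_spacing[2], in_spacing[0], in_spacing[1])
    out_sp = (out_spacing[2], out_spacing[0], out_spacing[1])
    shape = [int(math.floor(n * i / o + 1e-9)) for n, i, o in zip(vol.shape, in_sp, out_sp)]
    out = np.zeros(shape)
    for a in range(shape[0]):
        for b in range(shape[1]):
            for c in range(shape[2]):
                idx = []
                for k, (j, isp, osp, n) in enumerate(
                    zip((a, b, c), in_sp, out_sp, vol.shape)
                ):
                    x = ((j + 0.5) * osp) / isp - 0.5
                    idx.append(min(max(x, 0.0), n - 1))
                z0, y0, x0 = (int(math.floor(v)) for v in idx)
                z1, y1, x1 = (min(v + 1, n - 1) for v, n in zip((z0, y0, x0), vol.shape))
                fz, fy, fx = (v - int(math.floor(v)) for v in idx)
                acc = 0.0
                for dz, wz in ((z0, 1 - fz), (z1, fz)):
                    for dy, wy in ((y0, 1 - fy), (y1, fy)):
                        for dx, wx in ((x0, 1 - fx), (x1, fx)):
                            acc += wz * wy * wx * vol[dz, dy, dx]
                out[a, b, c] = acc
    return out


def brute_force_flood_fill(mask, connectivity):
    """BFS flood fill; returns a set of frozensets, one per component."""
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if (connectivity, order) in {(6, 1)} or connectivity == 26 or (
                    connectivity == 18 and order <= 2
                ):
                    offsets.append((dz, dy, dx))
    seen = np.zeros_like(mask, dtype=bool)
    comps = set()
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            z, y, x = queue.popleft()
            comp.add((z, y, x))
            for dz, dy, dx in offsets:
                nz, ny, nx = z + dz, y + dy, x + dx
                if (
                    0 <= nz < mask.shape[0]
                    and 0 <= ny < mask.shape[1]
                    and 0 <= nx < mask.shape[2]
                    and mask[nz, ny, nx]
                    and not seen[nz, ny, nx]
                ):
                    seen[nz, ny, nx] = True
                    queue.append((nz, ny, nx))
        comps.add(frozenset(comp))
    return comps


class TestResample:
    def test_constant_image_preserved(self):
        vol = np.full((4, 8, 8), 3.5)
        out = resample_semi3d(vol, (0.0625, 0.0625, 0.5), OUT_SP)
        assert out.shape == (20, 8, 8)
        assert np.allclose(out, 3.5)

    def test_linear_ramp_in_z_reproduced_exactly(self):
        # values linear in world z are invariant under linear interpolation
        n_slices = 6
        sp_in = (0.0625, 0.0625, 0.5)
        z_world = (np.arange(n_slices) + 0.5) * sp_in[2]
        vol = np.broadcast_to(z_world[:, None, None], (n_slices, 4, 4)).copy()
        out = resample_semi3d(vol, sp_in, OUT_SP)
        z_out = (np.arange(out.shape[0]) + 0.5) * OUT_SP[2]
        expected = np.clip(z_out, z_world[0], z_world[-1])  # clamped beyond centers
        assert np.allclose(out, expected[:, None, None], atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        vol = rng.random((4, 8, 8))
        in_sp = (0.0625, 0.0625, 0.5)
        out = resample_semi3d(vol, in_sp, OUT_SP)
        expected = brute_force_trilinear(vol, in_sp, OUT_SP)
        np.testing.assert_allclose(out, expected, atol=1e-9)

    def test_rejects_oversized_output_spacing(self):
        with pytest.raises(ValueError):
            resample_semi3d(np.ones((2, 4, 4)), (0.1, 0.1, 0.1), (10.0, 0.1, 0.1))

    def test_map_index_to_grid_center_convention(self):
        # native slice 3 (center z = 1.75 mm) lands in resampled slice 17
        idx = map_index_to_grid((3, 10, 20), (0.0625, 0.0625, 0.5), OUT_SP, (40, 96, 96))
        assert idx == (17, 10, 20)


class TestSegmentThreshold:
    def test_no_seeds_empty_mask(self):
        out = segment_threshold(np.ones((4, 16, 16)), [])
        assert not out.any()

    def test_single_plaque_mask_within_one_voxel_shell(self):
        """Noiseless sphere: segmentation within one resampled voxel of truth."""
        spec = PhantomSpec(
            plaques=[PlaqueTruth(center=(3.0, 3.0, 1.75), radius=0.14, delta_r2star=0.25)],
            noise_sigma=0.0,
            **SMALL_KW,
        )
        mev, truths = generate_phantom(spec)
        res = resample_semi3d(mev.volumes[0], spec.spacing, OUT_SP)
        t = truths[0]
        seed = (
            int(t.center[2] / OUT_SP[2]),
            int(t.center[0] / OUT_SP[0]),
            int(t.center[1] / OUT_SP[1]),
        )
        seg = segment_threshold(res, [seed])
        assert seg.any()
        zz = (np.arange(res.shape[0]) + 0.5) * OUT_SP[2]
        rr = (np.arange(res.shape[1]) + 0.5) * OUT_SP[0]
        cc = (np.arange(res.shape[2]) + 0.5) * OUT_SP[1]
        d2 = (
            (zz[:, None, None] - t.center[2]) ** 2
            + (rr[None, :, None] - t.center[0]) ** 2
            + (cc[None, None, :] - t.center[1]) ** 2
        )
        truth_region = d2 <= t.radius**2
        ball = np.ones((3, 3, 3), dtype=bool)
        assert not (seg & ~ndimage.binary_dilation(truth_region, ball)).any()
        assert (seg | ~ndimage.binary_erosion(truth_region, ball)).all()

    def test_two_disjoint_plaques_give_two_disjoint_regions(
        self, small_phantom_noiseless, small_spec_noiseless
    ):
        mev, truths = small_phantom_noiseless
        res = resample_semi3d(mev.volumes[0], small_spec_noiseless.spacing, OUT_SP)
        seeds = [
            (
                int(t.center[2] / OUT_SP[2]),
                int(t.center[0] / OUT_SP[0]),
                int(t.center[1] / OUT_SP[1]),
            )
            for t in truths[:2]
        ]
        seg = segment_threshold(res, seeds)
        comps = brute_force_flood_fill(seg, 26)
        assert len(comps) == 2

    def test_deterministic(self, small_phantom_noisy, small_spec_noisy):
        mev, truths = small_phantom_noisy
        res = resample_semi3d(mev.volumes[0], small_spec_noisy.spacing, OUT_SP)
        t = truths[0]
        seed = (
            int(t.center[2] / OUT_SP[2]),
            int(t.center[0] / OUT_SP[0]),
            int(t.center[1] / OUT_SP[1]),
        )
        a = segment_threshold(res, [seed])
        b = segment_threshold(res, [seed])
        np.testing.assert_array_equal(a, b)


class TestLabelComponents:
    def test_cube_arithmetic(self):
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        comps, discarded = label_components(mask, OUT_SP)
        assert discarded == 0
        assert len(comps) == 1
        assert comps[0].voxel_count == 27
        assert comps[0].volume_mm3 == pytest.approx(27 * 0.0625 * 0.0625 * 0.1)
        assert comps[0].slice_extent == (2, 4)

    def test_corner_touch_connectivity(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        comps26, _ = label_components(mask, OUT_SP, connectivity=26, min_voxels=1)
        comps6, _ = label_components(mask, OUT_SP, connectivity=6, min_voxels=1)
        assert len(comps26) == 1
        assert len(comps6) == 2

    def test_min_voxels_discards_speckle(self):
        mask = np.zeros((4, 8, 8), dtype=bool)
        mask[0, 0, 0] = True  # single voxel
        mask[2, 2:4, 2:4] = True  # 4 voxels
        comps, discarded = label_components(mask, OUT_SP, min_voxels=2)
        assert discarded == 1
        assert len(comps) == 1 and comps[0].voxel_count == 4

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_brute_force_flood_fill(self, connectivity, rng):
        for _ in range(20):
            mask = rng.random((12, 12, 12)) < 0.25
            comps, _ = label_components(mask, OUT_SP, connectivity, min_voxels=1)
            expected = brute_force_flood_fill(mask, connectivity)
            assert len(comps) == len(expected)
            assert sorted(c.voxel_count for c in comps) == sorted(
                len(s) for s in expected
            )

    def test_volume_conservation(self, rng):
        mask = rng.random((10, 10, 10)) < 0.3
        comps, _ = label_components(mask, OUT_SP, min_voxels=1)
        voxel_vol = OUT_SP[0] * OUT_SP[1] * OUT_SP[2]
        assert sum(c.volume_mm3 for c in comps) == pytest.approx(mask.sum() * voxel_vol)

    def test_labels_ordered_by_first_voxel(self):
        mask = np.zeros((4, 8, 8), dtype=bool)
        mask[3, 6:8, 6:8] = True
        mask[0, 1:3, 1:3] = True
        comps, _ = label_components(mask, OUT_SP)
        assert comps[0].slice_extent[0] < comps[1].slice_extent[0]
        assert [c.label for c in comps] == [1, 2]


class TestDiameters:
    @pytest.mark.parametrize(
        "area, expected",
        [(934.4, 34.5), (math.pi, 2.0), (0.0, 0.0)],
    )
    def test_circle_equivalent_diameter(self, area, expected):
        assert round(circle_equivalent_diameter(area), 1) == expected

    def test_sphere_equivalent_diameter(self):
        # sphere of diameter 100 um has volume (4/3) pi 0.05^3 mm^3
        vol = 4.0 / 3.0 * math.pi * 0.05**3
        assert sphere_equivalent_diameter(vol) == pytest.approx(100.0, rel=1e-12)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            circle_equivalent_diameter(-1.0)
        with pytest.raises(ValueError):
            sphere_equivalent_diameter(-1.0)


class TestSliceMetrics:
    def test_empty_plaque_mask(self):
        brain = np.ones((16, 16), dtype=bool)
        m = slice_metrics(np.zeros_like(brain), brain, (0.0625, 0.0625))
        assert (m.plaque_count, m.area_fraction_pct, m.plaque_areas_um2) == (0, 0.0, ())

    def test_full_coverage_is_100_percent(self):
        brain = np.ones((8, 8), dtype=bool)
        m = slice_metrics(brain, brain, (0.0625, 0.0625))
        assert m.area_fraction_pct == pytest.approx(100.0)

    def test_four_voxel_square_area(self):
        brain = np.ones((16, 16), dtype=bool)
        plaque = np.zeros_like(brain)
        plaque[4:6, 4:6] = True
        m = slice_metrics(plaque, brain, (0.0625, 0.0625))
        assert m.plaque_count == 1
        assert m.plaque_areas_um2[0] == pytest.approx(15625.0)

    def test_empty_brain_slice_flagged_undefined(self):
        m = slice_metrics(np.zeros((4, 4), bool), np.zeros((4, 4), bool), (0.0625, 0.0625))
        assert not m.defined


class TestQuantify:
    def test_plaque_free_phantom_reports_zero(self):
        spec = PhantomSpec(plaques=[], noise_sigma=0.0, **SMALL_KW)
        mev, _ = generate_phantom(spec)
        report = quantify(mev)
        assert report.total_count == 0
        assert report.total_volume_mm3 == 0.0
        assert all(s.plaque_count == 0 for s in report.per_slice if s.defined)

    def test_recovers_planted_plaques(self, small_phantom_noisy):
        mev, truths = small_phantom_noisy
        report = quantify(mev)
        assert report.total_count == len(truths)
        assert report.total_volume_mm3 == pytest.approx(
            sum(t.true_volume for t in truths), rel=0.6
        )

    def test_total_volume_equals_sum_of_components(self, small_phantom_noisy):
        report = quantify(small_phantom_noisy[0])
        assert report.total_volume_mm3 == pytest.approx(
            sum(c.volume_mm3 for c in report.components), abs=1e-12
        )
        assert report.total_count == len(report.components)

    def test_adding_disjoint_plaque_never_decreases_count(self):
        base = PhantomSpec(plaques=list(SMALL_PLAQUES), noise_sigma=0.0, **SMALL_KW)
        extra = PhantomSpec(
            plaques=list(SMALL_PLAQUES)
            + [PlaqueTruth(center=(3.0, 1.8, 3.25), radius=0.12, delta_r2star=0.3)],
            noise_sigma=0.0,
            **SMALL_KW,
        )
        n_base = quantify(generate_phantom(base)[0]).total_count
        n_extra = quantify(generate_phantom(extra)[0]).total_count
        assert n_extra >= n_base

    def test_report_parameters_echo_config(self, small_phantom_noisy):
        cfg = PipelineConfig(alpha=0.55, min_voxels=3)
        report = quantify(small_phantom_noisy[0], cfg)
        assert report.parameters["config"] == cfg.to_dict()

    def test_stage_errors_are_tagged(self):
        mev_bad = generate_phantom(
            PhantomSpec(plaques=[], noise_sigma=0.0, **SMALL_KW)
        )[0]
        for v in mev_bad.volumes:
            v[:] = 1.0  # constant image: brain masking is impossible
        with pytest.raises(PipelineStageError) as err:
            quantify(mev_bad)
        assert err.value.stage == "brain_mask"
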