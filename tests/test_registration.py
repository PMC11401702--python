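"""FA -> SLO registration: vessel maps, rigid phase, local phase, mapping."""

import numpy as np
import pytest
from skimage.filters import threshold_otsu

from octma.registration import (
    AffineParams,
    SearchGrid,
    StackGeometry,
    _warp_rot_scale,
    _xcorr_translation,
    _zncc_patch,
    extract_vessel_map,
    map_fa_point_to_bscan,
    phase1_rigid,
    phase2_local,
)
from octma.synthetic import SyntheticConfig, WarpParams, generate_enface_pair


def _pair(rotation=0.0, scale=1.0, translation=(0.0, 0.0), local=0.0, seed=0, noise=0.01):
    cfg = SyntheticConfig(
        enface_noise=noise,
        warp=WarpParams(
            rotation_deg=rotation, scale=scale, translation=translation, local_amplitude=local
        ),
    )
    return generate_enface_pair(cfg, seed)


def dice(a, b):
    return 2.0 * np.sum(a & b) / (a.sum() + b.sum())


class TestVesselMap:
    def test_straight_stroke_recovered(self):
        img = np.full((200, 200), 0.1)
        rows = np.arange(200)[:, None]
        img += 0.7 * np.exp(-((rows - 100.0) ** 2) / (2 * 2.5**2))  # horizontal vessel
        vmap = extract_vessel_map(img, "FA").image
        # stroke core: centerline +- 1 px (the ridge filter dips at the
        # Gaussian profile's shoulders by construction)
        stroke = np.zeros_like(img, dtype=bool)
        stroke[99:102, 10:190] = True
        thr = threshold_otsu(vmap)
        assert np.mean(vmap[stroke] > thr) >= 0.8

    def test_constant_image_zero_map(self):
        vmap = extract_vessel_map(np.full((50, 60), 0.4), "SLO")
        assert np.array_equal(vmap.image, np.zeros((50, 60)))

    def test_identity_pair_maps_agree(self):
        fa, slo, _ = _pair(noise=0.0)
        fmap = extract_vessel_map(fa, "FA").image
        smap = extract_vessel_map(slo, "SLO").image
        fmask = fmap > threshold_otsu(fmap)
        smask = smap > threshold_otsu(smap)
        assert dice(fmask, smask) >= 0.9

    def test_unknown_modality_rejected(self):
        with pytest.raises(ValueError):
            extract_vessel_map(np.zeros((10, 10)), "OCTA")


class TestPhase1Rigid:
    def test_identical_maps_identity_with_full_correlation(self):
        fa, _, _ = _pair(noise=0.0)
        vmap = extract_vessel_map(fa, "FA")
        grid = SearchGrid(
            rotations=np.array([-1.0, 0.0, 1.0]),
            scales=np.array([0.98, 1.0, 1.02]),
            coarse_downsample=1,
            mid_downsample=1,
        )
        aff = phase1_rigid(vmap, vmap, grid)
        assert aff.rotation == 0.0 and aff.scale == 1.0
        assert aff.translation == (0.0, 0.0)
        assert aff.correlation_score > 1.0 - 1e-9

    def test_recovers_known_warp_to_fine_step(self):
        fa, slo, _ = _pair(rotation=5.0, scale=1.05, translation=(10, -6), seed=3)
        aff = phase1_rigid(extract_vessel_map(fa, "FA"), extract_vessel_map(slo, "SLO"))
        assert abs(aff.rotation - 5.0) <= 0.1
        assert abs(aff.scale - 1.05) <= 0.005
        assert abs(aff.translation[0] - 10) <= 1 and abs(aff.translation[1] + 6) <= 1

    def test_never_scores_below_exhaustive_grid(self):
        """Brute-force oracle: scan the full coarse grid with the same
        scorer; the multistep result must match or beat it."""
        fa, slo, _ = _pair(rotation=2.0, scale=0.98, seed=5)
        fmap = extract_vessel_map(fa, "FA").image[::4, ::4]
        smap = extract_vessel_map(slo, "SLO").image[::4, ::4]
        rotations = np.arange(-4.0, 4.1, 2.0)
        scales = np.array([0.96, 1.0, 1.04])
        grid = SearchGrid(
            rotations=rotations, scales=scales, coarse_downsample=1, mid_downsample=1
        )
        from octma.registration import VesselMap

        aff = phase1_rigid(VesselMap(fmap, "FA"), VesselMap(smap, "SLO"), grid)
        for rot in rotations:
            for sc in scales:
                _, _, score = _xcorr_translation(_warp_rot_scale(fmap, rot, sc), smap)
                assert aff.correlation_score >= score - 1e-9

    def test_disjoint_maps_report_nonpositive_score(self):
        from octma.registration import VesselMap

        a = np.zeros((64, 64))
        a[5:15, 5:15] = 1.0
        b = np.zeros((64, 64))
        b[45:55, 45:55] = 1.0
        grid = SearchGrid(
            rotations=np.array([0.0]),
            scales=np.array([1.0]),
            coarse_downsample=1,
            mid_downsample=1,
            max_translation=0,
        )
        aff = phase1_rigid(VesselMap(a, "FA"), VesselMap(b, "SLO"), grid)
        assert aff.correlation_score <= 0.0

    def test_empty_grid_and_zero_map_rejected(self):
        from octma.registration import VesselMap

        fa, _, _ = _pair()
        vmap = extract_vessel_map(fa, "FA")
        with pytest.raises(ValueError, match="empty search grid"):
            phase1_rigid(vmap, vmap, SearchGrid(rotations=np.array([])))
        with pytest.raises(ValueError, match="no vessel signal"):
            phase1_rigid(vmap, VesselMap(np.zeros_like(vmap.image), "SLO"))


class TestPhase2Local:
    def test_zero_local_warp_displacements_vanish(self):
        fa, slo, gt = _pair(rotation=3.0, scale=1.02, translation=(5, 2), seed=7)
        aff = phase1_rigid(extract_vessel_map(fa, "FA"), extract_vessel_map(slo, "SLO"))
        ref = phase2_local(fa, slo, aff, gt.ma_points)
        for p in ref.patches:
            if not p.skipped:
                assert abs(p.displacement[0]) <= 1 and abs(p.displacement[1]) <= 1

    def test_local_warp_reduces_residual(self):
        fa, slo, gt = _pair(rotation=4.0, scale=1.03, translation=(8, -3), local=3.0, seed=6)
        aff = phase1_rigid(extract_vessel_map(fa, "FA"), extract_vessel_map(slo, "SLO"))
        ref = phase2_local(fa, slo, aff, gt.ma_points)
        r1, r2 = [], []
        for p, truth in zip(gt.ma_points, gt.ma_points_slo):
            q1 = aff.forward(p)
            q2 = q1 + np.array(ref.displacement_for(p))
            r1.append(np.linalg.norm(q1 - truth))
            r2.append(np.linalg.norm(q2 - truth))
        assert np.mean(r2) < np.mean(r1)

    def test_single_step_schedule_is_exhaustive(self):
        fa, slo, gt = _pair(rotation=2.0, local=2.5, seed=8)
        aff = phase1_rigid(extract_vessel_map(fa, "FA"), extract_vessel_map(slo, "SLO"))
        radius = 4
        ref = phase2_local(fa, slo, aff, gt.ma_points[:2], schedule=(1,), search_radius=radius)
        slo_inv = slo.max() - slo
        from skimage.transform import AffineTransform, warp

        fa_aligned = warp(
            fa, AffineTransform(matrix=np.linalg.inv(aff.matrix())), output_shape=slo.shape, order=1
        )
        for p in ref.patches:
            if p.skipped:
                continue
            cx, cy = int(round(p.center[0])), int(round(p.center[1]))
            half = p.patch_size // 2
            patch = fa_aligned[cy - half : cy + half, cx - half : cx + half]
            best = -np.inf
            best_d = None
            for dy in range(-radius, radius + 1):
                for dx in range(-radius, radius + 1):
                    s = _zncc_patch(
                        patch, slo_inv[cy - half + dy : cy + half + dy, cx - half + dx : cx + half + dx]
                    )
                    if s > best:
                        best, best_d = s, (dx, dy)
            assert p.displacement == best_d
            assert np.isclose(p.score, best)

    def test_refinement_never_worsens_patch_score(self):
        fa, slo, gt = _pair(rotation=4.0, local=3.0, seed=9)
        aff = phase1_rigid(extract_vessel_map(fa, "FA"), extract_vessel_map(slo, "SLO"))
        ref = phase2_local(fa, slo, aff, gt.ma_points)
        slo_inv = slo.max() - slo
        from skimage.transform import AffineTransform, warp

        fa_aligned = warp(
            fa, AffineTransform(matrix=np.linalg.inv(aff.matrix())), output_shape=slo.shape, order=1
        )
        for p in ref.patches:
            if p.skipped:
                continue
            cx, cy = int(round(p.center[0])), int(round(p.center[1]))
            half = p.patch_size // 2
            zero_score = _zncc_patch(
                fa_aligned[cy - half : cy + half, cx - half : cx + half],
                slo_inv[cy - half : cy + half, cx - half : cx + half],
            )
            assert p.score >= zero_score - 1e-12

    def test_out_of_bounds_patch_skipped_with_warning(self, caplog):
        fa, slo, _ = _pair(seed=10)
        aff = AffineParams(0.0, 1.0, (0.0, 0.0), 1.0, center=(384, 248))
        with caplog.at_level("WARNING"):
            ref = phase2_local(fa, slo, aff, np.array([[3.0, 3.0]]))
        assert ref.patches[0].skipped
        assert "skipped" in caplog.text


class TestMapFaPointToBscan:
    def _geometry(self):
        return StackGeometry(bscan_rows=np.linspace(49.6, 446.4, 31), image_shape=(496, 768))

    def test_identity_mapping(self):
        geom = self._geometry()
        aff = AffineParams(0.0, 1.0, (0.0, 0.0), 1.0, center=(384, 248))
        ann = map_fa_point_to_bscan((400.0, geom.bscan_rows[15]), aff, None, geom)
        assert (ann.bscan_index, ann.column) == (15, 400)

    def test_equidistant_point_takes_lower_index(self):
        # exactly representable rows so the tie is exact
        geom = StackGeometry(bscan_rows=np.arange(31) * 10.0 + 50.0, image_shape=(496, 768))
        aff = AffineParams(0.0, 1.0, (0.0, 0.0), 1.0, center=(384, 248))
        ann = map_fa_point_to_bscan((100.0, 125.0), aff, None, geom)
        assert ann.bscan_index == 7

    def test_outside_stack_rejected(self):
        geom = self._geometry()
        aff = AffineParams(0.0, 1.0, (0.0, 0.0), 1.0, center=(384, 248))
        with pytest.raises(ValueError, match="outside stack"):
            map_fa_point_to_bscan((100.0, 5.0), aff, None, geom)

    def test_composition_with_true_warp_zero_residual(self):
        """Mapping with the exact generator warp reproduces the implanted
        lesion columns to the pixel."""
        fa, slo, gt = _pair(rotation=4.0, scale=1.02, translation=(6, -2), seed=11, noise=0.0)
        w = gt.true_warp
        aff = AffineParams(
            rotation=w.params.rotation_deg,
            scale=w.params.scale,
            translation=w.params.translation,
            correlation_score=1.0,
            center=w.center,
        )
        geom = StackGeometry(bscan_rows=gt.bscan_rows, image_shape=slo.shape)
        for p, truth in zip(gt.ma_points, gt.ma_points_slo):
            ann = map_fa_point_to_bscan(p, aff, None, geom)
            assert abs(ann.column - truth[0]) <= 0.5 + 1e-9

    def test_recovered_registration_maps_columns_within_two_px(self):
        fa, slo, gt = _pair(rotation=5.0, scale=0.97, translation=(-7, 4), seed=12)
        aff = phase1_rigid(extract_vessel_map(fa, "FA"), extract_vessel_map(slo, "SLO"))
        ref = phase2_local(fa, slo, aff, gt.ma_points)
        geom = StackGeometry(bscan_rows=gt.bscan_rows, image_shape=slo.shape)
        for p, truth in zip(gt.ma_points, gt.ma_points_slo):
            ann = map_fa_point_to_bscan(p, aff, ref, geom)
            assert abs(ann.column - truth[0]) <= 2.0
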