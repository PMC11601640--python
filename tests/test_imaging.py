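import numpy as np
import pytest

from cyclekit import imaging
from cyclekit.imaging import (
    BiasField,
    SegmentationParams,
    compute_cdk2_activity,
    estimate_illumination_bias,
    flatten_and_subtract,
    make_cytoplasmic_ring,
    measure_movie,
    measure_sensor,
    segment_nuclei,
)
from cyclekit.synthetic import SimMovieConfig, render_movie
from cyclekit.synthetic.movie import _fill_ellipse


class TestBiasEstimation:
    def test_flat_illumination_surface_near_one(self, rng):
        frames = [np.full((128, 128), 50.0) + rng.normal(0, 0.5, (128, 128)) for _ in range(3)]
        bias = estimate_illumination_bias(frames)
        assert np.abs(bias.surface - 1.0).max() < 0.01
        assert bias.background == pytest.approx(50.0, rel=0.01)

    def test_linear_gradient_recovered(self):
        h, w = 128, 128
        yy, xx = np.mgrid[0:h, 0:w]
        truth = 1.0 + 0.2 * (xx / (w - 1) - 0.5)
        frames = [truth * 40.0 for _ in range(2)]
        bias = estimate_illumination_bias(frames)
        rel = np.abs(bias.surface - truth / truth.mean()) / (truth / truth.mean())
        assert rel.max() < 0.02

    def test_empty_frame_list_rejected(self):
        with pytest.raises(ValueError):
            estimate_illumination_bias([])

    def test_fully_covered_frames_refused(self, rng):
        frame = np.full((64, 64), 500.0)
        fg = np.ones((64, 64), dtype=bool)
        with pytest.raises(ValueError, match="refused"):
            estimate_illumination_bias([frame], foreground_masks=[fg])

    def test_generator_bias_recovered(self):
        cfg = SimMovieConfig(
            field_size_px=(256, 256), n_frames=2, n_cells_initial=4,
            bias_amplitude=0.2, noise_sd=0.0, seed=4,
        )
        stack, truth = render_movie(cfg)
        bias = estimate_illumination_bias([stack.data[i, 0] for i in range(2)])
        corrected = stack.data[0, 0] / bias.surface - bias.background
        from scipy import ndimage

        # stay clear of the smoothed nuclear halos
        far = ndimage.distance_transform_edt(truth.label_masks[0] == 0) > 6
        assert np.abs(corrected[far].mean()) < 1.0


class TestFlatten:
    def test_exact_inverse(self, rng):
        surface = 1.0 + 0.1 * rng.random((32, 32))
        surface /= surface.mean()
        bias = BiasField(surface=surface, background=20.0)
        img = surface * 20.0
        out = flatten_and_subtract(img, bias)
        assert np.allclose(out, 0.0)

    def test_identity_bias(self, rng):
        img = rng.random((16, 16)) + 1.0
        out = flatten_and_subtract(img, BiasField.identity((16, 16)))
        assert np.allclose(out, img)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            flatten_and_subtract(np.ones((4, 4)), BiasField.identity((5, 5)))

    def test_corrected_background_flat(self):
        cfg = SimMovieConfig(
            field_size_px=(256, 256), n_frames=2, n_cells_initial=4,
            bias_amplitude=0.2, noise_sd=2.0, seed=6,
        )
        stack, truth = render_movie(cfg)
        bias = estimate_illumination_bias([stack.data[i, 0] for i in range(2)])
        corrected = stack.data[0, 0] / bias.surface - bias.background
        cell_free = truth.label_masks[0] == 0
        assert abs(corrected[cell_free].mean()) < cfg.noise_sd


class TestSegmentation:
    def test_blank_frame_empty(self, rng):
        img = rng.normal(0, 1.0, (128, 128))
        assert segment_nuclei(img, SegmentationParams()) == []

    def test_ten_nuclei_recovered(self):
        cfg = SimMovieConfig(
            field_size_px=(448, 448), n_frames=1, n_cells_initial=10,
            noise_sd=0.0, seed=8, motion_step_px=0.0,
        )
        stack, truth = render_movie(cfg)
        img = stack.data[0, 0] - cfg.background
        dets = segment_nuclei(img, SegmentationParams(pixel_size_um=cfg.pixel_size_um))
        assert len(dets) == 10
        gt = {
            cid: (tr["y"][0], tr["x"][0], tr["area_px"][0])
            for cid, tr in truth.trajectories.items()
        }
        for d in dets:
            cy, cx = d.centroid
            match = min(gt.values(), key=lambda g: (g[0] - cy) ** 2 + (g[1] - cx) ** 2)
            assert np.hypot(match[0] - cy, match[1] - cx) < 1.0
            assert d.area_px == pytest.approx(match[2], rel=0.10)

    def test_close_nuclei_split(self):
        # two ellipses whose edges are ~3 px apart must yield 2 detections
        img = np.zeros((96, 96))
        lab = np.zeros((96, 96), dtype=np.uint16)
        _fill_ellipse(lab, 48, 38, 9, 9, 0.0, 1)
        _fill_ellipse(lab, 48, 59, 9, 9, 0.0, 2)
        img[lab > 0] = 1000.0
        from scipy import ndimage

        img = ndimage.gaussian_filter(img, 1.0)
        dets = segment_nuclei(img, SegmentationParams(pixel_size_um=0.65))
        assert len(dets) == 2

    def test_area_bounds_filter(self):
        img = np.zeros((64, 64))
        img[30:33, 30:33] = 1000.0  # 9 px ~ 3.8 um^2, below min area
        dets = segment_nuclei(img, SegmentationParams(pixel_size_um=0.65, min_area_um2=30))
        assert dets == []


class TestRing:
    @staticmethod
    def _single_detection(radius_um=5.0, pixel=0.65, shape=(128, 128), center=(64, 64)):
        lab = np.zeros(shape, dtype=np.uint16)
        r_px = radius_um / pixel
        _fill_ellipse(lab, center[0], center[1], r_px, r_px, 0.0, 1)
        ys, xs = np.nonzero(lab)
        sl = (slice(ys.min(), ys.max() + 1), slice(xs.min(), xs.max() + 1))
        return imaging.NucleusDetection(
            frame=0, label=1, centroid=center, area_px=float(lab.sum()),
            area_um2=float(lab.sum()) * pixel**2, mask_slice=sl, mask=lab[sl] > 0,
        ), lab

    def test_ring_distance_band_exhaustive(self):
        det, lab = self._single_detection()
        ring = make_cytoplasmic_ring(det, [det], 0.65, lab.shape)
        assert not ring.missing
        full = np.zeros(lab.shape, dtype=bool)
        full[ring.mask_slice][ring.mask] = True
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(lab == 0) * 0.65
        dist_out = ndimage.distance_transform_edt(~(lab > 0)) * 0.65
        ys, xs = np.nonzero(full)
        for y, x in zip(ys, xs):
            assert 2.0 < dist_out[y, x] <= 10.0
            assert lab[y, x] == 0

    def test_neighbor_exclusion(self):
        pixel = 0.65
        det1, lab1 = self._single_detection(center=(64, 40))
        det2, lab2 = self._single_detection(center=(64, 80))
        det2 = imaging.NucleusDetection(
            frame=0, label=2, centroid=det2.centroid, area_px=det2.area_px,
            area_um2=det2.area_um2, mask_slice=det2.mask_slice, mask=det2.mask,
        )
        ring = make_cytoplasmic_ring(det1, [det1, det2], pixel, lab1.shape)
        assert not ring.missing
        full = np.zeros(lab1.shape, dtype=bool)
        full[ring.mask_slice][ring.mask] = True
        from scipy import ndimage

        other = np.zeros(lab1.shape, dtype=bool)
        other[det2.mask_slice][det2.mask] = True
        dist_other = ndimage.distance_transform_edt(~other) * pixel
        assert dist_other[full].min() > 10.0

    def test_fully_crowded_ring_flagged(self):
        pixel = 0.65
        det, lab = self._single_detection(center=(64, 64))
        neighbors = []
        for i, (dy, dx) in enumerate([(-22, 0), (22, 0), (0, -22), (0, 22)], start=2):
            nd, _ = self._single_detection(center=(64 + dy, 64 + dx))
            neighbors.append(
                imaging.NucleusDetection(
                    frame=0, label=i, centroid=nd.centroid, area_px=nd.area_px,
                    area_um2=nd.area_um2, mask_slice=nd.mask_slice, mask=nd.mask,
                )
            )
        ring = make_cytoplasmic_ring(det, [det] + neighbors, pixel, lab.shape)
        assert ring.missing
        assert "crowding" in ring.reason


class TestMeasurement:
    def test_uniform_ring(self):
        det, lab = TestRing._single_detection()
        ring = make_cytoplasmic_ring(det, [det], 0.65, lab.shape)
        sensor = np.zeros(lab.shape)
        sensor[lab > 0] = 200.0
        full = np.zeros(lab.shape, dtype=bool)
        full[ring.mask_slice][ring.mask] = True
        sensor[full] = 100.0
        nuc, cyto = measure_sensor(sensor, det, ring, background_sd=5.0)
        assert cyto == 100.0
        assert nuc == 200.0

    def test_background_pixels_excluded_from_median(self):
        det, lab = TestRing._single_detection()
        ring = make_cytoplasmic_ring(det, [det], 0.65, lab.shape)
        full = np.zeros(lab.shape, dtype=bool)
        full[ring.mask_slice][ring.mask] = True
        ys, xs = np.nonzero(full)
        sensor = np.zeros(lab.shape)
        sensor[lab > 0] = 200.0
        half = len(ys) // 2
        sensor[ys[:half], xs[:half]] = 100.0  # other half stays 0 = background
        _, cyto = measure_sensor(sensor, det, ring, background_sd=2.5)
        assert cyto == 100.0

    def test_prescribed_activity_recovered(self):
        cfg = SimMovieConfig(
            field_size_px=(192, 192), n_frames=1, n_cells_initial=1,
            default_activity=0.8, noise_sd=8.0, seed=9, motion_step_px=0.0,
        )
        stack, _ = render_movie(cfg)
        det = measure_movie(stack.data, cfg.pixel_size_um)
        assert len(det) == 1
        assert det["activity"].iloc[0] == pytest.approx(0.8, abs=0.05)

    def test_activity_arithmetic(self):
        assert compute_cdk2_activity(100.0, 100.0) == 1.0
        assert compute_cdk2_activity(0.0, 100.0) == 0.0
        assert compute_cdk2_activity(60.0, 100.0) == pytest.approx(0.6)

    def test_missing_propagates(self):
        assert np.isnan(compute_cdk2_activity(np.nan, 100.0))
        assert np.isnan(compute_cdk2_activity(50.0, 0.0))
        assert np.isnan(compute_cdk2_activity(50.0, -1.0))


class TestInvariants:
    def test_scale_invariance_of_activity(self):
        det, lab = TestRing._single_detection()
        ring = make_cytoplasmic_ring(det, [det], 0.65, lab.shape)
        sensor = np.zeros(lab.shape)
        sensor[lab > 0] = 321.0
        full = np.zeros(lab.shape, dtype=bool)
        full[ring.mask_slice][ring.mask] = True
        sensor[full] = 111.0
        nuc1, cyto1 = measure_sensor(sensor, det, ring, background_sd=1.0)
        a1 = compute_cdk2_activity(cyto1, nuc1)
        ring2 = make_cytoplasmic_ring(det, [det], 0.65, lab.shape)
        nuc2, cyto2 = measure_sensor(sensor * 7.3, det, ring2, background_sd=1.0)
        a2 = compute_cdk2_activity(cyto2, nuc2)
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_segmentation_recall_precision(self, small_movie):
        cfg, stack, truth = small_movie
        det = measure_movie(stack.data, cfg.pixel_size_um)
        tp = fp = 0
        total_gt = 0
        for f in range(cfg.n_frames):
            gt = [
                (tr["y"][f - tr["frames"][0]], tr["x"][f - tr["frames"][0]])
                for tr in truth.trajectories.values()
                if tr["frames"][0] <= f <= tr["frames"][-1]
            ]
            total_gt += len(gt)
            sub = det[det["frame"] == f]
            for _, row in sub.iterrows():
                d = min(np.hypot(g[0] - row["y"], g[1] - row["x"]) for g in gt)
                if d < 5:
                    tp += 1
                else:
                    fp += 1
        recall = tp / total_gt
        precision = tp / (tp + fp)
        assert recall >= 0.95
        assert precision >= 0.95
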