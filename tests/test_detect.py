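import numpy as np
import pytest
from scipy import ndimage

from spermtrack.core import CalibrationProfile, iou
from spermtrack.detect import (
    ClassicalDetector,
    DetectorParams,
    assemble_detections,
    binarize,
    component_orientation,
    detect,
    find_head_candidates,
    find_tail_segments,
    gradient_magnitude,
    label_components,
    split_masks,
)
from spermtrack.evaluate import MatchResult, match_frame, precision_recall_f

from conftest import CAL


class TestGradient:
    def test_constant_image_zero(self):
        assert gradient_magnitude(np.full((16, 16), 7.0)).max() == 0.0

    def test_vertical_step_edge(self):
        img = np.zeros((16, 16))
        img[:, 8:] = 10.0
        g = gradient_magnitude(img)
        col = np.argmax(g.sum(axis=0))
        assert col in (7, 8)

    def test_matches_direct_convolution(self, rng):
        img = rng.random((5, 5))
        kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]])
        gx = ndimage.convolve(img, kx[::-1, ::-1], mode="nearest")
        gy = ndimage.convolve(img, kx.T[::-1, ::-1], mode="nearest")
        assert np.allclose(gradient_magnitude(img), np.hypot(gx, gy))


class TestComponents:
    def test_two_disjoint_squares(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:3, 1:3] = True
        mask[6:8, 6:8] = True
        comps = label_components(mask)
        assert len(comps) == 2 and all(c.area == 4 for c in comps)

    def test_diagonal_pair_connectivity(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[1, 1] = mask[2, 2] = True
        assert len(label_components(mask, connectivity=8)) == 1
        assert len(label_components(mask, connectivity=4)) == 2

    def test_empty_mask(self):
        assert label_components(np.zeros((5, 5), dtype=bool)) == []

    def test_horizontal_bar_orientation(self):
        mask = np.zeros((5, 12), dtype=bool)
        mask[2, 1:11] = True
        (c,) = label_components(mask)
        assert component_orientation(c) == pytest.approx(0.0, abs=1e-6)
        assert c.elongation > 10

    def test_rotated_bar_orientation(self):
        # rasterize a bar at 30 degrees (y down) and re-measure
        theta = np.radians(30)
        mask = np.zeros((64, 64), dtype=bool)
        for s in np.linspace(0, 40, 400):
            x = int(round(10 + s * np.cos(theta)))
            y = int(round(10 + s * np.sin(theta)))
            mask[y, x] = mask[y + 1, x] = True
        (c,) = label_components(mask)
        assert component_orientation(c) == pytest.approx(30.0, abs=2.0)

    def test_disk_is_isotropic(self):
        yy, xx = np.mgrid[:31, :31]
        mask = (yy - 15) ** 2 + (xx - 15) ** 2 <= 100
        (c,) = label_components(mask)
        assert c.elongation == pytest.approx(1.0, abs=0.05)
        component_orientation(c)  # defined, value immaterial

    def test_orientation_needs_two_pixels(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        (c,) = label_components(mask)
        with pytest.raises(ValueError):
            component_orientation(c)


@pytest.fixture(scope="module")
def stage_components(clean_scene):
    """Head/tail candidate components from frame 0 of the clean benchmark."""
    video, gt = clean_scene
    params = DetectorParams()
    g = gradient_magnitude(video.frames[0].astype(float))
    filled = ndimage.binary_fill_holes(binarize(g, params.threshold))
    thick, thin = split_masks(filled, params, CAL)
    return (
        label_components(thick),
        label_components(thin),
        params,
    )


class TestCandidateFilters:
    def test_heads_found_and_are_head_sized(self, stage_components):
        thick, _, params = stage_components
        heads = find_head_candidates(thick, params, CAL)
        assert len(heads) == 3  # one per rendered sperm
        um2 = CAL.microns_per_pixel**2
        for h in heads:
            assert params.head_area_um2[0] <= h.area * um2 <= params.head_area_um2[1]

    def test_tails_found_and_are_long_thin(self, stage_components):
        _, thin, params = stage_components
        tails = find_tail_segments(thin, params, CAL)
        assert len(tails) == 3
        for t in tails:
            assert t.major_extent * CAL.microns_per_pixel >= params.tail_min_length_um

    def test_tail_not_a_head_and_vice_versa(self, stage_components):
        thick, thin, params = stage_components
        # tail segments fail the head area/elongation window
        assert find_head_candidates(find_tail_segments(thin, params, CAL), params, CAL) == []
        # head blobs fail the tail length requirement
        assert find_tail_segments(find_head_candidates(thick, params, CAL), params, CAL) == []

    def test_assembly_pairs_all_three(self, stage_components, clean_scene):
        thick, thin, params = stage_components
        _, gt = clean_scene
        heads = find_head_candidates(thick, params, CAL)
        tails = find_tail_segments(thin, params, CAL)
        dets = assemble_detections(heads, tails, params, CAL)
        assert len(dets) == 3
        for ab in gt.annotations[0].boxes:
            assert max(iou(d.box, ab.box) for d in dets) > 0.5


class TestDetect:
    def test_blank_frame_empty(self):
        assert detect(np.full((64, 64), 128, dtype=np.uint8), cal=CAL) == []

    def test_deterministic(self, clean_scene):
        video, _ = clean_scene
        d1 = detect(video.frames[0], cal=CAL)
        d2 = detect(video.frames[0], cal=CAL)
        assert [d.box.as_tuple() for d in d1] == [d.box.as_tuple() for d in d2]

    def test_three_sperm_three_detections(self, clean_scene):
        video, _ = clean_scene
        dets = detect(video.frames[0], cal=CAL)
        assert len(dets) == 3
        confs = [d.confidence for d in dets]
        assert confs == sorted(confs, reverse=True)
        assert all(0 <= c <= 1 for c in confs)

    def test_translation_equivariance(self):
        """Integer-shifting a frame shifts every detection by the same
        offset (object kept clear of the borders)."""
        from spermtrack.simulate import SceneConfig, SpermPhantom, Stationary, render_frame

        cfg = SceneConfig(
            width_px=320, height_px=320, duration_s=0.5, calibration=CAL,
            sperm=(SpermPhantom(position_um=(55, 40), motion=Stationary(heading_deg=30)),),
            seed=4,
        )
        frame, _ = render_frame(cfg, 0.0)
        shifted = np.roll(frame, (7, -5), axis=(0, 1))  # y += 7, x -= 5
        d0 = detect(frame, cal=CAL)
        d1 = detect(shifted, cal=CAL)
        assert len(d0) == len(d1) == 1
        moved = d1[0].box.translate(5, -7).as_tuple()
        assert np.allclose(moved, d0[0].box.as_tuple(), atol=1e-6)

    def test_detection_count_bounded_by_heads(self, cluttered_scene):
        video, _ = cluttered_scene
        params = DetectorParams(emit_unpaired_heads=True)
        for frame in video.frames[:3]:
            g = gradient_magnitude(frame.astype(float))
            filled = ndimage.binary_fill_holes(binarize(g, params.threshold))
            thick, _ = split_masks(filled, params, CAL)
            n_heads = len(find_head_candidates(label_components(thick), params, CAL))
            assert len(detect(frame, params, CAL)) <= n_heads

    def test_candidate_reduction_on_clutter(self, cluttered_scene):
        """Assembly keeps far fewer candidates than raw labeling produces."""
        video, _ = cluttered_scene
        frame = video.frames[0]
        g = gradient_magnitude(frame.astype(float))
        n_raw = len(label_components(binarize(g, "otsu")))
        n_det = len(detect(frame, DetectorParams(), CAL))
        assert n_raw >= 5 * max(n_det, 1)


class TestFailureModes:
    def test_debris_head_without_tail_not_full_confidence(self):
        """On a debris-only field (no tails anywhere), the strict detector
        is silent; enabling unpaired-head emission surfaces the head-like
        debris, but only at reduced confidence."""
        from spermtrack.simulate import SceneConfig, render_frame

        cfg = SceneConfig(
            width_px=320, height_px=320, duration_s=0.5, calibration=CAL,
            n_debris=6, seed=9,
        )
        frame, _ = render_frame(cfg, 0.0)
        strict = detect(frame, DetectorParams(emit_unpaired_heads=False), CAL)
        loose = detect(frame, DetectorParams(emit_unpaired_heads=True), CAL)
        assert strict == []
        assert len(loose) >= 1  # the debris false-positive mode
        scale = DetectorParams().unpaired_confidence_scale
        assert all(d.confidence <= scale for d in loose)

    def test_occlusion_reduces_recall(self, clean_scene, cluttered_scene):
        params = DetectorParams()
        det = ClassicalDetector(params, CAL)

        def recall(scene):
            video, gt = scene
            total = MatchResult()
            for k, frame in enumerate(video.frames):
                total = total + match_frame(det(frame), gt.annotations[k].boxes, 0.45)
            return precision_recall_f(total)[1]

        assert recall(cluttered_scene) < recall(clean_scene)
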