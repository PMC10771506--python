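"""Segmentation chain: binarization, denoising, clustering, boundary."""

import numpy as np
import pytest

from clotflow.errors import (DegenerateClusteringError, ParameterError,
                             PipelineError)
from clotflow.segment import (SegmentationParams, binarize_frame,
                              cluster_labels, denoise_mask, extract_boundary,
                              segment_stack)
from clotflow.synth import render_stack
from conftest import make_ellipse_scene


class TestBinarize:
    def test_all_zero_frame_gives_empty_mask(self):
        with pytest.warns(UserWarning, match="constant"):
            mask = binarize_frame(np.zeros((32, 32)))
        assert mask.sum() == 0

    def test_two_level_frame_recovers_exact_mask(self, rendered_ellipse):
        scene, _, _ = rendered_ellipse
        exact = scene.schedule[0]["overall"].mask(scene.image_shape,
                                                  scene.pixel_size)
        frame = np.where(exact, 200, 20).astype(np.uint8)
        for rule in ("otsu", ("percentile", 80.0)):
            assert np.array_equal(binarize_frame(frame, rule), exact)

    def test_salt_noise_only_adds_isolated_pixels(self, rendered_ellipse):
        scene, stacks, _ = rendered_ellipse
        frame = stacks["CD41"].data[0]
        exact = scene.schedule[0]["overall"].mask(scene.image_shape,
                                                  scene.pixel_size)
        mask = binarize_frame(frame, "otsu")
        extra = mask & ~exact
        # every spurious foreground pixel is isolated after one median pass
        cleaned = denoise_mask(extra.astype(np.uint8), 3, 0.0)
        assert cleaned.sum() <= 0.001 * extra.size


class TestDenoise:
    def test_single_isolated_pixel_removed(self):
        mask = np.zeros((21, 21), dtype=np.uint8)
        mask[10, 10] = 1
        assert denoise_mask(mask, 3, 1.0).sum() == 0

    def test_solid_disk_preserved(self):
        yy, xx = np.mgrid[:64, :64]
        disk = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 20 ** 2).astype(np.uint8)
        out = denoise_mask(disk, 3, 1.0)
        assert abs(out.sum() - disk.sum()) < 0.05 * disk.sum()

    def test_pinhole_filled_by_gaussian(self):
        yy, xx = np.mgrid[:64, :64]
        disk = ((yy - 32) ** 2 + (xx - 32) ** 2 <= 20 ** 2).astype(np.uint8)
        disk[32, 32] = 0
        out = denoise_mask(disk, 3, 1.0)
        assert out[32, 32]

    def test_kernel_larger_than_image_rejected(self):
        with pytest.raises(ParameterError):
            denoise_mask(np.zeros((5, 5), dtype=np.uint8), 7, 1.0)


class TestCluster:
    def test_bimodal_frame_matches_threshold(self):
        rng = np.random.default_rng(0)
        frame = np.where(rng.random((48, 48)) < 0.3, 200.0, 20.0)
        labels = cluster_labels(frame)
        assert np.array_equal(labels, frame > 110)

    def test_trimodal_clot_label_covers_bright_level(self):
        rng = np.random.default_rng(1)
        frame = np.full((48, 48), 20.0)
        frame[10:38, 10:38] = 90.0
        frame[18:30, 18:30] = 200.0
        labels = cluster_labels(frame)
        assert labels[18:30, 18:30].all()

    def test_fixed_seed_deterministic(self):
        rng = np.random.default_rng(2)
        frame = rng.normal(100, 40, (48, 48))
        assert np.array_equal(cluster_labels(frame, seed=3),
                              cluster_labels(frame, seed=3))

    def test_constant_frame_degenerate(self):
        with pytest.raises(DegenerateClusteringError):
            cluster_labels(np.full((8, 8), 7.0))


class TestExtractBoundary:
    def test_single_ellipse_loop_area_within_ten_percent(self, rendered_ellipse):
        scene, _, _ = rendered_ellipse
        exact = scene.schedule[0]["overall"]
        labels = exact.mask(scene.image_shape, scene.pixel_size)
        b = extract_boundary(labels)
        area = b.enclosed_area(scene.pixel_size)
        assert abs(area - exact.area) / exact.area <= 0.10

    def test_distant_blob_discarded(self):
        yy, xx = np.mgrid[:96, :96]
        labels = ((yy - 40) ** 2 / 30 ** 2 + (xx - 40) ** 2 / 20 ** 2) <= 1
        labels[90:93, 90:93] = True
        b = extract_boundary(labels)
        # all loop pixels belong to the ellipse neighbourhood, not the blob
        assert b.pixels[:, 0].max() < 80

    def test_full_frame_foreground_yields_border_ring(self):
        labels = np.ones((40, 40), dtype=bool)
        b = extract_boundary(labels)
        r, c = b.pixels[:, 0], b.pixels[:, 1]
        on_border = (r <= 2) | (r >= 37) | (c <= 2) | (c >= 37)
        assert on_border.all()
        assert b.enclosed_area() > 0.8 * 40 * 40


class TestSegmentStack:
    def test_synthetic_stack_area_within_ten_percent(self, rendered_ellipse):
        scene, stacks, truth = rendered_ellipse
        boundaries, failed = segment_stack(stacks["CD41"])
        assert not failed
        for b in boundaries:
            area = b.enclosed_area(scene.pixel_size)
            exact = truth.areas["overall"][b.frame_index]
            assert abs(area - exact) / exact <= 0.10

    def test_zero_growth_stack_boundaries_consistent(self, rendered_ellipse):
        scene, stacks, _ = rendered_ellipse
        boundaries, _ = segment_stack(stacks["CD41"])
        areas = [b.enclosed_area(scene.pixel_size) for b in boundaries]
        assert np.ptp(areas) < 0.05 * np.mean(areas)

    def test_corrupted_frame_flagged_others_unaffected(self, rendered_ellipse):
        scene, stacks, _ = rendered_ellipse
        data = stacks["CD41"].data.copy()
        data = np.concatenate([data] * 3)           # 6 frames
        data[2] = 0                                  # corrupt one frame
        from clotflow.segment import ImageStack
        stack = ImageStack(data=data, pixel_size=scene.pixel_size)
        boundaries, failed = segment_stack(stack)
        assert failed == [2]
        assert boundaries[2] is None
        assert all(b is not None for i, b in enumerate(boundaries) if i != 2)

    def test_too_many_failures_aborts(self):
        from clotflow.segment import ImageStack
        stack = ImageStack(data=np.zeros((4, 32, 32)), pixel_size=0.5)
        with pytest.raises(PipelineError):
            segment_stack(stack)

    def test_determinism_under_fixed_seed(self, rendered_ellipse):
        _, stacks, _ = rendered_ellipse
        b1, _ = segment_stack(stacks["CD41"])
        b2, _ = segment_stack(stacks["CD41"])
        assert all(np.array_equal(x.pixels, y.pixels)
                   for x, y in zip(b1, b2))


def test_segmentation_accuracy_over_random_geometries():
    """Relative area error stays <= 10% across varied ellipse geometries."""
    rng = np.random.default_rng(12345)
    for trial in range(20):
        a = rng.uniform(10, 40)
        b = rng.uniform(10, a)
        rot = rng.uniform(0, np.pi)
        scene = make_ellipse_scene(a, b, rotation=rot, seed=trial,
                                   n_frames=1)
        stacks, _ = render_stack(scene)
        boundaries, failed = segment_stack(stacks["CD41"])
        assert not failed
        area = boundaries[0].enclosed_area(scene.pixel_size)
        assert abs(area - np.pi * a * b) / (np.pi * a * b) <= 0.10
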