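"""Stage-by-stage tests of the modified Canny detector."""

import numpy as np
import pytest
from scipy import ndimage

import fundusedge as fe
from fundusedge.canny import (
    IRRELEVANT,
    STRONG,
    WEAK,
    GradientField,
    detect_from_nms,
    pipeline_front,
)


class TestGaussianKernel:
    def test_size_one_is_unity(self):
        k = fe.gaussian_kernel(fe.GaussianSpec(1, 1.4))
        assert k.shape == (1, 1) and k[0, 0] == pytest.approx(1.0)

    def test_normalized(self):
        k = fe.gaussian_kernel(fe.GaussianSpec(5, 1.4))
        assert abs(k.sum() - 1.0) < 1e-12

    def test_symmetry_and_center_maximum(self):
        k = fe.gaussian_kernel(fe.GaussianSpec(5, 1.4))
        assert np.allclose(k, k[::-1, :]) and np.allclose(k, k[:, ::-1])
        assert np.allclose(k, k.T)
        assert k[2, 2] == k.max()

    def test_unnormalized_center_is_one(self):
        # exp(0) = 1 at the kernel centre before normalization
        spec = fe.GaussianSpec(5, 1.4)
        k = fe.gaussian_kernel(spec)
        unnorm = k / k[2, 2]
        x, y = 1, 2
        assert unnorm[2 + y, 2 + x] == pytest.approx(
            np.exp(-(x**2 + y**2) / (2 * spec.sigma**2))
        )

    def test_even_size_rejected(self):
        with pytest.raises(fe.ParameterError):
            fe.GaussianSpec(4, 1.4)


class TestSmooth:
    def test_constant_preserved(self):
        img = np.full((16, 16), 77, dtype=np.uint8)
        assert (fe.smooth(img) == 77).all()

    def test_impulse_response_is_the_kernel(self):
        img = np.zeros((15, 15), dtype=np.uint8)
        img[7, 7] = 255
        out = fe.smooth(img, fe.GaussianSpec(5, 1.4))
        expected = np.floor(255.0 * fe.gaussian_kernel(fe.GaussianSpec(5, 1.4)) + 0.5)
        assert (out[5:10, 5:10] == expected).all()

    def test_mean_conserved(self, rng):
        img = rng.integers(0, 256, (40, 40), dtype=np.uint8)
        assert abs(float(fe.smooth(img).mean()) - float(img.mean())) <= 1.0

    def test_image_smaller_than_kernel_rejected(self):
        with pytest.raises(fe.ParameterError):
            fe.smooth(np.zeros((3, 3), dtype=np.uint8), fe.GaussianSpec(5, 1.4))


class TestGradients:
    def test_constant_image_has_zero_magnitude(self):
        f = fe.gradients(np.full((10, 10), 50, dtype=np.uint8))
        assert (f.magnitude == 0).all()

    def test_vertical_step_edge(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[:, 4:] = 255
        f = fe.gradients(img)
        # hand-convolved Sobel on the step: columns 3 and 4 respond with
        # gx = 4*255 = 1020, gy = 0, angle 0 (horizontal edge normal)
        assert (f.gx[:, 3] == 1020).all() and (f.gx[:, 4] == 1020).all()
        assert (f.gy == 0).all()
        assert (f.magnitude[:, 3] == 1020).all()
        assert (f.angle[:, 3] == 0).all()
        assert (f.magnitude[:, :2] == 0).all()  # flat regions silent

    def test_magnitude_is_hypot_of_components(self, rng):
        f = fe.gradients(rng.integers(0, 256, (20, 20), dtype=np.uint8))
        assert np.allclose(f.magnitude, np.sqrt(f.gx**2 + f.gy**2))


def _field(mag, angle=0.0):
    mag = np.asarray(mag, dtype=np.float64)
    ang = np.full_like(mag, angle)
    return GradientField(np.cos(ang) * mag, np.sin(ang) * mag, mag, ang)


class TestNonmaxSuppression:
    def test_single_ridge_maximum_survives(self):
        # horizontal gradient: compare along columns; centre column wins
        mag = np.zeros((5, 5))
        mag[:, 1:4] = [0.0, 9.0, 5.0]
        mag[:, 1] = 5.0
        out = fe.nonmax_suppress(_field(mag, angle=0.0))
        assert (out[1:4, 2] == 9.0).all()  # ridge survives off the border
        assert (out[:, 1] == 0).all() and (out[:, 3] == 0).all()

    def test_plateau_ties_survive(self):
        mag = np.full((7, 7), 4.0)
        out = fe.nonmax_suppress(_field(mag, angle=0.0))
        assert (out[1:-1, 1:-1] == 4.0).all()  # equal neighbours are kept
        assert (out[0, :] == 0).all() and (out[:, -1] == 0).all()  # border frame

    def test_output_bounded_by_input(self, rng):
        f = fe.gradients(rng.integers(0, 256, (24, 24), dtype=np.uint8))
        out = fe.nonmax_suppress(f)
        assert (out <= f.magnitude).all()
        assert ((out == 0) | (out == f.magnitude)).all()

    def test_survivors_are_local_maxima_brute_force(self, rng):
        """Independent per-pixel re-check of the quantized-normal rule."""
        f = fe.gradients(rng.integers(0, 256, (18, 18), dtype=np.uint8))
        out = fe.nonmax_suppress(f)
        offs = [(0, 1), (1, 1), (1, 0), (1, -1)]
        h, w = out.shape
        for r in range(1, h - 1):
            for c in range(1, w - 1):
                deg = np.rad2deg(f.angle[r, c]) % 180.0
                dr, dc = offs[int((deg + 22.5) // 45.0) % 4]
                m = f.magnitude
                keep = m[r, c] >= m[r + dr, c + dc] and m[r, c] >= m[r - dr, c - dc]
                assert (out[r, c] > 0) == (keep and m[r, c] > 0)


class TestDoubleThreshold:
    def test_default_threshold_classes(self):
        nms = np.array([[5.0, 50.0, 200.0]])
        classes = fe.double_threshold(nms, 30, 105)
        assert classes.tolist() == [[IRRELEVANT, WEAK, STRONG]]

    def test_boundaries_are_strict(self):
        nms = np.array([[30.0, 105.0, 30.0001, 105.0001]])
        assert fe.double_threshold(nms, 30, 105).tolist() == [
            [IRRELEVANT, WEAK, WEAK, STRONG]
        ]

    def test_zero_thresholds_make_everything_strong(self, rng):
        nms = rng.random((6, 6)) + 0.1
        assert (fe.double_threshold(nms, 0, 0) == STRONG).all()

    def test_all_zero_grid_irrelevant(self):
        assert (fe.double_threshold(np.zeros((4, 4)), 30, 105) == IRRELEVANT).all()

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(fe.ParameterError):
            fe.double_threshold(np.zeros((2, 2)), 50, 10)


def hysteresis_oracle(classes):
    """Brute-force BFS from strong pixels through weak pixels (8-connected)."""
    h, w = classes.shape
    keep = classes == STRONG
    stack = list(zip(*np.nonzero(keep)))
    seen = set(stack)
    while stack:
        r, c = stack.pop()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (
                    0 <= rr < h and 0 <= cc < w
                    and (rr, cc) not in seen
                    and classes[rr, cc] != IRRELEVANT
                ):
                    seen.add((rr, cc))
                    stack.append((rr, cc))
    out = np.zeros((h, w), dtype=bool)
    for r, c in seen:
        out[r, c] = True
    return out


class TestHysteresis:
    def test_lone_weak_pixel_dropped(self):
        classes = np.zeros((5, 5), dtype=np.uint8)
        classes[2, 2] = WEAK
        assert not fe.hysteresis(classes).any()

    def test_weak_next_to_strong_kept(self):
        classes = np.zeros((5, 5), dtype=np.uint8)
        classes[2, 2] = STRONG
        classes[1, 1] = WEAK  # diagonal counts: 8-connectivity
        out = fe.hysteresis(classes)
        assert out[2, 2] and out[1, 1] and out.sum() == 2

    def test_chain_through_weak_pixels(self):
        classes = np.zeros((3, 5), dtype=np.uint8)
        classes[1, 1] = STRONG
        classes[1, 2] = classes[1, 3] = WEAK
        assert fe.hysteresis(classes)[1, 1:4].all()

    def test_matches_bfs_oracle_on_random_maps(self, rng):
        for _ in range(100):
            classes = rng.choice(
                [IRRELEVANT, WEAK, STRONG], size=(12, 12), p=[0.6, 0.3, 0.1]
            ).astype(np.uint8)
            assert (fe.hysteresis(classes) == hysteresis_oracle(classes)).all()


class TestRemoveOutline:
    def test_full_mask_is_identity(self, rng):
        edges = rng.random((8, 8)) > 0.7
        assert (fe.remove_outline(edges, np.ones((8, 8), bool)) == edges).all()

    def test_empty_mask_clears_everything(self, rng):
        edges = rng.random((8, 8)) > 0.5
        assert not fe.remove_outline(edges, np.zeros((8, 8), bool)).any()

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(fe.DimensionError):
            fe.remove_outline(np.ones((4, 4), bool), np.ones((5, 5), bool))

    def test_phantom_rim_removed(self, clean_vessel_phantom):
        """The bright disc rim is a massive gradient but must not appear."""
        img, truth = clean_vessel_phantom
        edges = fe.detect(img)
        rim = truth.retina_disc_mask & ~ndimage.binary_erosion(
            truth.retina_disc_mask, np.ones((3, 3)), iterations=3, border_value=0
        )
        assert not (edges & rim).any()


class TestDetect:
    def test_black_image_has_no_edges(self):
        img = np.zeros((64, 64, 3), dtype=np.uint8)
        assert not fe.detect(img).any()

    def test_deterministic(self, default_phantom):
        img, _ = default_phantom
        a = fe.detect(img)
        b = fe.detect(img)
        assert (a == b).all()

    def test_edges_hug_the_true_boundary(self, clean_vessel_phantom):
        img, truth = clean_vessel_phantom
        edges = fe.detect(img)
        assert edges.sum() > 50
        dt = ndimage.distance_transform_edt(~truth.vessel_boundary_map)
        assert (dt[edges] <= 2).mean() == 1.0

    def test_front_plus_tail_equals_detect(self, default_phantom):
        img, _ = default_phantom
        params = fe.DetectorParams.create(low=20, high=80)
        nms, mask = pipeline_front(img, params)
        assert (
            detect_from_nms(nms, mask, 20, 80) == fe.detect(img, params)
        ).all()


class TestDetectorParams:
    def test_tile_coupled_to_kernel(self):
        assert fe.DetectorParams().clahe.tile_size == 15
        assert fe.DetectorParams.create(kernel=7).clahe.tile_size == 21

    def test_explicit_tile_override(self):
        p = fe.DetectorParams.create(kernel=5, tile=31)
        assert p.clahe.tile_size == 31

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(fe.ParameterError):
            fe.DetectorParams(low_threshold=50, high_threshold=10)

    def test_yaml_round_trip(self, tmp_path):
        p = fe.DetectorParams.create(low=12, high=99, kernel=7, sigma=2.0)
        path = tmp_path / "params.yaml"
        fe.save_params(path, p)
        assert fe.load_params(path) == p
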