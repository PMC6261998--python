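import math

import numpy as np
import pytest
from scipy import ndimage, stats

from magspim import OpticsModel, make_phantom, render_view
from magspim.errors import BoundaryNotFoundError, InvalidInputError
from magspim.quality import (
    background_model,
    boundary_plane,
    foreground_mask,
    local_entropy,
    max_projection,
    plane_score,
    quality_profile,
    quantize,
)
from oracles import (
    exhaustive_otsu,
    loop_local_entropy,
    loop_mask,
    loop_masked_mean,
    loop_max_projection,
    numeric_chord_length,
)


class TestMaxProjection:
    def test_single_plane_identity(self, rng):
        plane = rng.uniform(0, 10, (6, 7))
        assert np.array_equal(max_projection(plane[None]), plane)

    def test_forced(self):
        stack = np.stack([np.zeros((4, 4)), np.full((4, 4), 5.0)])
        assert np.array_equal(max_projection(stack), np.full((4, 4), 5.0))

    def test_loop_oracle(self):
        rng = np.random.default_rng(11)
        stack = rng.uniform(0, 100, (8, 8, 8))
        assert np.array_equal(max_projection(stack), loop_max_projection(stack))

    def test_empty_rejected(self):
        with pytest.raises(InvalidInputError):
            max_projection(np.zeros((0, 4, 4)))


class TestBackgroundModel:
    def test_constant_image(self):
        bg = background_model(np.full((300, 300), 7.0))
        assert all(m == 7.0 and s == 0.0 for m, s in bg.corner_stats)
        assert bg.threshold == 7.0

    def test_engineered_corners(self):
        """Corners built to (mean, sd) pairs; threshold = max(mean + 3 sd) = 18."""
        img = np.zeros((300, 300))
        targets = {(0, 0): (10, 2), (0, 200): (11, 1), (200, 0): (9, 3), (200, 200): (10, 2.5)}
        for (y0, x0), (mean, sd) in targets.items():
            block = np.full((100, 100), float(mean))
            block.ravel()[::2] += sd
            block.ravel()[1::2] -= sd  # exactly half up, half down: population sd
            img[y0 : y0 + 100, x0 : x0 + 100] = block
        bg = background_model(img, corner_size=100)
        got = [(round(m, 9), round(s, 9)) for m, s in bg.corner_stats]
        assert got == [(10, 2), (11, 1), (9, 3), (10, 2.5)]
        assert bg.threshold == 18.0

    def test_gaussian_coverage(self):
        rng = np.random.default_rng(2)
        img = rng.normal(100.0, 5.0, (512, 512))
        bg = background_model(img, corner_size=100)
        frac_below = np.mean(img < bg.threshold)
        assert frac_below >= 0.997

    def test_small_image_warns_and_shrinks(self):
        with pytest.warns(UserWarning):
            bg = background_model(np.ones((40, 40)))
        assert bg.corner_size == 20

    def test_overlapping_corners_warn(self):
        with pytest.warns(UserWarning):
            background_model(np.ones((150, 150)), corner_size=100)


class TestForegroundMask:
    def test_boundary_strictness(self):
        plane = np.full((5, 5), 3.0)
        assert not foreground_mask(plane, 3.0).any()

    def test_single_pixel(self):
        plane = np.zeros((5, 5))
        plane[2, 3] = 4.0
        mask = foreground_mask(plane, 3.0)
        assert mask.sum() == 1 and mask[2, 3]

    def test_loop_oracle(self):
        rng = np.random.default_rng(5)
        plane = rng.uniform(0, 10, (12, 9))
        assert np.array_equal(foreground_mask(plane, 5.0), loop_mask(plane, 5.0))


class TestLocalEntropy:
    def test_constant_plane(self):
        ent = local_entropy(np.full((20, 20), 3.7))
        assert np.all(ent == 0.0)

    def test_monotone_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        plane = rng.integers(0, 8, (24, 24)).astype(float)
        # strictly monotone relabeling of the 8 quantised values
        relabeled = plane * 17.0 + 3.0
        a = local_entropy(plane, radius=3, vmin=0, vmax=7)
        b = local_entropy(relabeled, radius=3, vmin=3, vmax=7 * 17 + 3)
        assert np.allclose(a, b)

    def test_checkerboard_closed_form(self):
        """Interior entropy equals the two-class histogram entropy of the disk.

        The class counts come from an independent brute-force enumeration of
        the digital disk (81 pixels at radius 5, parity split 44/37).
        """
        counts = {0: 0, 1: 0}
        for dy in range(-5, 6):
            for dx in range(-5, 6):
                if dy * dy + dx * dx <= 25:
                    counts[(dy + dx) % 2] += 1
        assert sum(counts.values()) == 81
        n = sum(counts.values())
        expected = -sum(c / n * math.log2(c / n) for c in counts.values())

        yy, xx = np.indices((30, 30))
        board = ((yy + xx) % 2).astype(float)
        ent = local_entropy(board, radius=5)
        assert ent[15, 15] == pytest.approx(expected, abs=1e-9)
        # and the whole interior matches
        assert np.allclose(ent[5:-5, 5:-5], expected, atol=1e-9)

    def test_brute_force_oracle_with_borders(self):
        rng = np.random.default_rng(13)
        plane = rng.uniform(0, 255, (18, 15))
        q = quantize(plane)
        ours = local_entropy(plane, radius=5)
        brute = loop_local_entropy(q, radius=5)
        assert np.allclose(ours, brute, atol=1e-9)


class TestPlaneScore:
    def test_empty_mask_undefined(self):
        s = plane_score(np.ones((4, 4)), np.zeros((4, 4), dtype=bool))
        assert math.isnan(s)

    def test_uniform_entropy(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[1:4, 2:5] = True
        assert plane_score(np.full((6, 6), 2.5), mask) == 2.5

    def test_loop_oracle(self):
        rng = np.random.default_rng(9)
        emap = rng.uniform(0, 8, (20, 20))
        mask = rng.uniform(size=(20, 20)) > 0.5
        assert plane_score(emap, mask) == pytest.approx(loop_masked_mean(emap, mask))

    def test_shape_mismatch(self):
        with pytest.raises(InvalidInputError):
            plane_score(np.ones((4, 4)), np.ones((4, 5), dtype=bool))


class TestBoundaryPlane:
    def test_first_plane_max(self):
        rng = np.random.default_rng(1)
        stack = rng.uniform(0, 1, (6, 16, 16))
        stack[0, 8, 8] = 100.0
        z0, _ = boundary_plane(stack)
        assert z0 == 0

    def test_bimodal_otsu_between_modes(self):
        vals = np.concatenate([np.full(1000, 10.0), np.full(1000, 200.0)])
        rng = np.random.default_rng(0)
        rng.shuffle(vals)
        proj = vals.reshape(40, 50)
        stack = proj[None]
        _, thr = boundary_plane(stack)
        assert 10.0 < thr < 200.0
        assert thr == pytest.approx(exhaustive_otsu(proj), abs=1e-9)

    def test_phantom_entry_plane_ray_oracle(self):
        """z0 matches the sphere-entry plane predicted from geometry."""
        radius = 100.0
        ph = make_phantom(
            radius, 150, 80.0, seed=4, cap_axis=(0.0, 0.0, -1.0)
        )
        optics = OpticsModel(
            attenuation_length=np.inf, blur_sigma0=2.0, blur_growth=0.0,
            background_mean=50.0, background_sd=0.0,
        )
        nz, spacing = 64, 4.0
        stack = render_view(ph, optics, (nz, 64, 64), 4.0, spacing, seed=0)
        z0, _ = boundary_plane(stack.voxels)
        # nuclei start at shell radius >= 0.75 R toward -z; first bright plane
        z_min = (ph.positions[:, 2]).min()  # most-negative nucleus z (um)
        expected_plane = (z_min - (-(nz - 1) / 2 * spacing)) / spacing
        assert abs(z0 - expected_plane) <= 1.5  # within about one plane

    def test_no_boundary(self):
        with pytest.raises(BoundaryNotFoundError):
            boundary_plane(np.full((3, 8, 8), 5.0))


class TestQualityProfile:
    def _stack_identical_planes(self):
        rng = np.random.default_rng(3)
        plane = rng.uniform(0, 1, (64, 64))
        plane[20:40, 20:40] += 50.0
        return np.stack([plane] * 5)

    def test_constant_stack_scores_equal(self):
        prof = quality_profile(self._stack_identical_planes(), corner_size=16)
        assert prof.z0_index == 0
        s = prof.scores()
        assert np.all(~np.isnan(s))
        assert np.allclose(s, s[0])

    def test_omission_rule(self):
        rng = np.random.default_rng(7)
        stack = rng.uniform(0, 1, (8, 64, 64))
        stack[:4, 30:34, 30:34] += 100.0  # bright only in planes 0..3
        prof = quality_profile(stack, corner_size=16)
        omitted = [p.omitted for p in prof.plane_scores]
        assert prof.z0_index == 0
        assert omitted == [False] * 4 + [True] * 4
        assert all(math.isnan(p.score) for p in prof.plane_scores if p.omitted)

    def test_depth_assignment(self):
        rng = np.random.default_rng(7)
        stack = rng.uniform(0, 0.1, (8, 64, 64))  # background well below one Otsu bin
        stack[3:, 24:44, 24:44] += 100.0
        prof = quality_profile(stack, corner_size=16, plane_spacing=4.0)
        assert prof.z0_index == 3
        assert [p.depth_um for p in prof.plane_scores] == [0.0, 4.0, 8.0, 12.0, 16.0]

    def test_monotone_degradation_spearman(self):
        """Single view into a nucleus-filled sphere: deeper planes score lower.

        The phantom fills the sphere so that per-plane structure is
        statistically uniform and the depth trend reflects the modelled
        degradations rather than cap geometry.
        """
        ph = make_phantom(
            110.0, 500, 180.0, seed=2, cap_axis=(0.0, 0.0, -1.0), shell_fraction=(0.0, 0.9)
        )
        optics = OpticsModel(
            attenuation_length=80.0, blur_sigma0=2.0, blur_growth=0.2,
            background_mean=100.0, background_sd=2.0,
        )
        stack = render_view(ph, optics, (64, 128, 128), 4.0, 4.0, seed=1)
        prof = quality_profile(stack, corner_size=30)
        ok = prof.valid()
        rho = stats.spearmanr(prof.depths()[ok], prof.scores()[ok]).statistic
        assert rho < 0

    def test_pipeline_equivalence(self):
        """quality_profile equals manual composition of the sub-operations."""
        rng = np.random.default_rng(21)
        stack = rng.uniform(0, 1, (6, 48, 48))
        stack[2:5, 20:30, 20:30] += rng.uniform(10, 60, (3, 10, 10))
        prof = quality_profile(stack, radius=4, corner_size=12)

        proj = max_projection(stack)
        bg = background_model(proj, corner_size=12)
        z0, thr = boundary_plane(stack)
        gmin, gmax = stack.min(), stack.max()
        assert prof.z0_index == z0
        for p in prof.plane_scores:
            plane = stack[p.z_index]
            if not (plane > thr).any():
                assert p.omitted
                continue
            expected = plane_score(
                local_entropy(plane, radius=4, vmin=gmin, vmax=gmax),
                foreground_mask(plane, bg.threshold),
            )
            if math.isnan(expected):
                assert p.omitted
            else:
                assert p.score == pytest.approx(expected)


class TestInvariants:
    def test_offset_invariance(self):
        rng = np.random.default_rng(17)
        stack = rng.uniform(0, 10, (5, 64, 64))
        stack[2, 28:36, 28:36] += 200.0
        c = 37.5
        a = quality_profile(stack, corner_size=16)
        b = quality_profile(stack + c, corner_size=16)
        bin_width = (stack.max() - stack.min()) / 255
        assert b.background.threshold == pytest.approx(a.background.threshold + c, abs=1e-9)
        assert b.otsu_threshold == pytest.approx(a.otsu_threshold + c, abs=2 * bin_width)
        assert b.z0_index == a.z0_index
        sa, sb = a.scores(), b.scores()
        valid = ~np.isnan(sa)
        assert np.allclose(sa[valid], sb[valid], atol=0.05)

    def test_blur_strictly_decreases_score(self):
        rng = np.random.default_rng(23)
        plane = rng.uniform(0, 100, (64, 64))
        mask = np.ones_like(plane, dtype=bool)
        scores = []
        for sigma in (0.0, 1.0, 2.0, 4.0):
            blurred = ndimage.gaussian_filter(plane, sigma) if sigma else plane
            emap = local_entropy(blurred, radius=5, vmin=0.0, vmax=100.0)
            scores.append(plane_score(emap, mask))
        assert all(a > b for a, b in zip(scores, scores[1:]))

    def test_scores_bounded(self):
        rng = np.random.default_rng(29)
        stack = rng.uniform(0, 1, (4, 48, 48))
        stack[1:, 16:32, 16:32] += rng.uniform(5, 50, (3, 16, 16))
        prof = quality_profile(stack, corner_size=12)
        s = prof.scores()
        valid = ~np.isnan(s)
        assert np.all(s[valid] >= 0)
        assert np.all(s[valid] <= 8.0)  # log2(256)
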