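"""Particle quantification: conversions, thresholds, labeling and bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ihcquant.particles import (
    CoreImage,
    QuantConfig,
    filter_particles,
    invert,
    label_particles,
    particle_metrics,
    quantify_core,
    rgb_to_gray,
    threshold_mask,
)
from ihcquant.synthetic import CoreSpec, generate_core_image


def flood_fill_label(mask: np.ndarray, connectivity: int) -> list[int]:
    """Independent oracle: component areas by explicit stack-based flood fill."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    if connectivity == 4:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        nbrs = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                if (dy, dx) != (0, 0)]
    areas = []
    for y in range(h):
        for x in range(w):
            if mask[y, x] and not seen[y, x]:
                stack, area = [(y, x)], 0
                seen[y, x] = True
                while stack:
                    cy, cx = stack.pop()
                    area += 1
                    for dy, dx in nbrs:
                        ny, nx = cy + dy, cx + dx
                        if (0 <= ny < h and 0 <= nx < w and mask[ny, nx]
                                and not seen[ny, nx]):
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                areas.append(area)
    return sorted(areas)


class TestGrayscale:
    def test_fixed_points_and_mean_formula(self):
        rgb = np.array([[[255, 255, 255], [100, 150, 200]]], dtype=np.uint8)
        gray = rgb_to_gray(CoreImage(rgb, 8))
        assert gray.bit_depth == 16
        assert gray.pixels[0, 0] == 255 * 257
        assert gray.pixels[0, 1] == 150 * 257

    def test_matches_per_pixel_loop(self):
        rng = np.random.default_rng(0)
        rgb = rng.integers(0, 256, size=(13, 17, 3), dtype=np.uint8)
        gray = rgb_to_gray(CoreImage(rgb, 8)).pixels
        for y in range(13):
            for x in range(17):
                expected = round(int(rgb[y, x].astype(int).sum()) / 3) * 257
                assert gray[y, x] == expected

    def test_luma_mode(self):
        rgb = np.array([[[100, 150, 200]]], dtype=np.uint8)
        gray = rgb_to_gray(CoreImage(rgb, 8), mode="luma")
        assert gray.pixels[0, 0] == round(0.299 * 100 + 0.587 * 150 + 0.114 * 200) * 257

    def test_grayscale_passthrough(self):
        img = CoreImage(np.zeros((4, 4), dtype=np.uint8), 8)
        assert rgb_to_gray(img) is img


class TestInvert:
    def test_endpoint(self):
        img = CoreImage(np.array([[0, 255]], dtype=np.uint8), 8)
        np.testing.assert_array_equal(invert(img).pixels, [[255, 0]])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(hnp.arrays(np.uint8, (6, 7), elements=st.integers(0, 255)))
    def test_involution_and_mean_linearity(self, px):
        img = CoreImage(px, 8)
        inv = invert(img)
        np.testing.assert_array_equal(invert(inv).pixels, px)
        assert px.mean() + inv.pixels.mean() == pytest.approx(255.0)


class TestThreshold:
    def test_full_range_fixed_covers_everything(self):
        img = CoreImage(np.arange(256, dtype=np.uint8).reshape(16, 16), 8)
        assert threshold_mask(img, ("fixed", 0, 255)).all()

    def test_otsu_two_level_matches_brute_force(self):
        rng = np.random.default_rng(1)
        v = np.where(rng.random((50, 50)) < 0.4, 50, 200).astype(np.uint8)
        img = CoreImage(v, 8)
        mask = threshold_mask(img, ("otsu_dark",))
        np.testing.assert_array_equal(mask, v == 50)
        # brute-force maximization of inter-class variance over all 8-bit cuts
        best_t, best_var = None, -1.0
        for t in range(256):
            lo, hi = v[v <= t], v[t < v]
            if lo.size == 0 or hi.size == 0:
                continue
            w0, w1 = lo.size / v.size, hi.size / v.size
            var = w0 * w1 * (lo.mean() - hi.mean()) ** 2
            if var > best_var:
                best_var, best_t = var, t
        np.testing.assert_array_equal(mask, v <= best_t)

    def test_constant_image_warns_and_is_empty(self):
        img = CoreImage(np.full((8, 8), 255, dtype=np.uint8), 8)
        with pytest.warns(UserWarning):
            mask = threshold_mask(img, ("otsu_dark",))
        assert not mask.any()


class TestLabeling:
    def test_empty_mask(self):
        ps = label_particles(np.zeros((5, 5), dtype=bool))
        assert ps.count == 0 and ps.total_area == 0

    def test_diagonal_connectivity(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert label_particles(mask, connectivity=8).count == 1
        assert label_particles(mask, connectivity=4).count == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_flood_fill_oracle(self, connectivity):
        rng = np.random.default_rng(42)
        for density in (0.2, 0.5, 0.8):
            for _ in range(8):
                mask = rng.random((20, 20)) < density
                ps = label_particles(mask, connectivity=connectivity)
                assert sorted(p.area_px for p in ps.particles) == \
                    flood_fill_label(mask, connectivity)

    def test_area_bookkeeping_exact(self):
        rng = np.random.default_rng(3)
        mask = rng.random((64, 64)) < 0.3
        ps = label_particles(mask)
        assert ps.total_area == int(mask.sum())


class TestMetrics:
    def test_single_pixel(self):
        area, perim, circ = particle_metrics(np.ones((1, 1), dtype=bool))
        assert (area, perim) == (1, 4.0)
        assert circ == pytest.approx(4 * np.pi / 16)

    def test_three_by_three_square(self):
        area, perim, circ = particle_metrics(np.ones((3, 3), dtype=bool))
        assert (area, perim) == (9, 12.0)
        assert circ == pytest.approx(4 * np.pi * 9 / 144)

    def test_large_disc_analytic_crack_limit(self):
        """Crack perimeter of a digital disc is 8r, so circularity tends to
        pi^2/16 (~0.617), the analytic limit under this convention."""
        r = 100
        yy, xx = np.mgrid[-110:111, -110:111]
        disc = yy**2 + xx**2 <= r**2
        area, perim, circ = particle_metrics(disc)
        assert perim == pytest.approx(8 * r, rel=0.02)
        assert circ == pytest.approx(np.pi**2 / 16, rel=0.03)


class TestFilter:
    def _ps(self, areas):
        cols = []
        for a in areas:  # horizontal runs separated by gaps
            cols += [True] * a + [False]
        mask = np.array([cols])
        return label_particles(mask)

    def test_defaults_pass_all(self):
        ps = self._ps([5, 10, 20])
        out = filter_particles(ps)
        assert [p.area_px for p in out.particles] == [5, 10, 20]

    def test_size_bound_inclusive(self):
        ps = self._ps([5, 10, 20])
        out = filter_particles(ps, size_min=10)
        assert sorted(p.area_px for p in out.particles) == [10, 20]

    def test_circularity_filter_removes_single_pixel(self):
        ps = self._ps([1])
        assert filter_particles(ps, circ_max=0.5).count == 0

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            filter_particles(self._ps([1]), size_min=5, size_max=2)


class TestQuantifyCore:
    def test_blank_white_core(self):
        img = CoreImage(np.full((64, 64, 3), 255, dtype=np.uint8), 8)
        with pytest.warns(UserWarning):
            res = quantify_core(img)
        assert res.total_area == 0
        assert res.area_fraction == 0.0
        assert res.normalized_signal == 0.0

    def test_normalized_signal_is_stain_over_tissue(self):
        spec = CoreSpec(image_width_px=256, image_height_px=256,
                        tissue_fraction=0.5, stained_fraction=0.125,
                        noise_sd=0.0, seed=17)
        core = generate_core_image(spec)
        res = quantify_core(CoreImage(core.pixels, 8, "c"))
        assert res.normalized_signal == pytest.approx(0.25, abs=0.02)

    def test_area_fraction_scale_free(self):
        afs = []
        for size in (128, 256):
            core = generate_core_image(
                CoreSpec(image_width_px=size, image_height_px=size,
                         tissue_fraction=0.5, stained_fraction=0.06,
                         noise_sd=0.0, seed=23)
            )
            afs.append(quantify_core(CoreImage(core.pixels, 8, "c")).area_fraction)
        assert abs(afs[0] - afs[1]) <= 0.5

    def test_monotone_in_stained_fraction(self):
        tas = []
        for sf in (0.02, 0.05, 0.10):
            core = generate_core_image(
                CoreSpec(image_width_px=128, image_height_px=128,
                         tissue_fraction=0.5, stained_fraction=sf,
                         noise_sd=0.0, seed=29)
            )
            tas.append(quantify_core(CoreImage(core.pixels, 8, "c")).total_area)
        assert tas[0] <= tas[1] <= tas[2]

    def test_total_area_equals_count_times_average(self):
        core = generate_core_image(
            CoreSpec(image_width_px=128, image_height_px=128,
                     stained_fraction=0.05, noise_sd=2.0, seed=31)
        )
        res = quantify_core(CoreImage(core.pixels, 8, "c"))
        assert res.total_area == pytest.approx(res.count * res.average_size)
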