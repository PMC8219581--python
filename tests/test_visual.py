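"""Visual synthesis: gratings, checkerboards, dot fields, masks, dithering."""

import math

import numpy as np
import pytest

from stimkit import (
    apply_noise_filter,
    apply_shape_mask,
    checkerboard_value,
    composite_scene_frame,
    grating_luminance,
    quantize_noise_bit,
    render_stimulus_frame,
)
from stimkit.model import PropertyValue, RenderContext, Scene, Duration, StimulusSpec
from stimkit.visual import (
    RasterPatch,
    init_dot_field,
    resolve_stimulus_properties,
    update_dot_field,
)


def naive_grating(x, y, mean, contrast, sf, orientation, phase, sigma):
    """Independent double-loop reference for the grating equation."""
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        for j in range(x.shape[1]):
            c = contrast
            if sigma is not None:
                c *= math.exp(-(x[i, j] ** 2 + y[i, j] ** 2) / (2 * sigma**2))
            arg = (
                2 * math.pi * sf
                * (x[i, j] * math.cos(orientation) + y[i, j] * math.sin(orientation))
                + phase
            )
            out[i, j] = mean * (1 + c * math.cos(arg))
    return out


class TestGrating:
    def test_zero_contrast_is_flat(self):
        xs = np.linspace(-50, 50, 33)
        X, Y = np.meshgrid(xs, xs)
        L = grating_luminance(X, Y, mean=0.4, contrast=0.0, sf=0.05)
        assert np.allclose(L, 0.4)

    def test_center_peak_with_envelope(self):
        L = grating_luminance(0.0, 0.0, mean=0.5, contrast=0.3, sf=0.05,
                              phase=0.0, envelope_sigma=20.0)
        assert L == pytest.approx(0.5 * 1.3)

    def test_michelson_contrast_equals_parameter(self):
        # brute-force min/max over one finely sampled carrier period
        sf = 0.05
        x = np.linspace(0.0, 1.0 / sf, 100_001)
        L = grating_luminance(x, np.zeros_like(x), mean=0.5, contrast=0.3, sf=sf)
        michelson = (L.max() - L.min()) / (L.max() + L.min())
        assert michelson == pytest.approx(0.3, abs=1e-6)

    def test_mean_luminance_over_full_periods(self):
        # integer-pixel sampling of exactly 4 carrier periods
        xs = np.arange(64)
        X, Y = np.meshgrid(xs, xs)
        L = grating_luminance(X, Y, mean=0.5, contrast=1.0, sf=4 / 64)
        assert abs(L.mean() - 0.5) < 1e-3

    def test_matches_naive_double_loop(self):
        xs = np.arange(64) - 31.5
        X, Y = np.meshgrid(xs, -xs)
        kwargs = dict(mean=0.5, contrast=0.8, sf=0.07, orientation=0.3,
                      phase=1.1)
        got = grating_luminance(X, Y, envelope_sigma=15.0, **kwargs)
        ref = naive_grating(X, Y, sigma=15.0, **kwargs)
        assert np.max(np.abs(got - ref)) < 1e-12

    def test_carrier_contrast_modulation_reduces_periphery(self):
        L0 = grating_luminance(0.0, 0.0, contrast=1.0, sf=0.05,
                               carrier_contrast_mod=10.0)
        Lfar = grating_luminance(100.0, 0.0, contrast=1.0, sf=0.05,
                                 carrier_contrast_mod=10.0)
        assert abs(L0 - 0.5) > abs(Lfar - 0.5) - 1e-9
        assert Lfar == pytest.approx(0.5, abs=1e-6)

    def test_contrast_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            grating_luminance(0.0, 0.0, contrast=1.5)


class TestCheckerboard:
    def test_adjacent_rect_cells_alternate(self):
        params = {"check_w": 10.0, "check_h": 10.0}
        assert checkerboard_value(0.1, 0.1, "rect", params) == 0
        assert checkerboard_value(10.1, 0.1, "rect", params) == 1
        assert checkerboard_value(10.1, 10.1, "rect", params) == 0

    def test_two_cell_translation_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-100, 100, 1000)
        y = rng.uniform(-100, 100, 1000)
        params = {"check_w": 7.0, "check_h": 11.0}
        a = checkerboard_value(x, y, "rect", params)
        b = checkerboard_value(x + 14.0, y, "rect", params)
        assert np.array_equal(a, b)

    def test_radial_sector_rotation_flips_parity(self):
        # brute force over a 100x100 grid, avoiding sector/ring boundaries
        n_sectors, ring_w = 8, 10.0
        params = {"n_sectors": n_sectors, "ring_width": ring_w}
        xs = np.linspace(-60, 60, 100) + 0.137
        X, Y = np.meshgrid(xs, xs)
        r = np.hypot(X, Y)
        theta = np.mod(np.arctan2(Y, X), 2 * np.pi)
        sector_pos = theta / (2 * np.pi / n_sectors)
        off_boundary = (
            (r > 1.0)
            & (np.abs(sector_pos - np.round(sector_pos)) > 1e-3)
            & (np.abs(r / ring_w - np.round(r / ring_w)) > 1e-3)
        )
        a = checkerboard_value(X, Y, "radial", params)
        dphi = 2 * np.pi / n_sectors
        Xr = X * np.cos(dphi) - Y * np.sin(dphi)
        Yr = X * np.sin(dphi) + Y * np.cos(dphi)
        b = checkerboard_value(Xr, Yr, "radial", params)
        assert np.array_equal(a[off_boundary], 1 - b[off_boundary])

    def test_nonpositive_sizes_rejected(self):
        with pytest.raises(ValueError):
            checkerboard_value(0.0, 0.0, "rect", {"check_w": 0.0, "check_h": 1.0})
        with pytest.raises(ValueError):
            checkerboard_value(0.0, 0.0, "radial",
                               {"n_sectors": 0, "ring_width": 1.0})


class TestDotField:
    def test_full_coherence_linear_translation(self, rng):
        state = init_dot_field(200, 100.0, 1.0, 1000, rng)
        new = update_dot_field(
            state, "linear",
            {"speed": 2.0, "direction": 0.0, "coherence": 1.0,
             "lifetime": 1000, "aperture_radius": 100.0},
            rng,
        )
        survived = new.ages > 0
        assert survived.any()
        assert np.allclose(new.positions[survived, 0],
                           state.positions[survived, 0] + 2.0)
        assert np.allclose(new.positions[survived, 1],
                           state.positions[survived, 1])

    def test_expansive_increases_radius_by_speed(self, rng):
        state = init_dot_field(500, 100.0, 1.0, 1000, rng)
        r0 = np.hypot(state.positions[:, 0], state.positions[:, 1])
        new = update_dot_field(
            state, "expansive",
            {"speed": 1.0, "coherence": 1.0, "lifetime": 1000,
             "aperture_radius": 100.0},
            rng,
        )
        survived = new.ages > 0
        r1 = np.hypot(new.positions[survived, 0], new.positions[survived, 1])
        assert np.allclose(r1, r0[survived] + 1.0, atol=1e-9)

    def test_radial_preserves_radius(self, rng):
        state = init_dot_field(500, 100.0, 1.0, 1000, rng)
        r0 = np.hypot(state.positions[:, 0], state.positions[:, 1])
        new = update_dot_field(
            state, "radial",
            {"speed": 2.0, "coherence": 1.0, "lifetime": 1000,
             "aperture_radius": 100.0},
            rng,
        )
        survived = new.ages > 0
        r1 = np.hypot(new.positions[survived, 0], new.positions[survived, 1])
        assert np.allclose(r1, r0[survived], atol=1e-9)

    def test_zero_coherence_has_no_net_direction(self, rng):
        n = 10_000
        state = init_dot_field(n, 1000.0, 0.0, 10_000, rng)
        new = update_dot_field(
            state, "linear",
            {"speed": 1.0, "direction": 0.0, "coherence": 0.0,
             "lifetime": 10_000, "aperture_radius": 1000.0},
            rng,
        )
        survived = new.ages > 0
        d = new.positions[survived] - state.positions[survived]
        angles = np.arctan2(d[:, 1], d[:, 0])
        resultant = np.hypot(np.mean(np.cos(angles)), np.mean(np.sin(angles)))
        assert resultant < 0.03  # ~1.3/sqrt(n) Monte-Carlo bound

    def test_count_conserved_and_positions_inside(self, rng):
        state = init_dot_field(300, 50.0, 0.5, 10, rng)
        params = {"speed": 5.0, "direction": 1.0, "coherence": 0.5,
                  "lifetime": 10, "aperture_radius": 50.0}
        for _ in range(30):
            state = update_dot_field(state, "linear", params, rng)
            assert state.positions.shape == (300, 2)
            assert np.all(np.hypot(state.positions[:, 0],
                                   state.positions[:, 1]) <= 50.0 + 1e-9)
            assert np.all(state.ages < 10)

    def test_zero_aperture_rejected(self, rng):
        with pytest.raises(ValueError):
            init_dot_field(10, 0.0, 1.0, 10, rng)


def _flat_patch(h=21, w=31, value=0.5):
    return RasterPatch(origin=(0, 0),
                       pixels=np.full((h, w, 3), value),
                       alpha=np.ones((h, w)))


class TestShapeMask:
    def test_rectangle_keeps_everything(self):
        p = apply_shape_mask(_flat_patch(), "rectangle", (31, 21))
        assert np.all(p.alpha == 1.0)

    def test_ellipse_drops_corners_keeps_center(self):
        p = apply_shape_mask(_flat_patch(), "ellipse", (31, 21))
        assert p.alpha[10, 15] == 1.0
        for r, c in [(0, 0), (0, 30), (20, 0), (20, 30)]:
            assert p.alpha[r, c] == 0.0

    def test_cross_center_on_corners_off(self):
        p = apply_shape_mask(_flat_patch(), "cross", (31, 21))
        assert p.alpha[10, 15] == 1.0
        for r, c in [(0, 0), (0, 30), (20, 0), (20, 30)]:
            assert p.alpha[r, c] == 0.0

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError):
            apply_shape_mask(_flat_patch(), "pentagon", (31, 21))


class TestNoiseFilter:
    def test_zero_amplitude_is_identity(self, rng):
        p = _flat_patch()
        q = apply_noise_filter(p, 0.0, rng)
        assert np.array_equal(p.pixels, q.pixels)

    def test_noise_is_zero_mean(self, rng):
        p = _flat_patch(h=1000, w=1000)
        q = apply_noise_filter(p, 0.1, rng)
        diff = (q.pixels - p.pixels)[:, :, 0]
        bound = 3 * (0.1 / math.sqrt(3)) / 1000  # CLT over 10^6 pixels
        assert abs(diff.mean()) < bound

    def test_output_clipped_to_unit_interval(self, rng):
        p = _flat_patch(value=0.99)
        q = apply_noise_filter(p, 1.0, rng)
        assert q.pixels.min() >= 0.0 and q.pixels.max() <= 1.0


class TestNoiseBit:
    def test_exact_level_is_deterministic(self, rng):
        v = np.full((100,), 37 / 255.0)
        out = quantize_noise_bit(v, 8, rng)
        assert np.all(out == 37)

    def test_midway_value_splits_evenly(self, rng):
        v = np.full((40_000,), 0.5 / 255.0)
        out = quantize_noise_bit(v, 8, rng)
        assert set(np.unique(out)) <= {0, 1}
        # binomial(n=40000, p=0.5): 3 sigma on the mean is 0.5*3/sqrt(n)*2
        assert abs(out.mean() - 0.5) < 3 * 0.5 / 200

    def test_output_restricted_to_adjacent_levels(self, rng):
        v = rng.random(10_000)
        out = quantize_noise_bit(v, 8, rng).astype(float)
        lo = np.floor(v * 255)
        assert np.all((out == lo) | (out == lo + 1))

    def test_out_of_range_rejected(self, rng):
        with pytest.raises(ValueError):
            quantize_noise_bit(np.array([1.2]), 8, rng)


class TestRenderAndComposite:
    def _props(self, stim, display, **bindings):
        ctx = RenderContext(frame_index=0, total_frames=30, refresh_rate=60.0)
        return resolve_stimulus_properties(stim, display, bindings, ctx), ctx

    def test_patch_uniform_color(self, display):
        stim = StimulusSpec(
            name="p", type="patch", shape="rectangle",
            properties={"color": PropertyValue(value=[1.0, 0.0, 0.0]),
                        "size_x": PropertyValue(value=10.0),
                        "size_y": PropertyValue(value=10.0)},
        )
        props, ctx = self._props(stim, display)
        patch = render_stimulus_frame(stim, props, ctx, display)
        assert patch.pixels.shape == (10, 10, 3)
        assert np.allclose(patch.pixels, [1.0, 0.0, 0.0])
        assert np.all(patch.alpha == 1.0)

    def test_unrotated_grating_varies_along_columns_only(self, display):
        stim = StimulusSpec(
            name="g", type="grating", shape="rectangle",
            properties={"size_x": PropertyValue(value=64.0),
                        "size_y": PropertyValue(value=64.0),
                        "spatial_frequency": PropertyValue(
                            value=0.05, unit="cycles_per_px"),
                        "gratingRotation": PropertyValue(mode="variable")},
        )
        props, ctx = self._props(stim, display, gratingRotation=0.0)
        patch = render_stimulus_frame(stim, props, ctx, display)
        col_std = patch.pixels[:, :, 0].std(axis=0)
        row_var = patch.pixels[:, :, 0].std(axis=1)
        assert np.allclose(col_std, 0.0, atol=1e-12)  # rows identical
        assert row_var.max() > 0.1  # columns vary

    def test_dot_render_is_seed_deterministic(self, display):
        stim = StimulusSpec(
            name="d", type="dots_linear", shape="rectangle",
            properties={"size_x": PropertyValue(value=80.0),
                        "size_y": PropertyValue(value=80.0),
                        "n_dots": PropertyValue(value=50)},
        )
        props, ctx = self._props(stim, display)
        a = render_stimulus_frame(stim, props, ctx, display,
                                  rng=np.random.default_rng(7), dot_state={})
        b = render_stimulus_frame(stim, props, ctx, display,
                                  rng=np.random.default_rng(7), dot_state={})
        assert np.array_equal(a.pixels, b.pixels)
        assert np.array_equal(a.alpha, b.alpha)

    def test_auditory_type_dispatch_error(self, display):
        stim = StimulusSpec(name="t", type="tone", properties={})
        props, ctx = self._props(stim, display)
        with pytest.raises(ValueError, match="visual"):
            render_stimulus_frame(stim, props, ctx, display)

    def test_text_renders_glyph_pixels(self, display):
        stim = StimulusSpec(
            name="txt", type="text", shape="rectangle",
            properties={"text_string": PropertyValue(value="OK"),
                        "size_x": PropertyValue(value=60.0),
                        "size_y": PropertyValue(value=30.0)},
        )
        props, ctx = self._props(stim, display)
        patch = render_stimulus_frame(stim, props, ctx, display)
        assert patch.alpha.sum() > 0

    def _scene(self):
        return Scene(name="s", duration=Duration(0.5, "s"), objects=[])

    def test_no_patches_gives_uniform_background(self, display):
        buf = composite_scene_frame(self._scene(), [], display,
                                    background=(0.25, 0.5, 0.75))
        assert buf.pixels.shape == (600, 800, 3)
        assert np.allclose(buf.pixels[::50, ::50], [0.25, 0.5, 0.75], atol=1e-6)

    def test_opaque_patch_replaces_its_region_only(self, display):
        patch = RasterPatch(origin=(100, 200),
                            pixels=np.full((20, 30, 3), 1.0),
                            alpha=np.ones((20, 30)))
        buf = composite_scene_frame(self._scene(), [patch], display,
                                    background=(0.0, 0.0, 0.0))
        assert np.all(buf.pixels[200:220, 100:130] == 1.0)
        assert np.all(buf.pixels[:200, :] == 0.0)
        assert np.all(buf.pixels[220:, :] == 0.0)

    def test_non_overlapping_patches_commute(self, display):
        a = RasterPatch(origin=(10, 10), pixels=np.full((5, 5, 3), 0.9),
                        alpha=np.ones((5, 5)))
        b = RasterPatch(origin=(100, 100), pixels=np.full((5, 5, 3), 0.1),
                        alpha=np.ones((5, 5)))
        buf1 = composite_scene_frame(self._scene(), [a, b], display)
        buf2 = composite_scene_frame(self._scene(), [b, a], display)
        assert np.array_equal(buf1.pixels, buf2.pixels)

    def test_offscreen_patch_is_clipped_without_error(self, display):
        patch = RasterPatch(origin=(-10, -10), pixels=np.full((20, 20, 3), 1.0),
                            alpha=np.ones((20, 20)))
        buf = composite_scene_frame(self._scene(), [patch], display,
                                    background=(0.0, 0.0, 0.0))
        assert np.all(buf.pixels[:10, :10] == 1.0)
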