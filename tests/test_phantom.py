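"""Phantom generator: geometry, rendering, kinematics, determinism."""

import math

import numpy as np
import pytest

from nailfold import morphometry as mm
from nailfold import phantom
from nailfold.errors import GeometryError, InvalidParameterError


class TestCapillaryPath:
    def test_straight_limbs_match_principal_orientation(self):
        rng = np.random.default_rng(0)
        cap = phantom.make_capillary_path(
            (100.0, 150.0), math.pi / 2, 12.0, tortuosity=0.0, rng=rng
        )
        turn_pts = int(round(math.pi * 0.5 * 2.5 * 12.0))
        limb = np.r_[cap.orientations[:cap.apex_index - turn_pts],
                     cap.orientations[cap.apex_index + turn_pts:]]
        assert np.allclose(limb, math.pi / 2, atol=1e-9)

    def test_limb_arc_lengths(self):
        cap = phantom.make_capillary_path((0.0, 0.0), math.pi / 2, 10.0,
                                          limb_length_um=100.0,
                                          rng=np.random.default_rng(1))
        # 2 limbs * 100 um + turn of ~pi * 12.5 um at 1 um steps
        assert len(cap.points) == pytest.approx(200 + math.pi * 12.5, abs=3)
        assert cap.step_um == 1.0

    def test_shape_score_high_for_straight_hairpin(self):
        cap = phantom.make_capillary_path((0.0, 0.0), math.pi / 2, 12.0,
                                          tortuosity=0.0,
                                          rng=np.random.default_rng(2))
        turn = int(round(math.pi * 15.0))
        limb_orients = np.r_[cap.orientations[:cap.apex_index - turn],
                             cap.orientations[cap.apex_index + turn:]]
        assert mm.circular_dispersion(limb_orients) >= 0.9

    def test_determinism(self):
        a = phantom.make_capillary_path((5.0, 5.0), 1.3, 11.8, tortuosity=0.4,
                                        rng=np.random.default_rng(9))
        b = phantom.make_capillary_path((5.0, 5.0), 1.3, 11.8, tortuosity=0.4,
                                        rng=np.random.default_rng(9))
        assert np.array_equal(a.points, b.points)
        assert np.array_equal(a.orientations, b.orientations)

    @pytest.mark.parametrize("kwargs", [
        {"width_um": 0.0}, {"width_um": -3.0}, {"limb_length_um": 0.0},
        {"tortuosity": -0.1},
    ])
    def test_invalid_parameters(self, kwargs):
        base = dict(apex_xy=(0, 0), principal_orientation=1.0, width_um=10.0)
        base.update(kwargs)
        with pytest.raises(InvalidParameterError):
            phantom.make_capillary_path(**base)


class TestTruthGeneration:
    def test_density_definition(self):
        spec = phantom.PhantomSpec(n_capillaries=5, spacing_um=120,
                                   frame_shape=(420, 800), seed=4)
        truth = phantom.generate_truth(spec)
        span = truth.apices[:, 0].max() - truth.apices[:, 0].min()
        assert truth.density_truth == pytest.approx(5 / (span / 1000.0))

    def test_scale_consistency(self):
        """Halving the pixel scale while doubling frame dims leaves every
        um-unit ground truth unchanged."""
        a = phantom.generate_truth(phantom.PhantomSpec(seed=6))
        b = phantom.generate_truth(phantom.PhantomSpec(
            seed=6, pixel_scale_um=0.5, frame_shape=(960, 1280)))
        assert np.array_equal(a.apices, b.apices)
        for pa, pb in zip(a.paths, b.paths):
            assert np.array_equal(pa.points, pb.points)

    def test_overfull_frame_rejected(self):
        spec = phantom.PhantomSpec(n_capillaries=12, spacing_um=150,
                                   frame_shape=(480, 640))
        with pytest.raises(GeometryError):
            phantom.generate_truth(spec)


class TestRenderMosaic:
    def test_centerline_minima_and_profile_width(self):
        """A rendered 12-um tube shows its FWHM at the defining fraction."""
        spec = phantom.PhantomSpec(n_capillaries=1, width_um=12.0,
                                   frame_shape=(420, 300), noise_sd=0.0,
                                   tortuosity=0.0, derangement_spread=0.0,
                                   apex_y_jitter_um=0.0, margin_um=150.0, seed=1)
        truth = phantom.generate_truth(spec)
        img = phantom.render_mosaic(spec, truth)
        apex = truth.apices[0]
        row = int(apex[1]) + 60  # on the straight limb section
        profile = img[row]
        col = int(np.argmin(profile))
        # limb centerline x position
        limb_x = truth.paths[0].points[:, 0]
        assert min(abs(col - limb_x.min()), abs(col - limb_x.max())) <= 1.0
        depth = spec.background - profile.min()
        half = spec.background - 0.5 * depth
        below = np.flatnonzero(profile < half)
        runs = np.split(below, np.flatnonzero(np.diff(below) > 1) + 1)
        widths = [r[-1] - r[0] + 1 for r in runs]
        assert any(abs(w - 12.0) <= 1.5 for w in widths)

    def test_empty_spec_uniform_background(self):
        spec = phantom.PhantomSpec(n_capillaries=0, noise_sd=0.0, seed=0)
        truth = phantom.generate_truth(spec)
        img = phantom.render_mosaic(spec, truth)
        assert np.all(img == spec.background)

    def test_deterministic_rendering(self):
        spec = phantom.PhantomSpec(n_capillaries=3, frame_shape=(420, 640),
                                   spacing_um=120, noise_sd=5.0, seed=8)
        truth = phantom.generate_truth(spec)
        assert np.array_equal(phantom.render_mosaic(spec, truth),
                              phantom.render_mosaic(spec, truth))


class TestRenderVideo:
    def test_per_frame_displacement_follows_speed(self):
        """Cells advance v * 1000 / fps um per frame: at the healthy-control
        operating point (0.311 mm/s, 120 fps) that is 2.59 um.  Verified by
        cross-correlating the along-path intensity profile between frames."""
        assert 0.311 * 1000 / 120 == pytest.approx(2.5917, abs=1e-3)
        spec = phantom.PhantomSpec(n_capillaries=1, frame_shape=(300, 240),
                                   velocity_mm_s=0.311, noise_sd=0.0,
                                   tortuosity=0.0, derangement_spread=0.0,
                                   apex_y_jitter_um=0.0, margin_um=120.0,
                                   apex_y_um=120.0, n_frames=4, seed=5)
        truth = phantom.generate_truth(spec)
        video = phantom.render_video(spec, truth)
        cap = truth.paths[0]
        # sample intensity along the arterial limb only (monotone arc length)
        pts = cap.points[:cap.apex_index - 20]
        from scipy import ndimage
        profs = [
            ndimage.map_coordinates(np.asarray(f, float),
                                    [pts[:, 1], pts[:, 0]], order=1)
            for f in video.frames
        ]
        shifts = []
        for a, b in zip(profs[:-1], profs[1:]):
            a = a - a.mean()
            b = b - b.mean()
            xc = np.correlate(b, a, mode="full")
            shifts.append(np.argmax(xc) - (len(a) - 1))
        # cells move toward the apex or away, consistently, ~2.59 um/frame
        assert np.mean(np.abs(shifts)) == pytest.approx(2.59, abs=0.75)

    def test_zero_velocity_static_frames(self):
        spec = phantom.PhantomSpec(n_capillaries=2, frame_shape=(300, 400),
                                   spacing_um=120, velocity_mm_s=0.0,
                                   noise_sd=0.0, n_frames=3, seed=2,
                                   apex_y_um=120.0)
        truth = phantom.generate_truth(spec)
        video = phantom.render_video(spec, truth)
        assert np.array_equal(video.frames[0], video.frames[1])
        assert np.array_equal(video.frames[1], video.frames[2])

    def test_displacement_halves_at_double_frame_rate(self):
        v, fps = 0.311, 120.0
        assert (v * 1000 / (2 * fps)) == pytest.approx(0.5 * v * 1000 / fps)

    def test_too_few_frames_rejected(self):
        spec = phantom.PhantomSpec(n_frames=1)
        truth = phantom.generate_truth(spec)
        with pytest.raises(InvalidParameterError):
            phantom.render_video(spec, truth)


class TestOverlappingFrames:
    def _tiles(self, jitter, seed=0, n_tiles=3, overlap=0.3):
        spec = phantom.PhantomSpec(n_capillaries=6, spacing_um=130,
                                   frame_shape=(300, 420), noise_sd=3.0,
                                   seed=seed, apex_y_um=120.0)
        extent = phantom.overlapping_extent_um(spec, n_tiles, overlap)
        truth = phantom.generate_truth(spec, extent_um=extent)
        return spec, phantom.render_overlapping_frames(
            spec, truth, n_tiles, overlap, jitter_px=jitter)

    def test_geometry_and_offsets(self):
        spec, ts = self._tiles(jitter=0.0)
        assert len(ts.tiles) == 3
        step = round(0.7 * 420)
        assert np.allclose(ts.true_offsets[:, 0], [0, step, 2 * step])
        assert np.array_equal(ts.nominal_offsets, ts.true_offsets)

    def test_jitter_bounded(self):
        _, ts = self._tiles(jitter=10.0, seed=3)
        err = np.abs(ts.nominal_offsets - ts.true_offsets)
        assert err.max() <= 10.0
        assert err[1:].max() > 0.0

    def test_deterministic(self):
        _, a = self._tiles(jitter=5.0, seed=7)
        _, b = self._tiles(jitter=5.0, seed=7)
        assert all(np.array_equal(x, y) for x, y in zip(a.tiles, b.tiles))
        assert np.array_equal(a.nominal_offsets, b.nominal_offsets)

    def test_bad_parameters(self):
        spec = phantom.PhantomSpec(seed=0)
        truth = phantom.generate_truth(spec)
        with pytest.raises(InvalidParameterError):
            phantom.render_overlapping_frames(spec, truth, 1, 0.3)
        with pytest.raises(InvalidParameterError):
            phantom.render_overlapping_frames(spec, truth, 3, 1.2)
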