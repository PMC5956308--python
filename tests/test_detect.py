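"""Ridge filtering, apex detection, path tracing and width profiling."""

import math

import numpy as np
import pytest

from nailfold import detect, phantom
from nailfold.errors import InvalidParameterError, TraceError


class TestRidgeMap:
    def test_constant_image_zero_response(self):
        rm = detect.ridge_map(np.full((120, 140), 180.0), (8, 12))
        assert np.all(rm.response == 0.0)

    def test_response_concentrates_on_centerline(self, single_tube_phantom):
        spec, truth, image, ridge = single_tube_phantom
        cap = truth.paths[0]
        limb_pts = cap.points[30:80].astype(int)
        on_ridge = ridge.response[limb_pts[:, 1], limb_pts[:, 0]]
        background = np.median(ridge.response[ridge.response > 0])
        assert on_ridge.min() > 5 * max(background, 1e-9)
        # orientation along the vertical limb is pi/2 within 5 degrees
        orients = ridge.orientation[limb_pts[:, 1], limb_pts[:, 0]]
        d = np.abs(orients - math.pi / 2)
        assert np.degrees(np.minimum(d, math.pi - d).max()) < 5.0

    def test_rotation_equivariance(self, single_tube_phantom):
        spec, truth, image, ridge = single_tube_phantom
        rot = np.rot90(image)
        rm90 = detect.ridge_map(rot, (8, 12, 16), 1.0)
        W = image.shape[1]
        cap = truth.paths[0]
        p = cap.points[50].astype(int)  # on the vertical limb
        # pixel image[y, x] lands at rot[W-1-x, y] under a 90 deg CCW turn
        o1 = ridge.orientation[p[1], p[0]]
        o2 = rm90.orientation[W - 1 - p[0], p[1]]
        d = abs((o1 + math.pi / 2) % math.pi - o2)
        assert min(d, math.pi - d) < 0.1

    def test_requires_positive_scales(self):
        with pytest.raises(InvalidParameterError):
            detect.ridge_map(np.zeros((50, 50)), ())


class TestDetectApices:
    def test_empty_image_yields_no_apices(self):
        rm = detect.ridge_map(np.full((200, 200), 150.0), (8, 12))
        assert detect.detect_apices(rm) == []

    def test_finds_all_hairpins_near_truth(self, clean_row_phantom):
        spec, truth, image, ridge = clean_row_phantom
        apices = detect.detect_apices(ridge)
        assert len(apices) == spec.n_capillaries
        xs = [a.x for a in apices]
        assert xs == sorted(xs)  # left-to-right ordering
        for a in apices:
            d = np.hypot(truth.apices[:, 0] - a.x, truth.apices[:, 1] - a.y)
            assert d.min() <= 10.0

    def test_close_candidates_merge(self, clean_row_phantom):
        """With a merge radius wider than the spacing, neighbours collapse."""
        spec, truth, image, ridge = clean_row_phantom
        few = detect.detect_apices(ridge, min_separation_um=150.0)
        assert len(few) < spec.n_capillaries


class TestTracePath:
    def test_full_limbs_on_clean_tube(self, single_tube_phantom):
        spec, truth, image, ridge = single_tube_phantom
        apex = detect.detect_apices(ridge)[0]
        path = detect.trace_path(ridge, apex)
        assert path.limb_arc_lengths_um == (100.0, 100.0)
        assert len(path.points) == 201
        assert np.array_equal(path.points[path.apex_index], path.apex_xy)
        # determinism
        again = detect.trace_path(ridge, apex)
        assert np.array_equal(path.points, again.points)

    def test_limb_truncated_at_response_boundary(self):
        """A vessel shorter than the tracing budget stops at its end."""
        spec = phantom.PhantomSpec(n_capillaries=1, frame_shape=(300, 300),
                                   noise_sd=0.0, seed=1, tortuosity=0.0,
                                   derangement_spread=0.0, apex_y_jitter_um=0.0,
                                   margin_um=150.0, limb_length_um=45.0,
                                   apex_y_um=120.0)
        truth = phantom.generate_truth(spec)
        image = phantom.render_mosaic(spec, truth)
        ridge = detect.ridge_map(image, (8, 12, 16), 1.0)
        apex = detect.detect_apices(ridge)[0]
        path = detect.trace_path(ridge, apex, max_limb_um=100.0)
        assert max(path.limb_arc_lengths_um) < 100.0

    def test_off_ridge_apex_rejected(self, single_tube_phantom):
        spec, truth, image, ridge = single_tube_phantom
        with pytest.raises(TraceError):
            detect.trace_path(ridge, (5.0, 5.0))

    def test_orientation_consistency_along_limbs(self, single_tube_phantom):
        spec, truth, image, ridge = single_tube_phantom
        apex = detect.detect_apices(ridge)[0]
        path = detect.trace_path(ridge, apex)
        turn = int(round(math.pi * 0.5 * 2.5 * 12.0)) + 5
        limb = np.r_[path.orientations[:path.apex_index - turn],
                     path.orientations[path.apex_index + turn:]]
        R = abs(np.exp(2j * limb).mean())
        circ_sd = math.degrees(math.sqrt(-math.log(max(R, 1e-12)) / 2))
        assert circ_sd <= 5.0


class TestMeasureWidths:
    def test_constant_width_tube(self, single_tube_phantom):
        spec, truth, image, ridge = single_tube_phantom
        apex = detect.detect_apices(ridge)[0]
        path = detect.measure_widths(image, detect.trace_path(ridge, apex))
        w = path.widths[path.width_valid]
        assert abs(w.mean() - 12.0) <= 1.0
        assert path.width_valid.mean() > 0.9

    def test_cohort_operating_width(self):
        """At the healthy-control operating width (11.8 um) the mean path
        width is recovered within 1 um."""
        spec = phantom.PhantomSpec(n_capillaries=1, width_um=11.8,
                                   frame_shape=(420, 300), noise_sd=0.0,
                                   seed=2, tortuosity=0.0, margin_um=150.0,
                                   derangement_spread=0.0, apex_y_jitter_um=0.0)
        truth = phantom.generate_truth(spec)
        image = phantom.render_mosaic(spec, truth)
        ridge = detect.ridge_map(image, (8, 12, 16), 1.0)
        apex = detect.detect_apices(ridge)[0]
        path = detect.measure_widths(image, detect.trace_path(ridge, apex))
        w = path.widths[path.width_valid]
        assert abs(w.mean() - 11.8) <= 1.0

    def test_border_points_flagged(self, single_tube_phantom):
        spec, truth, image, ridge = single_tube_phantom
        apex = detect.detect_apices(ridge)[0]
        path = detect.trace_path(ridge, apex)
        # crop the mosaic so the profile at limb points leaves the image
        cropped = image[:, int(path.apex_xy[0]) - 30:]
        shifted = path
        shifted.points = path.points - [int(path.apex_xy[0]) - 30, 0]
        shifted.apex_xy = path.apex_xy - [int(path.apex_xy[0]) - 30, 0]
        measured = detect.measure_widths(cropped, shifted)
        assert (~measured.width_valid).sum() > 0


class TestRecallAcrossSeeds:
    @pytest.mark.parametrize("seed", range(6))
    def test_apex_count_within_one(self, seed):
        n = 4 + seed % 9
        spec = phantom.PhantomSpec(n_capillaries=n, spacing_um=100,
                                   frame_shape=(420, 120 + 100 * n),
                                   noise_sd=6.0, seed=seed)
        truth = phantom.generate_truth(spec)
        image = phantom.render_mosaic(spec, truth)
        ridge = detect.ridge_map(image, (8, 12, 16), 1.0)
        apices = detect.detect_apices(ridge)
        assert abs(len(apices) - n) <= 1
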