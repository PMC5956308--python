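"""Distal-row capillary detection, apex localisation, tracing, widths.

The detector is a classical multiscale ridge pipeline:

1. :func:`ridge_map` - Hessian ridge filtering at a set of physical scales.
   Dark tubes have a large positive second derivative across the vessel, so
   the response at scale sigma is the gamma-normalised largest Hessian
   eigenvalue ``sigma^2 * max(lambda_1, 0)``; the local vessel orientation
   is the eigenvector of the *smaller* eigenvalue (the along-ridge axis),
   taken modulo pi.
2. :func:`detect_apices` - apices are turning points of the orientation
   field: where the local axial coherence of orientations collapses (both
   limbs plus the turn are present) while the ridge response stays high.
   Candidates are non-maximum-suppressed at a minimum separation, refined to
   the topmost ridge pixel of their loop, and restricted to a band below the
   upper envelope of detections (the distal row is the topmost row).
3. :func:`trace_path` - bidirectional steepest-ridge following from the
   apex at a fixed 1 um arc-length step, with perpendicular re-centering on
   the ridge crest, truncated at 100 um per limb.
4. :func:`measure_widths` - full width at half depth of the intensity
   profile sampled perpendicular to the local orientation; the same
   definition the phantom renderer uses, so ground truth is commensurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import hessian_matrix, peak_local_max
from skimage.measure import label as cc_label

from .errors import InvalidParameterError, TraceError, WidthMeasurementError

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class RidgeMap:
    """Multiscale vesselness response and dominant local orientation."""

    response: np.ndarray     # gamma-normalised ridge strength, >= 0
    orientation: np.ndarray  # ridge direction, radians mod pi
    pixel_scale_um: float
    scales_um: tuple
    scale: np.ndarray = field(default=None, repr=False)  # best scale (um) per px

    _u: np.ndarray = field(default=None, repr=False)  # cos(2*theta), cached
    _v: np.ndarray = field(default=None, repr=False)  # sin(2*theta), cached

    def axial_fields(self):
        if self._u is None:
            self._u = np.cos(2.0 * self.orientation)
            self._v = np.sin(2.0 * self.orientation)
        return self._u, self._v


@dataclass
class ApexCandidate:
    x: float
    y: float
    score: float


@dataclass
class CapillaryPath:
    """One detected capillary: apex, ordered path, per-point measurements.

    Points run from the arterial-limb end through the apex to the
    venous-limb end at ~1 um arc-length spacing, in mosaic pixel
    coordinates.  Widths are NaN until :func:`measure_widths` fills them;
    ``width_valid`` marks points whose perpendicular profile was measurable.
    """

    apex_xy: np.ndarray            # (2,) px
    points: np.ndarray             # (n, 2) px
    orientations: np.ndarray       # (n,) radians mod pi
    widths: np.ndarray             # (n,) um
    width_valid: np.ndarray        # (n,) bool
    apex_index: int
    limb_arc_lengths_um: tuple     # (arterial, venous)
    detection_score: float
    pixel_scale_um: float


# ---------------------------------------------------------------------------
# ridge filtering
# ---------------------------------------------------------------------------

def ridge_map(mosaic, scales_um, pixel_scale_um=1.0) -> RidgeMap:
    """Multiscale Hessian ridge filter for dark tubes on a bright background.

    ``scales_um`` are target vessel widths (FWHM); each is converted to the
    matched Gaussian derivative scale sigma = width / 2.355 / pixel_scale.
    The per-pixel response is the maximum over scales; orientation comes
    from the best-responding scale.
    """
    scales_um = tuple(scales_um)
    if len(scales_um) == 0 or any(s <= 0 for s in scales_um):
        raise InvalidParameterError("need >= 1 strictly positive scale")
    image = np.asarray(mosaic, dtype=float)
    best = np.full(image.shape, -np.inf)
    orientation = np.zeros(image.shape)
    best_scale = np.full(image.shape, float(scales_um[0]))
    for scale in scales_um:
        sigma = max(scale * FWHM_TO_SIGMA / pixel_scale_um, 0.7)
        Hrr, Hrc, Hcc = hessian_matrix(
            image, sigma=sigma, order="rc", use_gaussian_derivatives=True
        )
        half_tr = 0.5 * (Hrr + Hcc)
        root = np.sqrt((0.5 * (Hrr - Hcc)) ** 2 + Hrc ** 2)
        lam1 = half_tr + root  # most positive = across a dark ridge
        resp = sigma ** 2 * np.clip(lam1, 0.0, None)
        # eigenvector of lam1 in (r, c) components: either (Hrc, lam1 - Hcc)
        # ... rows of (M - lam1 I) give two parallel forms; use whichever is
        # better conditioned at each pixel.  The ridge runs perpendicular.
        vr1, vc1 = Hrc, lam1 - Hrr
        vr2, vc2 = lam1 - Hcc, Hrc
        use2 = np.hypot(vr2, vc2) > np.hypot(vr1, vc1)
        vr = np.where(use2, vr2, vr1)
        vc = np.where(use2, vc2, vc1)
        degen = np.hypot(vr, vc) < 1e-12
        theta_across = np.arctan2(vr, np.where(degen, 1.0, vc))
        theta = np.mod(theta_across + math.pi / 2, math.pi)
        better = resp > best
        best[better] = resp[better]
        orientation[better] = theta[better]
        best_scale[better] = scale
    best[best < 0] = 0.0
    # Gaussian-derivative edge effects produce strong spurious responses in a
    # band of ~3 sigma around the image border; blank it
    margin = int(math.ceil(3.0 * max(scales_um) * FWHM_TO_SIGMA / pixel_scale_um))
    if margin > 0 and best.shape[0] > 2 * margin and best.shape[1] > 2 * margin:
        mask = np.zeros_like(best, dtype=bool)
        mask[margin:-margin, margin:-margin] = True
        best[~mask] = 0.0
    return RidgeMap(
        response=best,
        orientation=orientation,
        pixel_scale_um=pixel_scale_um,
        scales_um=scales_um,
        scale=best_scale,
    )


# ---------------------------------------------------------------------------
# apex detection
# ---------------------------------------------------------------------------

def _axial_coherence(ridge: RidgeMap, smooth_um: float) -> np.ndarray:
    """Response-weighted local mean resultant length of orientations.

    Near 1 where orientations agree over the smoothing window (straight
    limbs); low at hairpin turns where both limb axes and the turn mix.
    """
    u, v = ridge.axial_fields()
    w = ridge.response
    sig = max(smooth_um / ridge.pixel_scale_um, 1.0)
    wsum = ndimage.gaussian_filter(w, sig)
    ubar = ndimage.gaussian_filter(w * u, sig) / np.maximum(wsum, 1e-12)
    vbar = ndimage.gaussian_filter(w * v, sig) / np.maximum(wsum, 1e-12)
    return np.clip(np.hypot(ubar, vbar), 0.0, 1.0)


def detect_apices(ridge: RidgeMap, min_score=8.0, min_separation_um=30.0,
                  distal_band_um=80.0, smooth_um=8.0, turn_weight_min=0.25):
    """Locate capillary apices as orientation-turning points on strong ridges.

    Returns :class:`ApexCandidate` objects sorted left to right.  Candidates
    closer than ``min_separation_um`` are merged keeping the higher score
    (ties keep the leftmost); detections more than ``distal_band_um`` below
    the topmost apex are discarded as non-distal-row.
    """
    resp = ridge.response
    ps = ridge.pixel_scale_um
    if resp.max() <= min_score:
        return []
    coherence = _axial_coherence(ridge, smooth_um)
    turn = np.clip(1.0 - coherence, 0.0, 1.0)
    apex_score = np.where(resp >= min_score, resp * turn, 0.0)

    sep_px = max(int(round(min_separation_um / ps)), 1)
    thr = min_score * turn_weight_min
    peaks = peak_local_max(
        apex_score, min_distance=sep_px, threshold_abs=thr, exclude_border=False
    )
    if len(peaks) == 0:
        return []

    # refine each candidate to the topmost ridge pixel of its own loop
    refined = []
    win = max(int(round(1.2 * min_separation_um / ps)), 4)
    H, W = resp.shape
    for (py, px) in peaks:
        y0, y1 = max(py - win, 0), min(py + win + 1, H)
        x0, x1 = max(px - win, 0), min(px + win + 1, W)
        sub = resp[y0:y1, x0:x1]
        strong = sub >= max(0.35 * sub.max(), min_score * 0.5)
        labels = cc_label(strong, connectivity=2)
        lab = labels[py - y0, px - x0]
        if lab == 0:  # peak itself below the mask: snap to nearest strong pixel
            ys, xs = np.nonzero(strong)
            if len(ys) == 0:
                continue
            k = np.argmin((ys - (py - y0)) ** 2 + (xs - (px - x0)) ** 2)
            lab = labels[ys[k], xs[k]]
        ys, xs = np.nonzero(labels == lab)
        # apex = extreme component pixel along the loop's own principal axis
        # (robust to loops rotated away from vertical); pixels on interior
        # window edges are excluded so a neighbouring loop's limb clipping
        # the window corner cannot masquerade as the turning point
        interior = np.ones(len(ys), dtype=bool)
        if x0 > 0:
            interior &= xs > 0
        if x1 < W:
            interior &= xs < x1 - x0 - 1
        if y0 > 0:
            interior &= ys > 0
        if y1 < H:
            interior &= ys < y1 - y0 - 1
        if not interior.any():
            continue
        ys, xs = ys[interior], xs[interior]
        w = sub[ys, xs]
        u2 = np.cos(2.0 * ridge.orientation[y0:y1, x0:x1][ys, xs])
        v2 = np.sin(2.0 * ridge.orientation[y0:y1, x0:x1][ys, xs])
        psi = 0.5 * math.atan2(float((w * v2).sum()), float((w * u2).sum()))
        ux, uy = math.cos(psi), math.sin(psi)
        if uy > 0:  # orient the axis up the loop
            ux, uy = -ux, -uy
        proj = xs * ux + ys * uy
        best_k = np.flatnonzero(proj >= proj.max() - 1e-9)
        k = best_k[np.argmin(xs[best_k])]
        ax, ay = float(x0 + xs[k]), float(y0 + ys[k])
        # the component's extreme pixel sits on the outer skirt of the
        # (scale-blurred) ridge mask; slide down the loop axis onto the
        # response crest so tracing starts on the vessel proper
        ts = np.arange(0.0, 10.01, 0.5)
        cand_xy = np.column_stack([ax - ts * ux, ay - ts * uy])
        ok = ((cand_xy[:, 0] >= 0) & (cand_xy[:, 0] <= W - 1)
              & (cand_xy[:, 1] >= 0) & (cand_xy[:, 1] <= H - 1))
        vals = ndimage.map_coordinates(
            resp, [cand_xy[ok, 1], cand_xy[ok, 0]], order=1)
        best_t = int(np.argmax(vals))
        ax, ay = cand_xy[ok][best_t]
        # at a true turning point the tangent runs perpendicular to the loop
        # axis; on a limb or at a vessel-end termination it runs along it
        tangent = _local_orientation(ridge, (ax, ay))
        alignment = abs(math.cos(tangent - psi))
        if alignment > math.cos(math.radians(30.0)):
            continue
        refined.append(ApexCandidate(
            x=float(ax), y=float(ay),
            score=float(apex_score[py, px]),
        ))

    # greedy non-maximum suppression after refinement (higher score wins,
    # ties broken by leftmost)
    refined.sort(key=lambda a: (-a.score, a.x, a.y))
    kept = []
    for cand in refined:
        if all(math.hypot(cand.x - k.x, cand.y - k.y) >= sep_px for k in kept):
            kept.append(cand)

    # distal-row band below the upper envelope of detections
    if kept:
        y_top = min(k.y for k in kept)
        kept = [k for k in kept if k.y <= y_top + distal_band_um / ps]

    kept.sort(key=lambda a: (a.x, a.y))
    return kept


# ---------------------------------------------------------------------------
# tracing
# ---------------------------------------------------------------------------

def _bilinear(arr, xy):
    return ndimage.map_coordinates(
        arr, [[xy[1]], [xy[0]]], order=1, mode="nearest"
    )[0]


def _local_orientation(ridge: RidgeMap, xy):
    u, v = ridge.axial_fields()
    ui = _bilinear(u, xy)
    vi = _bilinear(v, xy)
    return 0.5 * math.atan2(vi, ui) % math.pi


def _trace_branch(ridge, start_xy, start_dir, r0, step_px, n_max, stop_frac,
                  min_prominence=1.15):
    resp = ridge.response
    H, W = resp.shape
    ps = ridge.pixel_scale_um
    pts = []
    pos = np.asarray(start_xy, dtype=float)
    prev = np.asarray(start_dir, dtype=float)
    for _ in range(n_max):
        theta = _local_orientation(ridge, pos)
        d = np.array([math.cos(theta), math.sin(theta)])
        if float(d @ prev) < 0:
            d = -d
        nxt = pos + step_px * d
        # re-center on the ridge crest perpendicular to the local orientation,
        # over a window matched to the locally detected vessel scale
        theta2 = _local_orientation(ridge, nxt)
        nvec = np.array([-math.sin(theta2), math.cos(theta2)])
        sigma_px = _bilinear(ridge.scale, nxt) * FWHM_TO_SIGMA / ps
        half = max(2.0, 1.2 * sigma_px)
        offsets = np.linspace(-half, half, 11)
        prof = np.array([_bilinear(resp, nxt + t * nvec) for t in offsets])
        k = int(np.argmax(prof))
        shift = offsets[k]
        if 0 < k < len(offsets) - 1:
            a, b, c = prof[k - 1], prof[k], prof[k + 1]
            denom = a - 2 * b + c
            if denom < -1e-12:
                shift += np.clip(0.5 * (a - c) / denom, -0.5, 0.5) * (offsets[1] - offsets[0])
        shift = float(np.clip(shift, -half, half))
        # a true ridge crest stands clearly above the window edges; in the
        # smooth blur beyond a vessel end the transverse profile is flat
        edge = max(min(prof[0], prof[-1]), 1e-12)
        if prof[k] < min_prominence * edge:
            break
        nxt = nxt + shift * nvec
        if not (1.0 <= nxt[0] <= W - 2 and 1.0 <= nxt[1] <= H - 2):
            break
        if _bilinear(resp, nxt) < stop_frac * r0:
            break
        step_vec = nxt - pos
        norm = np.linalg.norm(step_vec)
        if norm < 1e-9:
            break
        prev = step_vec / norm
        pos = nxt
        pts.append(pos.copy())
    return pts


def trace_path(ridge: RidgeMap, apex, max_limb_um=100.0, step_um=1.0,
               stop_frac=0.25) -> CapillaryPath:
    """Trace both limbs of a capillary outward from its apex.

    Steps a fixed ``step_um`` arc length along the local ridge orientation
    (sign continuity enforced), re-centering on the crest each step.  Each
    limb stops at ``max_limb_um`` arc length, at the image border, or when
    the response drops below ``stop_frac`` of the apex response.
    """
    ps = ridge.pixel_scale_um
    apex_xy = np.array([apex.x, apex.y]) if isinstance(apex, ApexCandidate) \
        else np.asarray(apex, dtype=float)
    r0 = _bilinear(ridge.response, apex_xy)
    if r0 <= 0:
        raise TraceError(f"apex at {tuple(apex_xy)} is not on a ridge")

    step_px = step_um / ps
    n_max = int(round(max_limb_um / step_um))
    theta0 = _local_orientation(ridge, apex_xy)
    d0 = np.array([math.cos(theta0), math.sin(theta0)])
    branch_a = _trace_branch(ridge, apex_xy, -d0, r0, step_px, n_max, stop_frac)
    branch_b = _trace_branch(ridge, apex_xy, d0, r0, step_px, n_max, stop_frac)

    pts = branch_a[::-1] + [apex_xy.copy()] + branch_b
    points = np.asarray(pts)
    orientations = np.array([_local_orientation(ridge, p) for p in points])
    n = len(points)
    score = float(r0)
    return CapillaryPath(
        apex_xy=apex_xy,
        points=points,
        orientations=orientations,
        widths=np.full(n, np.nan),
        width_valid=np.zeros(n, dtype=bool),
        apex_index=len(branch_a),
        limb_arc_lengths_um=(len(branch_a) * step_um, len(branch_b) * step_um),
        detection_score=score,
        pixel_scale_um=ps,
    )


# ---------------------------------------------------------------------------
# width measurement
# ---------------------------------------------------------------------------

def measure_widths(mosaic, path: CapillaryPath, profile_halfwidth_um=30.0,
                   sample_um=0.25, smooth_um=0.5, min_depth=8.0,
                   max_invalid_frac=0.5) -> CapillaryPath:
    """Fill per-point widths as the FWHM of the perpendicular profile.

    At each path point the intensity is sampled along the normal to the
    local orientation; the width is the full width at half the profile depth
    (background minus minimum), converted to micrometres.  Points whose
    profile leaves the image, or shows no clear vessel dip, are flagged
    invalid and excluded from summaries.

    Raises
    ------
    WidthMeasurementError
        If more than ``max_invalid_frac`` of the points are unmeasurable.
    """
    image = np.asarray(mosaic, dtype=float)
    H, W = image.shape
    # cubic spline sampling keeps the discretisation bias of the FWHM small
    # relative to bilinear interpolation, which widens narrow profiles
    spline = ndimage.spline_filter(image, order=3)
    ps = path.pixel_scale_um
    ts = np.arange(-profile_halfwidth_um, profile_halfwidth_um + 1e-9, sample_um)
    center = len(ts) // 2
    core = int(round(0.35 * profile_halfwidth_um / sample_um))  # own-vessel search window

    widths = np.full(len(path.points), np.nan)
    valid = np.zeros(len(path.points), dtype=bool)
    for i, (p, theta) in enumerate(zip(path.points, path.orientations)):
        nvec = np.array([-math.sin(theta), math.cos(theta)])
        xs = p[0] + ts / ps * nvec[0]
        ys = p[1] + ts / ps * nvec[1]
        if xs.min() < 0 or ys.min() < 0 or xs.max() > W - 1 or ys.max() > H - 1:
            continue  # truncated by the image border
        prof = ndimage.map_coordinates(spline, [ys, xs], order=3, prefilter=False)
        if smooth_um > 0:
            prof = ndimage.gaussian_filter1d(prof, smooth_um / sample_um)
        lo, hi = center - core, center + core + 1
        im = lo + int(np.argmin(prof[lo:hi]))
        top = np.sort(prof)[-max(len(prof) // 4, 1):]
        bg = float(np.median(top))
        depth = bg - prof[im]
        if depth < min_depth:
            continue
        half = prof[im] + 0.5 * depth
        # walk outward from the minimum to the first half-depth crossings
        jl = im
        while jl > 0 and prof[jl] < half:
            jl -= 1
        jr = im
        while jr < len(prof) - 1 and prof[jr] < half:
            jr += 1
        if prof[jl] < half or prof[jr] < half:
            continue  # no crossing inside the profile
        tl = ts[jl] + (half - prof[jl]) / (prof[jl + 1] - prof[jl] + 1e-12) * sample_um
        tr = ts[jr] - (half - prof[jr]) / (prof[jr - 1] - prof[jr] + 1e-12) * sample_um
        widths[i] = tr - tl
        valid[i] = widths[i] > 0

    if valid.mean() < 1.0 - max_invalid_frac:
        raise WidthMeasurementError(
            f"{(~valid).sum()}/{len(valid)} path points had unmeasurable widths"
        )
    path.widths = widths
    path.width_valid = valid
    return path
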