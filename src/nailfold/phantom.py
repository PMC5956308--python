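"""Software phantoms of the nailfold: geometry, still mosaics, and video.

The phantom stands in for clinical capillaroscopy imaging.  It draws a row
of hairpin-shaped distal-row capillary loops with known centerlines, widths,
orientations and red-blood-cell speeds, and renders them as noisy grayscale
frames, so every downstream stage (mosaicking, detection, width profiling,
velocimetry, cohort statistics) can be validated against exact ground truth.

Geometry lives in micrometres throughout; pixels enter only at render time
through ``pixel_scale_um``.  Image convention: x rightward, y downward,
orientations are tangent angles modulo pi.

Photometric model
-----------------
Vessels are dark tubes on a bright background with a Gaussian cross-section;
"width" is defined as the full width of the profile at half its depth
(FWHM), the same definition the width estimator uses.  In video, vessel
walls are rendered at reduced contrast and dark elliptical "cell" blobs
advect along the centerline at the capillary's ground-truth speed with
Poisson-distributed plasma gaps, so the temporal signal used by optical flow
dominates along the lumen.

Defaults are anchored to healthy-control population values: capillary width
11.8 um, flow velocity 0.311 mm/s, apex spacing 150 um (~6.7 apices/mm),
and a wrapped-normal spread of principal orientations of 0.45 rad (giving a
derangement score near 0.65).  Acquisition defaults match the imaging
system: 640 x 480 px frames, 1 um/px, 120 frames/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.spatial import cKDTree

from .errors import GeometryError, InvalidParameterError
from .mosaic import VideoSequence

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # sigma = FWHM / 2.355


# ---------------------------------------------------------------------------
# specs and ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Parameters of one synthetic nailfold.

    ``width_um`` and ``velocity_mm_s`` may be scalars (shared by all
    capillaries, with optional per-capillary jitter via ``width_sd_um``) or
    sequences of per-capillary values.
    """

    n_capillaries: int = 4
    spacing_um: float = 150.0          # mean inter-apex distance
    width_um: object = 11.8            # FWHM of the vessel cross-section
    width_sd_um: float = 0.0           # per-capillary spread when width_um is scalar
    limb_length_um: float = 100.0      # measured limb length from the apex
    tortuosity: float = 0.15           # SD of smooth tangent-angle wobble (rad)
    derangement_spread: float = 0.45   # SD of principal orientations about pi/2 (rad)
    velocity_mm_s: object = 0.311      # ground-truth cell speed
    frame_rate_hz: float = 120.0
    pixel_scale_um: float = 1.0
    frame_shape: tuple = (480, 640)    # (height, width) px
    noise_sd: float = 4.0              # additive Gaussian intensity noise
    n_frames: int = 20
    seed: int = 0
    # geometry details
    apex_turn_factor: float = 2.5      # apex turn diameter = factor * width
    apex_y_um: float = 170.0           # mean apex depth below the top edge
    apex_y_jitter_um: float = 12.0
    spacing_jitter_frac: float = 0.06
    margin_um: float = 80.0            # left/right clearance of the apex row
    # photometry
    background: float = 200.0
    tube_contrast: float = 60.0        # vessel depth in the still mosaic
    wall_contrast: float = 25.0        # vessel wall depth in video frames
    cell_contrast: float = 60.0        # cell blob depth in video frames
    cell_spacing_um: float = 25.0      # mean arc-length gap between cells
    cell_length_um: float = 8.0        # along-path extent of a cell blob

    def __post_init__(self):
        if self.n_capillaries < 0:
            raise InvalidParameterError("n_capillaries must be >= 0")
        for name in ("spacing_um", "limb_length_um", "frame_rate_hz",
                     "pixel_scale_um", "cell_spacing_um", "cell_length_um"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be strictly positive")
        for name in ("tortuosity", "derangement_spread", "noise_sd", "width_sd_um"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")
        if np.any(np.asarray(self.width_um, dtype=float) <= 0):
            raise InvalidParameterError("width_um must be strictly positive")
        if np.any(np.asarray(self.velocity_mm_s, dtype=float) < 0):
            raise InvalidParameterError("velocity_mm_s must be >= 0")

    def with_(self, **kwargs) -> "PhantomSpec":
        return replace(self, **kwargs)


@dataclass
class CapillaryTruth:
    """Ground-truth centerline of one capillary (um coordinates)."""

    points: np.ndarray        # (n, 2) of (x, y) um
    orientations: np.ndarray  # (n,) tangent angle mod pi
    widths: np.ndarray        # (n,) um
    apex_index: int
    step_um: float

    @property
    def apex_xy(self):
        return self.points[self.apex_index]

    @property
    def arc_length_um(self):
        return (len(self.points) - 1) * self.step_um


@dataclass
class PhantomTruth:
    """Full ground truth for one phantom nailfold."""

    paths: list                      # list[CapillaryTruth]
    apices: np.ndarray               # (n, 2) um
    principal_orientations: np.ndarray
    velocities_mm_s: np.ndarray
    widths_um: np.ndarray            # per-capillary nominal width
    frame_offsets: np.ndarray        # (n_frames, 2) true stage translation, px
    density_truth: float             # apices per mm over the apex span
    extent_um: tuple = (640.0, 480.0)  # (width, height)


@dataclass
class TileSet:
    """Overlapping sub-frames cropped from a wide virtual nailfold."""

    tiles: list
    true_offsets: np.ndarray     # (n, 2) px, relative to the first tile
    nominal_offsets: np.ndarray  # true offsets + bounded jitter


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def make_capillary_path(apex_xy, principal_orientation, width_um,
                        limb_length_um=100.0, tortuosity=0.0, rng=None,
                        step_um=1.0, turn_factor=2.5) -> CapillaryTruth:
    """Build one hairpin centerline with per-point width and orientation.

    Two limbs of arc length ``limb_length_um`` join at the apex through a
    semicircular turn of diameter ``turn_factor * width_um``.  Tortuosity is
    smooth band-limited angular noise of the given SD (rad) added to the
    tangent heading and integrated along arc length, so paths wobble but
    remain traceable.  With tortuosity 0 the limbs are exactly straight and
    axially parallel to ``principal_orientation``.
    """
    if limb_length_um <= 0 or width_um <= 0 or step_um <= 0:
        raise InvalidParameterError("lengths and widths must be strictly positive")
    if tortuosity < 0:
        raise InvalidParameterError("tortuosity must be >= 0")
    rng = np.random.default_rng(0) if rng is None else rng

    r = 0.5 * turn_factor * width_um
    n_limb = max(int(round(limb_length_um / step_um)), 1)
    n_turn = max(int(round(math.pi * r / step_um)), 4)
    n_seg = 2 * n_limb + n_turn
    s = np.arange(n_seg + 1) * step_um  # arc length at each point
    L = n_limb * step_um
    turn_len = n_turn * step_um

    # base heading: up the arterial limb, clockwise over the turn, down the
    # venous limb (y-down coordinates, loop pointing up before rotation)
    heading = np.full(n_seg + 1, -math.pi / 2)
    in_turn = (s >= L) & (s <= L + turn_len)
    heading[in_turn] = -math.pi / 2 + (s[in_turn] - L) / turn_len * math.pi
    heading[s > L + turn_len] = math.pi / 2

    # tortuosity is always drawn so the rng stream (and hence downstream
    # draws) does not depend on whether tortuosity is zero
    wobble = rng.standard_normal(n_seg + 1)
    if tortuosity > 0:
        wobble = gaussian_filter1d(wobble, sigma=12.0 / step_um, mode="reflect")
        sd = wobble.std()
        wobble = wobble / sd * tortuosity if sd > 0 else np.zeros_like(wobble)
        heading = heading + wobble

    rho = principal_orientation - math.pi / 2
    heading = heading + rho

    seg_heading = 0.5 * (heading[:-1] + heading[1:])
    steps = step_um * np.column_stack([np.cos(seg_heading), np.sin(seg_heading)])
    pts = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])

    apex_index = n_limb + n_turn // 2
    pts = pts - pts[apex_index] + np.asarray(apex_xy, dtype=float)

    return CapillaryTruth(
        points=pts,
        orientations=np.mod(heading, math.pi),
        widths=np.full(n_seg + 1, float(width_um)),
        apex_index=apex_index,
        step_um=step_um,
    )


def generate_truth(spec: PhantomSpec, rng=None, extent_um=None) -> PhantomTruth:
    """Sample the ground-truth geometry and kinematics for one nailfold.

    Apices are laid out left to right with jittered spacing; principal
    orientations are wrapped-normal about vertical with SD
    ``derangement_spread``.  ``extent_um`` overrides the canvas size (width,
    height) when generating for a wide virtual nailfold (see
    :func:`render_overlapping_frames`).
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    if extent_um is None:
        h, w = spec.frame_shape
        extent_um = (w * spec.pixel_scale_um, h * spec.pixel_scale_um)
    width_ext, height_ext = extent_um
    n = spec.n_capillaries

    gaps = spec.spacing_um * (
        1.0 + spec.spacing_jitter_frac * rng.standard_normal(max(n, 1))
    )
    xs = spec.margin_um + np.concatenate([[0.0], np.cumsum(gaps[1:n])]) if n else np.array([])
    if n and xs.max() > width_ext - 0.5 * spec.margin_um:
        raise GeometryError(
            f"{n} apices at ~{spec.spacing_um} um spacing do not fit a "
            f"{width_ext:.0f} um wide frame"
        )
    ys = spec.apex_y_um + spec.apex_y_jitter_um * rng.standard_normal(n)
    orient = np.mod(math.pi / 2 + spec.derangement_spread * rng.standard_normal(n), math.pi)

    base_w = np.asarray(spec.width_um, dtype=float)
    if base_w.ndim == 0:
        widths = float(base_w) + spec.width_sd_um * rng.standard_normal(n)
        widths = np.maximum(widths, 0.4 * float(base_w))
    else:
        if base_w.size != n:
            raise InvalidParameterError("width_um sequence must have n_capillaries entries")
        widths = base_w.astype(float).copy()

    base_v = np.asarray(spec.velocity_mm_s, dtype=float)
    if base_v.ndim == 0:
        velocities = np.full(n, float(base_v))
    else:
        if base_v.size != n:
            raise InvalidParameterError("velocity_mm_s sequence must have n_capillaries entries")
        velocities = base_v.astype(float).copy()

    def fits(path):
        pts = path.points
        return (pts[:, 0].min() >= 1.0 and pts[:, 1].min() >= 1.0
                and pts[:, 0].max() <= width_ext - 2.0
                and pts[:, 1].max() <= height_ext - 2.0)

    paths = []
    for i in range(n):
        path = make_capillary_path(
            (xs[i], ys[i]), orient[i], widths[i],
            limb_length_um=spec.limb_length_um, tortuosity=spec.tortuosity,
            rng=rng, turn_factor=spec.apex_turn_factor,
        )
        # a strongly rotated loop can poke outside the canvas; relax its
        # orientation toward vertical until the path fits
        for _ in range(6):
            if fits(path):
                break
            orient[i] = math.pi / 2 + 0.5 * (orient[i] - math.pi / 2)
            path = make_capillary_path(
                (xs[i], ys[i]), orient[i], widths[i],
                limb_length_um=spec.limb_length_um, tortuosity=spec.tortuosity,
                rng=rng, turn_factor=spec.apex_turn_factor,
            )
        if not fits(path):
            raise GeometryError(
                f"capillary {i} does not fit a {width_ext:.0f} x {height_ext:.0f} um frame"
            )
        paths.append(path)
    apices = np.array([p.apex_xy for p in paths]) if n else np.zeros((0, 2))

    if n >= 2:
        span_mm = (apices[:, 0].max() - apices[:, 0].min()) / 1000.0
        density = n / span_mm
    else:
        density = float("nan")

    return PhantomTruth(
        paths=paths,
        apices=apices,
        principal_orientations=orient,
        velocities_mm_s=velocities,
        widths_um=widths,
        frame_offsets=np.zeros((spec.n_frames, 2)),
        density_truth=density,
        extent_um=(width_ext, height_ext),
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _vessel_depth(spec: PhantomSpec, truth: PhantomTruth, shape) -> np.ndarray:
    """Unit-amplitude vessel tube profile rasterised onto a pixel canvas.

    Each pixel takes exp(-d^2 / 2 sigma^2) of its distance d to the nearest
    centerline point, with sigma set so the full width at half depth equals
    the local ground-truth width.  Overlapping tubes combine by maximum.
    """
    H, W = shape
    ps = spec.pixel_scale_um
    depth = np.zeros((H, W))
    for cap in truth.paths:
        pts_px = cap.points / ps
        if (pts_px[:, 0].min() < 0 or pts_px[:, 1].min() < 0
                or pts_px[:, 0].max() > W - 1 or pts_px[:, 1].max() > H - 1):
            raise GeometryError("capillary path extends outside the frame")
        # densify so nearest-point distance approximates distance-to-curve
        fine = np.empty((2 * len(pts_px) - 1, 2))
        fine[0::2] = pts_px
        fine[1::2] = 0.5 * (pts_px[:-1] + pts_px[1:])
        fine_w = np.empty(len(fine))
        fine_w[0::2] = cap.widths
        fine_w[1::2] = 0.5 * (cap.widths[:-1] + cap.widths[1:])
        sigma_px = fine_w * FWHM_TO_SIGMA / ps

        pad = int(np.ceil(3.5 * sigma_px.max())) + 2
        x0 = max(int(np.floor(pts_px[:, 0].min())) - pad, 0)
        x1 = min(int(np.ceil(pts_px[:, 0].max())) + pad, W - 1)
        y0 = max(int(np.floor(pts_px[:, 1].min())) - pad, 0)
        y1 = min(int(np.ceil(pts_px[:, 1].max())) + pad, H - 1)
        yy, xx = np.mgrid[y0:y1 + 1, x0:x1 + 1]
        grid = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
        d, idx = cKDTree(fine).query(grid, workers=1)
        contrib = np.exp(-d ** 2 / (2.0 * sigma_px[idx] ** 2)).reshape(yy.shape)
        region = depth[y0:y1 + 1, x0:x1 + 1]
        np.maximum(region, contrib, out=region)
    return depth


def render_mosaic(spec: PhantomSpec, truth: PhantomTruth, rng=None, shape=None):
    """Render the still nailfold image: dark tubes plus additive noise."""
    if shape is None:
        shape = spec.frame_shape
    rng = np.random.default_rng([spec.seed, 1]) if rng is None else rng
    depth = _vessel_depth(spec, truth, shape)
    image = spec.background - spec.tube_contrast * depth
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
    return image


def _cell_positions(spec: PhantomSpec, total_len: float, rng) -> np.ndarray:
    """Poisson-process cell positions along one capillary's arc length."""
    positions = []
    s = float(rng.exponential(spec.cell_spacing_um))
    while s < total_len:
        positions.append(s)
        s += spec.cell_length_um + rng.exponential(spec.cell_spacing_um)
    return np.asarray(positions)


def render_video(spec: PhantomSpec, truth: PhantomTruth, rng=None) -> VideoSequence:
    """Render a video: static vessel walls plus advecting dark cell blobs.

    Per frame, each cell advances along its capillary's centerline by
    ``velocity_mm_s * 1000 / frame_rate_hz`` micrometres (wrapping at the
    path ends), is rendered as an elongated Gaussian blob aligned with the
    local tangent, and independent Gaussian noise is added.
    """
    if spec.n_frames < 2:
        raise InvalidParameterError("render_video requires n_frames >= 2")
    rng = np.random.default_rng([spec.seed, 2]) if rng is None else rng
    H, W = spec.frame_shape
    ps = spec.pixel_scale_um
    walls = spec.background - spec.wall_contrast * _vessel_depth(spec, truth, (H, W))

    cells = [_cell_positions(spec, cap.arc_length_um, rng) for cap in truth.paths]
    ds = np.asarray(truth.velocities_mm_s) * 1000.0 / spec.frame_rate_hz  # um/frame

    sigma_a = spec.cell_length_um * FWHM_TO_SIGMA / ps  # along-path, px
    frames = []
    for t in range(spec.n_frames):
        cell_depth = np.zeros((H, W))
        for ci, cap in enumerate(truth.paths):
            if cells[ci].size == 0:
                continue
            s_now = np.mod(cells[ci] + t * ds[ci], cap.arc_length_um)
            f_idx = s_now / cap.step_um
            i0 = np.clip(f_idx.astype(int), 0, len(cap.points) - 2)
            frac = (f_idx - i0)[:, None]
            centers = (cap.points[i0] * (1 - frac) + cap.points[i0 + 1] * frac) / ps
            for k in range(len(centers)):
                cx, cy = centers[k]
                theta = cap.orientations[i0[k]]
                # cells fill the lumen: the visible vessel in capillaroscopy
                # is the red-cell column, so its cross-path FWHM must equal
                # the ground-truth width for width truth to be well defined
                sigma_c = cap.widths[i0[k]] * FWHM_TO_SIGMA / ps
                r = int(math.ceil(3.0 * sigma_a)) + 1
                xlo, xhi = int(cx) - r, int(cx) + r + 1
                ylo, yhi = int(cy) - r, int(cy) + r + 1
                xlo, ylo = max(xlo, 0), max(ylo, 0)
                xhi, yhi = min(xhi, W), min(yhi, H)
                if xlo >= xhi or ylo >= yhi:
                    continue
                yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
                dx, dy = xx - cx, yy - cy
                a = dx * math.cos(theta) + dy * math.sin(theta)
                c = -dx * math.sin(theta) + dy * math.cos(theta)
                blob = np.exp(-(a ** 2 / (2 * sigma_a ** 2) + c ** 2 / (2 * sigma_c ** 2)))
                region = cell_depth[ylo:yhi, xlo:xhi]
                np.maximum(region, blob, out=region)
        frame = walls - spec.cell_contrast * cell_depth
        if spec.noise_sd > 0:
            frame = frame + rng.normal(0.0, spec.noise_sd, size=frame.shape)
        frames.append(frame)

    return VideoSequence(
        frames=frames,
        frame_rate_hz=spec.frame_rate_hz,
        pixel_scale_um=ps,
        nominal_offsets=np.zeros((spec.n_frames, 2)),
    )


def overlapping_extent_um(spec: PhantomSpec, n_tiles: int, overlap_frac: float):
    """(width, height) in um of the virtual nailfold covered by the tiles."""
    h, w = spec.frame_shape
    step = int(round((1.0 - overlap_frac) * w))
    virtual_w = w + (n_tiles - 1) * step
    return (virtual_w * spec.pixel_scale_um, h * spec.pixel_scale_um)


def render_overlapping_frames(spec: PhantomSpec, truth: PhantomTruth,
                              n_tiles: int, overlap_frac: float,
                              jitter_px: float = 10.0, rng=None) -> TileSet:
    """Crop overlapping sub-frames from a wide virtual nailfold.

    Adjacent tiles share ``overlap_frac`` of their width; tiles wobble a few
    pixels vertically, emulating stage drift.  Nominal offsets are the true
    offsets plus bounded uniform jitter (<= ``jitter_px``), emulating
    imperfect motor tracking.  ``truth`` must have been generated for the
    extent returned by :func:`overlapping_extent_um`.
    """
    if n_tiles < 2:
        raise InvalidParameterError("render_overlapping_frames requires n_tiles >= 2")
    if not 0.0 < overlap_frac < 1.0:
        raise InvalidParameterError("overlap_frac must lie in (0, 1)")
    if jitter_px < 0 or jitter_px > 10:
        raise InvalidParameterError("jitter_px must lie in [0, 10]")
    rng = np.random.default_rng([spec.seed, 3]) if rng is None else rng

    h, w = spec.frame_shape
    step = int(round((1.0 - overlap_frac) * w))
    wobble_pad = 4
    virtual_shape = (h + 2 * wobble_pad, w + (n_tiles - 1) * step)
    base = spec.background - spec.tube_contrast * _vessel_depth(
        spec, truth, virtual_shape
    )

    xs = np.arange(n_tiles) * step
    ys = wobble_pad + rng.integers(-wobble_pad + 1, wobble_pad, size=n_tiles)
    tiles = []
    for i in range(n_tiles):
        tile = base[ys[i]:ys[i] + h, xs[i]:xs[i] + w].copy()
        if spec.noise_sd > 0:
            tile += rng.normal(0.0, spec.noise_sd, size=tile.shape)
        tiles.append(tile)

    true_offsets = np.column_stack([xs - xs[0], ys - ys[0]]).astype(float)
    jitter = rng.uniform(-jitter_px, jitter_px, size=(n_tiles, 2)) if jitter_px > 0 \
        else np.zeros((n_tiles, 2))
    jitter[0] = 0.0
    return TileSet(
        tiles=tiles,
        true_offsets=true_offsets,
        nominal_offsets=true_offsets + jitter,
    )


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------

#: Group-level phantom parameters anchored to the population means reported
#: for healthy controls (HC), primary Raynaud's (PRP) and systemic sclerosis
#: (SSc): capillary width (um), apex spacing (um, ~1000/density), red-cell
#: speed (mm/s), tortuosity and derangement spread (rad).
GROUP_PRESETS = {
    "HC": dict(width_um=11.8, spacing_um=149.0, velocity_mm_s=0.311,
               tortuosity=0.25, derangement_spread=0.465),
    "PRP": dict(width_um=12.7, spacing_um=137.0, velocity_mm_s=0.383,
                tortuosity=0.25, derangement_spread=0.432),
    "SSc": dict(width_um=15.0, spacing_um=181.0, velocity_mm_s=0.235,
                tortuosity=0.45, derangement_spread=0.555),
}

#: Between-subject SDs for the sampled parameters (population SE * sqrt(n)).
GROUP_SUBJECT_SD = {
    "HC": dict(width_um=1.6, spacing_um=12.0, velocity_mm_s=0.05),
    "PRP": dict(width_um=2.5, spacing_um=12.0, velocity_mm_s=0.08),
    "SSc": dict(width_um=3.0, spacing_um=18.0, velocity_mm_s=0.05),
}


def group_spec(group: str, rng=None, **overrides) -> PhantomSpec:
    """A :class:`PhantomSpec` for one subject of the given clinical group.

    Subject-level width, spacing and velocity are drawn around the group
    means with realistic between-subject spread when ``rng`` is given;
    without an rng the group means are used exactly.
    """
    if group not in GROUP_PRESETS:
        raise InvalidParameterError(f"unknown group {group!r}; expected HC, PRP or SSc")
    params = dict(GROUP_PRESETS[group])
    if rng is not None:
        sds = GROUP_SUBJECT_SD[group]
        params["width_um"] = max(params["width_um"] + sds["width_um"] * rng.standard_normal(), 6.0)
        params["spacing_um"] = max(params["spacing_um"] + sds["spacing_um"] * rng.standard_normal(), 60.0)
        params["velocity_mm_s"] = max(
            params["velocity_mm_s"] + sds["velocity_mm_s"] * rng.standard_normal(), 0.02
        )
    params.update(overrides)
    return PhantomSpec(**params)
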