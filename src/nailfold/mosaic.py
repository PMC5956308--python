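"""Translation-only frame registration and mosaic compositing.

A motorised x-y stage sweeps the capillaroscopy camera across the nailfold,
so consecutive video frames are related by in-plane translations.  Stage
tracking provides nominal offsets that are accurate to within a few pixels;
each pairwise registration refines the nominal offset by normalised
cross-correlation (NCC) template matching inside a bounded search window,
with parabolic sub-pixel interpolation of the correlation peak.

Coordinate convention: 0-based pixel indices, x rightward, y downward.  An
offset (dx, dy) places the moving frame's origin at column dx, row dy of the
fixed frame's coordinate system.  Overlapping pixels are composited by the
per-pixel mean, which doubles as temporal denoising of the static scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.registration import phase_cross_correlation

from .errors import InvalidParameterError, RegistrationError

#: Minimum fraction of the moving frame's area that must overlap the fixed
#: frame at the nominal offset for registration to be attempted.
MIN_OVERLAP_FRAC = 0.10


@dataclass
class VideoSequence:
    """Ordered grayscale frames from one digit plus acquisition metadata."""

    frames: list
    frame_rate_hz: float
    pixel_scale_um: float
    nominal_offsets: np.ndarray | None = None  # (n, 2) of (dx, dy) px

    def __post_init__(self):
        if self.frame_rate_hz <= 0 or self.pixel_scale_um <= 0:
            raise InvalidParameterError("frame rate and pixel scale must be positive")
        shapes = {np.asarray(f).shape for f in self.frames}
        if len(shapes) > 1:
            raise InvalidParameterError(f"frames have mixed shapes: {shapes}")
        if self.nominal_offsets is not None:
            self.nominal_offsets = np.asarray(self.nominal_offsets, dtype=float)
            if self.nominal_offsets.shape != (len(self.frames), 2):
                raise InvalidParameterError("need one (dx, dy) offset per frame")

    def __len__(self):
        return len(self.frames)


@dataclass
class Mosaic:
    """Composited still image with the refined per-frame offsets."""

    image: np.ndarray
    frame_offsets: np.ndarray  # (n, 2), relative to the first frame at (0, 0)
    pixel_scale_um: float
    source_frame_count: int
    quality_flags: list = field(default_factory=list)
    #: position of the mosaic's pixel (0, 0) in frame-0 coordinates; frame i
    #: sits at frame_offsets[i] - origin within the mosaic image
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))


def _parabolic_peak(values):
    """Sub-sample peak position of a 3-vector by quadratic interpolation."""
    a, b, c = values
    denom = a - 2.0 * b + c
    if denom >= -1e-12:  # flat or non-concave: keep the integer peak
        return 0.0
    shift = 0.5 * (a - c) / denom
    return float(np.clip(shift, -0.5, 0.5))


def register_pair(fixed, moving, initial_offset=(0.0, 0.0), search_radius=20):
    """Refine the offset of ``moving`` relative to ``fixed`` by NCC search.

    Parameters
    ----------
    fixed, moving : 2-D arrays
        Grayscale frames.
    initial_offset : (dx, dy)
        Nominal placement of the moving frame's origin in fixed coordinates.
    search_radius : int
        Half-width (px) of the search window around the nominal offset.

    Returns
    -------
    (offset, score)
        Refined (dx, dy) with sub-pixel precision and the peak NCC score in
        [-1, 1].

    Raises
    ------
    RegistrationError
        If the overlap at the initial offset is below 10 % of the moving
        frame's area or too small to search; the error carries the nominal
        offset as ``fallback_offset``.
    """
    fixed = np.asarray(fixed, dtype=float)
    moving = np.asarray(moving, dtype=float)
    # vessels are smooth at the few-pixel scale, so mild presmoothing costs
    # no structure but suppresses the sensor noise that otherwise jitters
    # the correlation peak along the (nearly y-uniform) vessel axes
    fixed = ndimage.gaussian_filter(fixed, 1.5)
    moving = ndimage.gaussian_filter(moving, 1.5)
    H, W = fixed.shape
    h, w = moving.shape
    dx0, dy0 = float(initial_offset[0]), float(initial_offset[1])
    idx, idy = int(round(dx0)), int(round(dy0))
    R = int(search_radius)
    if R < 1:
        raise InvalidParameterError("search_radius must be >= 1")

    # overlap rectangle in fixed coordinates
    x0, y0 = max(0, idx), max(0, idy)
    x1, y1 = min(W, idx + w), min(H, idy + h)
    if (x1 - x0) * (y1 - y0) < MIN_OVERLAP_FRAC * h * w:
        raise RegistrationError(
            f"overlap at nominal offset ({dx0:.1f}, {dy0:.1f}) below "
            f"{MIN_OVERLAP_FRAC:.0%} of frame area",
            fallback_offset=(dx0, dy0),
        )

    # template: overlap region of the moving frame, shrunk so the search
    # window around its nominal position stays inside the fixed frame
    mtx0, mty0 = x0 - idx + R, y0 - idy + R
    mtx1, mty1 = x1 - idx - R, y1 - idy - R
    if mtx1 - mtx0 < 8 or mty1 - mty0 < 8:
        raise RegistrationError(
            "overlap too small for the requested search radius",
            fallback_offset=(dx0, dy0),
        )
    template = moving[mty0:mty1, mtx0:mtx1]
    if template.std() < 1e-12:
        # featureless overlap: nothing to correlate against
        return (dx0, dy0), 0.0

    sx0, sy0 = mtx0 + idx - R, mty0 + idy - R
    sx1, sy1 = mtx1 + idx + R, mty1 + idy + R
    search = fixed[max(0, sy0):sy1, max(0, sx0):sx1]
    sx0, sy0 = max(0, sx0), max(0, sy0)

    ncc = match_template(search, template)
    pi, pj = np.unravel_index(int(np.argmax(ncc)), ncc.shape)
    score = float(np.clip(ncc[pi, pj], -1.0, 1.0))

    # parabolic sub-pixel refinement along each axis
    fy = _parabolic_peak(ncc[pi - 1:pi + 2, pj]) if 0 < pi < ncc.shape[0] - 1 else 0.0
    fx = _parabolic_peak(ncc[pi, pj - 1:pj + 2]) if 0 < pj < ncc.shape[1] - 1 else 0.0

    dx = (sx0 + pj + fx) - mtx0
    dy = (sy0 + pi + fy) - mty0

    # upsampled phase correlation between the integer-aligned overlap patches
    # tightens the sub-pixel estimate (the parabolic NCC peak model alone can
    # be a few tenths of a pixel off)
    iy, ix = sy0 + pi, sx0 + pj
    th, tw = template.shape
    if 0 <= iy and 0 <= ix and iy + th <= H and ix + tw <= W and score > 0.2:
        patch_fixed = fixed[iy:iy + th, ix:ix + tw]
        shift, _, _ = phase_cross_correlation(
            patch_fixed, template, upsample_factor=20, normalization=None
        )
        if abs(shift[0]) <= 1.5 and abs(shift[1]) <= 1.5:
            dy = (iy + shift[0]) - mty0
            dx = (ix + shift[1]) - mtx0
    return (float(dx), float(dy)), score


def compose_mosaic(sequence: VideoSequence, search_radius=20, min_score=0.3) -> Mosaic:
    """Chain pairwise registrations and composite frames by per-pixel mean.

    Consecutive frames are registered with the nominal inter-frame offset as
    the search seed.  A pair whose registration fails or scores below
    ``min_score`` falls back to its nominal offset and raises a quality flag
    on the returned :class:`Mosaic` (the pipeline treats flags as warnings,
    not errors).
    """
    n = len(sequence)
    if n == 0:
        raise InvalidParameterError("compose_mosaic requires >= 1 frame")
    frames = [np.asarray(f, dtype=float) for f in sequence.frames]
    h, w = frames[0].shape
    nominal = (
        sequence.nominal_offsets
        if sequence.nominal_offsets is not None
        else np.zeros((n, 2))
    )

    flags: list = []
    offsets = np.zeros((n, 2))
    for i in range(1, n):
        rel_nominal = nominal[i] - nominal[i - 1]
        try:
            rel, score = register_pair(
                frames[i - 1], frames[i], tuple(rel_nominal), search_radius
            )
            if score < min_score:
                flags.append(
                    f"frame {i}: NCC score {score:.3f} < {min_score}; using nominal offset"
                )
                rel = tuple(rel_nominal)
        except RegistrationError as exc:
            flags.append(f"frame {i}: {exc}; using nominal offset")
            rel = tuple(rel_nominal)
        offsets[i] = offsets[i - 1] + rel

    # composite: bilinear placement at sub-pixel positions, mean where frames overlap
    snapped = np.round(offsets)
    # sub-0.1 px deviations are below registration precision, not signal
    near = np.abs(offsets - snapped) < 0.1
    offsets[near] = snapped[near]
    origin = offsets.min(axis=0)
    pos = offsets - origin  # all >= 0
    out_w = int(np.ceil(pos[:, 0].max() + w))
    out_h = int(np.ceil(pos[:, 1].max() + h))
    acc = np.zeros((out_h + 1, out_w + 1))
    wacc = np.zeros_like(acc)
    ones = np.ones((h, w))
    for i, frame in enumerate(frames):
        px, py = pos[i]
        ix, iy = int(np.floor(px)), int(np.floor(py))
        fx, fy = px - ix, py - iy
        if fx == 0.0 and fy == 0.0:
            acc[iy:iy + h, ix:ix + w] += frame
            wacc[iy:iy + h, ix:ix + w] += ones
        else:
            padded = np.pad(frame, ((0, 1), (0, 1)))
            wpad = np.pad(ones, ((0, 1), (0, 1)))
            shifted = ndimage.shift(padded, (fy, fx), order=1, mode="constant")
            wshift = ndimage.shift(wpad, (fy, fx), order=1, mode="constant")
            acc[iy:iy + h + 1, ix:ix + w + 1] += shifted
            wacc[iy:iy + h + 1, ix:ix + w + 1] += wshift
    image = np.divide(acc, wacc, out=np.zeros_like(acc), where=wacc > 1e-9)
    image = image[:out_h, :out_w]

    return Mosaic(
        image=image,
        frame_offsets=offsets,
        pixel_scale_um=sequence.pixel_scale_um,
        source_frame_count=n,
        quality_flags=flags,
        origin=origin,
    )
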