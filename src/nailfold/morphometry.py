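"""Capillary- and nailfold-level morphometric summaries.

Orientations of capillary paths are *axial* quantities: a tangent direction
is only defined modulo pi (a vessel pointing "up" is the same as one pointing
"down").  All circular statistics therefore operate on doubled angles, the
standard device for axial data: an orientation theta maps to the unit vector
exp(2i*theta), averages are taken in that embedding, and results map back by
halving the argument.

Two scores derive from the mean resultant length R = |mean exp(2i*theta)|:

* shape score - R of the orientations along one capillary path.  Close to 1
  for a normal hairpin whose two limbs are axially parallel; low for
  tortuous, abnormally shaped capillaries.
* derangement score - R of the principal orientations of all capillaries in
  one nailfold.  High when the loops line up in a common direction, low for
  disorganised architecture.

Both scores live in [0, 1] by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, SummaryError

#: Canonical order of the six image-level parameters.
PARAMETERS = ("density", "mean_width", "max_width", "shape", "derangement", "flow")

PARAMETER_LABELS = {
    "density": "Capillary density (mm^-1)",
    "mean_width": "Mean width (um)",
    "max_width": "Max width (um)",
    "shape": "Shape score",
    "derangement": "Derangement score",
    "flow": "Mean flow velocity (mm/s)",
}


# ---------------------------------------------------------------------------
# axial circular statistics
# ---------------------------------------------------------------------------

def circular_dispersion(orientations) -> float:
    """Mean resultant length of angle-doubled orientations.

    Parameters
    ----------
    orientations : array-like of float
        Orientations in radians, interpreted modulo pi.

    Returns
    -------
    float
        R = |mean exp(2i*theta)| in [0, 1].  1 when all orientations are
        equal (mod pi); 0 for a perfectly balanced axial spread such as
        {0, pi/2}.

    Raises
    ------
    InvalidInputError
        If the input is empty or contains non-finite values.
    """
    theta = np.asarray(orientations, dtype=float).ravel()
    if theta.size == 0:
        raise InvalidInputError("circular_dispersion requires >= 1 orientation")
    if not np.all(np.isfinite(theta)):
        raise InvalidInputError("orientations must be finite")
    z = np.exp(2j * theta).mean()
    return float(min(abs(z), 1.0))


def axial_mean(orientations) -> float:
    """Principal (axial circular mean) orientation, in [0, pi).

    Half the argument of the mean doubled-angle vector.  Consistent with
    :func:`circular_dispersion`; well defined wherever R > 0.
    """
    theta = np.asarray(orientations, dtype=float).ravel()
    if theta.size == 0:
        raise InvalidInputError("axial_mean requires >= 1 orientation")
    z = np.exp(2j * theta).mean()
    return float(np.angle(z) / 2.0) % math.pi


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CapillaryMetrics:
    """Per-capillary summary used by the image-level aggregation."""

    capillary_id: int
    mean_width_um: float
    principal_orientation: float  # radians, mod pi
    shape_score: float
    mean_velocity_mm_s: float | None = None
    apex_x_um: float | None = None


@dataclass
class NailfoldMetrics:
    """The six image-level parameters for one digit.

    ``capillary_density_per_mm`` is NaN (and ``density_valid`` False) when
    fewer than two apices are available to define a span.
    """

    digit_id: str
    capillary_density_per_mm: float
    mean_width_um: float
    max_width_um: float
    shape_score: float
    derangement_score: float
    mean_flow_mm_s: float
    n_capillaries: int
    density_valid: bool = True

    def as_dict(self) -> dict:
        return {
            "density": self.capillary_density_per_mm,
            "mean_width": self.mean_width_um,
            "max_width": self.max_width_um,
            "shape": self.shape_score,
            "derangement": self.derangement_score,
            "flow": self.mean_flow_mm_s,
        }


@dataclass
class SubjectRecord:
    """Participant-level record: per-digit metrics plus their averages."""

    subject_id: str
    group: str  # one of HC, PRP, SSc
    per_digit: list = field(default_factory=list)
    participant_params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_capillary(path, flowrec=None, capillary_id: int = 0) -> CapillaryMetrics:
    """Reduce one traced capillary path to its scalar metrics.

    Parameters
    ----------
    path : CapillaryPath
        Traced path with per-point orientations and widths; points whose
        width could not be measured are excluded via ``path.width_valid``.
    flowrec : CapillaryFlow, optional
        Velocity record for this capillary; absent if flow estimation failed.

    Raises
    ------
    SummaryError
        If fewer than two path points carry a measurable width.
    """
    widths = np.asarray(path.widths, dtype=float)
    valid = np.asarray(path.width_valid, dtype=bool)
    if valid.sum() < 2:
        raise SummaryError(
            f"capillary {capillary_id}: only {int(valid.sum())} measurable width points"
        )
    orientations = np.asarray(path.orientations, dtype=float)
    return CapillaryMetrics(
        capillary_id=capillary_id,
        mean_width_um=float(widths[valid].mean()),
        principal_orientation=axial_mean(orientations),
        shape_score=circular_dispersion(orientations),
        mean_velocity_mm_s=None if flowrec is None else float(flowrec.mean_velocity_mm_s),
        apex_x_um=float(path.apex_xy[0]) if getattr(path, "apex_xy", None) is not None else None,
    )


def summarize_nailfold(capillaries, apices_x_um, digit_id: str = "") -> NailfoldMetrics:
    """Aggregate capillary metrics into the six image-level parameters.

    Density is the apex count divided by the leftmost-to-rightmost apex span
    in millimetres (n / span).  Mean flow averages only capillaries with a
    valid velocity; if none have one, flow is NaN.
    """
    caps = list(capillaries)
    if len(caps) == 0:
        raise InvalidInputError("summarize_nailfold requires >= 1 capillary")
    apices_x = np.asarray(apices_x_um, dtype=float)
    if apices_x.size != len(caps):
        raise InvalidInputError("one apex x position per capillary required")

    density_valid = len(caps) >= 2
    if density_valid:
        span_mm = (apices_x.max() - apices_x.min()) / 1000.0
        if span_mm <= 0:
            density, density_valid = float("nan"), False
        else:
            density = len(caps) / span_mm
    else:
        density = float("nan")

    widths = np.array([c.mean_width_um for c in caps])
    shapes = np.array([c.shape_score for c in caps])
    principal = np.array([c.principal_orientation for c in caps])
    flows = np.array(
        [c.mean_velocity_mm_s for c in caps if c.mean_velocity_mm_s is not None],
        dtype=float,
    )
    return NailfoldMetrics(
        digit_id=digit_id,
        capillary_density_per_mm=density,
        mean_width_um=float(widths.mean()),
        max_width_um=float(widths.max()),
        shape_score=float(shapes.mean()),
        derangement_score=circular_dispersion(principal),
        mean_flow_mm_s=float(flows.mean()) if flows.size else float("nan"),
        n_capillaries=len(caps),
        density_valid=density_valid,
    )


def summarize_subject(digits, subject_id: str, group: str) -> SubjectRecord:
    """Average per-digit parameters into participant-level parameters.

    Unweighted mean per parameter over the digits where that parameter is
    defined (NaN entries are excluded parameter-wise, so a digit with a
    failed flow measurement still contributes its structural parameters).
    """
    digits = list(digits)
    if len(digits) == 0:
        raise InvalidInputError("summarize_subject requires >= 1 digit")
    params = {}
    for name in PARAMETERS:
        vals = np.array([d.as_dict()[name] for d in digits], dtype=float)
        vals = vals[np.isfinite(vals)]
        params[name] = float(vals.mean()) if vals.size else float("nan")
    return SubjectRecord(
        subject_id=subject_id, group=group, per_digit=digits, participant_params=params
    )
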