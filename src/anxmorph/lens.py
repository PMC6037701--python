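"""Spherical-cap geometry of inter-leaflet membrane lenses.

Bright, mobile inclusions of protein plus anionic lipid trapped between
the two leaflets of a bilayer patch are modelled as a pair of back-to-back
spherical caps of in-plane radius ``w`` and half-thickness ``h``.  The
contact angle follows from sin(theta) = 2 h w / (h^2 + w^2), valid for
shallow caps (h <= w, i.e. at most a hemisphere).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["LensShape", "contact_angle", "cap_radius_of_curvature"]


def _validate(h: float, w: float) -> None:
    if not h > 0:
        raise ValueError("half-thickness h must be > 0")
    if not w > 0:
        raise ValueError("lens radius w must be > 0")
    if h > w:
        raise ValueError(
            f"h = {h:g} m exceeds w = {w:g} m: cap taller than a hemisphere "
            "is outside the shallow-lens model"
        )


def contact_angle(h: float, w: float) -> float:
    """Contact angle of a lens cap, in degrees.

    theta = arcsin(2 h w / (h^2 + w^2)), in (0, 90] for 0 < h <= w.
    Inputs in metres (any common unit works: the formula is scale
    invariant).
    """
    _validate(h, w)
    s = 2.0 * h * w / (h * h + w * w)
    return math.degrees(math.asin(min(s, 1.0)))


def cap_radius_of_curvature(h: float, w: float) -> float:
    """Sphere radius R = (h^2 + w^2) / (2 h) of each cap.

    Consistent with :func:`contact_angle` through R sin(theta) = w.
    """
    _validate(h, w)
    return (h * h + w * w) / (2.0 * h)


@dataclass(frozen=True)
class LensShape:
    """A lens measurement with its derived contact angle (SI units)."""

    w: float  # in-plane radius, m
    h: float  # half-thickness (cap height), m

    def __post_init__(self) -> None:
        _validate(self.h, self.w)

    @property
    def theta_contact(self) -> float:
        """Contact angle in degrees."""
        return contact_angle(self.h, self.w)

    @property
    def cap_radius(self) -> float:
        """Radius of curvature of each spherical cap, m."""
        return cap_radius_of_curvature(self.h, self.w)
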