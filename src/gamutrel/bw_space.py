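"""Geometry of the two-dimensional blackness-whiteness space.

Surface gray shades are represented as points in a plane whose axes are
perceptual *blackness* and *whiteness*.  Under a single illumination level,
the representations of all achromatic surfaces fall on a negatively sloped
straight line in this plane — a *gamut line* — running between a whiteness
intercept (the white end) and a blackness intercept (the black end).  This
module provides the vectors, lines, distances and projections that every
other part of the model is built on.  It knows nothing about luminance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = ["BWVector", "GamutLine", "distance", "line_point", "project_to_line"]

#: Gamut-line roles used elsewhere in the package.
LINE_ROLES = (
    "standard-luminance",
    "comparison-luminance",
    "increment",
    "decrement",
    "mixed",
)


@dataclass(frozen=True)
class BWVector:
    """A point or displacement in blackness-whiteness space.

    Parameters
    ----------
    blackness : float
        Perceptual blackness component.
    whiteness : float
        Perceptual whiteness component.

    Notes
    -----
    Both components must be finite.  Points representing composed surface
    gray shades lie in the upper-right quadrant (both components
    non-negative); displacements (contrast vectors, shift vectors, ground
    vectors) may formally carry a single non-zero component of either sign
    during intermediate computation.
    """

    blackness: float
    whiteness: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.blackness) and math.isfinite(self.whiteness)):
            raise ValueError(
                f"non-finite blackness-whiteness coordinates "
                f"({self.blackness!r}, {self.whiteness!r})"
            )

    def __add__(self, other: "BWVector") -> "BWVector":
        return BWVector(self.blackness + other.blackness, self.whiteness + other.whiteness)

    def __sub__(self, other: "BWVector") -> "BWVector":
        return BWVector(self.blackness - other.blackness, self.whiteness - other.whiteness)

    def __mul__(self, scalar: float) -> "BWVector":
        return BWVector(self.blackness * scalar, self.whiteness * scalar)

    __rmul__ = __mul__

    def __neg__(self) -> "BWVector":
        return BWVector(-self.blackness, -self.whiteness)

    def dot(self, other: "BWVector") -> float:
        return self.blackness * other.blackness + self.whiteness * other.whiteness

    def norm(self) -> float:
        return math.hypot(self.blackness, self.whiteness)

    def as_tuple(self) -> tuple[float, float]:
        return (self.blackness, self.whiteness)


ZERO = BWVector(0.0, 0.0)


@dataclass(frozen=True)
class GamutLine:
    """A negatively sloped gamut segment in blackness-whiteness space.

    The segment runs from ``offset + (0, whiteness_intercept)`` (its white
    end, parameter ``t = 0``) to ``offset + (blackness_intercept, 0)`` (its
    black end, ``t = 1``).  A pure luminance gamut has zero offset; increment,
    decrement and mixed gamuts are luminance gamuts translated by a contrast
    vector, and a comparison gamut is the standard gamut translated by an
    illuminant-shift vector.
    """

    whiteness_intercept: float
    blackness_intercept: float
    offset: BWVector = field(default=ZERO)
    role: str = "standard-luminance"

    def __post_init__(self) -> None:
        if not (
            math.isfinite(self.whiteness_intercept)
            and math.isfinite(self.blackness_intercept)
        ):
            raise ValueError("non-finite gamut intercepts")
        if self.whiteness_intercept < 0:
            raise ValueError(f"whiteness intercept must be >= 0, got {self.whiteness_intercept}")
        if self.blackness_intercept <= 0:
            raise ValueError(f"blackness intercept must be > 0, got {self.blackness_intercept}")
        if self.role not in LINE_ROLES:
            raise ValueError(f"unknown gamut role {self.role!r}; expected one of {LINE_ROLES}")

    @property
    def slope(self) -> float:
        """Slope of the line, -whiteness_intercept / blackness_intercept (< 0)."""
        return -self.whiteness_intercept / self.blackness_intercept


def distance(a: BWVector, b: BWVector) -> float:
    """Euclidean distance between two points in blackness-whiteness space.

    Perceptual matches in the model are minimal Euclidean mismatches, so
    this metric is the model's notion of perceptual dissimilarity between
    gray shades.  It is unweighted: the asymmetry between blackness and
    whiteness lives entirely in the photometric mapping constants.
    """
    return math.hypot(a.blackness - b.blackness, a.whiteness - b.whiteness)


def line_point(line: GamutLine, t: float) -> BWVector:
    """Point on a gamut segment at parameter ``t`` in [0, 1].

    ``t = 0`` is the whiteness-axis end of the segment, ``t = 1`` the
    blackness-axis end.
    """
    if not math.isfinite(t):
        raise ValueError(f"non-finite line parameter {t!r}")
    if t < 0.0 or t > 1.0:
        raise ValueError(f"line parameter t={t} outside [0, 1]")
    return BWVector(
        line.offset.blackness + t * line.blackness_intercept,
        line.offset.whiteness + (1.0 - t) * line.whiteness_intercept,
    )


def project_to_line(p: BWVector, line: GamutLine) -> tuple[float, float]:
    """Closest point on a gamut segment to ``p``.

    Returns ``(t_star, d_star)`` where ``t_star`` in [0, 1] minimises the
    distance from ``p`` to ``line_point(line, t)`` and ``d_star`` is that
    minimal distance.  When the orthogonal foot of the perpendicular falls
    outside the segment, ``t_star`` clips to the nearer endpoint.
    """
    b0 = line.blackness_intercept
    w0 = line.whiteness_intercept
    # Direction from the white end (t=0) to the black end (t=1).
    dirvec = BWVector(b0, -w0)
    d2 = dirvec.dot(dirvec)
    if d2 <= 0.0 or not math.isfinite(d2):
        raise ValueError("degenerate gamut line: zero-length segment")
    white_end = BWVector(line.offset.blackness, line.offset.whiteness + w0)
    t = (p - white_end).dot(dirvec) / d2
    t_star = min(1.0, max(0.0, t))
    d_star = distance(p, line_point(line, t_star))
    return t_star, d_star
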