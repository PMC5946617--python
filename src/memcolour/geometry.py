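"""Chromaticity-plane geometry for achromatic-adjustment data.

Colour adjustments live in the isoluminant chromaticity plane of the
Derrington-Krauskopf-Lennie (DKL) opponent colour space, with the
background grey at the origin.  Units are the plane's own arbitrary
units; no conversion from device or cone space happens here.

The memory colour effect is one-dimensional: each stimulus has a
*typical-hue axis* -- the unit direction of the mean typical adjustment
-- and every analysis starts by projecting 2-D adjustments onto that
axis.  The component orthogonal to the axis is discarded.

Sign convention (matters!): a *positive* projection points toward the
typical colour.  Grey adjustments of a colour-diagnostic object are
shifted *opposite* the typical hue (observers compensate for the memory
colour they perceive), so the measured memory colour effect is the
*negated* mean projection of those grey adjustments: compensating shifts
give a positive effect, shifts toward the typical hue a negative one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateAxisError, InvalidAxisError, InvalidInputError

__all__ = [
    "Chromaticity",
    "PolarChromaticity",
    "HueAxis",
    "to_polar",
    "from_polar",
    "hue_axis_from_typicals",
    "project",
    "project_coords",
    "measured_effect",
]

#: Below this mean radius a stimulus has no defined memory-colour direction.
DEGENERATE_AXIS_TOL = 1e-6

#: Unit-norm check tolerance for hue axes.
UNIT_NORM_TOL = 1e-9


@dataclass(frozen=True)
class Chromaticity:
    """A point in the isoluminant DKL plane; (0, 0) is the background grey."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidInputError(f"non-finite chromaticity ({self.x}, {self.y})")


@dataclass(frozen=True)
class PolarChromaticity:
    """Polar form: azimuth (hue angle, radians in [0, 2*pi)) and radius
    (saturation, same arbitrary units as the plane)."""

    azimuth: float
    radius: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.azimuth) and math.isfinite(self.radius)):
            raise InvalidInputError("non-finite polar chromaticity")
        if self.radius < 0:
            raise InvalidInputError(f"negative radius {self.radius}")
        if not 0.0 <= self.azimuth < 2.0 * math.pi:
            raise InvalidInputError(f"azimuth {self.azimuth} outside [0, 2*pi)")


@dataclass(frozen=True)
class HueAxis:
    """Per-stimulus unit direction of the typical colour."""

    stimulus_id: str
    ux: float
    uy: float

    def __post_init__(self) -> None:
        norm2 = self.ux * self.ux + self.uy * self.uy
        if abs(norm2 - 1.0) > UNIT_NORM_TOL:
            raise InvalidAxisError(
                f"hue axis for {self.stimulus_id!r} is not unit-norm "
                f"(|u|^2 = {norm2!r})"
            )

    @property
    def angle(self) -> float:
        """Hue angle of the axis in [0, 2*pi)."""
        return math.atan2(self.uy, self.ux) % (2.0 * math.pi)


def to_polar(c: Chromaticity) -> PolarChromaticity:
    """Convert to polar coordinates; the origin maps to (azimuth 0, radius 0)."""
    radius = math.hypot(c.x, c.y)
    azimuth = 0.0 if radius == 0.0 else math.atan2(c.y, c.x) % (2.0 * math.pi)
    if azimuth >= 2.0 * math.pi:  # tiny negative angles round up to 2*pi
        azimuth = 0.0
    return PolarChromaticity(azimuth=azimuth, radius=radius)


def from_polar(p: PolarChromaticity) -> Chromaticity:
    """Inverse of :func:`to_polar`."""
    return Chromaticity(p.radius * math.cos(p.azimuth), p.radius * math.sin(p.azimuth))


def hue_axis_from_typicals(
    stimulus_id: str,
    typicals: Sequence[Chromaticity] | np.ndarray,
    tol: float = DEGENERATE_AXIS_TOL,
) -> HueAxis:
    """Unit direction of the mean typical adjustment of one stimulus.

    Parameters
    ----------
    stimulus_id
        Identifier carried on the returned axis.
    typicals
        Typical adjustments, as ``Chromaticity`` objects or an (n, 2) array.
    tol
        Mean-radius threshold below which the stimulus is declared to have
        no memory-colour direction (raises :class:`DegenerateAxisError`).
    """
    xy = _as_xy(typicals)
    if xy.shape[0] == 0:
        raise InvalidInputError("need at least one typical adjustment")
    mx, my = float(xy[:, 0].mean()), float(xy[:, 1].mean())
    radius = math.hypot(mx, my)
    if radius <= tol:
        raise DegenerateAxisError(
            f"stimulus {stimulus_id!r}: mean typical adjustment has radius "
            f"{radius:.3g} <= {tol:g}; no memory-colour direction is defined"
        )
    return HueAxis(stimulus_id=stimulus_id, ux=mx / radius, uy=my / radius)


def project(c: Chromaticity, axis: HueAxis) -> float:
    """Signed scalar projection of an adjustment onto the typical-hue axis.

    Positive values point toward the typical colour.
    """
    return float(c.x * axis.ux + c.y * axis.uy)


def project_coords(xy: np.ndarray, axis: HueAxis) -> np.ndarray:
    """Vectorised :func:`project` for an (n, 2) coordinate array."""
    xy = np.asarray(xy, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise InvalidInputError(f"expected an (n, 2) array, got shape {xy.shape}")
    if not np.all(np.isfinite(xy)):
        raise InvalidInputError("non-finite coordinates in projection input")
    return xy[:, 0] * axis.ux + xy[:, 1] * axis.uy


def measured_effect(grey_object_projections: Iterable[float]) -> float:
    """Measured memory colour effect from grey adjustments of an object.

    Grey adjustments shifted *opposite* the typical hue (negative
    projections) yield a positive effect; shifts toward the typical hue
    yield a negative effect (a "negative memory colour index").
    """
    proj = np.asarray(list(grey_object_projections), dtype=float)
    if proj.size == 0:
        raise InvalidInputError("measured_effect needs at least one projection")
    if not np.all(np.isfinite(proj)):
        raise InvalidInputError("non-finite projection values")
    return float(-proj.mean())


def _as_xy(points: Sequence[Chromaticity] | np.ndarray) -> np.ndarray:
    if isinstance(points, np.ndarray):
        xy = np.asarray(points, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise InvalidInputError(f"expected an (n, 2) array, got shape {xy.shape}")
    else:
        xy = np.array([(p.x, p.y) for p in points], dtype=float).reshape(-1, 2)
    if not np.all(np.isfinite(xy)):
        raise InvalidInputError("non-finite coordinates")
    return xy
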