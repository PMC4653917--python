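"""Spatial pH gradient of the assay plate.

The assay geometry is a straight acidic color border (the yellow/blue
transition of bromophenol blue, at roughly pH 4.0) with a 1-D pH gradient
running perpendicular to it.  Positions are described by a signed distance
``d`` along the border normal: ``d > 0`` inside the acidic region, ``d < 0``
on the less acidic side, ``d = 0`` on the border itself.

A :class:`GradientField` is a monotone, piecewise-linear map from signed
distance to pH, clamped to its end values outside the measured span so the
virtual plate is defined everywhere a model worm can wander.  Fields are
either fitted from measured strip data (:func:`fit_gradient`) or built
parametrically (:func:`make_parametric_gradient`).
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Tuple

__all__ = [
    "GradientProfile",
    "GradientField",
    "fit_gradient",
    "ph_at",
    "make_parametric_gradient",
    "read_profile_csv",
    "write_profile_csv",
]


class GradientError(ValueError):
    """Raised for invalid gradient profiles (too few points, non-monotone pH)."""


@dataclass(frozen=True)
class GradientProfile:
    """Measured (distance, pH) pairs along the border normal.

    Parameters
    ----------
    points
        Sequence of ``(distance_mm, pH)`` pairs.  Distances must be strictly
        increasing and pH non-increasing (acid lies on the positive side).
        At least two points are required.
    label
        Free-text condition label (e.g. the buffer/HCl combination).
    """

    points: Tuple[Tuple[float, float], ...]
    label: str = ""

    def __post_init__(self) -> None:
        pts = tuple((float(d), float(p)) for d, p in self.points)
        object.__setattr__(self, "points", pts)
        if len(pts) < 2:
            raise GradientError("a gradient profile needs at least 2 points")
        ds = [d for d, _ in pts]
        phs = [p for _, p in pts]
        for a, b in zip(ds, ds[1:]):
            if not b > a:
                raise GradientError(
                    f"distances must be strictly increasing (got {a} then {b})"
                )
        for a, b in zip(phs, phs[1:]):
            if b > a:
                raise GradientError(
                    "pH must be non-increasing with distance "
                    f"(got {a} then {b}); acid lies on the positive side"
                )

    @property
    def distances(self) -> Tuple[float, ...]:
        return tuple(d for d, _ in self.points)

    @property
    def ph_values(self) -> Tuple[float, ...]:
        return tuple(p for _, p in self.points)


@dataclass(frozen=True)
class GradientField:
    """Monotone piecewise-linear pH field over the whole real line.

    Linear between the profile knots, constant (clamped) beyond the outermost
    knots.  Evaluation at a knot distance returns the knot pH exactly.
    """

    profile: GradientProfile
    _xs: Tuple[float, ...] = field(init=False, repr=False)
    _ys: Tuple[float, ...] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "_xs", self.profile.distances)
        object.__setattr__(self, "_ys", self.profile.ph_values)

    def ph_at_distance(self, d: float) -> float:
        """pH at signed border distance ``d`` (mm)."""
        xs, ys = self._xs, self._ys
        if d <= xs[0]:
            return ys[0]
        if d >= xs[-1]:
            return ys[-1]
        i = bisect_right(xs, d) - 1
        x0, x1 = xs[i], xs[i + 1]
        y0, y1 = ys[i], ys[i + 1]
        return y0 + (y1 - y0) * (d - x0) / (x1 - x0)

    __call__ = ph_at_distance

    @property
    def min_ph(self) -> float:
        return self._ys[-1]

    @property
    def max_ph(self) -> float:
        return self._ys[0]


def fit_gradient(
    points: Iterable[Tuple[float, float]], label: str = ""
) -> GradientField:
    """Fit a monotone interpolant through measured (distance, pH) points.

    Linear between knots, clamped outside.  Rejects profiles with fewer than
    two points or with pH increasing anywhere along the distance axis.
    """
    pts = sorted(((float(d), float(p)) for d, p in points), key=lambda t: t[0])
    return GradientField(GradientProfile(tuple(pts), label=label))


def ph_at(field: GradientField, position: Sequence[float]) -> float:
    """pH at a 2-D plate position ``(x, y)``.

    The border is the line x = 0; the field varies only along the border
    normal, so the result is independent of y.
    """
    return field.ph_at_distance(float(position[0]))


def make_parametric_gradient(
    border_ph: float = 4.0,
    slope: float = 0.5,
    span: float = 6.0,
    far_ph: float = 6.0,
    near_ph: float = 3.0,
    label: str = "",
) -> GradientField:
    """Build a linear gradient anchored at ``border_ph`` on the border.

    The field falls with ``slope`` (pH per mm) moving into the acid, and is
    clamped where it reaches ``far_ph`` (less acidic plateau) and ``near_ph``
    (acidic plateau), or at ±``span`` mm if the ramp has not reached the
    plateau by then.

    Requires ``slope > 0`` and ``far_ph > border_ph > near_ph``.
    """
    if slope <= 0:
        raise GradientError("slope must be > 0")
    if not (far_ph > border_ph > near_ph):
        raise GradientError(
            f"need far_ph > border_ph > near_ph, got {far_ph}, {border_ph}, {near_ph}"
        )
    if span <= 0:
        raise GradientError("span must be > 0")
    d_far = max((border_ph - far_ph) / slope, -span)
    d_near = min((border_ph - near_ph) / slope, span)
    pts = (
        (d_far, border_ph - slope * d_far),
        (0.0, border_ph),
        (d_near, border_ph - slope * d_near),
    )
    return GradientField(GradientProfile(pts, label=label))


# -- CSV round trip ----------------------------------------------------------
# Two columns (distance_mm, pH) with header; the condition label travels in a
# leading comment line so a plain spreadsheet still opens the file.


def write_profile_csv(profile: GradientProfile, path: str | Path) -> None:
    path = Path(path)
    lines = []
    if profile.label:
        lines.append(f"# label: {json.dumps(profile.label)}")
    lines.append("distance_mm,pH")
    for d, p in profile.points:
        lines.append(f"{d:.6g},{p:.6g}")
    path.write_text("\n".join(lines) + "\n")


def read_profile_csv(path: str | Path) -> GradientProfile:
    path = Path(path)
    label = ""
    points = []
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("label:"):
                label = json.loads(body[len("label:"):].strip())
            continue
        if line.lower().startswith("distance"):
            continue
        d_s, p_s = line.split(",")[:2]
        points.append((float(d_s), float(p_s)))
    return GradientProfile(tuple(points), label=label)
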