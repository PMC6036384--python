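"""Ideal fiducial-device constellation.

The device is four cylindrical copper-sulfate reservoirs: three arranged as
a scalene triangle (default side lengths 50.7, 69.2 and 88.9 mm) and a
fourth placed 12.7 mm above the base centroid.  Each reservoir is a
cylinder of 12.7 mm inner diameter and depth.  The six pairwise separations
are all distinct for the default geometry, which is what makes unambiguous
labeling of the detected markers possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

__all__ = ["DeviceTemplate", "build_template", "template_distances"]

DEFAULT_BASE_SIDES = (50.7, 69.2, 88.9)
DEFAULT_APEX_HEIGHT = 12.7
DEFAULT_MARKER_DIAMETER = 12.7
DEFAULT_MARKER_DEPTH = 12.7

LABELS = ("A", "B", "C", "D")
# label pairs in the order used throughout reports
PAIRS = tuple(combinations(LABELS, 2))


@dataclass(frozen=True)
class DeviceTemplate:
    """Ideal 4-marker constellation in a canonical frame.

    The base triangle lies in the z=0 plane with vertex A at the origin, B
    on the +x axis and C at positive y; labels are assigned so that the side
    opposite A is the shortest base side and the side opposite C the
    longest.  The apex marker D sits ``apex_height`` above the base
    centroid on +z.
    """

    base_sides: tuple[float, float, float]
    apex_height: float
    marker_diameter: float
    marker_depth: float
    points: np.ndarray = field(repr=False)  # (4, 3), rows A, B, C, D

    @property
    def v_marker(self) -> float:
        """Marker signal volume pi (d/2)^2 depth, mm^3 (~1608.8 for defaults)."""
        return float(np.pi * (self.marker_diameter / 2.0) ** 2 * self.marker_depth)

    @property
    def longest_dim(self) -> float:
        """Space diagonal of the marker cylinder, sqrt(d^2 + depth^2) mm."""
        return float(np.hypot(self.marker_diameter, self.marker_depth))

    @property
    def separations(self) -> np.ndarray:
        """The six pairwise marker separations, ordered as :data:`PAIRS`."""
        return np.array(
            [np.linalg.norm(self.points[i] - self.points[j])
             for i, j in combinations(range(4), 2)]
        )

    @property
    def separations_by_pair(self) -> dict[tuple[str, str], float]:
        return {p: float(d) for p, d in zip(PAIRS, self.separations)}

    def to_dict(self) -> dict:
        return {
            "base_sides": list(self.base_sides),
            "apex_height": self.apex_height,
            "marker_diameter": self.marker_diameter,
            "marker_depth": self.marker_depth,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceTemplate":
        return build_template(
            base_sides=tuple(d.get("base_sides", DEFAULT_BASE_SIDES)),
            apex_height=d.get("apex_height", DEFAULT_APEX_HEIGHT),
            marker_diameter=d.get("marker_diameter", DEFAULT_MARKER_DIAMETER),
            marker_depth=d.get("marker_depth", DEFAULT_MARKER_DEPTH),
        )


def build_template(
    base_sides: tuple[float, float, float] = DEFAULT_BASE_SIDES,
    apex_height: float = DEFAULT_APEX_HEIGHT,
    marker_diameter: float = DEFAULT_MARKER_DIAMETER,
    marker_depth: float = DEFAULT_MARKER_DEPTH,
) -> DeviceTemplate:
    """Construct the canonical device template.

    ``base_sides`` may be given in any order; they are sorted so that the
    side opposite vertex A is the shortest and the side opposite C the
    longest (|BC| <= |AC| <= |AB|).

    Raises
    ------
    ValueError
        If any dimension is non-positive or the sides violate the strict
        triangle inequality.
    """
    sides = tuple(float(s) for s in base_sides)
    if len(sides) != 3 or any(s <= 0 for s in sides):
        raise ValueError(f"base sides must be three positive lengths, got {sides}")
    if apex_height < 0 or marker_diameter <= 0 or marker_depth <= 0:
        raise ValueError("apex height must be >= 0 and marker dimensions > 0")
    a, b, c = sorted(sides)  # opposite A, B, C
    for (p, q, r) in ((a, b, c), (b, c, a), (c, a, b)):
        if p + q <= r:
            raise ValueError(
                f"degenerate base triangle: {p:g} + {q:g} <= {r:g} "
                "(strict triangle inequality violated)"
            )

    # A at origin, B on +x at distance |AB| = c; C from |AC| = b, |BC| = a.
    A = np.array([0.0, 0.0, 0.0])
    B = np.array([c, 0.0, 0.0])
    cx = (c * c + b * b - a * a) / (2.0 * c)
    cy = float(np.sqrt(b * b - cx * cx))
    C = np.array([cx, cy, 0.0])
    D = (A + B + C) / 3.0 + np.array([0.0, 0.0, float(apex_height)])
    pts = np.vstack([A, B, C, D])
    return DeviceTemplate(
        base_sides=(a, b, c),
        apex_height=float(apex_height),
        marker_diameter=float(marker_diameter),
        marker_depth=float(marker_depth),
        points=pts,
    )


def template_distances(t: DeviceTemplate) -> np.ndarray:
    """The six pairwise separations sorted descending — the matching
    signature used by the inter-marker distance discrimination step."""
    return np.sort(t.separations)[::-1]
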