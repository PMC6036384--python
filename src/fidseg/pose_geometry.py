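"""Device pose: group center-of-mass, base normal, spherical angles, and
rigid alignment to the template frame.

The device orientation is the unit normal of the base triangle,
``unit((B - A) x (C - A))``, with its sign fixed so that it points from the
base toward the apex marker D.  Fixing the sign by the apex (rather than by
the handedness of the A, B, C labels) makes the reported angles independent
of base-label permutations.  The normal's spherical angles in the LPS frame
are ``theta = arccos(n_z)`` (polar angle from Superior) and
``phi = atan2(n_y, n_x)`` (azimuth from Left toward Posterior), in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .device_template import DeviceTemplate, LABELS

__all__ = ["DeviceDetection", "RigidFit", "device_pose", "rigid_fit", "pose_difference"]


@dataclass
class RigidFit:
    """Proper rigid transform (rotation + translation) template -> world."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rms: float  # mm

    def apply(self, pts: np.ndarray) -> np.ndarray:
        return np.asarray(pts, float) @ self.rotation.T + self.translation


@dataclass
class DeviceDetection:
    """A localized device: four labeled marker COMs plus derived pose."""

    marker_coms: dict[str, np.ndarray]  # labels A..D -> world mm (LPS)
    device_com: np.ndarray
    normal: np.ndarray
    theta: float  # degrees, [0, 180]
    phi: float  # degrees, (-180, 180]; 0 by convention at the poles
    match_tolerance: float | None = None  # mm; tau used by the matcher
    rigid: RigidFit | None = None
    phi_degenerate: bool = False
    diagnostics: dict[str, Any] = field(default_factory=dict)

    @property
    def points(self) -> np.ndarray:
        """(4, 3) array of marker COMs in label order A, B, C, D."""
        return np.vstack([self.marker_coms[l] for l in LABELS])

    def separations(self) -> np.ndarray:
        """Six measured pairwise separations, ordered as template PAIRS."""
        p = self.points
        from itertools import combinations

        return np.array([np.linalg.norm(p[i] - p[j]) for i, j in combinations(range(4), 2)])

    def to_dict(self) -> dict:
        d = {
            "marker_coms_mm": {l: np.asarray(v).tolist() for l, v in self.marker_coms.items()},
            "device_com_mm": np.asarray(self.device_com).tolist(),
            "normal": np.asarray(self.normal).tolist(),
            "theta_deg": self.theta,
            "phi_deg": self.phi,
            "phi_degenerate": self.phi_degenerate,
            "match_tolerance_mm": self.match_tolerance,
            "diagnostics": _jsonable(self.diagnostics),
        }
        if self.rigid is not None:
            d["rigid_fit"] = {
                "rotation": self.rigid.rotation.tolist(),
                "translation": self.rigid.translation.tolist(),
                "rms_mm": self.rigid.rms,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DeviceDetection":
        rigid = None
        if "rigid_fit" in d:
            rf = d["rigid_fit"]
            rigid = RigidFit(np.asarray(rf["rotation"]), np.asarray(rf["translation"]), rf["rms_mm"])
        return cls(
            marker_coms={l: np.asarray(v, float) for l, v in d["marker_coms_mm"].items()},
            device_com=np.asarray(d["device_com_mm"], float),
            normal=np.asarray(d["normal"], float),
            theta=d["theta_deg"],
            phi=d["phi_deg"],
            match_tolerance=d.get("match_tolerance_mm"),
            rigid=rigid,
            phi_degenerate=d.get("phi_degenerate", False),
            diagnostics=d.get("diagnostics", {}),
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


_POLE_EPS = 1e-9


def device_pose(marker_coms: dict[str, np.ndarray] | np.ndarray):
    """Compute (device_com, normal, theta, phi) from four labeled markers.

    ``marker_coms`` is a label->point mapping or a (4, 3) array in A, B, C,
    D order.  The device COM is the unweighted mean of the four marker COMs
    (the markers are physically identical, so intensity weighting across
    markers would make the pose sequence-dependent).

    Raises
    ------
    ValueError
        If the base points A, B, C are (near-)collinear.
    """
    if isinstance(marker_coms, dict):
        pts = np.vstack([np.asarray(marker_coms[l], float) for l in LABELS])
    else:
        pts = np.asarray(marker_coms, float)
        if pts.shape != (4, 3):
            raise ValueError("expected four 3D points")
    A, B, C, D = pts
    n = np.cross(B - A, C - A)
    nn = np.linalg.norm(n)
    scale = max(np.linalg.norm(B - A), np.linalg.norm(C - A), 1e-12)
    if nn < 1e-9 * scale * scale:
        raise ValueError("collinear base points: device normal undefined")
    n = n / nn
    # sign: base -> apex
    if np.dot(n, D - (A + B + C) / 3.0) < 0:
        n = -n
    theta = float(np.degrees(np.arccos(np.clip(n[2], -1.0, 1.0))))
    degenerate = bool(abs(n[0]) < _POLE_EPS and abs(n[1]) < _POLE_EPS)
    phi = 0.0 if degenerate else float(np.degrees(np.arctan2(n[1], n[0])))
    if phi <= -180.0:
        phi += 360.0
    com = pts.mean(axis=0)
    return com, n, theta, phi, degenerate


def rigid_fit(template: DeviceTemplate, marker_coms: dict[str, np.ndarray] | np.ndarray) -> RigidFit:
    """Least-squares proper rigid alignment of the labeled template points
    onto the detected marker COMs (Kabsch, SVD-based).

    Raises
    ------
    ValueError
        If the optimal orthogonal transform is a reflection that cannot be
        corrected to a proper rotation (degenerate point sets only).
    """
    if isinstance(marker_coms, dict):
        tgt = np.vstack([np.asarray(marker_coms[l], float) for l in LABELS])
    else:
        tgt = np.asarray(marker_coms, float)
    src = template.points
    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    H = src_c.T @ tgt_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if d < 0 and S[-1] > 1e-9 and np.isclose(S[-2], S[-1]):
        raise ValueError("reflection-only optimum: cannot fit a proper rotation")
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = tgt.mean(axis=0) - R @ src.mean(axis=0)
    resid = src @ R.T + t - tgt
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return RigidFit(R, t, rms)


def _wrap_deg(a: float) -> float:
    """Wrap an angle difference into (-180, 180]."""
    a = (a + 180.0) % 360.0 - 180.0
    return a + 360.0 if a <= -180.0 else a


def pose_difference(
    a: DeviceDetection,
    b: DeviceDetection,
    commanded_shift: np.ndarray | None = None,
) -> dict:
    """Differences b - a in COM (per axis and norm, mm) and angles (deg).

    ``commanded_shift`` is a known, deliberately applied world translation
    of b relative to a (e.g. a 30 mm table shift); it is removed before the
    COM comparison.
    """
    shift = np.zeros(3) if commanded_shift is None else np.asarray(commanded_shift, float)
    d = np.asarray(b.device_com) - np.asarray(a.device_com) - shift
    return {
        "dx_mm": float(d[0]),
        "dy_mm": float(d[1]),
        "dz_mm": float(d[2]),
        "dcom_mm": float(np.linalg.norm(d)),
        "dtheta_deg": float(b.theta - a.theta),
        "dphi_deg": float(_wrap_deg(b.phi - a.phi)),
    }
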