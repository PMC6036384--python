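"""Synthetic MR acquisition simulator.

Generates 3D volumes containing the fiducial device over a body-like
background under the acquisition geometries of a clinical abdominal
protocol (in-plane 0.7-1.9 mm, slices 1.7-10 mm, gaps 0-2 mm, axial /
coronal / oblique planes).  The continuous scene — four marker cylinders,
a tissue ellipsoid with internal blob structures, air elsewhere — is
integrated over each voxel's sensitive volume (full in-plane footprint,
slice thickness in the slice direction; the gap region contributes
nothing) by supersampling, then Gaussian noise is added on a magnitude
floor and intensities are quantized to integers.

The simulator reproduces the features the detector depends on: partial
volume from thick slices and gaps, marker-sized background confusers,
integer-quantized noisy intensities, oblique scan planes and table shifts.
It does not model pulse-sequence contrast physics, coil profiles or
motion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .device_template import DeviceTemplate
from .volume_io import Volume3D

__all__ = [
    "AcquisitionSpec",
    "ScenePose",
    "PRESETS",
    "preset_spec",
    "rasterize_scene",
    "table1_suite",
    "repeatability_suite",
    "coronal_base_rotation",
]

# Acquisition geometry presets: in-plane (mm), slice thickness (mm),
# slice gap (mm), scan plane.  One preset per image set of the abdominal
# protocol (the in-phase / opposed-phase echoes count as two sets; the
# 3-plane localizer counts as one, represented by its axial plane).
PRESETS: dict[str, dict] = {
    "loc3plane": dict(in_plane_mm=(1.9, 1.9), slice_thickness_mm=10.0, slice_gap_mm=0.0, scan_plane="axial"),
    "ssfse": dict(in_plane_mm=(0.9, 0.9), slice_thickness_mm=6.0, slice_gap_mm=1.0, scan_plane="coronal"),
    "ip": dict(in_plane_mm=(0.7, 0.7), slice_thickness_mm=6.0, slice_gap_mm=1.0, scan_plane="axial"),
    "op": dict(in_plane_mm=(0.7, 0.7), slice_thickness_mm=6.0, slice_gap_mm=1.0, scan_plane="axial"),
    "lava": dict(in_plane_mm=(0.7, 0.7), slice_thickness_mm=1.7, slice_gap_mm=0.0, scan_plane="axial"),
    "fiesta": dict(in_plane_mm=(0.7, 0.7), slice_thickness_mm=4.0, slice_gap_mm=2.0, scan_plane="axial"),
    "spgr": dict(in_plane_mm=(0.7, 0.7), slice_thickness_mm=5.0, slice_gap_mm=1.0, scan_plane="axial"),
    "frfse": dict(in_plane_mm=(0.7, 0.7), slice_thickness_mm=7.0, slice_gap_mm=1.0, scan_plane="axial"),
}

SUITE_ORDER = ("loc3plane", "ssfse", "ip", "op", "lava", "fiesta", "spgr", "frfse")

# Default signal levels: plausible integer DICOM-like range.
DEFAULT_SIGNALS = dict(air=0.0, tissue=120.0, marker=400.0)
DEFAULT_NOISE_SIGMA = 10.0
DEFAULT_INTENSITY_MAX = 4095
# Scanner-fixed FOV, sized so the device stays inside at both table
# positions of the repeatability experiment (30 mm shift along z).
DEFAULT_FOV = (160.0, 110.0, 180.0)  # world extents, mm
DEFAULT_FOV_CENTER = (0.0, 20.0, 10.0)


@dataclass
class AcquisitionSpec:
    """Recipe for one synthetic scan."""

    name: str = "custom"
    in_plane_mm: tuple[float, float] = (0.7, 0.7)
    slice_thickness_mm: float = 5.0
    slice_gap_mm: float = 0.0
    scan_plane: str | np.ndarray = "axial"  # named plane or 3x3 direction matrix
    table_shift_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    fov_mm: tuple[float, float, float] = DEFAULT_FOV
    fov_center_mm: tuple[float, float, float] = DEFAULT_FOV_CENTER
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    signal_levels: dict = field(default_factory=lambda: dict(DEFAULT_SIGNALS))
    intensity_max: int = DEFAULT_INTENSITY_MAX
    supersample: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.in_plane_mm) <= 0 or self.slice_thickness_mm <= 0:
            raise ValueError("voxel dimensions must be > 0")
        if self.slice_gap_mm < 0:
            raise ValueError("slice gap must be >= 0")
        s = self.signal_levels
        if not s["marker"] > s["tissue"] > s["air"] >= 0:
            raise ValueError("signal levels must satisfy marker > tissue > air >= 0")

    @property
    def slice_spacing_mm(self) -> float:
        """Reconstructed inter-slice spacing dz = thickness + gap."""
        return self.slice_thickness_mm + self.slice_gap_mm

    @property
    def spacing(self) -> np.ndarray:
        return np.array([*self.in_plane_mm, self.slice_spacing_mm])


def preset_spec(name: str, **overrides) -> AcquisitionSpec:
    """Build an :class:`AcquisitionSpec` from a named preset."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    spec = AcquisitionSpec(name=name, **PRESETS[name])
    return replace(spec, **overrides) if overrides else spec


# rotation taking the canonical template frame (base in z=0, apex on +z)
# to a device lying with its base purely in the coronal plane, apex
# pointing Anterior (-y): expected orientation angles (90, -90) degrees.
def coronal_base_rotation() -> np.ndarray:
    return np.array([[1.0, 0.0, 0.0], [0.0, 0.0, -1.0], [0.0, 1.0, 0.0]])


@dataclass
class ScenePose:
    """Scene description: device pose plus the body-like background.

    ``device_position`` is the world position of the base-triangle
    centroid; ``device_orientation`` rotates the canonical template about
    that centroid.  The background is a tissue ellipsoid with seeded
    internal ellipsoidal blobs spanning marker-scale volumes — deliberate
    marker-sized confusers for the size/signal and matching stages.
    """

    device_position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    device_orientation: np.ndarray = field(default_factory=coronal_base_rotation)
    body_center: np.ndarray | None = field(default_factory=lambda: np.array([0.0, 85.0, 0.0]))
    body_semiaxes: np.ndarray = field(default_factory=lambda: np.array([130.0, 70.0, 200.0]))
    blobs: list = field(default_factory=list)  # (center(3), semiaxes(3), intensity)

    @classmethod
    def default(
        cls,
        seed: int = 0,
        n_blobs: int = 30,
        v_marker: float = 1608.8,
        tissue: float = DEFAULT_SIGNALS["tissue"],
    ) -> "ScenePose":
        """Baseline scene: device base in the coronal plane, standing off
        the anterior body surface (the housing keeps the reservoirs clear
        of the skin), with ``n_blobs`` seeded internal structures of
        0.2-4x the marker volume and 0.5-1.5x tissue intensity."""
        pose = cls()
        rng = np.random.default_rng(seed)
        blobs = []
        for _ in range(n_blobs):
            vol = v_marker * np.exp(rng.uniform(np.log(0.2), np.log(4.0)))
            ratios = rng.uniform(0.6, 1.6, size=3)
            base_r = (3.0 * vol / (4.0 * np.pi * np.prod(ratios))) ** (1.0 / 3.0)
            semi = ratios * base_r
            # uniform direction, radius biased outward, inside 0.85 shell
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            r = 0.85 * rng.uniform() ** (1.0 / 3.0)
            center = pose.body_center + u * r * pose.body_semiaxes
            intensity = tissue * rng.uniform(0.5, 1.5)
            blobs.append((center, semi, float(intensity)))
        pose.blobs = blobs
        return pose

    def posed_points(self, t: DeviceTemplate) -> np.ndarray:
        """World positions of the four marker centers."""
        centroid = t.points[:3].mean(axis=0)
        return (t.points - centroid) @ np.asarray(self.device_orientation).T + np.asarray(
            self.device_position, float
        )

    def marker_axis(self) -> np.ndarray:
        """World direction of the marker cylinder axes (template +z)."""
        return np.asarray(self.device_orientation) @ np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# Grid construction


_NAMED_PLANES = {
    # columns: world directions of the logical i, j, k axes (k = slice axis)
    "axial": np.eye(3),
    "coronal": np.array([[1.0, 0, 0], [0, 0, 1.0], [0, 1.0, 0]]).T,
    "sagittal": np.array([[0, 1.0, 0], [0, 0, 1.0], [1.0, 0, 0]]).T,
}


def oblique_plane(angle_deg: float, axis: str = "x") -> np.ndarray:
    """Axial plane tilted by ``angle_deg`` about an in-plane world axis."""
    a = np.radians(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], float)
    elif axis == "y":
        R = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], float)
    else:
        raise ValueError("axis must be 'x' or 'y'")
    return R  # columns: rotated axial axes


def _direction(spec: AcquisitionSpec) -> np.ndarray:
    if isinstance(spec.scan_plane, str):
        try:
            return _NAMED_PLANES[spec.scan_plane]
        except KeyError:
            raise ValueError(f"unknown scan plane {spec.scan_plane!r}") from None
    D = np.asarray(spec.scan_plane, float)
    if D.shape != (3, 3) or abs(abs(np.linalg.det(D)) - 1.0) > 1e-6:
        raise ValueError("scan_plane matrix must be 3x3 with |det| = 1")
    return D


def _grid(spec: AcquisitionSpec) -> tuple[tuple[int, int, int], np.ndarray]:
    """Grid shape and LPS affine for a spec (FOV centered on fov_center)."""
    D = _direction(spec)
    spacing = spec.spacing
    # grid-axis extents of the rotated bounding box of the world FOV box
    extents = np.abs(D.T) @ np.asarray(spec.fov_mm, float)
    shape = np.maximum(np.round(extents / spacing).astype(int), 1)
    A3 = D * spacing  # scales columns
    origin = np.asarray(spec.fov_center_mm, float) - A3 @ ((shape - 1) / 2.0)
    affine = np.eye(4)
    affine[:3, :3] = A3
    affine[:3, 3] = origin
    return tuple(int(n) for n in shape), affine


# ---------------------------------------------------------------------------
# Rasterization


def _index_bbox(affine: np.ndarray, center: np.ndarray, half: float, shape) -> tuple | None:
    """Voxel-index bounding box (slices) of a world box center +- half."""
    corners = center + half * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    inv = np.linalg.inv(affine)
    idx = corners @ inv[:3, :3].T + inv[:3, 3]
    lo = np.floor(idx.min(axis=0)).astype(int) - 1
    hi = np.ceil(idx.max(axis=0)).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(shape) - 1)
    if (hi < lo).any():
        return None
    return tuple(slice(a, b + 1) for a, b in zip(lo, hi))


def rasterize_scene(
    t: DeviceTemplate, pose: ScenePose, spec: AcquisitionSpec
) -> Volume3D:
    """Simulate one acquisition of the scene.

    The scene is shifted by ``spec.table_shift_mm`` (table and device move
    together; the scan FOV stays put), integrated over each voxel's
    sensitive volume with ``supersample``^3 samples, noise-corrupted
    (``|signal + N(0, sigma)|``) and quantized to integers in
    ``[0, intensity_max]``.  Deterministic for a fixed ``spec.seed``.
    """
    shape, affine = _grid(spec)
    shift = np.asarray(spec.table_shift_mm, float)
    sig = spec.signal_levels
    markers = pose.posed_points(t) + shift
    axis = pose.marker_axis()
    radius = t.marker_diameter / 2.0
    half_depth = t.marker_depth / 2.0
    marker_bound = float(np.hypot(radius, half_depth))

    # device-in-FOV check on the marker bounding spheres
    inv = np.linalg.inv(affine)
    midx = markers @ inv[:3, :3].T + inv[:3, 3]
    inside = ((midx >= -0.5) & (midx <= np.asarray(shape) - 0.5)).all(axis=1)
    if not inside.any():
        raise ValueError("device fully outside the field of view")
    if not inside.all():
        warnings.warn("device partially outside the field of view; markers clipped")

    A3 = affine[:3, :3].astype(np.float32)
    origin = affine[:3, 3].astype(np.float32)
    ni, nj, nk = shape
    i = np.arange(ni, dtype=np.float32)[:, None, None]
    j = np.arange(nj, dtype=np.float32)[None, :, None]
    k = np.arange(nk, dtype=np.float32)[None, None, :]
    X0 = A3[0, 0] * i + A3[0, 1] * j + A3[0, 2] * k + origin[0]
    Y0 = A3[1, 0] * i + A3[1, 1] * j + A3[1, 2] * k + origin[1]
    Z0 = A3[2, 0] * i + A3[2, 1] * j + A3[2, 2] * k + origin[2]
    X0, Y0, Z0 = np.broadcast_arrays(X0, Y0, Z0)

    # precompute index bounding boxes of the localized objects
    blob_boxes = []
    for center, semi, intensity in pose.blobs:
        c = np.asarray(center, float) + shift
        box = _index_bbox(affine, c, float(np.max(semi)) + 1.0, shape)
        blob_boxes.append((c, np.asarray(semi, float), float(intensity), box))
    marker_boxes = [
        _index_bbox(affine, m, marker_bound + 1.0, shape) for m in markers
    ]
    body_center = None if pose.body_center is None else np.asarray(pose.body_center, float) + shift

    ss = int(spec.supersample)
    offs = (np.arange(ss) + 0.5) / ss - 0.5
    # sub-voxel sample offsets in index units; the slice axis samples only
    # the excited slab (thickness), never the gap
    z_frac = spec.slice_thickness_mm / spec.slice_spacing_mm
    acc = np.zeros(shape, dtype=np.float32)
    tissue = np.float32(sig["tissue"])
    air = np.float32(sig["air"])
    marker_val = np.float32(sig["marker"])
    axis32 = axis.astype(np.float32)

    for oi in offs:
        for oj in offs:
            for ok in offs:
                dv = A3 @ np.array([oi, oj, ok * z_frac], dtype=np.float32)
                X = X0 + dv[0]
                Y = Y0 + dv[1]
                Z = Z0 + dv[2]
                val = np.full(shape, air, dtype=np.float32)
                if body_center is not None:
                    a, b, c = pose.body_semiaxes
                    q = (
                        ((X - body_center[0]) / a) ** 2
                        + ((Y - body_center[1]) / b) ** 2
                        + ((Z - body_center[2]) / c) ** 2
                    )
                    val[q <= 1.0] = tissue
                for center, semi, intensity, box in blob_boxes:
                    if box is None:
                        continue
                    q = (
                        ((X[box] - center[0]) / semi[0]) ** 2
                        + ((Y[box] - center[1]) / semi[1]) ** 2
                        + ((Z[box] - center[2]) / semi[2]) ** 2
                    )
                    val[box][q <= 1.0] = intensity
                for m, box in zip(markers, marker_boxes):
                    if box is None:
                        continue
                    dx = X[box] - np.float32(m[0])
                    dy = Y[box] - np.float32(m[1])
                    dz = Z[box] - np.float32(m[2])
                    ax = dx * axis32[0] + dy * axis32[1] + dz * axis32[2]
                    rad2 = dx * dx + dy * dy + dz * dz - ax * ax
                    val[box][(np.abs(ax) <= half_depth) & (rad2 <= radius * radius)] = marker_val
                acc += val
    img = acc / np.float32(ss**3)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        noise = rng.standard_normal(shape, dtype=np.float32) * np.float32(spec.noise_sigma)
        img = np.abs(img + noise)
    data = np.clip(np.rint(img), 0, spec.intensity_max).astype(np.int32)

    meta = {
        "preset": spec.name,
        "scan_plane": spec.scan_plane if isinstance(spec.scan_plane, str) else "matrix",
        "in_plane_mm": list(spec.in_plane_mm),
        "slice_thickness_mm": spec.slice_thickness_mm,
        "slice_gap_mm": spec.slice_gap_mm,
        "commanded_shift_mm": list(shift),
        "noise_sigma": spec.noise_sigma,
        "seed": int(spec.seed),
    }
    return Volume3D(data, affine, meta)


# ---------------------------------------------------------------------------
# Experiment suites


def _child_seeds(seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def table1_suite(
    t: DeviceTemplate, pose: ScenePose, seed: int = 0, **spec_overrides
) -> list[tuple[AcquisitionSpec, Volume3D]]:
    """The eight-preset acquisition suite (one volume per image set of the
    abdominal protocol), with per-volume noise seeds derived from ``seed``."""
    seeds = _child_seeds(seed, len(SUITE_ORDER))
    out = []
    for name, s in zip(SUITE_ORDER, seeds):
        spec = preset_spec(name, seed=s, **spec_overrides)
        out.append((spec, rasterize_scene(t, pose, spec)))
    return out


def repeatability_suite(
    t: DeviceTemplate,
    base_pose: ScenePose,
    seed: int = 0,
    preset: str = "spgr",
    oblique_angles_deg: tuple[float, float] = (10.0, 20.0),
    shift_mm: tuple[float, float, float] = (0.0, 0.0, 30.0),
    **spec_overrides,
) -> list[tuple[AcquisitionSpec, Volume3D]]:
    """Repeatability experiment: {axial, two obliques} x {no shift, table
    shift} at one preset; six volumes whose metadata records the commanded
    shift and plane.  The first (axial, unshifted) volume is the baseline.
    """
    planes: list[tuple[str, str | np.ndarray]] = [
        ("axial", "axial"),
        (f"oblique{oblique_angles_deg[0]:g}", oblique_plane(oblique_angles_deg[0], "x")),
        (f"oblique{oblique_angles_deg[1]:g}", oblique_plane(oblique_angles_deg[1], "y")),
    ]
    shifts = [(0.0, 0.0, 0.0), tuple(float(x) for x in shift_mm)]
    seeds = _child_seeds(seed, len(planes) * len(shifts))
    out = []
    n = 0
    for sh in shifts:
        for plane_name, plane in planes:
            spec = preset_spec(
                preset,
                scan_plane=plane,
                table_shift_mm=sh,
                seed=seeds[n],
                **spec_overrides,
            )
            vol = rasterize_scene(t, base_pose, spec)
            vol.meta["plane"] = plane_name
            vol.meta["translated"] = any(abs(x) > 0 for x in sh)
            out.append((spec, vol))
            n += 1
    return out
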