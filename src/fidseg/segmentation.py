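"""Automatic fiducial-device segmentation.

The detector localizes a four-marker fiducial device in a 3D MR volume in
five stages, all parameterized relative to the device template so the same
settings work across acquisition geometries whose voxel volumes differ by
more than an order of magnitude:

1. **Noise threshold** ``N_T``: from the integer intensity histogram (bin
   width 1), the first zero-crossing of the forward-difference derivative
   after the background (noise) peak.  Voxels below ``N_T`` are treated as
   zero downstream.
2. **Reference signal threshold** ``R_T``: the mean intensity of voxels in
   26-connected sets whose physical volume lies strictly inside
   ``(0.5, 3) x V_marker`` — i.e. of marker-sized objects.
3. **Iterative size/signal discrimination**: progressively decreasing
   thresholds ``ST_n = (n/4) R_T`` for ``n = 7..2``; at each level,
   26-connected sets strictly inside ``(0.35, 1.3) x V_marker`` are merged
   into a composite candidate mask unless the merge would grow an object
   past ``1.3 x V_marker`` (in which case the new set is discarded).
4. **Shape discrimination**: candidates whose extent along any logical
   axis exceeds ``1.5 x`` the marker's space diagonal (26.9 mm for the
   default 12.7 mm cylinder) are removed.
5. **Inter-marker distance discrimination**: search for four candidates
   whose intensity-weighted COMs reproduce the six template separations
   within a tolerance that starts at +-1 mm and grows in 1 mm increments.

All voxel-set volumes are compared in mm^3 (voxel count x dx dy dz, with dz
including any slice gap); COMs and distances are computed in world mm so
anisotropic and oblique grids are handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations, permutations
from typing import Any, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial.distance import pdist, squareform

from .device_template import DeviceTemplate, LABELS, template_distances
from .pose_geometry import DeviceDetection, device_pose, rigid_fit
from .volume_io import Volume3D, voxel_to_world

__all__ = [
    "CandidateSet",
    "SegmentationConfig",
    "SegmentationError",
    "compute_noise_threshold",
    "connected_sets",
    "reference_threshold",
    "iterative_signal_size",
    "shape_filter",
    "match_device",
    "segment_fiducial",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_EPS = 1e-9


class SegmentationError(RuntimeError):
    """A detection stage failed; ``stage`` names the failing step."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class CandidateSet:
    """One 26-connected voxel set with physical measurements attached."""

    voxels: np.ndarray  # (N, 3) int indices
    intensities: np.ndarray  # (N,) original (pre-threshold) intensities
    volume_mm3: float
    com_world: np.ndarray  # intensity-weighted COM, world mm
    extents_mm: np.ndarray  # (max-min+1) * spacing per logical axis
    provenance: tuple = ()  # which ST_n iteration(s) contributed
    touches_boundary: bool = False

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class SegmentationConfig:
    """Tunable parameters of the five detection stages.

    All size windows are expressed as multiples of the marker volume
    ``v_marker`` and are strict inequalities; ``st_numerators`` gives the
    quarters of ``R_T`` used by the iterative stage (7/4 down to 2/4).
    """

    v_marker: float
    shape_max_mm: float
    size_window_ref: tuple[float, float] = (0.5, 3.0)
    size_window_candidate: tuple[float, float] = (0.35, 1.3)
    st_numerators: tuple[int, ...] = (7, 6, 5, 4, 3, 2)
    match_tol_start: float = 1.0
    match_tol_step: float = 1.0
    match_tol_max: float = 5.0
    # 3-bin moving-average smoothing of the intensity histogram before the
    # noise-threshold scan.  On by default: with few voxels per bin,
    # counting noise alone produces spurious non-negative forward
    # differences inside the background mode; the average restores the
    # intended peak/valley structure and is inconsequential on large,
    # smooth histograms.
    smooth_histogram: bool = True

    def __post_init__(self) -> None:
        for lo, hi in (self.size_window_ref, self.size_window_candidate):
            if not 0 < lo < hi:
                raise ValueError("size windows must satisfy 0 < low < high")
        if list(self.st_numerators) != sorted(self.st_numerators, reverse=True):
            raise ValueError("st_numerators must be strictly decreasing")
        if min(self.match_tol_start, self.match_tol_step, self.match_tol_max) <= 0:
            raise ValueError("matching tolerances must be > 0")

    @classmethod
    def from_template(cls, t: DeviceTemplate, **overrides) -> "SegmentationConfig":
        cfg = cls(v_marker=t.v_marker, shape_max_mm=1.5 * t.longest_dim)
        return replace(cfg, **overrides) if overrides else cfg


# ---------------------------------------------------------------------------
# Step 1: noise threshold


def compute_noise_threshold(v: Volume3D, smooth: bool = False) -> int:
    """Histogram-derivative noise threshold ``N_T``.

    The histogram uses bin width 1 over the full integer intensity range.
    The background peak is the histogram maximum over the lower half of the
    occupied intensity range, excluding the I=0 bin (exact zero can be
    artificially massive in reconstructed images).  ``N_T`` is the smallest
    intensity above the peak at which the forward difference
    ``h(I+1) - h(I)`` first becomes >= 0.  With ``smooth=True`` a 3-bin
    moving average is applied to the histogram first (for ragged
    histograms; off by default).
    """
    data = v.data
    lo_i, hi_i = int(data.min()), int(data.max())
    if hi_i == lo_i:
        raise SegmentationError(
            "noise_threshold", "constant-intensity volume: no noise/signal separation"
        )
    h = np.bincount(data.ravel(), minlength=hi_i + 1).astype(float)
    if smooth:
        h = np.convolve(h, np.ones(3) / 3.0, mode="same")
    occ = np.flatnonzero(h > 0)
    lo, hi = occ[0], occ[-1]
    half = int(lo + (hi - lo) // 2)
    search = h.copy()
    search[0] = 0.0
    if half < 1 or search[: half + 1].max() <= 0:
        raise SegmentationError(
            "noise_threshold", "no background peak in the lower intensity range"
        )
    peak = int(np.argmax(search[: half + 1]))
    d = np.diff(h)  # d[i] = h(i+1) - h(i)
    for i in range(peak + 1, len(d)):
        if d[i] >= 0:
            return i
    raise SegmentationError(
        "noise_threshold",
        "histogram strictly decreasing after the background peak: "
        "no noise/signal separation (volume likely contains no signal)",
    )


# ---------------------------------------------------------------------------
# Step 2: connected sets and the reference threshold


def _sets_from_labels(
    lab: np.ndarray,
    n_labels: int,
    v: Volume3D,
    provenance: tuple = (),
    only: np.ndarray | None = None,
) -> list[CandidateSet]:
    """Build CandidateSets from a labeled array (labels 1..n).

    ``only`` optionally restricts to a subset of label ids.  Output is
    deterministically ordered by (volume, lexicographic first voxel).
    """
    if n_labels == 0:
        return []
    flat = lab.ravel()
    nz = np.flatnonzero(flat)
    labs = flat[nz]
    if only is not None:
        m = np.isin(labs, only)
        nz, labs = nz[m], labs[m]
        if nz.size == 0:
            return []
    order = np.argsort(labs, kind="stable")
    nz, labs = nz[order], labs[order]
    starts = np.searchsorted(labs, np.unique(labs))
    bounds = np.append(starts, labs.size)

    vv = v.voxel_volume
    spacing = v.spacing
    shape = v.shape
    dflat = v.data.ravel()
    dims = np.asarray(shape)
    out = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        lin = nz[s:e]
        ijk = np.column_stack(np.unravel_index(lin, shape)).astype(np.int32)
        inten = dflat[lin].astype(np.int64)
        w = inten.astype(float)
        world = voxel_to_world(v, ijk)
        com = (world * w[:, None]).sum(axis=0) / w.sum()
        lo = ijk.min(axis=0)
        hi = ijk.max(axis=0)
        extents = (hi - lo + 1) * spacing
        touches = bool((lo == 0).any() or (hi == dims - 1).any())
        out.append(
            CandidateSet(
                voxels=ijk,
                intensities=inten,
                volume_mm3=float(len(lin) * vv),
                com_world=com,
                extents_mm=extents,
                provenance=provenance,
                touches_boundary=touches,
            )
        )
    out.sort(key=lambda c: (c.volume_mm3, tuple(c.voxels[0])))
    return out


def connected_sets(v: Volume3D, threshold: float, provenance: tuple = ()) -> list[CandidateSet]:
    """Maximal 26-connected components of voxels with intensity >= threshold."""
    mask = v.data >= threshold
    lab, n = ndi.label(mask, structure=_STRUCT26)
    return _sets_from_labels(lab, n, v, provenance)


def reference_threshold(sets: Sequence[CandidateSet], cfg: SegmentationConfig) -> float:
    """Mean intensity over all voxels of marker-sized sets.

    A set qualifies if its volume lies strictly inside
    ``size_window_ref x v_marker`` (default ``(0.5, 3) x V_marker``).
    """
    lo = cfg.size_window_ref[0] * cfg.v_marker
    hi = cfg.size_window_ref[1] * cfg.v_marker
    total = 0.0
    count = 0
    for s in sets:
        if lo < s.volume_mm3 < hi:
            total += float(s.intensities.sum())
            count += s.n_voxels
    if count == 0:
        raise SegmentationError(
            "reference_threshold",
            f"no marker-sized object: no connected set with volume strictly in "
            f"({lo:.0f}, {hi:.0f}) mm^3",
        )
    return total / count


# ---------------------------------------------------------------------------
# Step 3: iterative size and signal discrimination


def iterative_signal_size(
    v: Volume3D,
    r_t: float,
    cfg: SegmentationConfig,
    noise_threshold: float = 0.0,
) -> list[CandidateSet]:
    """Composite marker-candidate extraction at thresholds ``(n/4) R_T``.

    For each ``n`` in ``st_numerators`` the background-thresholded image is
    thresholded at ``ST_n``; 26-connected sets strictly inside the
    candidate size window are merged into a composite mask.  A set is
    merged only if its union with any overlapping or 26-adjacent composite
    object stays within ``1.3 x V_marker``; otherwise the new set is
    discarded and the composite is unchanged.
    """
    if r_t <= 0:
        raise ValueError("reference threshold must be > 0")
    vm = cfg.v_marker
    vv = v.voxel_volume
    lo = cfg.size_window_candidate[0] * vm
    hi = cfg.size_window_candidate[1] * vm
    limit_count = hi / vv  # union volume cap, in voxels

    comp_lab = np.zeros(v.shape, dtype=np.int32)
    comp_sizes: dict[int, int] = {}
    contributions: dict[int, set] = {}
    next_label = 1
    shape = np.asarray(v.shape)

    for n in cfg.st_numerators:
        st = (n / 4.0) * r_t
        mask = (v.data >= st) & (v.data >= noise_threshold)
        lab, k = ndi.label(mask, structure=_STRUCT26)
        if k == 0:
            continue
        counts = np.bincount(lab.ravel())[1:]
        vols = counts * vv
        kept_ids = np.flatnonzero((vols > lo) & (vols < hi)) + 1
        if kept_ids.size == 0:
            continue
        for cand in _sets_from_labels(lab, k, v, provenance=(n,), only=kept_ids):
            ijk = cand.voxels
            # composite labels overlapping or 26-adjacent to this set
            pad_lo = np.maximum(ijk.min(axis=0) - 1, 0)
            pad_hi = np.minimum(ijk.max(axis=0) + 1, shape - 1)
            sl = tuple(slice(a, b + 1) for a, b in zip(pad_lo, pad_hi))
            sub = np.zeros(pad_hi - pad_lo + 1, dtype=bool)
            rel = ijk - pad_lo
            sub[rel[:, 0], rel[:, 1], rel[:, 2]] = True
            dil = ndi.binary_dilation(sub, structure=_STRUCT26)
            neighbors = np.unique(comp_lab[sl][dil])
            neighbors = neighbors[neighbors > 0]

            in_comp = comp_lab[ijk[:, 0], ijk[:, 1], ijk[:, 2]] > 0
            new_count = int((~in_comp).sum())
            union_count = new_count + sum(comp_sizes[int(nb)] for nb in neighbors)
            if union_count > limit_count + _EPS:
                continue  # growth rejected: keep the composite as it was
            if neighbors.size:
                target = int(neighbors[0])
                if neighbors.size > 1:
                    merge_mask = np.isin(comp_lab, neighbors[1:])
                    comp_lab[merge_mask] = target
                    for nb in neighbors[1:]:
                        contributions.setdefault(target, set()).update(
                            contributions.pop(int(nb), set())
                        )
                        comp_sizes.pop(int(nb), None)
            else:
                target = next_label
                next_label += 1
            comp_lab[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = target
            comp_sizes[target] = union_count
            contributions.setdefault(target, set()).add(n)

    if not comp_sizes:
        raise SegmentationError(
            "iterative_signal_size",
            "no candidates: composite mask empty after all signal thresholds",
        )
    # final connected sets of the composite mask (original intensities)
    lab, k = ndi.label(comp_lab > 0, structure=_STRUCT26)
    sets = _sets_from_labels(lab, k, v)
    for s in sets:
        ids = np.unique(comp_lab[s.voxels[:, 0], s.voxels[:, 1], s.voxels[:, 2]])
        prov: set = set()
        for i in ids:
            prov |= contributions.get(int(i), set())
        s.provenance = tuple(sorted(prov, reverse=True))
    return sets


# ---------------------------------------------------------------------------
# Step 4: shape discrimination


def shape_filter(sets: Sequence[CandidateSet], cfg: SegmentationConfig) -> list[CandidateSet]:
    """Retain candidates whose extent along every logical axis does not
    exceed ``shape_max_mm`` (26.9 mm for the default marker)."""
    return [s for s in sets if (s.extents_mm <= cfg.shape_max_mm + _EPS).all()]


# ---------------------------------------------------------------------------
# Step 5: inter-marker distance discrimination


def _assign_labels(points: np.ndarray, t: DeviceTemplate) -> tuple[dict, np.ndarray, float]:
    """Label the four matched points A..D by their distance signature.

    Tries all 24 permutations and keeps the one minimizing the RMS error of
    the labeled pairwise distances against the template separations (the
    six separations are distinct for the default geometry, so the optimum
    is unique up to numerical noise).
    """
    ref = t.separations
    pair_idx = list(combinations(range(4), 2))
    best_perm, best_rms = None, np.inf
    for perm in permutations(range(4)):
        p = points[list(perm)]
        d = np.array([np.linalg.norm(p[i] - p[j]) for i, j in pair_idx])
        rms = float(np.sqrt(((d - ref) ** 2).mean()))
        if rms < best_rms - 1e-12:
            best_rms, best_perm = rms, perm
    order = np.asarray(best_perm)
    coms = {lab: points[order[i]] for i, lab in enumerate(LABELS)}
    return coms, order, best_rms


def match_device(
    sets: Sequence[CandidateSet], t: DeviceTemplate, cfg: SegmentationConfig
) -> DeviceDetection:
    """Find four candidates whose COMs reproduce the template separations.

    For tolerance tau = ``match_tol_start``, increasing by
    ``match_tol_step`` up to ``match_tol_max``: a 4-subset matches if its
    six sorted pairwise distances each differ from the template's sorted
    six by at most tau.  Among matches at the smallest feasible tau, the
    subset minimizing the RMS of the sorted-distance errors wins.
    """
    if len(sets) < 4:
        raise SegmentationError(
            "match_device", f"device not found: only {len(sets)} candidates (need 4)"
        )
    coms = np.array([s.com_world for s in sets])
    ref_sorted = template_distances(t)

    # Cheap prefilter: a true marker has >= 3 other candidates within the
    # largest template separation + the maximum tolerance.  Never removes a
    # member of a matchable subset.
    reach = ref_sorted[0] + cfg.match_tol_max + _EPS
    dist = squareform(pdist(coms))
    active = np.flatnonzero((dist <= reach).sum(axis=1) - 1 >= 3)
    if active.size < 4:
        raise SegmentationError(
            "match_device",
            "device not found: fewer than 4 mutually reachable candidates",
        )

    combs = np.array(list(combinations(active.tolist(), 4)))
    pair_idx = list(combinations(range(4), 2))
    six = np.stack([dist[combs[:, i], combs[:, j]] for i, j in pair_idx], axis=1)
    six_sorted = np.sort(six, axis=1)[:, ::-1]
    dev = np.abs(six_sorted - ref_sorted)
    max_dev = dev.max(axis=1)
    rms_dev = np.sqrt((dev**2).mean(axis=1))

    tau = cfg.match_tol_start
    while tau <= cfg.match_tol_max + _EPS:
        hits = np.flatnonzero(max_dev <= tau + _EPS)
        if hits.size:
            best = hits[np.argmin(rms_dev[hits])]
            subset = combs[best]
            marker_coms, order, label_rms = _assign_labels(coms[subset], t)
            com, normal, theta, phi, degen = device_pose(marker_coms)
            fit = rigid_fit(t, marker_coms)
            det = DeviceDetection(
                marker_coms=marker_coms,
                device_com=com,
                normal=normal,
                theta=theta,
                phi=phi,
                match_tolerance=float(tau),
                rigid=fit,
                phi_degenerate=degen,
            )
            det.diagnostics.update(
                n_candidates=len(sets),
                matched_set_indices=[int(subset[i]) for i in order],
                sorted_distance_rms_mm=float(rms_dev[best]),
                labeled_distance_rms_mm=float(label_rms),
                boundary_flags=[bool(sets[int(i)].touches_boundary) for i in subset[order]],
            )
            return det
        tau += cfg.match_tol_step
    raise SegmentationError(
        "match_device",
        f"device not found at tolerance <= {cfg.match_tol_max:g} mm "
        f"(best sorted-distance RMS over {len(combs)} subsets: {rms_dev.min():.2f} mm)",
    )


# ---------------------------------------------------------------------------
# Full pipeline


def segment_fiducial(
    v: Volume3D,
    t: DeviceTemplate,
    cfg: SegmentationConfig | None = None,
    keep_voxels: bool = False,
) -> DeviceDetection:
    """Run the five detection stages in order and return the device pose.

    Diagnostics recorded on the result: ``N_T``, ``R_T``, candidate counts
    per stage and the matching tolerance used.  With ``keep_voxels=True``
    the matched markers' voxel index arrays are attached (for mask export).
    Stage failures raise :class:`SegmentationError` naming the stage.
    """
    if cfg is None:
        cfg = SegmentationConfig.from_template(t)
    n_t = compute_noise_threshold(v, smooth=cfg.smooth_histogram)
    base_sets = connected_sets(v, n_t)
    r_t = reference_threshold(base_sets, cfg)
    candidates = iterative_signal_size(v, r_t, cfg, noise_threshold=n_t)
    shaped = shape_filter(candidates, cfg)
    det = match_device(shaped, t, cfg)
    det.diagnostics.update(
        noise_threshold=int(n_t),
        reference_threshold=float(r_t),
        n_sets_noise_level=len(base_sets),
        n_candidates_composite=len(candidates),
        n_candidates_shape=len(shaped),
    )
    if keep_voxels:
        idx = det.diagnostics["matched_set_indices"]
        det.diagnostics["marker_voxels"] = {
            lab: shaped[i].voxels for lab, i in zip(LABELS, idx)
        }
    return det


def detection_mask(det: DeviceDetection, v: Volume3D) -> np.ndarray:
    """Labeled mask (1..4 = A..D) from a detection run with
    ``keep_voxels=True``."""
    if "marker_voxels" not in det.diagnostics:
        raise ValueError("detection was not run with keep_voxels=True")
    out = np.zeros(v.shape, dtype=np.int32)
    for value, lab in enumerate(LABELS, start=1):
        ijk = det.diagnostics["marker_voxels"][lab]
        out[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = value
    return out
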