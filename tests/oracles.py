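"""Independent reference implementations used as test oracles.

These are deliberately naive (pure-Python loops, exhaustive enumeration)
and share no code with the package internals they check.
"""

from __future__ import annotations

from itertools import combinations, permutations, product

import numpy as np


def bfs_label_26(mask: np.ndarray) -> np.ndarray:
    """Connected-component labeling under 26-connectivity by flood fill."""
    mask = np.asarray(mask, bool)
    labels = np.zeros(mask.shape, dtype=int)
    offsets = [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]
    nxt = 1
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        stack = [start]
        labels[start] = nxt
        while stack:
            i, j, k = stack.pop()
            for di, dj, dk in offsets:
                p = (i + di, j + dj, k + dk)
                if (
                    0 <= p[0] < mask.shape[0]
                    and 0 <= p[1] < mask.shape[1]
                    and 0 <= p[2] < mask.shape[2]
                    and mask[p]
                    and not labels[p]
                ):
                    labels[p] = nxt
                    stack.append(p)
        nxt += 1
    return labels


def noise_threshold_scan(counts) -> int | None:
    """Exhaustive scan for the histogram noise threshold.

    Background peak: the largest bin over the lower half of the occupied
    intensity range, ignoring bin 0.  Threshold: the smallest intensity
    above the peak whose forward difference h(I+1)-h(I) is >= 0.  Returns
    None when no such intensity exists.
    """
    h = list(counts)
    occupied = [i for i, c in enumerate(h) if c > 0]
    lo, hi = occupied[0], occupied[-1]
    half = lo + (hi - lo) // 2
    peak, peak_count = None, 0
    for i in range(1, half + 1):
        if i < len(h) and h[i] > peak_count:
            peak, peak_count = i, h[i]
    if peak is None:
        return None
    for i in range(peak + 1, len(h) - 1):
        if h[i + 1] - h[i] >= 0:
            return i
    return None


def brute_force_match(coms: np.ndarray, template_points: np.ndarray, tau: float):
    """All 4-subsets whose sorted pairwise distances match the template's
    within tau, with the RMS of the sorted-distance errors."""
    ref = sorted(
        (np.linalg.norm(template_points[i] - template_points[j]) for i, j in combinations(range(4), 2)),
        reverse=True,
    )
    hits = []
    for subset in combinations(range(len(coms)), 4):
        d = sorted(
            (np.linalg.norm(coms[i] - coms[j]) for i, j in combinations(subset, 2)),
            reverse=True,
        )
        devs = [abs(x - y) for x, y in zip(d, ref)]
        if max(devs) <= tau + 1e-9:
            rms = float(np.sqrt(np.mean(np.square(devs))))
            hits.append((subset, rms))
    return hits


def best_label_assignment(points: np.ndarray, template_points: np.ndarray):
    """Exhaustive labeling of 4 matched points against the template."""
    pair_idx = list(combinations(range(4), 2))
    ref = np.array([np.linalg.norm(template_points[i] - template_points[j]) for i, j in pair_idx])
    best, best_rms = None, np.inf
    for perm in permutations(range(4)):
        p = points[list(perm)]
        d = np.array([np.linalg.norm(p[i] - p[j]) for i, j in pair_idx])
        rms = float(np.sqrt(((d - ref) ** 2).mean()))
        if rms < best_rms:
            best, best_rms = perm, rms
    return best, best_rms


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a random quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_grid_rigid_rms(src: np.ndarray, tgt: np.ndarray, n: int = 20000, seed: int = 0) -> float:
    """Brute-force rigid-fit RMS: random quaternion search followed by an
    annealed local quaternion walk (translation solved in closed form per
    rotation via the centroids).  Derivative-free and SVD-free."""
    rng = np.random.default_rng(seed)
    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)

    def quat_to_rot(q):
        w, x, y, z = q / np.linalg.norm(q)
        return np.array(
            [
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
            ]
        )

    def rms_of(q):
        resid = src_c @ quat_to_rot(q).T - tgt_c
        return float(np.sqrt((resid**2).sum(axis=1).mean()))

    best_q, best = None, np.inf
    for _ in range(n):
        q = rng.standard_normal(4)
        r = rms_of(q)
        if r < best:
            best, best_q = r, q / np.linalg.norm(q)
    scale = 0.1
    while scale > 1e-7:
        improved = False
        for _ in range(200):
            q = best_q + scale * rng.standard_normal(4)
            r = rms_of(q)
            if r < best:
                best, best_q = r, q / np.linalg.norm(q)
                improved = True
        if not improved:
            scale *= 0.5
    return float(best)
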