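"""Per-plane maxima detection, z-linking and iterative feature filtering.

Candidate spots are strict local intensity maxima found independently in
every z-plane, capped at a per-plane budget proportional to the slice
area.  Candidates without a neighboring maximum in an adjacent plane are
discarded; the survivors form z-groups, filtered down to a volume-based
feature budget by thresholding the brightness margins Babs-Bback and
Bperi-Bback.  Each surviving group contributes its brightest member to
the round's feature point cloud.

Brightness attributes per candidate:

* ``Babs``  — absolute brightness (the pixel value at the maximum);
* ``Bback`` — local background, the median of an annulus around it;
* ``Bperi`` — periphery brightness, the mean of the 8-neighbor ring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "DetectionParams",
    "maxima_target",
    "feature_target",
    "detect_plane_maxima",
    "link_z_groups",
    "iterative_feature_filter",
    "detect_features",
]

CANDIDATE_COLUMNS = ["x", "y", "z", "Babs", "Bback", "Bperi"]
FEATURE_COLUMNS = CANDIDATE_COLUMNS + ["zgroup_id"]


@dataclass(frozen=True)
class DetectionParams:
    """Knobs for the detection stage.

    ``maxima_area_factor`` converts slice area (µm²) into the per-plane
    candidate budget; ``feature_volume_factor`` converts stack volume
    (µm³) into the final feature budget.  ``bback_annulus`` is the
    (inner, outer) Euclidean radius of the local-background annulus.
    """

    maxima_area_factor: float = 0.5
    feature_volume_factor: float = 0.5
    local_max_radius_px: int = 2
    link_radius_px: float = 2.0
    max_iterations: int = 30
    init_margin_threshold: float = 0.0
    bback_annulus: tuple[int, int] = (3, 5)

    def __post_init__(self) -> None:
        if self.maxima_area_factor < 0 or self.feature_volume_factor < 0:
            raise ValueError("factors must be >= 0")
        if self.local_max_radius_px < 1:
            raise ValueError("local_max_radius_px must be >= 1")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def maxima_target(area_um2: float, factor: float = 0.5) -> int:
    """Per-plane candidate budget: floor(slice area in µm² × factor)."""
    if area_um2 < 0:
        raise ValueError("area must be >= 0")
    return int(math.floor(area_um2 * factor))


def feature_target(volume_um3: float, factor: float = 0.5) -> int:
    """Per-stack feature budget: floor(volume in µm³ × factor)."""
    if volume_um3 < 0:
        raise ValueError("volume must be >= 0")
    return int(math.floor(volume_um3 * factor))


def _annulus_offsets(inner: int, outer: int) -> np.ndarray:
    dy, dx = np.mgrid[-outer : outer + 1, -outer : outer + 1]
    r = np.hypot(dx, dy)
    mask = (r >= inner) & (r <= outer)
    return np.column_stack([dy[mask], dx[mask]])


_PERI_OFFSETS = np.array(
    [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
)


def _neighborhood_stat(plane, ys, xs, offsets, stat):
    """Apply stat over clipped neighborhood values for each (y, x)."""
    ny, nx = plane.shape
    out = np.empty(len(ys))
    for k, (y, x) in enumerate(zip(ys, xs)):
        yy = np.clip(y + offsets[:, 0], 0, ny - 1)
        xx = np.clip(x + offsets[:, 1], 0, nx - 1)
        out[k] = stat(plane[yy, xx])
    return out


def detect_plane_maxima(
    plane: np.ndarray,
    target: int,
    params: DetectionParams = DetectionParams(),
    z: int = 0,
) -> pd.DataFrame:
    """Strict local maxima of a single z-plane, brightest first.

    A pixel qualifies when it is strictly greater than every other pixel
    within a square window of half-width ``local_max_radius_px``.  At
    most *target* candidates are returned, ordered by Babs descending
    with (y, x) lexicographic tie-breaks.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise ValueError("plane must be 2D")
    empty = pd.DataFrame(columns=CANDIDATE_COLUMNS)
    if plane.size == 0 or target <= 0:
        return empty

    r = params.local_max_radius_px
    size = 2 * r + 1
    footprint = np.ones((size, size), dtype=bool)
    footprint[r, r] = False
    neighbor_max = ndimage.maximum_filter(plane, footprint=footprint, mode="constant", cval=-np.inf)
    ys, xs = np.nonzero(plane > neighbor_max)
    if len(ys) == 0:
        return empty

    vals = plane[ys, xs]
    # brightest first; ties resolved by (y, x) for determinism
    order = np.lexsort((xs, ys, -vals))[:target]
    ys, xs, vals = ys[order], xs[order], vals[order]

    ann = _annulus_offsets(*params.bback_annulus)
    bback = _neighborhood_stat(plane, ys, xs, ann, np.median)
    bperi = _neighborhood_stat(plane, ys, xs, _PERI_OFFSETS, np.mean)

    # refine to sub-pixel by intensity-weighted centroid above local
    # background; integer-pixel maxima would quantize the feature cloud
    # and dominate the registration error budget
    ny, nx = plane.shape
    xf = xs.astype(float)
    yf = ys.astype(float)
    for k, (y0, x0) in enumerate(zip(ys, xs)):
        ylo, yhi = max(0, y0 - 2), min(ny, y0 + 3)
        xlo, xhi = max(0, x0 - 2), min(nx, x0 + 3)
        w = np.clip(plane[ylo:yhi, xlo:xhi] - bback[k], 0, None)
        total = w.sum()
        if total > 0:
            gy, gx = np.mgrid[ylo:yhi, xlo:xhi]
            yf[k] = (w * gy).sum() / total
            xf[k] = (w * gx).sum() / total
    return pd.DataFrame(
        {"x": xf, "y": yf, "z": z, "Babs": vals, "Bback": bback, "Bperi": bperi}
    )


def link_z_groups(
    candidates: pd.DataFrame, link_radius_px: float = 2.0
) -> pd.DataFrame:
    """Link maxima across adjacent planes into z-groups.

    Two candidates are neighbors when they sit on adjacent planes
    (|Δz| = 1) within ``link_radius_px`` in xy; groups are the
    transitive closure of that relation.  Singletons — maxima with no
    adjacent-plane neighbor — are removed.
    """
    if len(candidates) == 0:
        return candidates.assign(zgroup_id=pd.Series(dtype=int))
    df = candidates.reset_index(drop=True)
    n = len(df)
    parent = np.arange(n)

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    from scipy.spatial import cKDTree

    by_plane = {int(z): g for z, g in df.groupby("z")}
    for z, g in by_plane.items():
        nxt = by_plane.get(z + 1)
        if nxt is None:
            continue
        tree = cKDTree(nxt[["x", "y"]].to_numpy(dtype=float))
        pairs = tree.query_ball_point(g[["x", "y"]].to_numpy(dtype=float), link_radius_px)
        for local_i, hits in zip(g.index, pairs):
            for local_j in hits:
                union(int(local_i), int(nxt.index[local_j]))

    roots = np.array([find(i) for i in range(n)])
    _, sizes = np.unique(roots, return_counts=True)
    size_of = dict(zip(*np.unique(roots, return_counts=True)))
    keep = np.array([size_of[r] >= 2 for r in roots])
    out = df[keep].copy()
    # compact group ids in first-appearance order
    kept_roots = roots[keep]
    remap = {r: i for i, r in enumerate(pd.unique(kept_roots))}
    out["zgroup_id"] = [remap[r] for r in kept_roots]
    return out.reset_index(drop=True)


def _surviving_groups(df: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Apply the margin threshold; keep groups with >= 2 surviving members."""
    m = np.minimum(df.Babs - df.Bback, df.Bperi - df.Bback)
    kept = df[m >= threshold]
    sizes = kept.groupby("zgroup_id")["x"].transform("size")
    return kept[sizes >= 2]


def iterative_feature_filter(
    groups: pd.DataFrame,
    volume_um3: float,
    params: DetectionParams = DetectionParams(),
) -> pd.DataFrame:
    """Filter z-groups to the volume-based feature budget.

    A single threshold scalar is applied to both margins
    (Babs - Bback and Bperi - Bback); it is tuned by bisection until the
    number of surviving groups is at most ``feature_target(volume)``,
    since survival count is monotone non-increasing in the threshold.
    Only groups keeping >= 2 members survive, and each contributes one
    feature: its brightest member.

    The returned frame carries ``attrs['threshold']`` and
    ``attrs['converged']``; ``converged`` is False when the iteration
    budget ran out before the count dropped under target (best effort).
    """
    target = feature_target(volume_um3, params.feature_volume_factor)
    empty = pd.DataFrame(columns=FEATURE_COLUMNS)
    if len(groups) == 0 or target == 0:
        empty.attrs.update(threshold=params.init_margin_threshold, converged=True)
        return empty

    t = params.init_margin_threshold
    surv = _surviving_groups(groups, t)
    converged = True
    if surv.zgroup_id.nunique() > target:
        margins = np.minimum(groups.Babs - groups.Bback, groups.Bperi - groups.Bback)
        lo, hi = t, float(margins.max()) + 1.0  # count(hi) == 0 <= target
        converged = False
        for _ in range(params.max_iterations):
            mid = 0.5 * (lo + hi)
            n_mid = _surviving_groups(groups, mid).zgroup_id.nunique()
            if n_mid > target:
                lo = mid
            else:
                hi = mid
                converged = True
        t = hi
        surv = _surviving_groups(groups, t)

    # brightest member per group; (z, y, x) lexicographic tie-break
    surv = surv.sort_values(["Babs", "z", "y", "x"], ascending=[False, True, True, True])
    features = surv.groupby("zgroup_id", as_index=False).first()[FEATURE_COLUMNS]
    # sub-plane z: margin-weighted mean of the group's member planes
    w = np.clip(surv.Babs - surv.Bback, 0, None)
    zw = (
        pd.DataFrame({"zgroup_id": surv.zgroup_id, "wz": w * surv.z, "w": w})
        .groupby("zgroup_id")
        .sum()
    )
    refined = (zw.wz / zw.w).where(zw.w > 0)
    features = features.set_index("zgroup_id")
    features["z"] = refined.combine_first(features["z"])
    features = features.reset_index()[FEATURE_COLUMNS + []]
    features = features.sort_values("zgroup_id").reset_index(drop=True)[FEATURE_COLUMNS]
    features.attrs.update(threshold=t, converged=converged)
    return features


def detect_features(
    stack: np.ndarray,
    pixel_size_um: float,
    z_step_um: float = 0.4,
    params: DetectionParams = DetectionParams(),
) -> pd.DataFrame:
    """Full detection chain for one image stack: planes -> cloud.

    Runs per-plane maxima detection with the area-based budget, links
    z-groups, and applies the iterative volume-based filter.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be 3D [z, y, x]")
    nz, ny, nx = stack.shape
    area = ny * nx * pixel_size_um**2
    plane_target = maxima_target(area, params.maxima_area_factor)
    per_plane = [
        detect_plane_maxima(stack[z], plane_target, params, z=z) for z in range(nz)
    ]
    per_plane = [p for p in per_plane if len(p)]
    candidates = pd.concat(per_plane, ignore_index=True) if per_plane else pd.DataFrame(
        columns=CANDIDATE_COLUMNS
    )
    grouped = link_z_groups(candidates, params.link_radius_px)
    volume = area * nz * z_step_um
    return iterative_feature_filter(grouped, volume, params)
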