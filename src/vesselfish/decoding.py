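"""Pixel-profile decoding of registered multi-round stacks.

Every voxel gets a profile of ``n_rounds × n_channels`` intensities
(round-major, channel-minor slot order; 16 values for the default
two-color eight-round layout).  Profiles concentrated on few slots are
matched against the codebook by cosine similarity; same-gene voxels are
grouped by 6-connectivity, filtered, localized to a single 3D position,
validated against raw-image maxima, and emitted as transcripts.  Hits
on deliberately unassigned codes estimate decoding specificity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .codebook import Codebook

__all__ = [
    "build_profiles",
    "profile_score",
    "score_and_filter_profiles",
    "assign_codes",
    "PixelGroup",
    "group_and_filter_pixels",
    "localize_and_validate",
    "SpecificityReport",
    "estimate_specificity",
    "decode_stacks",
]

TRANSCRIPT_COLUMNS = ["x", "y", "z", "gene", "code_score", "group_size"]


def build_profiles(stacks: dict[tuple[int, int], np.ndarray]) -> np.ndarray:
    """Stack per-(round, channel) images into per-voxel profiles.

    Returns an array of shape ``(nz, ny, nx, n_slots)`` with slots in
    round-major, channel-minor order.  All stacks must share one shape.
    """
    if not stacks:
        raise ValueError("no stacks given")
    keys = sorted(stacks)  # (round, channel) lexicographic == round-major
    shapes = {stacks[k].shape for k in keys}
    if len(shapes) > 1:
        raise ValueError(f"stack shapes differ: {sorted(shapes)}")
    return np.stack([np.asarray(stacks[k], dtype=np.float32) for k in keys], axis=-1)


def profile_score(profiles: np.ndarray) -> np.ndarray:
    """Concentration score s = n·Σv² / (Σv)², in [1, n]; 0 for empty profiles.

    A uniform profile scores 1, a one-hot profile scores n: the score is
    the profile's variance from zero normalized by total brightness,
    invariant to intensity scaling.
    """
    v = np.asarray(profiles, dtype=float)
    n = v.shape[-1]
    total = v.sum(axis=-1)
    sq = (v**2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = n * sq / total**2
    return np.where(total > 0, s, 0.0)


def score_and_filter_profiles(profiles: np.ndarray, min_score: float = 2.0) -> np.ndarray:
    """Retain profiles whose concentration score reaches ``min_score``."""
    if min_score < 1:
        raise ValueError("min_score must be >= 1")
    v = np.atleast_2d(np.asarray(profiles, dtype=float))
    s = profile_score(v)
    return v[s >= min_score]


def assign_codes(
    profiles: np.ndarray,
    codebook: Codebook,
    min_match: float = 0.7,
    include_unused: bool = True,
) -> np.ndarray:
    """Per-profile code assignment by cosine similarity.

    Returns an integer array (profiles' leading shape) indexing into
    the codebook's used codes followed by its unused codes, or -1 where
    no code reaches ``min_match`` or the best match is tied.
    """
    codes = codebook.all_codes() if include_unused else codebook.codes
    if codes.shape[0] == 0:
        raise ValueError("empty codebook")
    v = np.asarray(profiles, dtype=float)
    lead = v.shape[:-1]
    flat = v.reshape(-1, v.shape[-1])

    code_norm = codes / np.linalg.norm(codes, axis=1, keepdims=True)
    vnorm = np.linalg.norm(flat, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        sims = (flat @ code_norm.T) / vnorm[:, None]
    sims = np.nan_to_num(sims, nan=-1.0)

    best = np.argmax(sims, axis=1)
    best_sim = sims[np.arange(len(flat)), best]
    sims[np.arange(len(flat)), best] = -np.inf
    runner_up = sims.max(axis=1)
    assigned = np.where(
        (best_sim >= min_match) & (best_sim > runner_up + 1e-12), best, -1
    )
    return assigned.reshape(lead)


@dataclass
class PixelGroup:
    """A 6-connected component of same-code voxels."""

    code_index: int
    voxels: np.ndarray  # (n, 3) int array of (z, y, x)

    @property
    def size(self) -> int:
        return len(self.voxels)


_STRUCT6 = ndimage.generate_binary_structure(3, 1)  # faces only


def group_and_filter_pixels(
    assignment: np.ndarray,
    min_size: int = 2,
    min_extent_axes: int = 2,
) -> list[PixelGroup]:
    """Group same-code voxels by 6-connectivity and filter the groups.

    Retained groups have at least ``min_size`` voxels, every voxel
    keeps a direct (face-adjacent) same-group neighbor — automatic for
    6-connected components of size >= 2 — and the bounding box spans
    >= 2 voxels along at least ``min_extent_axes`` of the three axes.
    """
    assignment = np.asarray(assignment)
    if assignment.ndim != 3:
        raise ValueError("assignment map must be 3D [z, y, x]")
    groups: list[PixelGroup] = []
    for code_idx in np.unique(assignment):
        if code_idx < 0:
            continue
        labels, n = ndimage.label(assignment == code_idx, structure=_STRUCT6)
        for obj_idx, sl in enumerate(ndimage.find_objects(labels), start=1):
            voxels = np.argwhere(labels[sl] == obj_idx) + [s.start for s in sl]
            if len(voxels) < min_size:
                continue
            extents = voxels.max(axis=0) - voxels.min(axis=0) + 1
            if (extents >= 2).sum() < min_extent_axes:
                continue
            groups.append(PixelGroup(int(code_idx), voxels))
    return groups


def _local_max_map(stack: np.ndarray) -> np.ndarray:
    """Boolean map of strict 26-neighborhood local maxima.

    Strictness matters: flat background is a plateau, and plateau
    voxels must not validate decoded groups as real spots.
    """
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    # -inf padding: an edge-plane voxel must only beat its real
    # neighbors, while replicated padding would make it beat itself
    mx = ndimage.maximum_filter(stack, footprint=footprint, mode="constant", cval=-np.inf)
    return stack > mx


def localize_and_validate(
    groups: list[PixelGroup],
    stacks: dict[tuple[int, int], np.ndarray],
    codebook: Codebook,
    k_required: int | None = None,
    search_radius_px: int = 2,
) -> pd.DataFrame:
    """Turn retained pixel groups into a transcript table.

    Each group's transcript position is the member voxel with maximal
    summed on-bit intensity.  The transcript is kept only when an
    intensity local maximum lies within ``search_radius_px`` (in xy,
    ±1 plane in z) of that position in at least ``k_required`` of the
    code's on-bit images (default: code weight − 1).  The code score is
    the cosine match between the voxel's profile and the binary code.
    Groups assigned to unused codes are never emitted as transcripts.
    """
    if k_required is None:
        k_required = max(1, codebook.code_weight - 1)
    keys = sorted(stacks)
    profile_stack = build_profiles(stacks)
    all_codes = codebook.all_codes()
    n_used = len(codebook.genes)
    maxmaps = {k: _local_max_map(np.asarray(stacks[k], dtype=float)) for k in keys}
    nz, ny, nx = profile_stack.shape[:3]

    rows = []
    for g in groups:
        code = all_codes[g.code_index]
        on_slots = np.flatnonzero(code)
        zz, yy, xx = g.voxels.T
        summed = profile_stack[zz, yy, xx][:, on_slots].sum(axis=1)
        best = int(np.argmax(summed))
        z, y, x = (int(v) for v in g.voxels[best])

        n_confirmed = 0
        for slot in on_slots:
            m = maxmaps[keys[slot]]
            z0, z1 = max(0, z - 1), min(nz, z + 2)
            y0, y1 = max(0, y - search_radius_px), min(ny, y + search_radius_px + 1)
            x0, x1 = max(0, x - search_radius_px), min(nx, x + search_radius_px + 1)
            if m[z0:z1, y0:y1, x0:x1].any():
                n_confirmed += 1
        if n_confirmed < k_required:
            continue

        prof = profile_stack[z, y, x].astype(float)
        denom = np.linalg.norm(prof) * np.linalg.norm(code)
        score = float(prof @ code / denom) if denom > 0 else 0.0
        if g.code_index < n_used:
            rows.append((x, y, z, codebook.genes[g.code_index], score, g.size))
    return pd.DataFrame(rows, columns=TRANSCRIPT_COLUMNS)


@dataclass
class SpecificityReport:
    """Decoding false-positive estimate from unused-code hits.

    ``ratio`` is the per-code-normalized rate of unused-code hits
    relative to used-code hits: (unused/n_unused) / (used/n_used).
    """

    used_hits: int
    unused_hits: int
    n_used_codes: int
    n_unused_codes: int
    ratio: float
    defined: bool

    def to_dict(self) -> dict:
        return {
            "used_hits": self.used_hits,
            "unused_hits": self.unused_hits,
            "n_used_codes": self.n_used_codes,
            "n_unused_codes": self.n_unused_codes,
            "false_positive_ratio": self.ratio,
            "defined": self.defined,
        }


def estimate_specificity(code_hits: np.ndarray, codebook: Codebook) -> SpecificityReport:
    """Specificity from per-code hit counts (used codes first, then unused)."""
    n_used = len(codebook.genes)
    n_unused = len(codebook.unused_codes)
    if n_unused == 0:
        raise ValueError("codebook has no unused codes; specificity undefined")
    code_hits = np.asarray(code_hits)
    if len(code_hits) != n_used + n_unused:
        raise ValueError("hit counts must cover every code, used then unused")
    used_hits = int(code_hits[:n_used].sum())
    unused_hits = int(code_hits[n_used:].sum())
    if used_hits == 0:
        return SpecificityReport(0, unused_hits, n_used, n_unused, float("nan"), False)
    ratio = (unused_hits / n_unused) / (used_hits / n_used)
    return SpecificityReport(used_hits, unused_hits, n_used, n_unused, ratio, True)


def decode_stacks(
    stacks: dict[tuple[int, int], np.ndarray],
    codebook: Codebook,
    min_score: float = 2.0,
    min_match: float = 0.7,
    k_required: int | None = None,
) -> tuple[pd.DataFrame, SpecificityReport | None]:
    """Full decoding chain on registered stacks.

    Returns the transcript table and a specificity report (None when
    the codebook reserves no unused codes).
    """
    profiles = build_profiles(stacks)
    scores = profile_score(profiles)
    assignment = assign_codes(profiles, codebook, min_match=min_match)
    assignment[scores < min_score] = -1
    groups = group_and_filter_pixels(assignment)
    transcripts = localize_and_validate(groups, stacks, codebook, k_required=k_required)

    report = None
    if len(codebook.unused_codes) > 0:
        hits = np.zeros(len(codebook.genes) + len(codebook.unused_codes), dtype=int)
        for g in groups:
            hits[g.code_index] += 1
        report = estimate_specificity(hits, codebook)
    return transcripts, report
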