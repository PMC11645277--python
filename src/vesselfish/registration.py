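"""Rigid round-to-round registration.

Feature point clouds from each imaging round are aligned to the round-1
cloud with iterative closest point (ICP): mutual-nearest-neighbor
correspondences alternate with a closed-form orthogonal Procrustes
(Kabsch) update.  The estimated rigid transform is then applied to the
image stacks by tri-linear resampling.

Points are (x, y, z) row vectors in pixel units; stacks are arrays
indexed ``[z, y, x]``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "RigidTransform3D",
    "IcpResult",
    "icp_register",
    "multistart_icp",
    "transform_points",
    "resample_stack",
]


@dataclass
class RigidTransform3D:
    """Proper rigid transform: p -> rotation @ p + translation."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        R = self.rotation
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (improper rotation)")

    @classmethod
    def identity(cls) -> "RigidTransform3D":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_z_rotation(cls, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform3D":
        a = np.deg2rad(angle_deg)
        R = np.array(
            [
                [np.cos(a), -np.sin(a), 0.0],
                [np.sin(a), np.cos(a), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform3D":
        return RigidTransform3D(self.rotation.T, -self.rotation.T @ self.translation)

    def compose(self, other: "RigidTransform3D") -> "RigidTransform3D":
        """self ∘ other: apply *other* first, then *self*."""
        return RigidTransform3D(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def to_dict(self) -> dict:
        return {"rotation": self.rotation.tolist(), "translation": self.translation.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform3D":
        return cls(np.array(d["rotation"]), np.array(d["translation"]))

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load_json(cls, path) -> "RigidTransform3D":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class IcpResult:
    transform: RigidTransform3D
    rms: float
    rms_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False


def transform_points(points: np.ndarray, transform: RigidTransform3D) -> np.ndarray:
    """Map an (N, 3) point array through a rigid transform."""
    return transform.apply(points)


def _procrustes(moving: np.ndarray, reference: np.ndarray) -> RigidTransform3D:
    """Least-squares rigid transform mapping paired moving -> reference (Kabsch)."""
    mu_m = moving.mean(axis=0)
    mu_r = reference.mean(axis=0)
    H = (moving - mu_m).T @ (reference - mu_r)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    return RigidTransform3D(R, t)


def _mutual_nn(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices (ia, ib) of mutual nearest neighbors between point sets."""
    tree_b = cKDTree(b)
    tree_a = cKDTree(a)
    _, a_to_b = tree_b.query(a)
    _, b_to_a = tree_a.query(b)
    ia = np.arange(len(a))
    mutual = b_to_a[a_to_b] == ia
    return ia[mutual], a_to_b[mutual]


def icp_register(
    moving: np.ndarray,
    reference: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-6,
    trim: float = 0.5,
) -> IcpResult:
    """Align *moving* onto *reference* by trimmed rigid ICP.

    Correspondences are mutual nearest neighbors recomputed each
    iteration; of those pairs only the closest ``trim`` fraction enters
    the closed-form Procrustes update, which makes the fit robust to
    points present in only one cloud (feature clouds of different
    imaging rounds share only the transcripts whose codes are on in
    both rounds).  The iteration trace records the RMS distance over
    the trimmed pairs — the quantity the update minimizes; ``rms`` is
    that residual after the final transform.  Iteration stops when the
    residual changes by less than *tol* pixels, or after *max_iter*
    iterations.  Both clouds need at least three non-collinear points.
    """
    moving = np.atleast_2d(np.asarray(moving, dtype=float))
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    if not (0 < trim <= 1):
        raise ValueError("trim must be in (0, 1]")
    for name, cloud in (("moving", moving), ("reference", reference)):
        if cloud.shape[0] < 3:
            raise ValueError(f"{name} cloud has {cloud.shape[0]} points; need >= 3")
        if np.linalg.matrix_rank(cloud - cloud.mean(axis=0)) < 2:
            raise ValueError(f"{name} cloud is collinear/degenerate")

    T = RigidTransform3D.identity()
    trace: list[float] = []
    prev_rms = np.inf
    converged = False
    it = 0
    rms = np.inf
    for it in range(1, max_iter + 1):
        current = T.apply(moving)
        ia, ib = _mutual_nn(current, reference)
        if len(ia) < 3:
            raise ValueError("fewer than 3 mutual-nearest-neighbor correspondences")
        d = np.linalg.norm(current[ia] - reference[ib], axis=1)
        k = max(3, int(np.ceil(trim * len(d))))
        keep = np.argsort(d, kind="stable")[:k]
        rms = float(np.sqrt(np.mean(d[keep] ** 2)))
        trace.append(rms)
        if abs(prev_rms - rms) < tol:
            converged = True
            break
        prev_rms = rms
        step = _procrustes(current[ia[keep]], reference[ib[keep]])
        T = step.compose(T)

    return IcpResult(T, rms, trace, n_iterations=it, converged=converged)


def multistart_icp(
    moving: np.ndarray,
    reference: np.ndarray,
    trim: float = 0.4,
    step_px: float = 3.0,
    max_shift_px: float = 6.0,
    z_shifts: tuple[float, ...] = (-1.0, 0.0, 1.0),
    max_rotation_deg: float = 10.0,
    max_translation_px: float = 12.0,
    **icp_kwargs,
) -> IcpResult:
    """Trimmed ICP from a grid of initial translations; best residual wins.

    Plain ICP only converges from within about half the typical spot
    spacing; feature clouds of different rounds share few points, so a
    coarse grid of xy starts (± ``max_shift_px`` at ``step_px``) and z
    starts is searched and the run with the lowest trimmed RMS kept.

    Candidate transforms beyond ``max_rotation_deg`` or
    ``max_translation_px`` are rejected: inter-round stage drift is
    small by construction, and on sparse clouds a large spurious
    transform can otherwise match a trimmed handful of points almost
    perfectly.  Raises ``ValueError`` when no start yields a plausible
    transform.
    """
    import itertools

    grid = np.arange(-max_shift_px, max_shift_px + 1e-9, step_px)
    best: IcpResult | None = None
    for dx, dy, dz in itertools.product(grid, grid, z_shifts):
        pre = RigidTransform3D(np.eye(3), (dx, dy, dz))
        try:
            res = icp_register(pre.apply(moving), reference, trim=trim, **icp_kwargs)
        except ValueError:
            continue
        T = res.transform.compose(pre)
        if T.rotation_angle_deg() > max_rotation_deg:
            continue
        if np.linalg.norm(T.translation) > max_translation_px:
            continue
        if best is None or res.rms < best.rms:
            best = IcpResult(T, res.rms, res.rms_trace, res.n_iterations, res.converged)
    if best is None:
        raise ValueError("no ICP start produced a plausible registration")
    return best


def resample_stack(stack: np.ndarray, transform: RigidTransform3D, fill: float = 0.0) -> np.ndarray:
    """Resample a ``[z, y, x]`` stack through a rigid transform.

    Output voxel v takes the tri-linearly interpolated input value at
    ``transform⁻¹(v)``; samples outside the field get *fill*.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be 3D [z, y, x]")
    # transform acts on (x, y, z); array axes are (z, y, x) -> permute.
    P = np.array([[0, 0, 1], [0, 1, 0], [1, 0, 0]], dtype=float)
    inv = transform.inverse()
    M = P @ inv.rotation @ P.T
    off = P @ inv.translation
    # grid-constant: boundary samples interpolate against the fill value
    # instead of being zeroed outright, so a numerically-on-the-edge
    # sample (e.g. under a near-identity transform) keeps its intensity
    return ndimage.affine_transform(
        stack.astype(float), M, offset=off, order=1, mode="grid-constant", cval=fill
    )
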