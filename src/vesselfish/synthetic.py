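"""Synthetic scenes standing in for multiplexed smFISH tissue data.

Three generators cover the pipeline's inputs end to end:

* random point-source transcript scenes rendered into the on-bit
  (round, channel) images of a combinatorial codebook, with optional
  per-round rigid offsets and additive Gaussian background noise;
* vessel cross-sections — annular rings of marker-positive spatial
  bins — with a planted caliber-dependent gene emitted at a higher
  per-bin rate in larger vessels;
* low-plex 2D multi-channel 8-bit images with blobs of known channel
  membership, for the background-removal / co-expression stage.

Everything is deterministic given the seed carried by the scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codebook import Codebook
from .registration import RigidTransform3D

__all__ = [
    "VesselSpec",
    "GroundTruthScene",
    "make_random_scene",
    "make_vessel_scene",
    "render_rounds",
    "make_rnascope_fixture",
]

#: default per-bin Bernoulli rates for the caliber-dependent gene,
#: larger vs smaller vessels
CALIBER_RATE_LARGE = 0.6
CALIBER_RATE_SMALL = 0.2


@dataclass(frozen=True)
class VesselSpec:
    """One planted vessel cross-section (an annulus in a single z-slab)."""

    cx: float
    cy: float
    outer_radius: float
    wall_thickness: float
    vessel_type: str = "artery"

    def __post_init__(self) -> None:
        if self.outer_radius <= 0 or self.wall_thickness <= 0:
            raise ValueError("vessel radius and wall thickness must be positive")
        if self.wall_thickness > self.outer_radius:
            raise ValueError("wall thickness exceeds outer radius")
        if self.vessel_type not in ("artery", "vein"):
            raise ValueError(f"unknown vessel_type {self.vessel_type!r}")


@dataclass
class GroundTruthScene:
    """Planted transcripts plus acquisition parameters.

    ``transcripts`` is a DataFrame with columns x, y, z, gene
    (0-based pixel coordinates; z in plane indices).  ``round_offsets``
    holds one rigid transform per imaging round (round 0 is identity);
    it describes how the sample moved in that round, so a transcript at
    p appears at offset(p) in that round's raw images.
    """

    shape: tuple[int, int, int]  # (nx, ny, nz)
    pixel_size_um: float
    transcripts: pd.DataFrame
    vessels: list[VesselSpec] = field(default_factory=list)
    round_offsets: list[RigidTransform3D] = field(default_factory=list)
    background: float = 10.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny, nz = self.shape
        t = self.transcripts
        if len(t):
            ok = (
                (t.x >= 0).all()
                and (t.x < nx).all()
                and (t.y >= 0).all()
                and (t.y < ny).all()
                and (t.z >= 0).all()
                and (t.z < nz).all()
            )
            if not ok:
                raise ValueError("transcript coordinates outside the field")


def make_random_scene(
    genes: list[str],
    n_transcripts: int,
    shape: tuple[int, int, int] = (192, 192, 10),
    min_separation: float = 6.0,
    margin: int = 8,
    z_margin: int = 2,
    pixel_size_um: float = 0.138,
    background: float = 10.0,
    noise_sd: float = 0.0,
    round_offsets: list[RigidTransform3D] | None = None,
    seed: int = 0,
) -> GroundTruthScene:
    """Scatter transcripts uniformly, enforcing a minimum 3D separation.

    The separation keeps decoded pixel groups of distinct transcripts
    disjoint so that recovery can be scored one-to-one against truth.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    placed: list[tuple[float, float, float]] = []
    attempts = 0
    while len(placed) < n_transcripts:
        attempts += 1
        if attempts > 200 * n_transcripts:
            raise RuntimeError("could not place transcripts at requested separation")
        x = rng.uniform(margin, nx - margin)
        y = rng.uniform(margin, ny - margin)
        z = rng.uniform(z_margin, nz - z_margin)
        if placed:
            d = np.linalg.norm(np.array(placed) - np.array([x, y, z]), axis=1)
            if d.min() < min_separation:
                continue
        placed.append((x, y, z))
    gene_draw = rng.choice(genes, size=n_transcripts)
    df = pd.DataFrame(placed, columns=["x", "y", "z"])
    df["gene"] = gene_draw
    return GroundTruthScene(
        shape=shape,
        pixel_size_um=pixel_size_um,
        transcripts=df,
        round_offsets=list(round_offsets or []),
        background=background,
        noise_sd=noise_sd,
        seed=seed,
    )


def ring_bins(vessel: VesselSpec, pitch: float) -> list[tuple[int, int]]:
    """Pitch-lattice tiles whose centroid falls inside the vessel wall annulus."""
    r_out = vessel.outer_radius
    r_in = r_out - vessel.wall_thickness
    i_lo = int((vessel.cx - r_out) // pitch) - 1
    i_hi = int((vessel.cx + r_out) // pitch) + 1
    j_lo = int((vessel.cy - r_out) // pitch) - 1
    j_hi = int((vessel.cy + r_out) // pitch) + 1
    out = []
    for i in range(i_lo, i_hi + 1):
        for j in range(j_lo, j_hi + 1):
            cx = (i + 0.5) * pitch
            cy = (j + 0.5) * pitch
            d = np.hypot(cx - vessel.cx, cy - vessel.cy)
            if r_in <= d <= r_out:
                out.append((i, j))
    return out


def make_vessel_scene(
    vessels: list[VesselSpec],
    shape: tuple[int, int, int] = (4096, 4096, 1),
    pitch: float = 50.0,
    pan_ec_gene: str = "VWF",
    artery_gene: str = "GJA5",
    vein_gene: str = "ACKR1",
    caliber_gene: str = "SULF1",
    caliber_threshold_bins: int = 30,
    caliber_rate_large: float = CALIBER_RATE_LARGE,
    caliber_rate_small: float = CALIBER_RATE_SMALL,
    counts_per_bin: int = 2,
    min_separation: float = 5.0,
    background_rate: float = 0.0,
    background_genes: list[str] | None = None,
    pixel_size_um: float = 0.138,
    seed: int = 0,
) -> GroundTruthScene:
    """Plant annular vessel cross-sections as marker-positive bins.

    Every lattice bin on a vessel's wall receives ``counts_per_bin``
    pan-EC transcripts and ``counts_per_bin`` arterial or venous marker
    transcripts at uniform positions inside the tile.  The
    caliber-dependent gene is emitted per bin as a Bernoulli draw whose
    rate depends on whether the vessel's wall covers more than
    ``caliber_threshold_bins`` bins.  ``background_rate`` is the
    expected count of uniformly scattered nuisance transcripts per bin
    over the whole field.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = shape
    rows: list[tuple[float, float, float, str]] = []
    placed: list[tuple[float, float, float]] = []

    def uniform_in_tile(i: int, j: int) -> tuple[float, float, float]:
        # rejection-sample so transcripts stay resolvable as separate
        # spots when the scene is rendered and decoded
        for _ in range(200):
            x = rng.uniform(i * pitch, (i + 1) * pitch)
            y = rng.uniform(j * pitch, (j + 1) * pitch)
            z = rng.uniform(0, nz)
            p = (min(x, nx - 1e-6), min(y, ny - 1e-6), min(z, nz - 1e-6))
            if not placed or min_separation <= 0:
                break
            d = np.linalg.norm(np.asarray(placed) - np.asarray(p), axis=1)
            if d.min() >= min_separation:
                break
        placed.append(p)
        return p

    for vessel in vessels:
        bins = ring_bins(vessel, pitch)
        rate = caliber_rate_large if len(bins) > caliber_threshold_bins else caliber_rate_small
        type_gene = artery_gene if vessel.vessel_type == "artery" else vein_gene
        for (i, j) in bins:
            for _ in range(counts_per_bin):
                rows.append((*uniform_in_tile(i, j), pan_ec_gene))
                rows.append((*uniform_in_tile(i, j), type_gene))
            if rng.uniform() < rate:
                rows.append((*uniform_in_tile(i, j), caliber_gene))

    if background_rate > 0:
        if not background_genes:
            raise ValueError("background_rate > 0 requires background_genes")
        n_tiles = int(np.ceil(nx / pitch) * np.ceil(ny / pitch))
        n_bg = rng.poisson(background_rate * n_tiles)
        for _ in range(n_bg):
            x = rng.uniform(0, nx)
            y = rng.uniform(0, ny)
            z = rng.uniform(0, nz)
            rows.append((x, y, z, rng.choice(background_genes)))

    df = pd.DataFrame(rows, columns=["x", "y", "z", "gene"])
    return GroundTruthScene(
        shape=shape,
        pixel_size_um=pixel_size_um,
        transcripts=df,
        vessels=list(vessels),
        seed=seed,
    )


def _add_gaussian_spot(
    stack: np.ndarray,
    x: float,
    y: float,
    z: float,
    amplitude: float,
    sd_xy: float,
    sd_z: float,
) -> None:
    """Accumulate an anisotropic 3D Gaussian into stack[z, y, x] in place."""
    nz, ny, nx = stack.shape
    rx = int(np.ceil(4 * sd_xy))
    rz = max(1, int(np.ceil(3 * sd_z)))
    x0, x1 = max(0, int(x) - rx), min(nx, int(x) + rx + 1)
    y0, y1 = max(0, int(y) - rx), min(ny, int(y) + rx + 1)
    z0, z1 = max(0, int(z) - rz), min(nz, int(z) + rz + 1)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    g = np.exp(
        -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sd_xy**2) - (zz - z) ** 2 / (2 * sd_z**2)
    )
    stack[z0:z1, y0:y1, x0:x1] += amplitude * g


def render_rounds(
    scene: GroundTruthScene,
    codebook: Codebook,
    amplitude: float = 200.0,
    sd_xy: float = 1.2,
    sd_z: float = 0.8,
    poisson: bool = False,
) -> tuple[dict[tuple[int, int], np.ndarray], pd.DataFrame]:
    """Render the scene into one stack per (round, channel).

    Each transcript contributes a 3D Gaussian spot to exactly the images
    where its gene's code is on.  Per-round rigid offsets (rounds >= 2)
    displace the spot in that round's raw images.  Background and
    Gaussian read noise are added per stack; with ``poisson=True`` the
    noiseless image is additionally Poisson-resampled.  Returns the
    stacks and the scene's truth table unmodified.
    """
    rng = np.random.default_rng(scene.seed + 1)
    nx, ny, nz = scene.shape
    n_rounds, n_channels = codebook.n_rounds, codebook.n_channels
    stacks = {
        (r, c): np.zeros((nz, ny, nx), dtype=np.float64)
        for r in range(n_rounds)
        for c in range(n_channels)
    }

    missing = set(scene.transcripts.gene) - set(codebook.genes)
    if missing:
        raise KeyError(f"scene genes absent from codebook: {sorted(missing)}")

    offsets = scene.round_offsets
    pts = scene.transcripts[["x", "y", "z"]].to_numpy(dtype=float)
    # positions per round, offsets applied to rounds >= 2
    per_round_pts = []
    for r in range(n_rounds):
        if r < len(offsets) and offsets[r] is not None:
            per_round_pts.append(offsets[r].apply(pts) if len(pts) else pts)
        else:
            per_round_pts.append(pts)

    for idx, gene in enumerate(scene.transcripts.gene):
        for slot in codebook.on_slots(gene):
            r, c = divmod(int(slot), n_channels)
            x, y, z = per_round_pts[r][idx]
            _add_gaussian_spot(stacks[(r, c)], x, y, z, amplitude, sd_xy, sd_z)

    for key, stack in stacks.items():
        if poisson:
            stack[:] = rng.poisson(np.clip(stack, 0, None)).astype(float)
        stack += scene.background
        if scene.noise_sd > 0:
            stack += rng.normal(0.0, scene.noise_sd, size=stack.shape)
        np.clip(stack, 0, None, out=stack)
        stacks[key] = stack.astype(np.float32)

    return stacks, scene.transcripts.copy()


def make_rnascope_fixture(
    pattern_counts: dict[tuple[str, ...], int],
    channels: tuple[str, ...] = ("ACTA2", "CDH5", "TINAGL1"),
    shape: tuple[int, int] = (512, 512),
    amplitude: float = 200.0,
    blob_sigma: float = 2.0,
    background: float = 5.0,
    noise_sd: float = 0.0,
    margin: int = 16,
    min_separation: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a multi-channel 8-bit 2D image with known blob memberships.

    ``pattern_counts`` maps a channel subset to the number of blobs
    positive in exactly those channels, e.g. ``{("ACTA2",): 10,
    ("ACTA2", "TINAGL1"): 5}``.  Returns the (C, H, W) uint8 image and
    a truth table with x, y, amplitude and one boolean column per
    channel.  Intensities are clipped into [0, 255], never wrapped.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    for pattern in pattern_counts:
        unknown = set(pattern) - set(channels)
        if unknown:
            raise ValueError(f"pattern references unknown channels: {sorted(unknown)}")

    placed: list[tuple[float, float]] = []
    rows = []
    for pattern, n in pattern_counts.items():
        for _ in range(n):
            for _ in range(10_000):
                x = rng.uniform(margin, w - margin)
                y = rng.uniform(margin, h - margin)
                if not placed or np.hypot(
                    np.array(placed)[:, 0] - x, np.array(placed)[:, 1] - y
                ).min() >= min_separation:
                    break
            else:
                raise RuntimeError("could not place blobs at requested separation")
            placed.append((x, y))
            row = {"x": x, "y": y, "amplitude": amplitude}
            for ch in channels:
                row[ch] = ch in pattern
            rows.append(row)

    truth = pd.DataFrame(rows, columns=["x", "y", "amplitude", *channels])
    img = np.zeros((len(channels), h, w), dtype=np.float64)
    yy, xx = np.mgrid[0:h, 0:w]
    for _, row in truth.iterrows():
        g = row["amplitude"] * np.exp(
            -((xx - row["x"]) ** 2 + (yy - row["y"]) ** 2) / (2 * blob_sigma**2)
        )
        for ci, ch in enumerate(channels):
            if row[ch]:
                img[ci] += g
    img += background
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0, 255).astype(np.uint8), truth
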