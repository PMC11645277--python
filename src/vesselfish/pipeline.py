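"""End-to-end orchestration: stacks -> transcripts -> bins -> vessels.

Stage order follows the acquisition pipeline: per-round spot detection,
ICP registration of every round to round one, stack resampling,
per-pixel profile decoding, square-tile binning, marker subsetting and
vessel quantification.  Every run writes a manifest recording stage
parameters and input hashes so outputs are traceable to config + seed;
rerunning an identical config reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as vio
from .binning import bin_transcripts, filter_bins, subset_by_markers, write_binmatrix
from .codebook import Codebook, read_codebook
from .decoding import decode_stacks
from .detection import DetectionParams, detect_features
from .registration import multistart_icp, resample_stack
from .vessels import VesselParams, cluster_vessels, compare_calibers, vessels_table

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "register_rounds"]


class PipelineError(RuntimeError):
    """Stage-labeled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    stacks_dir: str
    codebook_csv: str
    out_dir: str
    pixel_size_um: float = 0.138
    z_step_um: float = 0.4
    n_rounds: int = 8
    n_channels: int = 2
    detection: DetectionParams = field(default_factory=DetectionParams)
    min_score: float = 2.0
    min_match: float = 0.7
    pitch: float = 50.0
    vessel: VesselParams = field(default_factory=VesselParams)
    pan_ec_gene: str = "VWF"
    artery_gene: str = "GJA5"
    vein_gene: str = "ACKR1"
    stat_genes: list[str] = field(default_factory=lambda: ["SULF1"])
    roi: str = "roi0"
    seed: int = 0


def register_rounds(
    stacks: dict[tuple[int, int], np.ndarray],
    pixel_size_um: float,
    z_step_um: float,
    params: DetectionParams,
    n_channels: int,
):
    """Detect per-round feature clouds and align rounds >= 2 to round 1.

    Channel clouds of one round are pooled into that round's cloud.
    Returns (registered stacks, transforms per round, rms per round).
    """
    from .registration import RigidTransform3D

    rounds = sorted({r for r, _ in stacks})
    clouds = {}
    for r in rounds:
        parts = [np.empty((0, 3))]
        for c in range(n_channels):
            if (r, c) in stacks:
                feats = detect_features(stacks[(r, c)], pixel_size_um, z_step_um, params)
                parts.append(feats[["x", "y", "z"]].to_numpy(dtype=float))
        clouds[r] = np.vstack(parts)

    transforms, rms = {}, {}
    registered = {}
    ref = clouds[rounds[0]]
    for r in rounds:
        if r == rounds[0]:
            transforms[r] = RigidTransform3D.identity()
            rms[r] = 0.0
            for c in range(n_channels):
                if (r, c) in stacks:
                    registered[(r, c)] = np.asarray(stacks[(r, c)], dtype=float)
            continue
        if len(clouds[r]) >= 3:
            try:
                result = multistart_icp(clouds[r], ref)
            except ValueError:
                result = None
        else:
            result = None
        if result is None:
            # a round whose on-bit images carry too few spots for a
            # plausible alignment stays untransformed rather than fail
            transforms[r] = RigidTransform3D.identity()
            rms[r] = float("nan")
            for c in range(n_channels):
                if (r, c) in stacks:
                    registered[(r, c)] = np.asarray(stacks[(r, c)], dtype=float)
            continue
        transforms[r] = result.transform
        rms[r] = result.rms
        for c in range(n_channels):
            if (r, c) in stacks:
                registered[(r, c)] = resample_stack(stacks[(r, c)], result.transform)
    return registered, transforms, rms


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, writing artifacts and a manifest under out_dir.

    Returns a dict of the in-memory artifacts (transcripts, bin matrix,
    vessels table, comparisons, specificity report).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "inputs": {}, "seed": config.seed}
    t_start = time.time()

    def stage(name):
        manifest["stages"][name] = {"t_start_s": round(time.time() - t_start, 3)}
        return name

    # --- load inputs -----------------------------------------------------
    name = stage("load")
    try:
        stacks = vio.read_roundstacks(config.stacks_dir)
    except (FileNotFoundError, OSError) as e:
        raise PipelineError(name, f"cannot read stacks from {config.stacks_dir}: {e}")
    try:
        codebook = read_codebook(config.codebook_csv, config.n_rounds, config.n_channels)
    except (FileNotFoundError, ValueError) as e:
        raise PipelineError(name, f"cannot read codebook {config.codebook_csv}: {e}")
    shapes = {s.shape for s in stacks.values()}
    if len(shapes) > 1:
        raise PipelineError(name, f"inconsistent stack shapes: {sorted(shapes)}")
    for p in sorted(Path(config.stacks_dir).iterdir()):
        if p.suffix == ".tif":
            manifest["inputs"][p.name] = vio.file_sha256(p)
    manifest["inputs"][Path(config.codebook_csv).name] = vio.file_sha256(config.codebook_csv)

    # --- detection + registration ---------------------------------------
    stage("register")
    registered, transforms, rms = register_rounds(
        stacks, config.pixel_size_um, config.z_step_um, config.detection, config.n_channels
    )
    for r, T in transforms.items():
        T.save_json(out / f"transform_round{r + 1}.json")
    manifest["stages"]["register"]["rms_px"] = {str(r + 1): v for r, v in rms.items()}

    # --- decoding --------------------------------------------------------
    stage("decode")
    transcripts, specificity = decode_stacks(
        registered, codebook, min_score=config.min_score, min_match=config.min_match
    )
    vio.write_transcripts(transcripts, out / "transcripts.csv")
    if specificity is not None:
        (out / "specificity.json").write_text(json.dumps(specificity.to_dict(), indent=2))

    # --- binning ---------------------------------------------------------
    stage("bin")
    bm = bin_transcripts(transcripts, pitch=config.pitch, genes=codebook.genes, roi=config.roi)
    bm = filter_bins(bm)
    write_binmatrix(bm, out / "binmatrix")

    # --- vessels ---------------------------------------------------------
    stage("vessels")
    comparisons = None
    markers = [config.pan_ec_gene, config.artery_gene]
    if set(markers) <= set(bm.genes):
        arterial = subset_by_markers(bm, require_all=markers)
        clusters = cluster_vessels(arterial, config.vessel, vessel_type="artery")
        vtable = vessels_table(clusters, arterial)
        vtable.to_csv(out / "vessels.csv", index=False)
        from .vessels import vessel_gene_stats

        stat_rows = []
        for c in clusters:
            for gene in config.stat_genes:
                if gene in arterial.genes:
                    pct, mean = vessel_gene_stats(c, arterial, gene)
                    stat_rows.append((c.id, gene, pct, mean))
        pd.DataFrame(
            stat_rows, columns=["vessel_id", "gene", "pct_expressing", "mean_expressing"]
        ).to_csv(out / "vessel_stats.csv", index=False)
        calibers = {c.caliber for c in clusters}
        stat_genes = [g for g in config.stat_genes if g in bm.genes]
        if {"larger", "smaller"} <= calibers and stat_genes:
            comparisons = compare_calibers(clusters, arterial, stat_genes, config.vessel)
            comparisons.to_csv(out / "comparisons.csv", index=False)
    else:
        clusters, vtable = [], pd.DataFrame(
            columns=["vessel_id", "roi", "vessel_type", "n_bins", "caliber"]
        )
        manifest["stages"]["vessels"]["skipped"] = "vessel marker genes not in panel"

    # --- manifest --------------------------------------------------------
    manifest["config"] = dataclasses.asdict(config)
    manifest["elapsed_s"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    return {
        "transcripts": transcripts,
        "bin_matrix": bm,
        "vessels": vtable,
        "comparisons": comparisons,
        "specificity": specificity,
        "transforms": transforms,
    }
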