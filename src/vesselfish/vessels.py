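"""Vessel objects from marker-positive bins, caliber classes, statistics.

Marker-positive bins (e.g. VWF & GJA5 co-expressing bins for arteries)
are grouped into individual vessels by single-linkage agglomerative
clustering cut at 1.5 bin pitches — equivalent to 8-neighborhood
connected components of the bin lattice.  Clusters under five bins are
discarded; the survivors are classed as larger (> 30 bins) or smaller
(≤ 30 bins) caliber.  Per-vessel marker statistics (percentage of bins
expressing a gene, and mean counts over expressing bins only) are
compared between groups with the two-sided Wilcoxon rank-sum test under
Benjamini–Hochberg adjustment across genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import AgglomerativeClustering
from statsmodels.stats.multitest import multipletests

from .binning import BinMatrix

__all__ = [
    "VesselParams",
    "VesselCluster",
    "GroupComparison",
    "cluster_vessels",
    "classify_caliber",
    "vessel_gene_stats",
    "compare_groups",
    "bh_adjust",
    "compare_calibers",
]

EXACT_RANKSUM_MAX_N = 8


@dataclass(frozen=True)
class VesselParams:
    min_cluster_bins: int = 5
    caliber_threshold_bins: int = 30
    linkage_threshold_px: float | None = None  # None -> 1.5 × pitch

    def __post_init__(self) -> None:
        if self.min_cluster_bins < 1:
            raise ValueError("min_cluster_bins must be >= 1")
        if self.caliber_threshold_bins < self.min_cluster_bins:
            raise ValueError("caliber threshold below minimum cluster size")


@dataclass
class VesselCluster:
    id: int
    bin_indices: np.ndarray
    vessel_type: str
    caliber: str  # "larger" | "smaller"

    @property
    def n_bins(self) -> int:
        return len(self.bin_indices)


@dataclass
class GroupComparison:
    statistic: float  # Mann-Whitney U of group a
    p_value: float
    n_a: int
    n_b: int
    p_adjusted: float | None = None


def classify_caliber(n_bins: int, params: VesselParams = VesselParams()) -> str:
    """Larger caliber iff the vessel spans more than the threshold bin count."""
    return "larger" if n_bins > params.caliber_threshold_bins else "smaller"


def cluster_vessels(
    bm: BinMatrix,
    params: VesselParams = VesselParams(),
    vessel_type: str = "artery",
) -> list[VesselCluster]:
    """Group marker-positive bins into vessels by single-linkage clustering.

    The input matrix must already be subset to the vessel type's marker
    rule.  The linkage cut defaults to 1.5 bin pitches, which joins
    exactly the 8-neighborhood-adjacent bins of the lattice; clusters
    with fewer than ``min_cluster_bins`` bins are removed.
    """
    threshold = params.linkage_threshold_px
    if threshold is None:
        threshold = 1.5 * bm.pitch
    if bm.n_bins == 0:
        return []
    if bm.n_bins == 1:
        labels = np.zeros(1, dtype=int)
    else:
        model = AgglomerativeClustering(
            n_clusters=None,
            distance_threshold=threshold,
            linkage="single",
        )
        labels = model.fit_predict(bm.centroids())

    clusters = []
    next_id = 0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        if len(idx) < params.min_cluster_bins:
            continue
        clusters.append(
            VesselCluster(next_id, idx, vessel_type, classify_caliber(len(idx), params))
        )
        next_id += 1
    return clusters


def vessel_gene_stats(
    cluster: VesselCluster, bm: BinMatrix, gene: str
) -> tuple[float, float]:
    """(pct_expressing, mean_expressing) for one gene in one vessel.

    pct_expressing is the percentage of the vessel's bins with at least
    one count; mean_expressing averages counts over expressing bins
    only and is NaN when no bin expresses the gene.
    """
    counts = bm.gene_counts(gene)[cluster.bin_indices]
    expressing = counts >= 1
    pct = 100.0 * expressing.sum() / len(counts)
    mean = float(counts[expressing].mean()) if expressing.any() else float("nan")
    return pct, mean


def compare_groups(values_a, values_b) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) comparison.

    Uses the exact null distribution when the smaller group has at most
    eight observations and the pooled sample is tie-free; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(a), len(b)) <= EXACT_RANKSUM_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return GroupComparison(float(res.statistic), float(res.pvalue), len(a), len(b))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_calibers(
    clusters: list[VesselCluster],
    bm: BinMatrix,
    genes: list[str],
    params: VesselParams = VesselParams(),
) -> pd.DataFrame:
    """Larger- vs smaller-caliber comparison of per-vessel gene statistics.

    For every gene and both metrics (pct_expressing, mean_expressing;
    vessels are the replicates, NaN means dropped), runs the two-sided
    rank-sum test between caliber groups and BH-adjusts within each
    metric across all genes tested in the run.
    """
    larger = [c for c in clusters if c.caliber == "larger"]
    smaller = [c for c in clusters if c.caliber == "smaller"]
    if not larger or not smaller:
        raise ValueError("need at least one vessel in each caliber group")

    rows = []
    for metric_idx, metric in enumerate(["pct_expressing", "mean_expressing"]):
        for gene in genes:
            va = [vessel_gene_stats(c, bm, gene)[metric_idx] for c in larger]
            vb = [vessel_gene_stats(c, bm, gene)[metric_idx] for c in smaller]
            va = [v for v in va if not np.isnan(v)]
            vb = [v for v in vb if not np.isnan(v)]
            if not va or not vb:
                rows.append((gene, metric, np.nan, np.nan, len(va), len(vb)))
                continue
            cmp = compare_groups(va, vb)
            rows.append((gene, metric, cmp.statistic, cmp.p_value, cmp.n_a, cmp.n_b))
    df = pd.DataFrame(rows, columns=["gene", "metric", "statistic", "p", "n_larger", "n_smaller"])
    df["p_adj"] = np.nan
    for metric in df.metric.unique():
        sel = df.metric == metric
        valid = sel & df.p.notna()
        if valid.any():
            df.loc[valid, "p_adj"] = bh_adjust(df.loc[valid, "p"].to_numpy())
    return df


def vessels_table(clusters: list[VesselCluster], bm: BinMatrix) -> pd.DataFrame:
    """Summary table: one row per vessel (id, roi, type, size, caliber)."""
    rows = []
    for c in clusters:
        rois = pd.unique(bm.roi[c.bin_indices])
        rows.append((c.id, ",".join(map(str, rois)), c.vessel_type, c.n_bins, c.caliber))
    return pd.DataFrame(rows, columns=["vessel_id", "roi", "vessel_type", "n_bins", "caliber"])
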