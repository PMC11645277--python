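"""Square-tile binning of transcript tables into bin × gene counts.

Transcripts are aggregated into a fixed lattice of square tiles
(default pitch 50 px, ~7 µm at the instrument's pixel size); tile
centroids sit at (i + 0.5)·pitch, so assignment is nearest-centroid for
interior points and deterministic at tile boundaries.  z is ignored.
The resulting matrix supports the vessel-marker subsetting rules and
Pearson gene–gene correlation used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "BinMatrix",
    "bin_transcripts",
    "filter_bins",
    "subset_by_markers",
    "gene_correlation",
    "write_binmatrix",
    "read_binmatrix",
]


@dataclass
class BinMatrix:
    """Bins × genes integer count matrix with bin centroids.

    ``counts[b, g]`` is the number of transcripts of gene g in bin b.
    ``x``/``y`` are bin centroid coordinates in pixels; ``roi`` labels
    the region each bin came from (bins are per-ROI; concatenated
    matrices carry the label along).
    """

    x: np.ndarray
    y: np.ndarray
    genes: list[str]
    counts: np.ndarray
    pitch: float = 50.0
    roi: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.roi is None:
            self.roi = np.array(["roi0"] * len(self.x), dtype=object)
        else:
            self.roi = np.asarray(self.roi, dtype=object)
        if self.counts.shape != (len(self.x), len(self.genes)):
            raise ValueError("counts shape does not match bins × genes")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in bin matrix") from None

    def gene_counts(self, gene: str) -> np.ndarray:
        return self.counts[:, self.gene_index(gene)]

    def select(self, mask: np.ndarray) -> "BinMatrix":
        return BinMatrix(
            self.x[mask], self.y[mask], list(self.genes), self.counts[mask],
            pitch=self.pitch, roi=self.roi[mask],
        )

    def centroids(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def to_anndata(self):
        """Bins-as-observations AnnData view (sparse X)."""
        import anndata
        from scipy import sparse

        obs = pd.DataFrame({"x": self.x, "y": self.y, "roi": self.roi.astype(str)})
        obs.index = obs.index.astype(str)
        var = pd.DataFrame(index=pd.Index(self.genes, name="gene"))
        ad = anndata.AnnData(X=sparse.csr_matrix(self.counts), obs=obs, var=var)
        ad.uns["pitch"] = self.pitch
        return ad

    @classmethod
    def concat(cls, parts: list["BinMatrix"]) -> "BinMatrix":
        if not parts:
            raise ValueError("nothing to concatenate")
        genes = parts[0].genes
        if any(p.genes != genes for p in parts):
            raise ValueError("gene lists differ between parts")
        return cls(
            np.concatenate([p.x for p in parts]),
            np.concatenate([p.y for p in parts]),
            list(genes),
            np.vstack([p.counts for p in parts]),
            pitch=parts[0].pitch,
            roi=np.concatenate([p.roi for p in parts]),
        )


def bin_transcripts(
    transcripts: pd.DataFrame,
    pitch: float = 50.0,
    genes: list[str] | None = None,
    roi: str = "roi0",
) -> BinMatrix:
    """Bin transcript x/y coordinates to the nearest pitch-lattice centroid.

    A transcript at (x, y) lands in tile (floor(x/pitch), floor(y/pitch))
    with centroid ((i + 0.5)·pitch, (j + 0.5)·pitch); z is collapsed.
    Total counts are conserved.  ``genes`` fixes the column order (and
    may include genes absent from this table); by default the columns
    are the sorted genes observed.
    """
    if pitch < 1:
        raise ValueError("pitch must be >= 1 px")
    if genes is None:
        genes = sorted(pd.unique(transcripts.gene)) if len(transcripts) else []
    gene_pos = {g: i for i, g in enumerate(genes)}
    if len(transcripts):
        unknown = set(transcripts.gene) - set(genes)
        if unknown:
            raise ValueError(f"transcripts carry genes outside the gene list: {sorted(unknown)}")
        xy = transcripts[["x", "y"]].to_numpy(dtype=float)
        if not np.isfinite(xy).all():
            raise ValueError("non-finite transcript coordinates")
        tiles = np.floor(xy / pitch).astype(np.int64)
        tile_ids, inverse = np.unique(tiles, axis=0, return_inverse=True)
        counts = np.zeros((len(tile_ids), len(genes)), dtype=np.int64)
        gidx = transcripts.gene.map(gene_pos).to_numpy()
        np.add.at(counts, (inverse, gidx), 1)
        cx = (tile_ids[:, 0] + 0.5) * pitch
        cy = (tile_ids[:, 1] + 0.5) * pitch
    else:
        counts = np.zeros((0, len(genes)), dtype=np.int64)
        cx = cy = np.zeros(0)
    return BinMatrix(cx, cy, list(genes), counts, pitch=pitch,
                     roi=np.array([roi] * len(cx), dtype=object))


def filter_bins(bm: BinMatrix) -> BinMatrix:
    """Keep bins with more than one gene and more than one count.

    i.e. at least two distinct genes with nonzero counts AND a total
    count of at least two.  Idempotent.
    """
    n_genes_per_bin = (bm.counts > 0).sum(axis=1)
    total = bm.counts.sum(axis=1)
    return bm.select((n_genes_per_bin >= 2) & (total >= 2))


def subset_by_markers(
    bm: BinMatrix,
    require_any: list[str] | None = None,
    require_all: list[str] | None = None,
    exclude: list[str] | None = None,
) -> BinMatrix:
    """Marker-based bin subsetting.

    Retains bins with a nonzero count for at least one ``require_any``
    gene, a count >= 1 for every ``require_all`` gene, and a zero count
    for every ``exclude`` gene.  The vasculature rule, for example, is
    ``require_any=[VWF, MYH11, KCNJ8], exclude=[TTN]``; arterial bins
    are ``require_all=[VWF, GJA5]``.
    """
    mask = np.ones(bm.n_bins, dtype=bool)
    if require_any:
        any_mask = np.zeros(bm.n_bins, dtype=bool)
        for g in require_any:
            any_mask |= bm.gene_counts(g) > 0
        mask &= any_mask
    for g in require_all or []:
        mask &= bm.gene_counts(g) >= 1
    for g in exclude or []:
        mask &= bm.gene_counts(g) == 0
    return bm.select(mask)


def gene_correlation(bm: BinMatrix) -> pd.DataFrame:
    """Pearson correlation of gene counts across bins.

    Zero-variance genes are dropped (their correlation is undefined);
    the dropped names are reported in ``attrs['dropped']``.  Requires
    at least two bins.
    """
    if bm.n_bins < 2:
        raise ValueError("need >= 2 bins for correlation")
    df = pd.DataFrame(bm.counts, columns=bm.genes)
    variable = df.columns[df.std(ddof=0) > 0]
    dropped = [g for g in bm.genes if g not in set(variable)]
    corr = df[variable].corr(method="pearson")
    corr.attrs["dropped"] = dropped
    return corr


def write_binmatrix(bm: BinMatrix, prefix) -> None:
    """Write matrix.mtx + bins.tsv + genes.tsv under the given prefix dir."""
    from scipy import io as sio
    from scipy import sparse

    prefix = Path(prefix)
    prefix.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(prefix / "matrix.mtx", sparse.coo_matrix(bm.counts))
    pd.DataFrame({"x": bm.x, "y": bm.y, "roi": bm.roi.astype(str)}).to_csv(
        prefix / "bins.tsv", sep="\t", index=False
    )
    pd.DataFrame({"gene": bm.genes}).to_csv(prefix / "genes.tsv", sep="\t", index=False)
    (prefix / "pitch.txt").write_text(str(bm.pitch))


def read_binmatrix(prefix) -> BinMatrix:
    from scipy import io as sio

    prefix = Path(prefix)
    counts = np.asarray(sio.mmread(prefix / "matrix.mtx").todense()).astype(np.int64)
    bins = pd.read_csv(prefix / "bins.tsv", sep="\t")
    genes = pd.read_csv(prefix / "genes.tsv", sep="\t")["gene"].tolist()
    pitch = float((prefix / "pitch.txt").read_text())
    return BinMatrix(
        bins.x.to_numpy(), bins.y.to_numpy(), genes, counts, pitch=pitch,
        roi=bins.roi.to_numpy(dtype=object),
    )
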