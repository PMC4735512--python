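"""Cluster calling and colocalization for single-molecule localization data.

Localizations (switching events of individual dyes, in nm) are rasterized
into square bins; any 8-connected set of non-empty bins surrounded by empty
bins is a cluster, including isolated single bins.  The bin edge adapts to
the per-cell localization density::

    bin_size = 15 nm * (average localizations per cell / localizations in this cell) ** 0.5

clamped to [10, 30] nm.  Two-channel colocalization always uses fixed 15-nm
bins on a grid shared by both channels, excludes single-bin clusters (below
the ~30 nm resolution limit), and reports per channel the fraction of
localizations in colocalized clusters relative to all localizations in
multi-bin clusters.

Cluster diameter is the equivalent-square edge ``bin_size * sqrt(n_bins)``
(configurable estimator; a single bin sits at the resolution limit).
Cluster-size distributions are weighted by localization count, matching how
a molecule-rich cluster dominates the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LocalizationTable",
    "BinGrid",
    "ClusterSet",
    "adaptive_bin_size",
    "rasterize",
    "call_clusters",
    "cluster_diameter",
    "weighted_size_distribution",
    "weighted_median_diameter",
    "count_clusters_above",
    "colocalization",
    "subsample_robustness",
    "analyze_cell",
    "analyze_table",
    "read_localizations",
]

DEFAULT_BIN_NM = 15.0
BIN_MIN_NM = 10.0
BIN_MAX_NM = 30.0
RESOLUTION_LIMIT_NM = 30.0

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class LocalizationTable:
    """Per-localization positions (nm) with channel and cell labels."""

    x: np.ndarray
    y: np.ndarray
    channel: np.ndarray
    cell_id: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.channel = np.asarray(self.channel)
        self.cell_id = np.asarray(self.cell_id)
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("localization coordinates must be finite")

    def __len__(self) -> int:
        return len(self.x)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LocalizationTable":
        return cls(
            df["x_nm"].to_numpy(float),
            df["y_nm"].to_numpy(float),
            df["channel"].to_numpy(),
            df["cell_id"].to_numpy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x_nm": self.x, "y_nm": self.y, "channel": self.channel, "cell_id": self.cell_id}
        )

    def subset(self, mask: np.ndarray) -> "LocalizationTable":
        return LocalizationTable(
            self.x[mask], self.y[mask], self.channel[mask], self.cell_id[mask]
        )


def read_localizations(path) -> LocalizationTable:
    """Read a delimited localization table with header x_nm,y_nm,channel,cell_id."""
    return LocalizationTable.from_frame(pd.read_csv(path))


@dataclass
class BinGrid:
    """Rasterized localization counts on a square-bin grid."""

    bin_size: float
    origin: tuple[float, float]
    counts: np.ndarray  # (ny, nx) non-negative ints

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ClusterSet:
    """Called clusters: label image plus per-cluster bins/localizations."""

    grid: BinGrid
    labels: np.ndarray        # (ny, nx) int, 0 = background
    n_bins: np.ndarray        # (n_clusters,)
    n_localizations: np.ndarray

    @property
    def n_clusters(self) -> int:
        return len(self.n_bins)

    def diameters(self) -> np.ndarray:
        if self.n_clusters == 0:
            return np.zeros(0)
        return cluster_diameter(self.n_bins, self.grid.bin_size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": np.arange(1, self.n_clusters + 1),
                "n_bins": self.n_bins,
                "n_localizations": self.n_localizations,
                "diameter_nm": self.diameters(),
            }
        )


def adaptive_bin_size(n_cell: float, n_avg: float) -> float:
    """Adaptive bin edge (nm) for a cell with ``n_cell`` localizations in a
    cohort averaging ``n_avg`` per cell; clamped to [10, 30] nm."""
    if n_cell <= 0 or n_avg <= 0:
        raise ValueError("localization counts must be positive")
    raw = DEFAULT_BIN_NM * np.sqrt(n_avg / n_cell)
    return float(np.clip(raw, BIN_MIN_NM, BIN_MAX_NM))


def rasterize(
    table: LocalizationTable,
    bin_size: float,
    origin: tuple[float, float] | None = None,
    shape: tuple[int, int] | None = None,
) -> BinGrid:
    """Assign each localization to one half-open square bin.

    Bins are ``[origin + i*b, origin + (i+1)*b)``: a point exactly on a
    boundary goes to the higher-index bin.  Default origin is the minimum
    coordinate, so every point falls on the grid.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if len(table) == 0:
        return BinGrid(bin_size, origin or (0.0, 0.0), np.zeros((1, 1), dtype=np.int64))
    if origin is None:
        origin = (float(table.x.min()), float(table.y.min()))
    ix = np.floor((table.x - origin[0]) / bin_size).astype(np.int64)
    iy = np.floor((table.y - origin[1]) / bin_size).astype(np.int64)
    if shape is None:
        shape = (int(iy.max()) + 1, int(ix.max()) + 1)
    counts = np.zeros(shape, dtype=np.int64)
    np.add.at(counts, (iy, ix), 1)
    return BinGrid(bin_size, origin, counts)


def call_clusters(grid: BinGrid) -> ClusterSet:
    """8-connected components of non-empty bins (single bins included)."""
    labels, n = ndimage.label(grid.counts > 0, structure=_EIGHT_CONNECTED)
    if n == 0:
        return ClusterSet(grid, labels, np.zeros(0, np.int64), np.zeros(0, np.int64))
    idx = np.arange(1, n + 1)
    n_bins = ndimage.sum_labels(np.ones_like(grid.counts), labels, idx).astype(np.int64)
    n_locs = ndimage.sum_labels(grid.counts, labels, idx).astype(np.int64)
    return ClusterSet(grid, labels, n_bins, n_locs)


def cluster_diameter(n_bins, bin_size: float):
    """Equivalent-square-edge diameter: bin_size * sqrt(n_bins)."""
    n = np.asarray(n_bins)
    if np.any(n < 1):
        raise ValueError("clusters must contain at least one bin")
    out = bin_size * np.sqrt(n)
    return float(out) if np.isscalar(n_bins) else out


def weighted_size_distribution(
    clusters: ClusterSet, bin_edges: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Localization-weighted diameter histogram and weighted median.

    Each cluster contributes its localization count as weight; the histogram
    is normalized to 1 and the weighted median is the smallest diameter at
    which the cumulative localization weight reaches one half.
    """
    if clusters.n_clusters == 0:
        raise ValueError("no clusters to summarize")
    d = clusters.diameters()
    w = clusters.n_localizations.astype(float)
    if bin_edges is None:
        bin_edges = np.logspace(np.log10(max(d.min(), 1.0)), np.log10(d.max() + 1.0), 30)
    hist, edges = np.histogram(d, bins=bin_edges, weights=w)
    total = w.sum()
    hist = hist / total
    return hist, edges, weighted_median_diameter(clusters)


def weighted_median_diameter(clusters: ClusterSet) -> float:
    d = clusters.diameters()
    w = clusters.n_localizations.astype(float)
    order = np.argsort(d, kind="stable")
    cum = np.cumsum(w[order])
    k = int(np.searchsorted(cum, 0.5 * w.sum()))
    return float(d[order][min(k, len(d) - 1)])


def count_clusters_above(clusters: ClusterSet, threshold: float = RESOLUTION_LIMIT_NM) -> int:
    """Number of clusters with diameter strictly above the threshold."""
    return int((clusters.diameters() > threshold).sum())


def analyze_cell(
    table: LocalizationTable, n_avg: float | None = None, bin_size: float | None = None
) -> ClusterSet:
    """Cluster one cell's localizations with the adaptive (or given) bin size."""
    if bin_size is None:
        n_avg = float(len(table)) if n_avg is None else n_avg
        bin_size = adaptive_bin_size(len(table), n_avg)
    return call_clusters(rasterize(table, bin_size))


def analyze_table(table: LocalizationTable) -> pd.DataFrame:
    """Per-cell cluster summaries; the cohort average localization count is
    computed over the table's cell_id groups."""
    cells = pd.unique(table.cell_id)
    n_avg = len(table) / len(cells)
    rows = []
    for cell in cells:
        sub = table.subset(table.cell_id == cell)
        clusters = analyze_cell(sub, n_avg=n_avg)
        rows.append(
            {
                "cell_id": cell,
                "n_localizations": len(sub),
                "bin_size_nm": adaptive_bin_size(len(sub), n_avg),
                "n_clusters": clusters.n_clusters,
                "n_clusters_above_30nm": count_clusters_above(clusters),
                "weighted_median_diameter_nm": weighted_median_diameter(clusters)
                if clusters.n_clusters
                else np.nan,
            }
        )
    return pd.DataFrame(rows)


def colocalization(
    table_a: LocalizationTable,
    table_b: LocalizationTable,
    bin_size: float = DEFAULT_BIN_NM,
) -> tuple[float, float]:
    """Two-channel colocalization fractions on a shared fixed-bin grid.

    Clusters are called per channel independently on the same grid;
    single-bin clusters (below the resolution limit) are excluded.  A
    cluster is colocalized if at least one of its bins holds localizations
    from both channels.  Per channel the fraction is localizations in
    colocalized clusters over localizations in all multi-bin clusters.

    Raises ValueError if a channel has no multi-bin clusters (the fraction
    is undefined).
    """
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValueError("both channels must contain localizations")
    origin = (
        float(min(table_a.x.min(), table_b.x.min())),
        float(min(table_a.y.min(), table_b.y.min())),
    )
    nx = int(
        np.floor((max(table_a.x.max(), table_b.x.max()) - origin[0]) / bin_size)
    ) + 1
    ny = int(
        np.floor((max(table_a.y.max(), table_b.y.max()) - origin[1]) / bin_size)
    ) + 1
    grid_a = rasterize(table_a, bin_size, origin=origin, shape=(ny, nx))
    grid_b = rasterize(table_b, bin_size, origin=origin, shape=(ny, nx))
    clusters_a = call_clusters(grid_a)
    clusters_b = call_clusters(grid_b)

    def multi_bin_mask(clusters: ClusterSet) -> np.ndarray:
        multi = np.flatnonzero(clusters.n_bins > 1) + 1
        if not len(multi):
            raise ValueError("channel has no multi-bin clusters; fraction undefined")
        return np.isin(clusters.labels, multi)

    # Cluster-vs-cluster overlap on the shared grid: a bin counts when both
    # channels' (above-resolution) clusters claim it.
    mask_a = multi_bin_mask(clusters_a)
    mask_b = multi_bin_mask(clusters_b)
    both = mask_a & mask_b

    def channel_fraction(clusters: ClusterSet, own_mask: np.ndarray) -> float:
        multi = np.flatnonzero(clusters.n_bins > 1) + 1
        overlapping = set(np.unique(clusters.labels[both]).tolist()) - {0}
        locs = clusters.n_localizations
        denom = locs[multi - 1].sum()
        num = sum(int(locs[lab - 1]) for lab in multi if lab in overlapping)
        return float(num / denom)

    return channel_fraction(clusters_a, mask_a), channel_fraction(clusters_b, mask_b)


def subsample_robustness(
    table: LocalizationTable, seed: int, n_avg: float | None = None
) -> dict:
    """Split localizations 50/50 at random, rerun the pipeline on each half,
    and score the divergence of the two weighted diameter distributions.

    The divergence is the two-sample Kolmogorov-Smirnov distance between the
    localization-weighted diameter distributions of the two halves; values
    well below ~0.15 indicate the sampling density saturates the size
    estimates.
    """
    if len(table) < 2:
        raise ValueError("need at least 2 localizations to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(table))
    half = len(table) // 2
    mask = np.zeros(len(table), dtype=bool)
    mask[perm[:half]] = True
    halves = [table.subset(mask), table.subset(~mask)]
    results = []
    for sub in halves:
        clusters = analyze_cell(sub, n_avg=n_avg if n_avg is not None else len(sub))
        results.append(clusters)
    ks = _weighted_ks(
        results[0].diameters(), results[0].n_localizations.astype(float),
        results[1].diameters(), results[1].n_localizations.astype(float),
    )
    return {"halves": results, "ks_distance": ks}


def _weighted_ks(d1, w1, d2, w2) -> float:
    """KS distance between two weighted empirical diameter distributions."""
    grid = np.unique(np.concatenate([d1, d2]))

    def cdf(d, w):
        order = np.argsort(d)
        d, w = d[order], w[order]
        cum = np.cumsum(w) / w.sum()
        idx = np.searchsorted(d, grid, side="right") - 1
        out = np.where(idx >= 0, cum[np.clip(idx, 0, None)], 0.0)
        return out

    return float(np.abs(cdf(d1, w1) - cdf(d2, w2)).max())
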