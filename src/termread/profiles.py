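"""Metagene profiles at poly(A) sites and k-means clustering of convergent pairs.

Metagene rows are genes at least ``min_neighbor_distance`` from their
neighbors (so that signal near the anchor is attributable to the gene
itself), aligned on the poly(A) site and strand-flipped so every row reads
5'->3'.  Convergent gene pairs are clustered on the concatenated
strand-specific profiles of both conditions within a window anchored at
the midpoint of the two partners' poly(A) sites.

The k-means implementation is Lloyd's algorithm with a deterministic
farthest-first cascade: the solution for k centroids is seeded from the
solution for k-1 plus the point farthest from its centroid, guaranteeing
that the within-cluster sum of squares is non-increasing in k, with
optional k-means++ random restarts on top.  Empty clusters are re-seeded
at the point farthest from its assigned centroid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import kmeans_plusplus

from .annotation import Gene, GenomeAnnotation
from .coverage import StrandedCoverage
from .diffexpr import DEResults

logger = logging.getLogger(__name__)


@dataclass
class MetageneMatrix:
    matrix: pd.DataFrame       # rows: genes/pairs, columns: bin offsets (bp, window start-relative)
    flank: int
    bin_size: int
    anchor: str = "polyA"

    @property
    def anchor_column(self) -> int:
        """Index of the first column at/after the anchor."""
        return self.flank // self.bin_size

    @property
    def positions(self) -> np.ndarray:
        """Bin-center offsets relative to the anchor, in bp."""
        n = self.matrix.shape[1]
        return (np.arange(n) + 0.5) * self.bin_size - self.flank


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series
    centroids: np.ndarray
    wcss: float
    cluster_sizes: pd.Series


def _neighbor_gaps(annotation: GenomeAnnotation) -> dict[str, tuple[float, float]]:
    gaps: dict[str, tuple[float, float]] = {}
    for chrom in annotation.chroms():
        genes = annotation.by_chrom(chrom)
        for i, g in enumerate(genes):
            left = g.start - genes[i - 1].end if i > 0 else np.inf
            right = genes[i + 1].start - g.end if i < len(genes) - 1 else np.inf
            gaps[g.gene_id] = (left, right)
    return gaps


def _extract_window(
    coverage: StrandedCoverage, chrom: str, strand: str, start: int, end: int
) -> np.ndarray:
    """Window values on the bin grid; out-of-chromosome bins are NaN."""
    bs = coverage.bin_size
    n_bins = coverage.n_bins(chrom)
    b0, b1 = start // bs, end // bs
    out = np.full(b1 - b0, np.nan)
    lo, hi = max(b0, 0), min(b1, n_bins)
    if hi > lo:
        out[lo - b0 : hi - b0] = coverage.track(chrom, strand)[lo:hi]
    return out


def metagene_matrix(
    coverage: StrandedCoverage,
    annotation: GenomeAnnotation,
    flank: int = 500,
    bin_size: int | None = None,
    min_neighbor_distance: int = 200,
    genes: Sequence[Gene] | None = None,
) -> MetageneMatrix:
    """Per-gene coverage rows over poly(A) +/- ``flank``, oriented 5'->3'.

    Genes closer than ``min_neighbor_distance`` to a neighboring gene (either
    side, either strand) are dropped.  Windows running off a chromosome end
    are padded with NaN.
    """
    bs = bin_size or coverage.bin_size
    if bs != coverage.bin_size:
        raise ValueError("metagene bin size must equal the coverage bin size")
    if flank % bs:
        raise ValueError("flank must be a multiple of the bin size")
    gaps = _neighbor_gaps(annotation)
    rows, index = [], []
    for g in genes if genes is not None else annotation:
        left, right = gaps.get(g.gene_id, (np.inf, np.inf))
        if min(left, right) < min_neighbor_distance:
            continue
        anchor = (g.polya_site // bs) * bs
        row = _extract_window(coverage, g.chrom, g.strand, anchor - flank, anchor + flank)
        if g.strand == "-":
            row = row[::-1]
        rows.append(row)
        index.append(g.gene_id)
    n_cols = 2 * flank // bs
    matrix = pd.DataFrame(
        np.array(rows).reshape(len(rows), n_cols) if rows else np.empty((0, n_cols)),
        index=pd.Index(index, name="gene_id"),
        columns=np.arange(n_cols) * bs,
    )
    return MetageneMatrix(matrix, flank, bs)


def metagene_average(
    mat: MetageneMatrix,
    ci: float = 0.95,
    bootstrap: bool = False,
    n_boot: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Column-wise mean curve with a confidence band across rows.

    Normal-approximation band by default; percentile bootstrap over rows
    with ``bootstrap=True``.  Columns that are all-missing are flagged NaN.
    """
    X = mat.matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows for an average profile")
    mean = np.nanmean(X, axis=0)
    n = np.sum(np.isfinite(X), axis=0)
    if bootstrap:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, X.shape[0], size=(n_boot, X.shape[0]))
        boots = np.nanmean(X[idx], axis=1)
        lo = np.nanquantile(boots, (1 - ci) / 2, axis=0)
        hi = np.nanquantile(boots, 1 - (1 - ci) / 2, axis=0)
    else:
        sem = np.nanstd(X, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
        z = stats.norm.ppf(1 - (1 - ci) / 2)
        lo, hi = mean - z * sem, mean + z * sem
    return pd.DataFrame(
        {"position": mat.positions, "mean": mean, "ci_low": lo, "ci_high": hi,
         "n": n},
    )


# ---------------------------------------------------------------------------
# convergent-pair feature matrix
# ---------------------------------------------------------------------------

def convergent_pair_matrix(
    coverage_by_condition: Mapping[str, StrandedCoverage],
    annotation: GenomeAnnotation,
    flank: int = 500,
    zscore: bool = True,
    anchor: str = "midpoint",
) -> tuple[MetageneMatrix, list[tuple[Gene, Gene]]]:
    """Feature rows for convergent pairs: both strands x both conditions.

    Each row concatenates, for the window anchored at the midpoint between
    the two partners' poly(A) sites (or at the plus-strand partner's
    poly(A) with ``anchor='plus'``), the plus- and minus-strand profiles in
    every condition.  Rows are z-scored by default so clustering groups
    profile *shapes* rather than absolute levels.
    """
    conditions = list(coverage_by_condition)
    pairs = annotation.convergent_pairs()
    any_cov = coverage_by_condition[conditions[0]]
    bs = any_cov.bin_size
    rows, index, kept = [], [], []
    for plus_gene, minus_gene in pairs:
        if anchor == "midpoint":
            center = (plus_gene.polya_site + minus_gene.polya_site) // 2
        elif anchor == "plus":
            center = plus_gene.polya_site
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
        center = (center // bs) * bs
        feats = []
        for cond in conditions:
            cov = coverage_by_condition[cond]
            for strand in "+-":
                feats.append(
                    _extract_window(
                        cov, plus_gene.chrom, strand, center - flank, center + flank
                    )
                )
        row = np.concatenate(feats)
        if not np.all(np.isfinite(row)):
            continue
        rows.append(row)
        index.append(f"{plus_gene.gene_id}|{minus_gene.gene_id}")
        kept.append((plus_gene, minus_gene))
    X = np.array(rows) if rows else np.empty((0, 4 * (2 * flank // bs)))
    if zscore and len(rows):
        mu = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    matrix = pd.DataFrame(X, index=pd.Index(index, name="pair_id"))
    return MetageneMatrix(matrix, flank, bs, anchor="pair-midpoint"), kept


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------

def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int = 300) -> tuple[np.ndarray, np.ndarray, float]:
    centers = centers.copy()
    labels = np.full(X.shape[0], -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        # re-seed empty clusters at the point farthest from its centroid
        for c in range(centers.shape[0]):
            if not np.any(new_labels == c):
                far = d2[np.arange(X.shape[0]), new_labels].argmax()
                centers[c] = X[far]
                new_labels[far] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(centers.shape[0]):
            centers[c] = X[labels == c].mean(axis=0)
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    wcss = float(d2[np.arange(X.shape[0]), labels].sum())
    return labels, centers, wcss


def _maximin_init(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-first seeds, starting nearest the grand mean."""
    mean = X.mean(axis=0)
    first = int(((X - mean) ** 2).sum(axis=1).argmin())
    idx = [first]
    d2 = ((X - X[first]) ** 2).sum(axis=1)
    for _ in range(1, k):
        nxt = int(d2.argmax())
        idx.append(nxt)
        d2 = np.minimum(d2, ((X - X[nxt]) ** 2).sum(axis=1))
    return X[idx].copy()


def _solve_k(X: np.ndarray, k: int, seed: int, n_init: int) -> tuple[np.ndarray, np.ndarray, float]:
    if k == 1:
        c = X.mean(axis=0, keepdims=True)
        return np.zeros(X.shape[0], dtype=int), c, float(((X - c) ** 2).sum())
    # cascade from the k-1 solution: add the worst-fit point as a new seed
    _, prev_centers, _ = _solve_k(X, k - 1, seed, n_init)
    d2 = ((X[:, None, :] - prev_centers[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    cascade_init = np.vstack([prev_centers, X[d2.argmax()]])
    candidates = [_lloyd(X, cascade_init), _lloyd(X, _maximin_init(X, k))]
    # random restarts sample from a canonically sorted copy of the rows, so
    # the chosen partition does not depend on input row order
    canonical = X[np.lexsort(X.T[::-1])]
    rs = np.random.RandomState(seed)
    for _ in range(n_init):
        init, _ = kmeans_plusplus(canonical, n_clusters=k, random_state=rs)
        candidates.append(_lloyd(X, init))
    # strict improvement required to displace the deterministic candidates
    best = candidates[0]
    for cand in candidates[1:]:
        if cand[2] < best[2] * (1 - 1e-12):
            best = cand
    return best


def kmeans_cluster(
    mat: MetageneMatrix | pd.DataFrame | np.ndarray,
    k: int = 4,
    seed: int = 0,
    n_init: int = 10,
) -> ClusterResult:
    """Cluster rows into ``k`` groups; deterministic for a fixed seed.

    Labels are canonicalized by order of first appearance, so equivalent
    partitions of permuted inputs agree up to the row order.
    """
    if isinstance(mat, MetageneMatrix):
        frame = mat.matrix
    elif isinstance(mat, pd.DataFrame):
        frame = mat
    else:
        frame = pd.DataFrame(np.asarray(mat, dtype=float))
    X = frame.to_numpy(dtype=float)
    if k > X.shape[0]:
        raise ValueError("k cannot exceed the number of rows")
    labels, centers, wcss = _solve_k(X, k, seed, n_init)
    # canonical relabeling by first appearance
    remap: dict[int, int] = {}
    for lab in labels:
        if lab not in remap:
            remap[lab] = len(remap)
    canonical = np.array([remap[lab] for lab in labels])
    centers = centers[np.array(sorted(remap, key=remap.get))]
    assignments = pd.Series(canonical, index=frame.index, name="cluster")
    sizes = assignments.value_counts().sort_index()
    return ClusterResult(k, assignments, centers, wcss, sizes)


# ---------------------------------------------------------------------------
# per-cluster partner comparisons
# ---------------------------------------------------------------------------

def boxplot_stats(values: np.ndarray) -> dict[str, float]:
    """Median, quartiles and Tukey outlier count (1.5*IQR whiskers)."""
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    outliers = np.sum((values < q1 - 1.5 * iqr) | (values > q3 + 1.5 * iqr))
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "n_outliers": int(outliers),
        "n": int(values.size),
    }


def cluster_partner_stats(
    deresult: DEResults,
    pairs: Sequence[tuple[Gene, Gene]],
    assignments: pd.Series,
    welch: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per cluster and strand: boxplot summaries and a two-sample t-test.

    Compares the log2 fold-change distributions of the plus- and
    minus-strand partners within each cluster (pooled-variance Student's
    t-test by default, Welch with ``welch=True``).  Clusters with fewer
    than two pairs are skipped.
    """
    lfc = deresult.frame["log2fc"]
    rows, tests = [], []
    for cluster in sorted(assignments.unique()):
        pair_ids = assignments.index[assignments == cluster]
        plus_vals, minus_vals = [], []
        for pid in pair_ids:
            plus_id, minus_id = pid.split("|")
            if plus_id in lfc.index and minus_id in lfc.index:
                plus_vals.append(float(lfc[plus_id]))
                minus_vals.append(float(lfc[minus_id]))
        plus_arr, minus_arr = np.array(plus_vals), np.array(minus_vals)
        if plus_arr.size < 2:
            logger.info("cluster %s has <2 pairs; t-test skipped", cluster)
            continue
        for strand, arr in (("+", plus_arr), ("-", minus_arr)):
            rows.append({"cluster": cluster, "strand": strand, **boxplot_stats(arr)})
        t, p = stats.ttest_ind(plus_arr, minus_arr, equal_var=not welch)
        tests.append(
            {
                "cluster": cluster,
                "t": float(t),
                "p_value": float(p),
                "n_pairs": int(plus_arr.size),
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(tests)


# ---------------------------------------------------------------------------
# plotting
# ---------------------------------------------------------------------------

def plot_metagene(averages: Mapping[str, pd.DataFrame], path=None, ax=None):
    """Overlay mean +/- CI metagene curves per condition; anchor at 0."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    for label, avg in averages.items():
        ax.plot(avg["position"], avg["mean"], label=label)
        ax.fill_between(avg["position"], avg["ci_low"], avg["ci_high"], alpha=0.25)
    ax.axvline(0, color="k", lw=0.8, ls="--")
    ax.set_xlabel("distance from poly(A) site (bp)")
    ax.set_ylabel("signal")
    ax.legend(frameon=False)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
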