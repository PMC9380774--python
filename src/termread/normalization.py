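"""Between-sample normalization anchored on spike-in genes.

Two stages are provided:

* :func:`spikein_size_factors` — a median-of-ratios estimator restricted to
  the spike-in genes.  Because spike-ins are added in fixed proportion per
  sample, their counts trace sequencing depth alone, so the per-sample
  median ratio to the spike-in geometric-mean reference is a size factor
  that is valid even when most biological genes change.
* :func:`ruv_like_factor_removal` — an optional SVD stage that estimates
  unwanted sample-space factors from centered spike-in log-counts and
  regresses them out of every gene, for technical structure that a single
  scale factor cannot capture.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .counts import CountTable

PSEUDOCOUNT = 0.5  # for logs of zero counts


def spikein_size_factors(table: CountTable, rescale: bool = True) -> pd.Series:
    """Per-sample size factors from spike-in median-of-ratios.

    ``factor_s = median_g( count_gs / geomean_g )`` over spike-in genes with
    a positive geometric mean.  With ``rescale`` the factors are divided by
    their own geometric mean, so identical samples get factors of exactly 1.
    """
    spikes = table.spikein_counts().astype(float)
    if (spikes.sum(axis=0) == 0).any():
        bad = spikes.columns[spikes.sum(axis=0) == 0].tolist()
        raise ValueError(f"all spike-in counts are zero in sample(s) {bad}")
    logs = np.log(spikes.where(spikes > 0))
    log_geomean = logs.mean(axis=1)
    usable = log_geomean.notna() & np.isfinite(log_geomean)
    if not usable.any():
        raise ValueError("no spike-in gene has positive counts in every sample")
    ratios = np.log(spikes.loc[usable]).sub(log_geomean[usable], axis=0)
    factors = np.exp(ratios.median(axis=0))
    if rescale:
        factors = factors / np.exp(np.log(factors).mean())
    factors.name = "size_factor"
    return factors


def normalize_counts(table: CountTable) -> CountTable:
    """Attach spike-in size factors to the table."""
    return table.with_size_factors(spikein_size_factors(table))


def ruv_like_factor_removal(
    log_table: pd.DataFrame,
    spikein_mask: np.ndarray | pd.Series,
    n_factors: int,
) -> pd.DataFrame:
    """Remove SVD-estimated unwanted variation, learned on spike-ins only.

    ``log_table`` is a genes x samples matrix of log-scale normalized
    counts.  The top ``n_factors`` right-singular vectors of the row-centered
    spike-in submatrix define sample-space directions of unwanted variation;
    every gene's centered profile is projected off that span.  With
    ``n_factors=0``, or spike-ins carrying no between-sample variance, the
    transformation is the identity.
    """
    n_samples = log_table.shape[1]
    if n_factors >= n_samples:
        raise ValueError("n_factors must be smaller than the number of samples")
    if n_factors == 0:
        return log_table.copy()
    spikes = log_table.loc[np.asarray(spikein_mask, dtype=bool)]
    centered = spikes.sub(spikes.mean(axis=1), axis=0)
    if np.allclose(centered.values, 0.0):
        return log_table.copy()
    _, s, vt = np.linalg.svd(centered.values, full_matrices=False)
    keep = min(n_factors, int(np.sum(s > 1e-12 * s[0])))
    if keep == 0:
        return log_table.copy()
    W = vt[:keep].T  # samples x keep, orthonormal
    row_means = log_table.mean(axis=1)
    centered_all = log_table.sub(row_means, axis=0).values
    adjusted = centered_all - centered_all @ W @ W.T
    return pd.DataFrame(
        adjusted, index=log_table.index, columns=log_table.columns
    ).add(row_means, axis=0)


def log_normalized(table: CountTable, pseudocount: float = PSEUDOCOUNT) -> pd.DataFrame:
    """log2 of size-factor-normalized counts with a pseudocount."""
    return np.log2(table.normalized() + pseudocount)
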