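"""Opposite-strand and gene-orientation statistics for readthrough data.

When termination fails, polymerases run past the poly(A) site into
neighboring territory.  On the same strand this inflates the signal of the
next codirectional gene; on the opposite strand the invading polymerase
suppresses initiation of convergent neighbors (transcription interference).
The statistics here quantify both signatures:

* strand-paired log2 fold changes per gene and per genome-tiling 1-kb
  window, and their (anti)correlation;
* a chi-square test of independence between the per-gene direction of
  change and the gene's local orientation class;
* a readthrough index normalizing the downstream-of-poly(A) fold change to
  the fold change of the 1-kb genic region upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import CHROMOSOME_END, GenomeAnnotation
from .coverage import StrandedCoverage
from .diffexpr import DEResults, NS
from .normalization import PSEUDOCOUNT

logger = logging.getLogger(__name__)


@dataclass
class StrandPairSet:
    """Positionally matched (own, opposite) log2 fold-change pairs."""

    pairs: pd.DataFrame  # columns: own, opposite (+ metadata columns)
    kind: str = "gene"   # "gene" or "window"
    excluded: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    chi2: float
    dof: int
    p_value: float
    expected: pd.DataFrame
    residuals: pd.DataFrame  # standardized residuals
    exact_fallback: bool = False


def _interval_fc(
    cov_t: StrandedCoverage,
    cov_c: StrandedCoverage,
    chrom: str,
    strand: str,
    start: int,
    end: int,
    pseudocount: float,
) -> float:
    a = cov_t.interval_sum(chrom, strand, start, end)
    b = cov_c.interval_sum(chrom, strand, start, end)
    return float(np.log2((a + pseudocount) / (b + pseudocount)))


def opposite_strand_pairs(
    deresult: DEResults,
    annotation: GenomeAnnotation,
    coverage_by_condition: Mapping[str, StrandedCoverage],
    pseudocount: float = PSEUDOCOUNT,
) -> StrandPairSet:
    """Pair each gene's own log2FC with the opposite-strand change over its interval.

    The opposite value is the log2 ratio (treated vs control, with
    pseudocount) of normalized opposite-strand signal summed over the gene's
    own genomic interval.  Genes whose interval lies outside the coverage
    grid are excluded and logged.
    """
    cov_t = coverage_by_condition[deresult.treated]
    cov_c = coverage_by_condition[deresult.control]
    rows, excluded = [], []
    for g in annotation:
        if g.gene_id not in deresult.frame.index:
            continue
        opp = "-" if g.strand == "+" else "+"
        if (g.chrom, opp) not in cov_t.values or cov_t.interval_values(
            g.chrom, opp, g.start, g.end
        ).size == 0:
            excluded.append(g.gene_id)
            continue
        rows.append(
            (
                g.gene_id,
                g.strand,
                float(deresult.frame.loc[g.gene_id, "log2fc"]),
                _interval_fc(cov_t, cov_c, g.chrom, opp, g.start, g.end, pseudocount),
            )
        )
    if excluded:
        logger.info("opposite_strand_pairs: excluded %d gene(s): %s",
                    len(excluded), ", ".join(excluded[:10]))
    pairs = pd.DataFrame(rows, columns=["gene_id", "strand", "own", "opposite"])
    return StrandPairSet(pairs.set_index("gene_id"), kind="gene", excluded=excluded)


def ground_truth_pairs(
    annotation: GenomeAnnotation,
    expected_by_condition: Mapping[str, StrandedCoverage],
    truth_by_condition: Mapping[str, "pd.DataFrame"],
    treated: str,
    control: str,
    pseudocount: float = PSEUDOCOUNT,
) -> StrandPairSet:
    """Strand pairs built from the generator's latent state, free of count noise.

    Own value is the true effective-expression log2 change; opposite value
    is the log2 change of noise-free opposite-strand signal over the gene's
    interval.  This is the oracle pairing against which the observed-data
    anticorrelation is judged.
    """
    t_truth, c_truth = truth_by_condition[treated], truth_by_condition[control]
    cov_t, cov_c = expected_by_condition[treated], expected_by_condition[control]
    rows = []
    for g in annotation:
        if g.gene_id not in t_truth.index:
            continue
        own = float(
            np.log2(
                t_truth.loc[g.gene_id, "e_effective"]
                / c_truth.loc[g.gene_id, "e_effective"]
            )
        )
        opp = "-" if g.strand == "+" else "+"
        rows.append(
            (
                g.gene_id,
                g.strand,
                own,
                _interval_fc(cov_t, cov_c, g.chrom, opp, g.start, g.end, pseudocount),
            )
        )
    pairs = pd.DataFrame(rows, columns=["gene_id", "strand", "own", "opposite"])
    return StrandPairSet(pairs.set_index("gene_id"), kind="gene-truth")


def window_pairs(
    coverage_by_condition: Mapping[str, StrandedCoverage],
    treated: str,
    control: str,
    window: int = 1000,
    pseudocount: float = PSEUDOCOUNT,
) -> StrandPairSet:
    """Per non-overlapping genome tile, the (plus, minus) log2FC pair.

    Tiles are ``window`` bp wide; a chromosome shorter than the window
    yields a single truncated tile.
    """
    cov_t, cov_c = coverage_by_condition[treated], coverage_by_condition[control]
    rows = []
    for chrom in cov_t.chroms():
        length = cov_t.n_bins(chrom) * cov_t.bin_size
        n_tiles = max(1, -(-length // window))
        for i in range(n_tiles):
            start, end = i * window, min(length, (i + 1) * window)
            rows.append(
                (
                    chrom,
                    start,
                    _interval_fc(cov_t, cov_c, chrom, "+", start, end, pseudocount),
                    _interval_fc(cov_t, cov_c, chrom, "-", start, end, pseudocount),
                )
            )
    pairs = pd.DataFrame(rows, columns=["chrom", "start", "own", "opposite"])
    return StrandPairSet(pairs, kind="window")


def anticorrelation(
    pairs: StrandPairSet, method: str = "pearson"
) -> tuple[float, float]:
    """Correlation between paired strand-specific changes, with two-sided p."""
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs")
    x = pairs.pairs["own"].to_numpy(dtype=float)
    y = pairs.pairs["opposite"].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one strand's changes; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return float(r), float(p)


def classify_orientation(
    annotation: GenomeAnnotation, oriented: bool = False
) -> pd.Series:
    """Per-gene orientation class from its two flanking junctions.

    Default: the unordered pair of flanking relations, e.g.
    ``codirectional|convergent`` (sorted alphabetically) — genes at a
    chromosome boundary include ``chromosome-end``.  With ``oriented=True``
    the class is the relation at the gene's 5' (upstream) junction only,
    which is what separates genes that *receive* codirectional readthrough
    from those that do not.
    """
    flanks = annotation.flanking_relations(mirror=oriented)
    if oriented:
        classes = {gid: f"5p-{rel[0]}" for gid, rel in flanks.items()}
    else:
        classes = {gid: "|".join(sorted(rel)) for gid, rel in flanks.items()}
    s = pd.Series(classes, name="orientation_class")
    s.index.name = "gene_id"
    return s


def orientation_chi2(
    directions: pd.Series,
    classes: pd.Series,
    include_ns: bool = False,
    min_class_n: int = 1,
) -> ContingencyResult:
    """Chi-square test of independence: direction of change x orientation class.

    By default only significant genes (``up`` / ``down``) enter the table.
    Standardized residuals ``(O - E) / sqrt(E (1 - r/n)(1 - c/n))`` carry the
    direction of association.  If any expected cell is below 1 the Pearson
    statistic is unreliable; the result is flagged and, for 2x2 tables,
    Fisher's exact p-value is substituted.
    """
    df = pd.concat([directions.rename("direction"), classes.rename("klass")], axis=1)
    df = df.dropna()
    if not include_ns:
        df = df[df["direction"] != NS]
    observed = pd.crosstab(df["direction"], df["klass"])
    observed = observed.loc[:, observed.sum(axis=0) >= min_class_n]
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        raise ValueError("need >=2 direction classes and >=2 orientation classes")
    chi2, p, dof, expected = stats.chi2_contingency(observed.values, correction=False)
    expected = pd.DataFrame(expected, index=observed.index, columns=observed.columns)
    n = observed.values.sum()
    row_frac = observed.sum(axis=1).values[:, None] / n
    col_frac = observed.sum(axis=0).values[None, :] / n
    resid = (observed.values - expected.values) / np.sqrt(
        expected.values * (1 - row_frac) * (1 - col_frac)
    )
    residuals = pd.DataFrame(resid, index=observed.index, columns=observed.columns)
    fallback = bool((expected.values < 1).any())
    if fallback and observed.shape == (2, 2):
        _, p = stats.fisher_exact(observed.values)
    return ContingencyResult(
        observed, float(chi2), int(dof), float(p), expected, residuals, fallback
    )


def readthrough_index(
    coverage_by_condition: Mapping[str, StrandedCoverage],
    annotation: GenomeAnnotation,
    treated: str,
    control: str,
    downstream_window: int = 500,
    upstream_window: int = 1000,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.Series:
    """FC(downstream of poly(A)) / FC(1-kb genic region upstream), per gene.

    Strand-aware: for minus-strand genes the downstream window extends to
    lower coordinates.  Genes with zero upstream signal in either condition
    get NaN (flagged undefined).
    """
    cov_t, cov_c = coverage_by_condition[treated], coverage_by_condition[control]
    out = {}
    for g in annotation:
        if g.strand == "+":
            dw = (g.polya_site, g.polya_site + downstream_window)
            uw = (max(0, g.polya_site - upstream_window), g.polya_site)
        else:
            dw = (max(0, g.polya_site - downstream_window), g.polya_site)
            uw = (g.polya_site, g.polya_site + upstream_window)
        up_t = cov_t.interval_sum(g.chrom, g.strand, *uw)
        up_c = cov_c.interval_sum(g.chrom, g.strand, *uw)
        if up_t == 0 or up_c == 0:
            out[g.gene_id] = np.nan
            continue
        fc_down = (cov_t.interval_sum(g.chrom, g.strand, *dw) + pseudocount) / (
            cov_c.interval_sum(g.chrom, g.strand, *dw) + pseudocount
        )
        fc_up = up_t / up_c
        out[g.gene_id] = fc_down / fc_up
    s = pd.Series(out, name="readthrough_index")
    s.index.name = "gene_id"
    return s
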