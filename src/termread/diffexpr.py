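"""Strand-specific per-gene differential expression between two conditions.

The test is a Wald test on the difference of log mean normalized counts
under a negative-binomial noise model: for gene *g* and condition *c* with
``n_c`` replicates and normalized mean ``m_gc``,

    Var(log m_gc)  ~=  (1/m_gc + phi_g) / n_c

where ``phi_g`` is a per-gene method-of-moments dispersion shrunk toward
the across-genes mean (an empirical-Bayes-style stabilization that matters
at two or three replicates).  P-values come from the standard normal,
multiple testing is Benjamini-Hochberg, and direction calls are ``up`` /
``down`` among genes at FDR < alpha, ``ns`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .counts import CountTable
from .normalization import PSEUDOCOUNT, spikein_size_factors

UP, DOWN, NS = "up", "down", "ns"

#: prior degrees of freedom pulling per-gene dispersions to the global mean
DISPERSION_PRIOR_DF = 10.0


def gene_log2fc(
    normalized: pd.DataFrame,
    conditions: dict[str, str],
    treated: str,
    control: str,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.Series:
    """log2((mean_treated + p) / (mean_control + p)) per gene."""
    for cond in (treated, control):
        if cond not in conditions.values():
            raise ValueError(f"condition {cond!r} missing from the table")
    t_cols = [s for s, c in conditions.items() if c == treated]
    c_cols = [s for s, c in conditions.items() if c == control]
    lfc = np.log2(
        (normalized[t_cols].mean(axis=1) + pseudocount)
        / (normalized[c_cols].mean(axis=1) + pseudocount)
    )
    lfc.name = "log2fc"
    return lfc


def _mom_dispersions(normalized: pd.DataFrame, groups: list[list[str]]) -> pd.Series:
    """Pooled within-condition method-of-moments NB dispersion per gene."""
    num = pd.Series(0.0, index=normalized.index)
    den = 0
    grand = normalized.mean(axis=1)
    excess = pd.Series(0.0, index=normalized.index)
    for cols in groups:
        if len(cols) < 2:
            continue
        m = normalized[cols].mean(axis=1)
        v = normalized[cols].var(axis=1, ddof=1)
        excess += (v - m) * (len(cols) - 1)
        num += (m**2) * (len(cols) - 1)
        den += len(cols) - 1
    if den == 0:
        return pd.Series(np.nan, index=normalized.index)
    phi = (excess / num.replace(0.0, np.nan)).clip(lower=0.0)
    phi[grand <= 0] = np.nan
    return phi


def shrink_dispersions(phi: pd.Series, prior_df: float = DISPERSION_PRIOR_DF, residual_df: float = 2.0) -> pd.Series:
    """Shrink per-gene dispersions toward the global mean trend."""
    global_phi = float(np.nanmean(phi))
    if not np.isfinite(global_phi):
        global_phi = 0.0
    shrunk = (residual_df * phi.fillna(global_phi) + prior_df * global_phi) / (
        residual_df + prior_df
    )
    return shrunk.clip(lower=1e-8)


def bh_fdr(pvalues: np.ndarray | pd.Series, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg adjusted p-values and rejection calls at ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    ok = np.isfinite(p)
    adj = np.full_like(p, np.nan)
    reject = np.zeros(p.size, dtype=bool)
    if ok.any():
        reject[ok], adj[ok], _, _ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
    return adj, reject


def nb_test(
    normalized: pd.DataFrame,
    conditions: dict[str, str],
    treated: str,
    control: str,
    pseudocount: float = PSEUDOCOUNT,
    dispersion_prior_df: float = DISPERSION_PRIOR_DF,
) -> pd.DataFrame:
    """Wald test per gene; returns log2fc, se, stat and p_value columns."""
    t_cols = [s for s, c in conditions.items() if c == treated]
    c_cols = [s for s, c in conditions.items() if c == control]
    if not t_cols or not c_cols:
        raise ValueError("both conditions need at least one sample")
    lfc = gene_log2fc(normalized, conditions, treated, control, pseudocount)
    if len(t_cols) < 2 or len(c_cols) < 2:
        raise ValueError(
            "p-values need >=2 replicates per condition; use gene_log2fc alone"
        )
    phi = _mom_dispersions(normalized, [t_cols, c_cols])
    residual_df = float(len(t_cols) + len(c_cols) - 2)
    phi = shrink_dispersions(phi, dispersion_prior_df, residual_df)

    m_t = normalized[t_cols].mean(axis=1) + pseudocount
    m_c = normalized[c_cols].mean(axis=1) + pseudocount
    var_log = (1.0 / m_t + phi) / len(t_cols) + (1.0 / m_c + phi) / len(c_cols)
    se = np.sqrt(var_log) / np.log(2.0)  # on the log2 scale
    stat = lfc / se
    # moderated-t reference: the shrunken dispersion carries residual_df
    # real plus dispersion_prior_df borrowed degrees of freedom; a normal
    # reference is too light-tailed deep out at 2-3 replicates
    p = 2.0 * stats.t.sf(np.abs(stat), df=residual_df + dispersion_prior_df)
    return pd.DataFrame(
        {
            "log2fc": lfc,
            "se": se,
            "stat": stat,
            "p_value": p,
            "dispersion": phi,
        }
    )


@dataclass
class DEResults:
    """Per-gene fold changes, significance and direction calls."""

    frame: pd.DataFrame  # log2fc, se, stat, p_value, padj, direction
    alpha: float
    treated: str
    control: str

    @property
    def log2fc(self) -> pd.Series:
        return self.frame["log2fc"]

    @property
    def direction(self) -> pd.Series:
        return self.frame["direction"]

    def significant(self) -> pd.DataFrame:
        return self.frame[self.frame["direction"] != NS]

    def n_up(self) -> int:
        return int((self.frame["direction"] == UP).sum())

    def n_down(self) -> int:
        return int((self.frame["direction"] == DOWN).sum())

    def summary(self) -> str:
        lines = [
            f"Differential expression: {self.treated} vs {self.control}",
            f"genes tested: {len(self.frame)}",
            f"FDR alpha:    {self.alpha}",
            f"up:           {self.n_up()}",
            f"down:         {self.n_down()}",
            f"ns:           {int((self.frame['direction'] == NS).sum())}",
        ]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")


class DifferentialExpression:
    """Model object: NB Wald differential expression on a count table.

    Parameters
    ----------
    table : CountTable
        Gene x sample counts; if size factors are absent they are computed
        from the spike-ins at fit time.  Spike-in genes are excluded from
        testing but retained for normalization.
    treated, control : str
        Condition labels; default to the table's second and first condition.
    """

    def __init__(
        self,
        table: CountTable,
        treated: str | None = None,
        control: str | None = None,
    ) -> None:
        conds = table.condition_names()
        if len(conds) < 2 and (treated is None or control is None):
            raise ValueError("need two conditions for differential expression")
        self.table = table
        self.control = control if control is not None else conds[0]
        self.treated = treated if treated is not None else conds[1]

    def fit(
        self,
        alpha: float = 0.05,
        pseudocount: float = PSEUDOCOUNT,
        dispersion_prior_df: float = DISPERSION_PRIOR_DF,
    ) -> DEResults:
        table = self.table
        if table.size_factors is None:
            table = table.with_size_factors(spikein_size_factors(table))
        normalized = table.normalized()
        mask = ~table.meta["is_spikein"].values
        normalized = normalized.loc[mask]
        conditions = {
            s: c
            for s, c in table.conditions.items()
            if c in (self.treated, self.control)
        }
        n_t = sum(c == self.treated for c in conditions.values())
        n_c = sum(c == self.control for c in conditions.values())
        if min(n_t, n_c) < 2:
            # single replicate: fold changes only, no inference
            lfc = gene_log2fc(
                normalized, conditions, self.treated, self.control, pseudocount
            )
            frame = pd.DataFrame(
                {
                    "log2fc": lfc,
                    "se": np.nan,
                    "stat": np.nan,
                    "p_value": np.nan,
                    "padj": np.nan,
                    "direction": NS,
                }
            )
            return DEResults(frame, alpha, self.treated, self.control)
        frame = nb_test(
            normalized, conditions, self.treated, self.control, pseudocount,
            dispersion_prior_df,
        )
        padj, reject = bh_fdr(frame["p_value"].values, alpha)
        frame["padj"] = padj
        direction = np.where(
            reject & (frame["log2fc"] > 0),
            UP,
            np.where(reject & (frame["log2fc"] < 0), DOWN, NS),
        )
        frame["direction"] = direction
        return DEResults(frame, alpha, self.treated, self.control)
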