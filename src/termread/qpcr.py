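"""Spike-in-normalized ddCt quantification of qPCR data.

Each Ct is normalized to the mean Ct of a fixed set of spike-in amplicons
measured in the same condition and replicate (dCt = Ct_i - Ct_spike-in);
the fold change between treated and untreated conditions is
``FC = E^-(ddCt)`` with ``ddCt = dCt_treated - dCt_control`` and perfect
amplification efficiency E = 2 by default.  The readthrough level of a
gene is the fold change at a position downstream of the poly(A) site
normalized to the fold change of the genic region 1 kb upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .simulate import MINUS_AUXIN, PLUS_AUXIN


@dataclass
class QpcrTable:
    """Tidy Ct measurements: amplicon, condition, fraction, replicate, ct."""

    frame: pd.DataFrame
    spike_amplicons: tuple[str, ...]

    REQUIRED = ("amplicon", "condition", "replicate", "ct")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"qPCR table missing columns {missing}")
        if not self.spike_amplicons:
            raise ValueError("spike-in amplicon set must be non-empty")
        if (self.frame["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        if "fraction" not in self.frame.columns:
            self.frame = self.frame.assign(fraction="nascent")

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.frame["condition"]:
            seen.setdefault(c, None)
        return list(seen)

    @classmethod
    def from_csv(cls, path: str | Path, spike_amplicons: Sequence[str]) -> "QpcrTable":
        return cls(pd.read_csv(path), tuple(spike_amplicons))

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def spike_ct(table: QpcrTable) -> pd.Series:
    """Mean spike-in Ct per (condition, fraction, replicate).

    Every spike amplicon must be measured in every group; a missing one
    raises, because a silently shifting spike set would bias all dCts.
    """
    spikes = table.frame[table.frame["amplicon"].isin(table.spike_amplicons)]
    grouped = spikes.groupby(["condition", "fraction", "replicate"])
    for key, grp in grouped:
        present = set(grp["amplicon"])
        missing = set(table.spike_amplicons) - present
        if missing:
            raise ValueError(f"spike amplicon(s) {sorted(missing)} missing in group {key}")
    out = grouped["ct"].mean()
    out.name = "ct_spikein"
    return out


def delta_ct(table: QpcrTable) -> pd.DataFrame:
    """Per-measurement dCt = Ct - Ct_spike-in of the matching group."""
    ref = spike_ct(table)
    df = table.frame[~table.frame["amplicon"].isin(table.spike_amplicons)].copy()
    key = pd.MultiIndex.from_frame(df[["condition", "fraction", "replicate"]])
    df["delta_ct"] = df["ct"].to_numpy() - ref.loc[key].to_numpy()
    return df


def fold_change(
    table: QpcrTable,
    treated: str = PLUS_AUXIN,
    control: str = MINUS_AUXIN,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-amplicon (and fraction) fold change ``E^-(ddCt)``.

    dCts are averaged over replicates within each condition before the
    difference is taken.
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    df = delta_ct(table)
    for cond in (treated, control):
        if cond not in set(df["condition"]):
            raise ValueError(f"condition {cond!r} missing from the table")
    mean_dct = (
        df.groupby(["amplicon", "fraction", "condition"])["delta_ct"].mean().unstack()
    )
    ddct = mean_dct[treated] - mean_dct[control]
    out = ddct.rename("delta_delta_ct").to_frame()
    out["fold_change"] = efficiency ** (-out["delta_delta_ct"])
    return out.reset_index()


def readthrough_level(fc_downstream: float, fc_upstream_1kb: float) -> float:
    """Downstream fold change normalized to the genic fold change 1 kb upstream."""
    if fc_downstream <= 0 or fc_upstream_1kb <= 0:
        raise ValueError("fold changes must be positive")
    return fc_downstream / fc_upstream_1kb


def readthrough_levels(
    fc_table: pd.DataFrame, pairs: dict[str, tuple[str, str]]
) -> pd.Series:
    """Readthrough levels for named (downstream, upstream) amplicon pairs."""
    fc = fc_table.set_index("amplicon")["fold_change"]
    out = {
        gene: readthrough_level(float(fc[down]), float(fc[up]))
        for gene, (down, up) in pairs.items()
    }
    s = pd.Series(out, name="readthrough_level")
    s.index.name = "gene"
    return s
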