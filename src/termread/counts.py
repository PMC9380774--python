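"""Gene-by-sample count tables with condition labels and spike-in flags.

On disk the table is a TSV with columns ``gene_id, chrom, strand,
is_spikein`` followed by one integer column per sample.  Sample names follow
``{condition}_rep{i}``, from which the condition map is recovered on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


def condition_of(sample: str) -> str:
    if "_rep" not in sample:
        raise ValueError(f"sample name {sample!r} does not follow '<condition>_rep<i>'")
    return sample.rsplit("_rep", 1)[0]


@dataclass
class CountTable:
    counts: pd.DataFrame           # genes x samples, integer
    meta: pd.DataFrame             # gene_id-indexed: chrom, strand, is_spikein
    conditions: dict[str, str]     # sample -> condition
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.meta["is_spikein"].any():
            raise ValueError("count table must contain at least one spike-in gene")
        if set(self.counts.columns) != set(self.conditions):
            raise ValueError("condition map does not match sample columns")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValueError("size factors must be positive")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions[s] == condition]

    def condition_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.conditions[s], None)
        return list(seen)

    def spikein_counts(self) -> pd.DataFrame:
        return self.counts.loc[self.meta["is_spikein"].values]

    def gene_counts(self) -> pd.DataFrame:
        """Counts of the biological (non-spike-in) genes."""
        return self.counts.loc[~self.meta["is_spikein"].values]

    def normalized(self) -> pd.DataFrame:
        """Counts divided by per-sample size factors (requires normalization)."""
        if self.size_factors is None:
            raise ValueError("size factors not set; run spike-in normalization first")
        return self.counts / self.size_factors

    def with_size_factors(self, factors: pd.Series) -> "CountTable":
        return CountTable(self.counts, self.meta, dict(self.conditions), factors)


def write_counts(table: CountTable, path: str | Path) -> None:
    out = table.meta.copy()
    out.insert(2, "is_spikein", out.pop("is_spikein").astype(int))
    df = pd.concat([out, table.counts], axis=1)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts(path: str | Path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    meta_cols = ["chrom", "strand", "is_spikein"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    meta = df[meta_cols].copy()
    meta["is_spikein"] = meta["is_spikein"].astype(bool)
    counts = df.drop(columns=meta_cols)
    counts = counts.astype(int)
    conditions = {s: condition_of(s) for s in counts.columns}
    return CountTable(counts, meta, conditions)
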