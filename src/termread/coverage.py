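"""Strand-split binned coverage tracks and bedGraph text IO.

A :class:`StrandedCoverage` stores one float array per ``(chrom, strand)``
on a common bin grid (default 10 bp).  Tracks are either ``raw`` (arbitrary
signal units) or ``CPM`` (counts per million: every bin scaled so that the
grand total over all bins of both strands is 1e6).  Smoothing is a centered
running mean over a window of ``smooth_length`` base pairs, mirroring the
common genome-browser preprocessing of nascent RNA-seq tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

RAW = "raw"
CPM = "CPM"


@dataclass
class StrandedCoverage:
    bin_size: int
    values: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    normalization: str = RAW

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.normalization not in (RAW, CPM):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        for key, arr in list(self.values.items()):
            arr = np.asarray(arr, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite coverage values on {key}")
            self.values[key] = arr
        self._sync_grids()

    def _sync_grids(self) -> None:
        # both strands of a chromosome share one bin grid
        for chrom in self.chroms():
            n = max(
                self.values[(chrom, s)].size
                for s in "+-"
                if (chrom, s) in self.values
            )
            for s in "+-":
                if (chrom, s) in self.values:
                    arr = self.values[(chrom, s)]
                    if arr.size < n:
                        self.values[(chrom, s)] = np.pad(arr, (0, n - arr.size))
                else:
                    self.values[(chrom, s)] = np.zeros(n)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for chrom, _ in self.values:
            seen.setdefault(chrom, None)
        return list(seen)

    def n_bins(self, chrom: str) -> int:
        return self.values[(chrom, "+")].size

    def track(self, chrom: str, strand: str) -> np.ndarray:
        return self.values[(chrom, strand)]

    def total(self) -> float:
        """Sum of bin values over all chromosomes and both strands."""
        return float(sum(arr.sum() for arr in self.values.values()))

    def interval_values(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Bin values overlapping [start, end); out-of-range bins are dropped."""
        b0 = max(0, start // self.bin_size)
        b1 = min(self.n_bins(chrom), -(-end // self.bin_size))
        return self.track(chrom, strand)[b0:b1]

    def interval_sum(self, chrom: str, strand: str, start: int, end: int) -> float:
        return float(self.interval_values(chrom, strand, start, end).sum())

    def copy(self) -> "StrandedCoverage":
        return StrandedCoverage(
            self.bin_size,
            {k: v.copy() for k, v in self.values.items()},
            self.normalization,
        )


def mean_coverage(tracks: list["StrandedCoverage"]) -> "StrandedCoverage":
    """Bin-wise mean of replicate tracks sharing one grid and normalization."""
    if not tracks:
        raise ValueError("no tracks to pool")
    first = tracks[0]
    if any(t.bin_size != first.bin_size or t.normalization != first.normalization for t in tracks):
        raise ValueError("tracks must share bin size and normalization")
    values = {
        key: np.mean([t.values[key] for t in tracks], axis=0)
        for key in first.values
    }
    return StrandedCoverage(first.bin_size, values, first.normalization)


# ---------------------------------------------------------------------------
# smoothing + CPM
# ---------------------------------------------------------------------------

def smooth_and_bin(
    coverage: StrandedCoverage,
    bin_size: int = 10,
    smooth_length: int = 20,
    normalize: bool = True,
) -> StrandedCoverage:
    """Rebin, smooth with a running mean, and optionally scale to CPM.

    ``smooth_length`` must be at least ``bin_size``; the running-mean window
    is ``smooth_length // bin_size`` bins.  For an even window the extra bin
    is taken downstream, so an impulse smoothed with a 2-bin window spreads
    half its mass into the preceding bin.  CPM scaling divides by the grand
    total over both strands, so the scaled track sums to 1e6.
    """
    if smooth_length < bin_size:
        raise ValueError("smooth_length must be >= bin_size")
    if bin_size % coverage.bin_size:
        raise ValueError("bin_size must be a multiple of the input bin size")
    if not coverage.values or coverage.total() == 0:
        raise ValueError("empty coverage track")

    factor = bin_size // coverage.bin_size
    window = max(1, smooth_length // bin_size)
    out: dict[tuple[str, str], np.ndarray] = {}
    for key, arr in coverage.values.items():
        if factor > 1:
            pad = (-arr.size) % factor
            arr = np.pad(arr, (0, pad)).reshape(-1, factor).mean(axis=1)
        out[key] = _running_mean(arr, window)

    result = StrandedCoverage(bin_size, out, RAW)
    if normalize:
        total = result.total()
        if total == 0:
            raise ValueError("empty coverage track")
        for key in result.values:
            result.values[key] = result.values[key] * (1e6 / total)
        result.normalization = CPM
    return result


def _running_mean(arr: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return arr.astype(float)
    # centered window; even windows extend one bin further downstream
    left = (window - 1) // 2
    padded = np.pad(arr.astype(float), (left, window - 1 - left), mode="edge")
    csum = np.concatenate(([0.0], np.cumsum(padded)))
    return (csum[window:] - csum[:-window]) / window


# ---------------------------------------------------------------------------
# bedGraph text IO (one file per strand)
# ---------------------------------------------------------------------------

def strand_paths(prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    return (
        prefix.with_suffix(".plus.bedgraph"),
        prefix.with_suffix(".minus.bedgraph"),
    )


def write_bedgraph(coverage: StrandedCoverage, prefix: str | Path) -> tuple[Path, Path]:
    """Write strand-split bedGraph files; equal adjacent bins are run-length merged."""
    plus_path, minus_path = strand_paths(prefix)
    for strand, path in (("+", plus_path), ("-", minus_path)):
        with open(path, "w") as fh:
            for chrom in coverage.chroms():
                arr = coverage.track(chrom, strand)
                if arr.size == 0:
                    continue
                # run-length encode
                change = np.flatnonzero(np.diff(arr)) + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [arr.size]))
                for b0, b1 in zip(starts, ends):
                    v = arr[b0]
                    if v == 0:
                        continue
                    fh.write(
                        f"{chrom}\t{b0 * coverage.bin_size}\t{b1 * coverage.bin_size}\t{v:.8g}\n"
                    )
    return plus_path, minus_path


def read_bedgraph(
    plus_path: str | Path,
    minus_path: str | Path,
    bin_size: int = 10,
    normalization: str = RAW,
    chrom_lengths: dict[str, int] | None = None,
) -> StrandedCoverage:
    """Read two strand-split bedGraph files onto a common bin grid.

    Intervals must be sorted and non-overlapping within each chromosome;
    violations raise with the offending line number.  Interval boundaries
    not aligned to the grid contribute their overlap-weighted mean.
    """
    raw: dict[tuple[str, str], dict[str, list]] = {}
    maxend: dict[str, int] = dict(chrom_lengths or {})
    for strand, path in (("+", plus_path), ("-", minus_path)):
        last: dict[str, int] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 bedGraph fields")
                chrom, s, e, v = fields
                start, end, value = int(s), int(e), float(v)
                if end <= start:
                    raise ValueError(f"{path}:{lineno}: empty interval")
                if chrom in last and start < last[chrom]:
                    raise ValueError(
                        f"{path}:{lineno}: unsorted or overlapping interval on {chrom}"
                    )
                last[chrom] = end
                maxend[chrom] = max(maxend.get(chrom, 0), end)
                rec = raw.setdefault((chrom, strand), {"start": [], "end": [], "value": []})
                rec["start"].append(start)
                rec["end"].append(end)
                rec["value"].append(value)

    values: dict[tuple[str, str], np.ndarray] = {}
    for chrom, length in maxend.items():
        n_bins = -(-length // bin_size)
        for strand in "+-":
            arr = np.zeros(n_bins)
            rec = raw.get((chrom, strand))
            if rec:
                for start, end, value in zip(rec["start"], rec["end"], rec["value"]):
                    b0, b1 = start // bin_size, -(-end // bin_size)
                    for b in range(b0, b1):
                        lo = max(start, b * bin_size)
                        hi = min(end, (b + 1) * bin_size)
                        arr[b] += value * (hi - lo) / bin_size
            values[(chrom, strand)] = arr
    return StrandedCoverage(bin_size, values, normalization)
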