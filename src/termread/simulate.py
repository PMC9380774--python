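"""Synthetic nascent RNA-seq data with known ground truth.

The generator emulates the study design the analysis pipeline was built
for: a compact genome of closely packed genes in codirectional, convergent
and divergent arrangements; two conditions, one with a functional 3'-end
processing machinery (low termination failure) and one where the machinery
is depleted (high termination failure); strand-specific coverage in which
failed termination produces exponentially decaying readthrough signal past
the poly(A) site; transcription interference that suppresses initiation of
genes whose promoters are overrun by opposite-strand readthrough;
condition-invariant spike-in genes on a dedicated chromosome; and
negative-binomial count noise.

The model, per gene *i* with baseline expression ``e_i`` (log-normal):

* gene-body signal per bin is the effective expression ``e'_i``;
* readthrough signal at distance ``d`` past the poly(A) site is
  ``e_i * f * exp(-d / L)`` on the gene's own strand, where ``f`` is the
  condition's termination-failure fraction and ``L`` the decay length;
* interference input ``I_j`` is the mean opposite-strand readthrough over
  the promoter window (TSS +/- 100 bp), and ``e'_j = e_j / (1 + alpha*I_j)``
  in a single pass from the baselines (no fixed-point iteration).

Everything is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import Gene, GenomeAnnotation
from .coverage import RAW, StrandedCoverage
from .counts import CountTable

MAIN_CHROM = "chrI"
SPIKE_CHROM = "spikein"
PROMOTER_HALF_WINDOW = 100  # bp either side of the TSS

#: untreated / depleted condition labels used throughout the package
MINUS_AUXIN = "-auxin"
PLUS_AUXIN = "+auxin"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults encode the emulated design: substantial termination failure
    only in the +auxin (depletion) condition, kilobase-scale readthrough
    decay, and moderate biological count dispersion.
    """

    n_genes: int = 500
    chrom_length: int | None = None          # bp; None -> sized to fit
    gene_length_range: tuple[int, int] = (500, 2500)
    intergap_distribution: tuple[float, float] = (200.0, 100.0)  # mean, sd bp
    strand_scheme: Mapping[str, float] = field(
        default_factory=lambda: {"codirectional": 0.5, "convergent": 0.25, "divergent": 0.25}
    )
    expression_mu: float = 3.0               # log-normal location of e_i
    expression_sigma: float = 1.0
    termination_failure: Mapping[str, float] = field(
        default_factory=lambda: {MINUS_AUXIN: 0.05, PLUS_AUXIN: 0.6}
    )
    readthrough_decay_L: float = 1000.0      # bp
    interference_alpha: float = 0.5
    nb_dispersion: float = 0.05              # phi; Var = mu + phi*mu^2
    library_scale: float | Mapping[str, float] = 1.0
    n_spikeins: int = 200
    n_replicates: int = 2
    bin_size: int = 10
    seed: int = 0
    poisson: bool = False                    # phi -> 0 limit

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        lo, hi = self.gene_length_range
        if not (0 < lo <= hi):
            raise ValueError("gene_length_range must be positive and ordered")
        for cond, f in self.termination_failure.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"termination_failure[{cond!r}] must be in [0, 1]")
        if self.readthrough_decay_L <= 0:
            raise ValueError("readthrough_decay_L must be positive")
        if self.nb_dispersion <= 0 and not self.poisson:
            raise ValueError("nb_dispersion must be positive (or set poisson=True)")
        if self.interference_alpha < 0:
            raise ValueError("interference_alpha must be >= 0")
        if self.bin_size <= 0 or self.n_spikeins < 1 or self.n_replicates < 1:
            raise ValueError("bin_size, n_spikeins and n_replicates must be positive")
        total = sum(self.strand_scheme.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError("strand_scheme fractions must sum to 1")
        conv = self.strand_scheme.get("convergent", 0.0)
        div = self.strand_scheme.get("divergent", 0.0)
        # convergent and divergent junctions alternate on a linear chromosome,
        # so their achievable fractions are equal
        if abs(conv - div) > 0.05:
            raise ValueError(
                "convergent and divergent junction fractions must match "
                "(they alternate along a chromosome)"
            )

    @property
    def conditions(self) -> list[str]:
        return list(self.termination_failure)

    def sample_names(self) -> list[str]:
        return [
            f"{cond}_rep{r}"
            for cond in self.conditions
            for r in range(1, self.n_replicates + 1)
        ]

    def sample_scale(self, sample: str) -> float:
        if isinstance(self.library_scale, Mapping):
            return float(self.library_scale[sample])
        return float(self.library_scale)


@dataclass
class GroundTruth:
    """Per-gene latent parameters behind one condition's expected coverage."""

    condition: str
    table: pd.DataFrame  # index gene_id: e_baseline, f_true, interference_input, e_effective


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def generate_genome(config: SimulationConfig) -> GenomeAnnotation:
    """Lay out non-overlapping genes along one chromosome plus a spike-in chromosome.

    Strands follow a two-state Markov chain with persistence equal to the
    codirectional target fraction, which makes realized junction fractions
    converge on the requested scheme.  Poly(A) sites sit at the 3' boundary
    of each gene interval.  Raises if the genes cannot be packed into
    ``chrom_length``.
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    gap_mu, gap_sd = config.intergap_distribution
    gaps = np.maximum(20, rng.normal(gap_mu, gap_sd, size=config.n_genes)).astype(int)

    if config.chrom_length is not None and int(lengths.sum()) > config.chrom_length:
        raise ValueError(
            f"infeasible packing: total gene length {int(lengths.sum())} bp "
            f"exceeds chrom_length {config.chrom_length} bp"
        )

    p_keep = float(config.strand_scheme.get("codirectional", 0.5))
    strands = np.empty(config.n_genes, dtype="<U1")
    strands[0] = "+" if rng.random() < 0.5 else "-"
    flips = rng.random(config.n_genes - 1) >= p_keep
    for i in range(1, config.n_genes):
        prev = strands[i - 1]
        strands[i] = ("-" if prev == "+" else "+") if flips[i - 1] else prev

    genes = []
    pos = int(gaps[0])
    width = max(4, len(str(config.n_genes)))
    for i in range(config.n_genes):
        start = pos
        end = start + int(lengths[i])
        genes.append(Gene(f"g{i + 1:0{width}d}", MAIN_CHROM, start, end, strands[i]))
        pos = end + int(gaps[i])
    main_end = genes[-1].end

    if config.chrom_length is not None:
        if main_end > config.chrom_length:
            raise ValueError(
                f"infeasible packing: layout ends at {main_end} bp, "
                f"chrom_length is {config.chrom_length} bp"
            )
        main_len = config.chrom_length
    else:
        main_len = main_end + 2000  # headroom for terminal readthrough

    spike_pos = 200
    for j in range(config.n_spikeins):
        genes.append(
            Gene(f"spike_{j + 1:03d}", SPIKE_CHROM, spike_pos, spike_pos + 1000, "+")
        )
        spike_pos += 1200

    return GenomeAnnotation(
        genes, {MAIN_CHROM: main_len, SPIKE_CHROM: spike_pos + 200}
    )


def baseline_expression(annotation: GenomeAnnotation, config: SimulationConfig) -> pd.Series:
    """Condition-invariant per-gene baseline expression ``e_i`` (coverage units).

    Drawn log-normally from a seed derived from the config seed, so both
    conditions of one simulation share identical baselines.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    ids = [g.gene_id for g in annotation]
    values = rng.lognormal(config.expression_mu, config.expression_sigma, size=len(ids))
    return pd.Series(values, index=pd.Index(ids, name="gene_id"), name="e_baseline")


# ---------------------------------------------------------------------------
# expected coverage
# ---------------------------------------------------------------------------

def _add_interval(arr: np.ndarray, start: int, end: int, value: float, bin_size: int) -> None:
    """Add ``value`` over [start, end) with fractional weight on edge bins."""
    start = max(start, 0)
    end = min(end, arr.size * bin_size)
    if end <= start:
        return
    b0, b1 = start // bin_size, -(-end // bin_size)
    arr[b0:b1] += value
    # trim partial overlap at the edges
    arr[b0] -= value * (start - b0 * bin_size) / bin_size
    if b1 * bin_size > end:
        arr[b1 - 1] -= value * (b1 * bin_size - end) / bin_size


def _readthrough_profile(
    arr: np.ndarray, gene: Gene, e: float, f: float, L: float, bin_size: int
) -> None:
    """Deposit ``e*f*exp(-d/L)`` downstream of the poly(A) site on ``arr``."""
    if e * f <= 0:
        return
    n_bins = arr.size
    reach = int(10 * L)
    if gene.strand == "+":
        b0 = gene.polya_site // bin_size
        b1 = min(n_bins, -(-(gene.polya_site + reach) // bin_size))
        centers = (np.arange(b0, b1) + 0.5) * bin_size
        d = np.maximum(0.0, centers - gene.polya_site)
    else:
        b1 = -(-gene.polya_site // bin_size)
        b0 = max(0, (gene.polya_site - reach) // bin_size)
        centers = (np.arange(b0, b1) + 0.5) * bin_size
        d = np.maximum(0.0, gene.polya_site - centers)
    arr[b0:b1] += e * f * np.exp(-d / L)


def simulate_expected_coverage(
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    condition: str,
    baselines: pd.Series | None = None,
) -> tuple[StrandedCoverage, GroundTruth]:
    """Noise-free expected strand-specific coverage for one condition.

    Spike-in genes get their baseline signal in every condition and are
    exempt from readthrough and interference, mirroring an exogenous
    spike-in reference.
    """
    if condition not in config.termination_failure:
        raise ValueError(f"unknown condition {condition!r}")
    f = float(config.termination_failure[condition])
    L = config.readthrough_decay_L
    alpha = config.interference_alpha
    bs = config.bin_size
    if baselines is None:
        baselines = baseline_expression(annotation, config)

    values = {
        (chrom, strand): np.zeros(-(-annotation.chrom_length(chrom) // bs))
        for chrom in annotation.chroms()
        for strand in "+-"
    }

    # pass 1: readthrough from baselines
    readthrough = {k: np.zeros_like(v) for k, v in values.items()}
    for g in annotation:
        if g.chrom == SPIKE_CHROM:
            continue
        _readthrough_profile(
            readthrough[(g.chrom, g.strand)], g, float(baselines[g.gene_id]), f, L, bs
        )

    # pass 2: interference input at each promoter, effective expression
    records = []
    for g in annotation:
        e = float(baselines[g.gene_id])
        if g.chrom == SPIKE_CHROM:
            records.append((g.gene_id, e, 0.0, 0.0, e))
            continue
        opp = "-" if g.strand == "+" else "+"
        w0, w1 = g.tss - PROMOTER_HALF_WINDOW, g.tss + PROMOTER_HALF_WINDOW
        track = readthrough[(g.chrom, opp)]
        b0 = max(0, w0 // bs)
        b1 = min(track.size, -(-w1 // bs))
        I = float(track[b0:b1].mean()) if b1 > b0 else 0.0
        e_eff = e / (1.0 + alpha * I)
        records.append((g.gene_id, e, f, I, e_eff))

    truth = pd.DataFrame.from_records(
        records,
        columns=["gene_id", "e_baseline", "f_true", "interference_input", "e_effective"],
    ).set_index("gene_id")

    # pass 3: compose gene bodies (effective) + readthrough (baseline-scaled)
    for g in annotation:
        _add_interval(
            values[(g.chrom, g.strand)],
            g.start,
            g.end,
            float(truth.loc[g.gene_id, "e_effective"]),
            bs,
        )
    for key in values:
        values[key] += readthrough[key]

    coverage = StrandedCoverage(bs, values, RAW)
    return coverage, GroundTruth(condition, truth)


# ---------------------------------------------------------------------------
# count noise
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mu: np.ndarray, phi: float, poisson: bool) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    if poisson or phi < 1e-12:
        return rng.poisson(mu)
    n = 1.0 / phi
    p = n / (n + mu)
    return rng.negative_binomial(n, p)


def sample_counts(
    expected_by_condition: Mapping[str, StrandedCoverage],
    annotation: GenomeAnnotation,
    config: SimulationConfig,
    seed: int | None = None,
) -> tuple[CountTable, dict[str, StrandedCoverage]]:
    """Draw negative-binomial gene counts and per-bin observed coverage.

    Per-gene count means are ``library_scale * sum(expected bins over the
    gene interval on its strand)``; per-bin observed coverage is an
    independent NB draw around ``library_scale * expected``.  Spike-in genes
    inherit condition-independent expectations from the generator.
    """
    if config.nb_dispersion <= 0 and not config.poisson:
        raise ValueError("nb_dispersion must be positive")
    seed = config.seed if seed is None else seed
    genes = list(annotation)
    gene_ids = [g.gene_id for g in genes]

    counts: dict[str, np.ndarray] = {}
    observed: dict[str, StrandedCoverage] = {}
    conditions: dict[str, str] = {}
    for ci, cond in enumerate(config.conditions):
        expected = expected_by_condition[cond]
        for arr in expected.values.values():
            if (arr < 0).any():
                raise ValueError("expected coverage must be non-negative")
        gene_mu = np.array(
            [
                expected.interval_sum(g.chrom, g.strand, g.start, g.end)
                for g in genes
            ]
        )
        for r in range(1, config.n_replicates + 1):
            sample = f"{cond}_rep{r}"
            scale = config.sample_scale(sample)
            rng = np.random.default_rng(np.random.SeedSequence([seed, ci, r]))
            counts[sample] = _nb_draw(
                rng, scale * gene_mu, config.nb_dispersion, config.poisson
            )
            obs = {
                key: _nb_draw(rng, scale * arr, config.nb_dispersion, config.poisson).astype(float)
                for key, arr in expected.values.items()
            }
            observed[sample] = StrandedCoverage(expected.bin_size, obs, RAW)
            conditions[sample] = cond

    meta = pd.DataFrame(
        {
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "is_spikein": [g.chrom == SPIKE_CHROM for g in genes],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    table = CountTable(
        pd.DataFrame(counts, index=meta.index), meta, conditions
    )
    return table, observed


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[GenomeAnnotation, dict[str, tuple[StrandedCoverage, GroundTruth]], CountTable, dict[str, StrandedCoverage]]:
    """End-to-end convenience: genome, expected coverage per condition, counts."""
    annotation = generate_genome(config)
    baselines = baseline_expression(annotation, config)
    expected = {
        cond: simulate_expected_coverage(annotation, config, cond, baselines)
        for cond in config.conditions
    }
    table, observed = sample_counts(
        {cond: cov for cond, (cov, _) in expected.items()}, annotation, config
    )
    return annotation, expected, table, observed


# ---------------------------------------------------------------------------
# cleavage time courses
# ---------------------------------------------------------------------------

def simulate_cleavage_timecourse(
    y_max: float,
    y_0: float,
    k: float,
    timepoints: Sequence[float],
    noise_sd: float = 0.0,
    n_rep: int = 3,
    seed: int = 0,
    complex_name: str = "complex",
):
    """Replicate %-cleaved time courses from the exponential-plateau model.

    ``Y(t) = Y_max - (Y_max - Y_0) * exp(-k t)`` plus Gaussian noise on the
    percentage scale.  Returns a :class:`termread.kinetics.TimeCourseSet`
    whose intensities are consistent with the noisy percentages (initial
    substrate intensity fixed at 100 units).
    """
    from .kinetics import TimeCourseSet  # local import to avoid a cycle

    if not (0 <= y_0 < y_max <= 100):
        raise ValueError("require 0 <= Y_0 < Y_Max <= 100")
    if k <= 0:
        raise ValueError("rate constant k must be positive")
    t = np.asarray(timepoints, dtype=float)
    if t.ndim != 1 or (t < 0).any():
        raise ValueError("timepoints must be non-negative")

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_rep + 1):
        y = y_max - (y_max - y_0) * np.exp(-k * t)
        if noise_sd > 0:
            y = y + rng.normal(0.0, noise_sd, size=t.size)
        for ti, yi in zip(t, y):
            rows.append((complex_name, rep, ti, 100.0 * (1 - yi / 100.0), 100.0))
    df = pd.DataFrame(
        rows, columns=["complex", "replicate", "time_min", "intensity", "intensity_t0"]
    )
    return TimeCourseSet(df)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    true_fold_changes: Mapping[str, float],
    spikein_cts: Mapping[str, float],
    noise_sd_ct: float = 0.0,
    seed: int = 0,
    n_replicates: int = 3,
    fraction: str = "nascent",
):
    """Ct table with known +auxin/-auxin fold changes, assuming perfect efficiency.

    Target amplicons get a baseline Ct in the untreated condition; the
    treated Ct is shifted by ``-log2(FC)`` so that the ddCt analysis
    recovers the input fold change.  Spike-in amplicon Cts are
    condition-invariant.
    """
    from .qpcr import QpcrTable

    for amp, fc in true_fold_changes.items():
        if fc <= 0:
            raise ValueError(f"fold change for {amp!r} must be positive")
    rng = np.random.default_rng(seed)
    baselines = {
        amp: 18.0 + 7.0 * rng.random() for amp in true_fold_changes
    }
    rows = []
    for rep in range(1, n_replicates + 1):
        for cond in (MINUS_AUXIN, PLUS_AUXIN):
            for amp, ct in spikein_cts.items():
                noise = rng.normal(0.0, noise_sd_ct) if noise_sd_ct > 0 else 0.0
                rows.append((amp, cond, fraction, rep, ct + noise))
            for amp, fc in true_fold_changes.items():
                ct = baselines[amp]
                if cond == PLUS_AUXIN:
                    ct -= math.log2(fc)
                noise = rng.normal(0.0, noise_sd_ct) if noise_sd_ct > 0 else 0.0
                rows.append((amp, cond, fraction, rep, ct + noise))
    df = pd.DataFrame(
        rows, columns=["amplicon", "condition", "fraction", "replicate", "ct"]
    )
    return QpcrTable(df, spike_amplicons=tuple(spikein_cts))
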