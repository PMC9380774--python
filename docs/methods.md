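# Methods

This note documents the models implemented in `termread`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions that matter for reproducibility.

## The readthrough/interference model behind the generator

The generator emulates a depletion experiment on the 3′-end processing
machinery, read out by strand-specific nascent RNA-seq: an untreated
condition (−auxin) with mostly functional termination and a depleted
condition (+auxin) in which a large fraction of transcription events fail
to terminate at the poly(A) site.

Per gene *i* with baseline expression `e_i`:

- **Gene body.** Expected coverage across the gene interval is the
  effective expression `e'_i` (units: arbitrary signal per 10-bp bin).
- **Readthrough.** At distance `d` past the poly(A) site, on the gene's own
  strand, expected signal is `e_i · f · exp(−d/L)`, where `f` is the
  condition's termination-failure fraction and `L` the decay length.
  Exponential decay is a modeling choice: the data motivating this package
  show decaying readthrough without pinning a functional form, and a single
  length scale is the simplest shape with the right qualitative behavior.
- **Interference.** The interference input `I_j` is the mean opposite-strand
  readthrough over the promoter window (TSS ± 100 bp; no window is
  prescribed by the source experiments, ±100 bp covers a compact yeast-like
  promoter). Effective expression is

      e'_j = e_j / (1 + α · I_j)

  computed in a single pass from the baselines — readthrough is always
  sourced from `e_i`, not `e'_i`, so there are no higher-order cascades or
  fixed points. This is the simplest monotone, bounded interference model
  that reproduces the observed strand anticorrelation; α = 0 recovers
  `e' = e` exactly.

Counts are negative binomial around `library_scale ×` the expected signal
(variance `μ + φμ²`), drawn independently per gene (summed over its
interval) and per coverage bin. Spike-in genes live on a dedicated
chromosome, receive no readthrough or interference, and have
condition-invariant expectations — emulating a second-species spike-in
added in fixed proportion.

### Generator defaults and their rationale

| parameter | default | rationale |
| --- | --- | --- |
| `n_genes` | 500 | enough junctions for stable orientation statistics at interactive runtimes |
| `gene_length_range` | 500–2500 bp | yeast-like ORF lengths |
| `intergap_distribution` | 200 ± 100 bp | compact yeast-like intergenic spacing (floored at 20 bp) |
| `strand_scheme` | 50% codirectional, 25% + 25% conv/div | coin-flip strand choice, as in a compact genome |
| `expression_mu, sigma` | 3.0, 1.0 (log-normal) | ~2 orders of magnitude of expression, median ≈ 20 units/bin |
| `termination_failure` | 0.05 (−auxin), 0.6 (+auxin) | near-complete termination when the machinery is present; majority failure upon depletion |
| `readthrough_decay_L` | 1000 bp | readthrough typically invades the next gene and dies within the one after |
| `interference_alpha` | 0.5 | produces clear but not saturating promoter suppression |
| `nb_dispersion` | 0.05 | typical bulk RNA-seq biological dispersion |
| `n_spikeins` | 200 | a scaled-down transcriptome-sized spike set; with the median-of-ratios estimator the size-factor standard error is ≈ 1.253·√φ/√n, and 200 genes put it near 2%, comparable to a whole-transcriptome spike-in |
| `n_replicates` | 2 | minimal replicated design |
| `bin_size` | 10 bp | matches the 10-bp binning used for browser-style tracks |

**Strand scheme constraint.** On a linear chromosome, convergent and
divergent junctions alternate between codirectional runs, so their counts
differ by at most one; arbitrary unequal convergent/divergent targets are
unrealizable. Strands follow a two-state Markov chain whose persistence is
the codirectional target; the config rejects schemes with conv ≠ div.

### What the generator does not emulate

No read-level sampling (counts and binned coverage are drawn directly), no
splicing, no 5′ ends/soft boundaries (genes are hard intervals with the
poly(A) site at the 3′ boundary), no pervasive antisense background
transcription, no RNAPII elastic-collision mechanics, and no overlapping
genes. Consequences worth keeping in mind: opposite-strand signal over most
genes is near zero in the untreated condition, so per-gene opposite-strand
log-ratios are noisier and more saturated than in real data, where
background transcription tempers them. Passing tests demonstrate that the
statistics recover the modeled phenomena at realistic noise; they do not
certify performance on real libraries with background, mappability and
annotation artifacts.

## Normalization

Primary method: spike-in **median-of-ratios** — per sample, the median over
spike-in genes of the count divided by that gene's geometric mean across
samples, rescaled to geometric mean 1. Deterministic, robust to a minority
of misbehaving spike-ins, and valid when most biological genes change
(exactly the situation in a termination-defect experiment, where
readthrough inflates total signal). An optional RUV-style stage estimates
`k` unwanted sample-space factors by SVD of row-centered spike-in
log-counts (pseudocount 0.5) and projects them out of every gene; `k = 0`
and variance-free spike-ins are identities. The projection removes any
genuine biology aligned with the unwanted directions — it is a trade, not a
free lunch, which is why it is optional and off by default.

## Differential expression

Per-gene Wald test on the difference of log mean normalized counts.
Model-based variance `Var(log m_c) ≈ (1/m_c + φ_g)/n_c` with a
method-of-moments per-gene dispersion pooled within conditions and shrunk
toward the across-genes mean with 10 prior degrees of freedom (at 2–3
replicates the per-gene estimate is nearly uninformative, so the global
mean dominates). P-values use a **moderated-t** reference with
`residual df + prior df` degrees of freedom: a normal reference is
measurably too light-tailed deep in the tail at two replicates, which
inflates family-wise discoveries under the null; the borrowed-df t
reference restores control at a small cost in power. Benjamini–Hochberg
FDR at α = 0.05; direction calls (`up`/`down`) only among significant
genes. With a single replicate per condition the model refuses p-values
and emits fold changes only. Log fold changes use pseudocount 0.5 and are
not shrunk.

## Interference statistics

- **Gene pairing.** A gene's "corresponding opposite position" is its own
  interval projected onto the opposite strand; the opposite value is the
  log₂ ratio of summed normalized coverage (pseudocount as in the DE
  module). `ground_truth_pairs` provides the same pairing from the
  generator's latent state (own value = true e′ change), which is the
  oracle for anticorrelation checks: the observed-data gene-level
  correlation is attenuated by the saturated opposite-strand log-ratios
  discussed above, while the 1-kb window statistic is robust.
- **Windows** are non-overlapping 1-kb tiles (the "sliding" analysis in
  genome-summary tools at 1-kb bin size amounts to tiling).
- **Correlation** is Pearson by default; Spearman is a flag.
- **Orientation χ².** Genes are classed by their flanking junctions —
  either the unordered pair (default) or, with `oriented=True`, the
  relation at the gene's 5′ junction, which isolates genes that receive
  codirectional readthrough into their body. Pearson χ² without continuity
  correction; standardized residuals `(O−E)/√(E(1−r/n)(1−c/n))` carry the
  association's direction. Expected cells < 1 flag the result and, for 2×2
  tables, substitute Fisher's exact p.
- **Readthrough index** = FC(500 bp downstream of poly(A)) / FC(1 kb of
  gene body upstream), strand-aware; zero upstream signal yields NaN.

## Metagene profiles and clustering

Metagene rows are genes at least 200 bp from both neighbors (so the window
is attributable to the anchored gene), aligned on the poly(A) site,
strand-flipped to read 5′→3′, NaN-padded at chromosome edges. The band is
a normal-approximation 95% CI across rows (percentile bootstrap available).

Convergent pairs are represented by the concatenated plus/minus profiles
in both conditions over a 1-kb window anchored at the midpoint of the two
poly(A) sites (per-gene anchoring available), z-scored per row so clusters
reflect profile shape. k-means is Lloyd's algorithm with a deterministic
initialization cascade: the k-centroid solution is seeded from the
(k−1)-solution plus the worst-fit point, alongside a farthest-first seed
and k-means++ restarts drawn from a canonically sorted copy of the rows.
Consequences: fixed seed ⇒ bit-identical output; partitions are invariant
to row order; WCSS is non-increasing in k; empty clusters are re-seeded at
the point farthest from its centroid. Default k = 4 mirrors the common
choice of "few clusters with distinct patterns"; per-cluster partner
comparisons use a pooled-variance two-sample t-test (Welch optional) with
Tukey 1.5·IQR outlier marking.

## Cleavage kinetics

Percent cleaved `Y = (1 − S_t/S_0)·100` is deliberately not clipped to
[0, 100] before fitting. The global fit shares `Y_max` and `Y_0` across
complexes ("globally restrained") with per-complex rates, by
trust-region-reflective least squares with bounds `Y_max ∈ (0, 200]`,
`Y_0 ∈ [−100, 100]`, `k ≥ 1e−6 min⁻¹`. Initialization: `Y_0` ← mean Y at
the first timepoint, `Y_max` ← mean at the last, `k` ← slope of
`ln(Y_max − Y)` vs t. Rates at the lower bound, or a vanishing plateau
amplitude (flat data, k unidentifiable), raise a warning. The half-time
`t50 = ln(2(Y_max−Y_0)/Y_max)/k` solves `Y(t50) = Y_max/2` exactly and is
undefined when `Y_0 ≥ Y_max/2` (an explicit error).

Uncertainty is a seeded percentile bootstrap. The default resamples
leverage-inflated fit residuals pooled within each complex
(inflation `√(N/(N−p))`, with each complex charged its rate plus a share
of the two shared parameters). Case resampling of replicates within
timepoints is available (`method="case"`, with a `√(n/(n−1))` small-sample
inflation) but runs narrow when only two or three replicates exist per
timepoint — measured at 3 replicates its 95% intervals cover ≈ 88% vs
≈ 92% for the residual scheme — hence the residual default. Intervals are
labeled bootstrap percentile CIs; they are not standard errors of the fit.

The two CYC1-derived RNA substrates used in the corresponding in vitro
assays ship as package data (`data/cyc1_substrates.fasta`): the 42-nt
precleaved form ending at the cleavage site, carrying the non-canonical
AAGAA polyadenylation signal at position 21, and the full-length form with
the 3′ extension.

## qPCR

Cts of the spike-in amplicon set (default three transcripts) are averaged
per condition/fraction/replicate; `ΔCt = Ct − Ct_spike`, replicate-averaged
per condition; `ΔΔCt = ΔCt_treated − ΔCt_control`; `FC = E^(−ΔΔCt)` with
perfect efficiency E = 2 by default (the `2^−ΔΔCt` formula presumes it; an
efficiency parameter is exposed). The readthrough level of a gene is the
fold change of its downstream amplicon divided by that of the genic
amplicon 1 kb upstream.

## Orchestration, seeds, problem sizes

One TOML file configures all stages; unknown keys are rejected. A single
global seed derives per-stage seeds (`seed·1000003 + crc32(stage) mod 2³¹`),
so identical config + seed produces byte-identical outputs, including
`report.json`. Pipeline condition coverage is replicate-pooled and
CPM-scaled (grand total over both strands = 1e6) after a 20-bp running
mean; CPM is computed jointly over strands. Cross-condition level
comparisons (e.g. metagene curves between conditions) should use
spike-in size factors rather than CPM, because readthrough changes the
total signal itself; the test suite does exactly that.

Test and validation problem sizes were chosen to make the checks sharp at
interactive runtimes: 500-gene genomes (20 seeds) for correlation
properties, 300-gene genomes (20 replicates) for null calibration,
2000-draw Monte Carlo for the χ² size, 50 trials × 200 bootstrap draws for
kinetic recovery. The full default pipeline runs in about a second on one
CPU.

## Known limitations

- The NB Wald test is mildly conservative at two replicates (per-gene
  type-I rate ≈ 0.036 at nominal 0.05 in the null simulation); DESeq2-class
  GLM machinery would be sharper but is intentionally out of scope.
- The RUV-style stage estimates unwanted factors from spike-ins only and
  assumes they span technical variation; library-preparation effects that
  do not touch spike-ins are invisible to it.
- Interference is a static initiation-rate model; it does not represent
  collision dynamics, elongation-rate changes, or readthrough of the
  interfering polymerase being itself interfered with.
- Gene-level opposite-strand ratios in sparse synthetic genomes saturate
  (see above); prefer the window statistic or the ground-truth pairing when
  quantifying anticorrelation strength in simulations.
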