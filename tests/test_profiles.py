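import numpy as np
import pandas as pd
import pytest

from termread.annotation import Gene, GenomeAnnotation
from termread.coverage import StrandedCoverage
from termread.diffexpr import DifferentialExpression
from termread.profiles import (
    boxplot_stats,
    cluster_partner_stats,
    convergent_pair_matrix,
    kmeans_cluster,
    metagene_average,
    metagene_matrix,
)
from termread.simulate import (
    MINUS_AUXIN,
    PLUS_AUXIN,
    SPIKE_CHROM,
    SimulationConfig,
    sample_counts,
    simulate_expected_coverage,
)


def flat_cov(n_bins=2000, value=1.0):
    return StrandedCoverage(
        10,
        {
            ("chrI", "+"): np.full(n_bins, value),
            ("chrI", "-"): np.full(n_bins, value),
        },
    )


def spaced_annotation():
    return GenomeAnnotation(
        [
            Gene("a", "chrI", 2000, 4000, "+"),
            Gene("b", "chrI", 6000, 8000, "-"),
            Gene("c", "chrI", 8150, 9000, "+"),  # 150 bp from b
        ],
        {"chrI": 20000},
    )


def test_flat_coverage_gives_unit_matrix():
    mat = metagene_matrix(flat_cov(), spaced_annotation(), flank=500)
    assert "a" in mat.matrix.index
    np.testing.assert_allclose(mat.matrix.loc["a"], 1.0)
    assert mat.matrix.shape[1] == 100
    assert mat.anchor_column == 50


def test_neighbor_distance_filter():
    mat = metagene_matrix(
        flat_cov(), spaced_annotation(), flank=500, min_neighbor_distance=200
    )
    assert "b" not in mat.matrix.index  # 150 bp gap to c
    assert "c" not in mat.matrix.index
    assert list(mat.matrix.index) == ["a"]


def test_minus_strand_rows_are_mirrored():
    track = np.zeros(2000)
    track[405:450] = 3.0  # asymmetric feature right of the plus anchor at 4000
    cov = StrandedCoverage(10, {("chrI", "+"): track, ("chrI", "-"): track.copy()})
    plus = GenomeAnnotation([Gene("p", "chrI", 2000, 4000, "+")], {"chrI": 20000})
    # a minus-strand gene whose poly(A) site sits at the same coordinate
    minus = GenomeAnnotation([Gene("m", "chrI", 4000, 6000, "-")], {"chrI": 20000})
    mp = metagene_matrix(cov, plus, flank=500).matrix.loc["p"].to_numpy()
    mm = metagene_matrix(cov, minus, flank=500).matrix.loc["m"].to_numpy()
    np.testing.assert_allclose(mm, mp[::-1])


def test_window_beyond_chromosome_is_nan_padded():
    ann = GenomeAnnotation([Gene("edge", "chrI", 0, 300, "+")], {"chrI": 20000})
    mat = metagene_matrix(flat_cov(), ann, flank=500)
    row = mat.matrix.loc["edge"].to_numpy()
    assert np.isnan(row[:20]).all()  # window extends 200 bp left of the chromosome
    assert np.isfinite(row[20:]).all()


def test_metagene_average_basics():
    mat = metagene_matrix(flat_cov(), spaced_annotation(), flank=500,
                          min_neighbor_distance=0)
    avg = metagene_average(mat)
    np.testing.assert_allclose(avg["mean"], 1.0)
    np.testing.assert_allclose(avg["ci_high"] - avg["ci_low"], 0.0)
    # rows {0, 2} average to 1
    m = mat.matrix.copy()
    m.iloc[0] = 0.0
    m.iloc[1] = 2.0
    mat2 = type(mat)(m.iloc[:2], mat.flank, mat.bin_size)
    avg2 = metagene_average(mat2)
    np.testing.assert_allclose(avg2["mean"], 1.0)
    with pytest.raises(ValueError, match="2 rows"):
        metagene_average(type(mat)(m.iloc[:1], mat.flank, mat.bin_size))


def blobs(seed=0, centers=(0.0, 8.0, 16.0), n=25, d=6):
    rng = np.random.default_rng(seed)
    return np.vstack([rng.normal(c, 1.0, (n, d)) for c in centers])


def test_kmeans_separated_blobs_partition():
    X = blobs(centers=(0.0, 20.0))
    res = kmeans_cluster(X, k=2, seed=0)
    labels = res.assignments.to_numpy()
    assert len(set(labels[:25])) == 1
    assert len(set(labels[25:])) == 1
    assert labels[0] != labels[25]


def test_kmeans_deterministic_and_permutation_invariant():
    X = blobs()
    base = kmeans_cluster(X, k=3, seed=5)
    again = kmeans_cluster(X, k=3, seed=5)
    assert base.assignments.equals(again.assignments)
    assert np.allclose(base.centroids, again.centroids, atol=1e-12)
    perm = np.random.default_rng(1).permutation(X.shape[0])
    permuted = kmeans_cluster(X[perm], k=3, seed=5)
    # identical partition up to label renaming
    for c in range(3):
        orig_labels = base.assignments.to_numpy()[perm][permuted.assignments == c]
        assert len(set(orig_labels)) == 1


def test_kmeans_wcss_nesting():
    X = blobs(seed=3, centers=(0.0, 5.0, 10.0, 30.0))
    w = [kmeans_cluster(X, k=k, seed=0).wcss for k in (1, 2, 4, 6)]
    assert w == sorted(w, reverse=True)


def test_kmeans_validation():
    with pytest.raises(ValueError, match="exceed"):
        kmeans_cluster(np.zeros((3, 2)), k=5)


def test_boxplot_stats_by_hand():
    s = boxplot_stats(np.array([1.0, 2, 3, 4, 5]))
    assert s["median"] == 3.0
    assert (s["q1"], s["q3"]) == (2.0, 4.0)
    assert s["n_outliers"] == 0


def interference_pair_setup():
    """Convergent pairs where the minus-strand partner is weakly expressed."""
    genes, spikes = [], []
    pos = 2000
    for i in range(12):
        genes.append(Gene(f"p{i:02d}", "chrI", pos, pos + 1000, "+"))
        genes.append(Gene(f"m{i:02d}", "chrI", pos + 1100, pos + 2100, "-"))
        pos += 4000
    for j in range(30):
        spikes.append(Gene(f"spike_{j:03d}", SPIKE_CHROM, 200 + 1200 * j, 1200 + 1200 * j, "+"))
    ann = GenomeAnnotation(genes + spikes, {"chrI": pos + 2000, SPIKE_CHROM: 1200 * 30 + 400})
    baselines = pd.Series(
        {g.gene_id: (200.0 if g.gene_id.startswith("p") else 20.0) for g in genes}
        | {s.gene_id: 50.0 for s in spikes}
    )
    cfg = SimulationConfig(
        n_genes=24, interference_alpha=0.5, n_spikeins=30, seed=0, n_replicates=3
    )
    expected = {
        cond: simulate_expected_coverage(ann, cfg, cond, baselines)[0]
        for cond in cfg.conditions
    }
    return ann, cfg, expected


def test_interference_skews_against_weak_partner():
    ann, cfg, expected = interference_pair_setup()
    table, _ = sample_counts(expected, ann, cfg)
    de = DifferentialExpression(table, treated=PLUS_AUXIN, control=MINUS_AUXIN).fit()
    mat, pairs = convergent_pair_matrix(expected, ann, flank=500)
    assignments = kmeans_cluster(mat, k=1, seed=0).assignments
    box, tests = cluster_partner_stats(de, pairs, assignments)
    med = box.set_index("strand")["median"]
    assert med["-"] < med["+"]  # the weak convergent partner is suppressed
    assert (tests["p_value"] < 0.05).all()


def test_cluster_partner_stats_identical_distributions():
    frame = pd.DataFrame(
        {"log2fc": [0.5, 0.5, 1.0, 1.0]},
        index=["p0", "m0", "p1", "m1"],
    )
    frame["direction"] = "ns"
    from termread.diffexpr import DEResults

    res = DEResults(frame, 0.05, PLUS_AUXIN, MINUS_AUXIN)
    pairs = [
        (Gene("p0", "chrI", 0, 100, "+"), Gene("m0", "chrI", 200, 300, "-")),
        (Gene("p1", "chrI", 400, 500, "+"), Gene("m1", "chrI", 600, 700, "-")),
    ]
    assignments = pd.Series([0, 0], index=["p0|m0", "p1|m1"])
    box, tests = cluster_partner_stats(res, pairs, assignments)
    assert tests.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
    assert tests.loc[0, "p_value"] == pytest.approx(1.0)


def test_convergent_pair_matrix_features(default_dataset):
    ann = default_dataset["annotation"]
    cov = default_dataset["cond_cov"]
    mat, pairs = convergent_pair_matrix(cov, ann, flank=500)
    assert len(pairs) == len(mat.matrix)
    # 2 strands x 2 conditions x 100 bins
    assert mat.matrix.shape[1] == 400
    # z-scored rows
    np.testing.assert_allclose(mat.matrix.mean(axis=1), 0.0, atol=1e-9)
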