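import numpy as np
import pandas as pd
import pytest

from termread.annotation import Gene, GenomeAnnotation
from termread.coverage import StrandedCoverage
from termread.interference import (
    StrandPairSet,
    anticorrelation,
    ground_truth_pairs,
    opposite_strand_pairs,
    orientation_chi2,
    readthrough_index,
    window_pairs,
)
from termread.simulate import (
    MINUS_AUXIN,
    PLUS_AUXIN,
    SimulationConfig,
    baseline_expression,
    generate_genome,
    simulate_expected_coverage,
)


def pairset(own, opposite):
    return StrandPairSet(pd.DataFrame({"own": own, "opposite": opposite}))


def test_perfectly_mirrored_pairs():
    x = np.linspace(-2, 2, 20)
    r, p = anticorrelation(pairset(x, -x))
    assert r == pytest.approx(-1.0)
    assert p < 1e-10


def test_independent_noise_uncorrelated():
    rng = np.random.default_rng(0)
    r, _ = anticorrelation(pairset(rng.normal(size=500), rng.normal(size=500)))
    assert abs(r) < 0.1


def test_anticorrelation_validation():
    with pytest.raises(ValueError, match="3 pairs"):
        anticorrelation(pairset([1.0], [2.0]))
    with pytest.raises(ValueError, match="variance"):
        anticorrelation(pairset([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
    with pytest.raises(ValueError, match="method"):
        anticorrelation(pairset([1.0, 2, 3], [1.0, 2, 3]), method="kendall")


def test_spearman_option():
    x = np.arange(10.0)
    r, _ = anticorrelation(pairset(x, -np.exp(x)), method="spearman")
    assert r == pytest.approx(-1.0)


def test_window_pairs_tiling():
    cov = {
        PLUS_AUXIN: StrandedCoverage(
            10, {("chrI", "+"): np.ones(1000), ("chrI", "-"): np.ones(1000)}
        ),
        MINUS_AUXIN: StrandedCoverage(
            10, {("chrI", "+"): np.ones(1000), ("chrI", "-"): np.ones(1000)}
        ),
    }
    tiles = window_pairs(cov, PLUS_AUXIN, MINUS_AUXIN, window=1000)
    assert len(tiles) == 10  # 10-kb chromosome -> ten 1-kb tiles
    np.testing.assert_allclose(tiles.pairs[["own", "opposite"]].values, 0.0)
    # chromosome shorter than the window -> one truncated tile
    short = {
        c: StrandedCoverage(10, {("chrI", "+"): np.ones(30), ("chrI", "-"): np.ones(30)})
        for c in (PLUS_AUXIN, MINUS_AUXIN)
    }
    assert len(window_pairs(short, PLUS_AUXIN, MINUS_AUXIN, window=1000)) == 1


def test_opposite_strand_pairs_symmetric_construction(default_dataset):
    de = default_dataset["de"]
    ann = default_dataset["annotation"]
    cov = default_dataset["cond_cov"]
    pairs = opposite_strand_pairs(de, ann, cov)
    # every tested biological gene is paired exactly once
    assert len(pairs) == de.frame.shape[0]
    assert not pairs.excluded


def test_off_grid_gene_excluded(default_dataset):
    de = default_dataset["de"]
    cov = default_dataset["cond_cov"]
    far = Gene(de.frame.index[0], "chrI", 10_000_000, 10_001_000, "+")
    ann = GenomeAnnotation([far])
    pairs = opposite_strand_pairs(de, ann, cov)
    assert pairs.excluded == [far.gene_id]


def test_convergent_partners_change_in_opposite_directions():
    cfg = SimulationConfig(n_genes=300, interference_alpha=1.0, seed=21)
    ann = generate_genome(cfg)
    b = baseline_expression(ann, cfg)
    expected, truths = {}, {}
    for cond in cfg.conditions:
        cov, t = simulate_expected_coverage(ann, cfg, cond, b)
        expected[cond], truths[cond] = cov, t.table
    gp = ground_truth_pairs(ann, expected, truths, PLUS_AUXIN, MINUS_AUXIN)
    conv_ids = [g.gene_id for pair in ann.convergent_pairs() for g in pair]
    sub = gp.pairs.loc[gp.pairs.index.intersection(conv_ids)]
    opposite_sign = (sub["own"] < 0) & (sub["opposite"] > 0)
    assert opposite_sign.mean() > 0.5


def test_chi2_uniform_table():
    directions = pd.Series(["up"] * 20 + ["down"] * 20)
    classes = pd.Series((["a"] * 10 + ["b"] * 10) * 2)
    res = orientation_chi2(directions, classes)
    assert res.chi2 == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_chi2_two_by_two_by_hand():
    # [[30,10],[10,30]]: chi2 = n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 20
    directions = pd.Series(["up"] * 40 + ["down"] * 40)
    classes = pd.Series(["a"] * 30 + ["b"] * 10 + ["a"] * 10 + ["b"] * 30)
    res = orientation_chi2(directions, classes)
    assert res.chi2 == pytest.approx(20.0)
    assert res.dof == 1
    # association direction is read off the standardized residuals
    assert res.residuals.loc["up", "a"] > 0
    assert res.residuals.loc["up", "b"] < 0


def test_chi2_type_one_error_under_independence():
    rng = np.random.default_rng(123)
    rejections = 0
    n_sims = 200
    for _ in range(n_sims):
        directions = pd.Series(rng.choice(["up", "down"], size=200, p=[0.4, 0.6]))
        classes = pd.Series(rng.choice(["a", "b", "c"], size=200, p=[0.5, 0.3, 0.2]))
        if orientation_chi2(directions, classes).p_value < 0.05:
            rejections += 1
    assert rejections / n_sims <= 0.06


def test_chi2_small_expected_cells_flagged():
    # expected cell (up, b) = 5 * 1 / 7 < 1 -> Fisher fallback
    directions = pd.Series(["up"] * 5 + ["down"] * 2)
    classes = pd.Series(["a"] * 5 + ["a", "b"])
    res = orientation_chi2(directions, classes)
    assert res.exact_fallback
    assert 0.0 <= res.p_value <= 1.0


def test_readthrough_index_definition():
    # plus-strand gene, poly(A) at 2000: downstream FC 4, upstream FC 2 -> index 2
    up_c = np.zeros(400)
    up_c[100:200] = 10.0   # upstream region 1000-2000
    up_c[200:250] = 5.0    # downstream region 2000-2500
    up_t = np.zeros(400)
    up_t[100:200] = 20.0
    up_t[200:250] = 20.0
    cov = {
        MINUS_AUXIN: StrandedCoverage(10, {("chrI", "+"): up_c, ("chrI", "-"): np.zeros(400)}),
        PLUS_AUXIN: StrandedCoverage(10, {("chrI", "+"): up_t, ("chrI", "-"): np.zeros(400)}),
    }
    ann = GenomeAnnotation([Gene("g", "chrI", 1000, 2000, "+")])
    idx = readthrough_index(cov, ann, PLUS_AUXIN, MINUS_AUXIN)
    assert idx["g"] == pytest.approx(2.0, rel=1e-2)  # pseudocount shifts it slightly


def test_readthrough_index_minus_strand_and_undefined():
    c = np.zeros(400)
    c[100:200] = 10.0  # gene body 1000-2000, minus strand, poly(A) at 1000
    c[50:100] = 5.0    # downstream (lower coordinates)
    t = np.zeros(400)
    t[100:200] = 10.0
    t[50:100] = 10.0
    cov = {
        MINUS_AUXIN: StrandedCoverage(10, {("chrI", "-"): c, ("chrI", "+"): np.zeros(400)}),
        PLUS_AUXIN: StrandedCoverage(10, {("chrI", "-"): t, ("chrI", "+"): np.zeros(400)}),
    }
    ann = GenomeAnnotation(
        [Gene("g", "chrI", 1000, 2000, "-"), Gene("empty", "chrI", 3000, 3500, "-", 3000)]
    )
    idx = readthrough_index(cov, ann, PLUS_AUXIN, MINUS_AUXIN)
    assert idx["g"] == pytest.approx(2.0, rel=1e-2)
    assert np.isnan(idx["empty"])  # zero upstream signal -> undefined


def test_null_readthrough_index_near_one():
    cfg = SimulationConfig(
        n_genes=150, seed=30,
        termination_failure={MINUS_AUXIN: 0.2, PLUS_AUXIN: 0.2},
    )
    ann = generate_genome(cfg)
    b = baseline_expression(ann, cfg)
    cov = {c: simulate_expected_coverage(ann, cfg, c, b)[0] for c in cfg.conditions}
    idx = readthrough_index(cov, ann, PLUS_AUXIN, MINUS_AUXIN).dropna()
    assert np.nanmedian(np.abs(idx - 1.0)) < 1e-9
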