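import numpy as np
import pandas as pd
import pytest

from termread.annotation import Gene, GenomeAnnotation
from termread.simulate import (
    MINUS_AUXIN,
    PLUS_AUXIN,
    SPIKE_CHROM,
    SimulationConfig,
    _nb_draw,
    baseline_expression,
    generate_genome,
    sample_counts,
    simulate_cleavage_timecourse,
    simulate_expected_coverage,
    simulate_dataset,
    simulate_qpcr,
)


def single_gene_setup(strand="+", e=10.0, f=0.5, L=1000.0, alpha=0.0):
    gene = (
        Gene("g1", "chrI", 5000, 7000, strand)
        if strand == "+"
        else Gene("g1", "chrI", 13000, 15000, "-")
    )
    ann = GenomeAnnotation(
        [gene, Gene("spike_001", SPIKE_CHROM, 0, 1000, "+")],
        {"chrI": 20000, SPIKE_CHROM: 1200},
    )
    cfg = SimulationConfig(
        n_genes=1,
        termination_failure={MINUS_AUXIN: f, PLUS_AUXIN: f},
        readthrough_decay_L=L,
        interference_alpha=alpha,
        n_spikeins=1,
        seed=0,
    )
    baselines = pd.Series({"g1": e, "spike_001": 5.0})
    cov, truth = simulate_expected_coverage(ann, cfg, PLUS_AUXIN, baselines)
    return gene, cfg, cov, truth


def test_readthrough_decay_formula():
    # signal at distance d past the poly(A) site is e * f * exp(-d/L)
    e, f, L = 10.0, 0.5, 1000.0
    assert e * f * np.exp(-1.0) == pytest.approx(1.839, abs=5e-4)
    gene, cfg, cov, _ = single_gene_setup(e=e, f=f, L=L)
    track = cov.track("chrI", "+")
    for b in (700, 750, 790):  # bins past the poly(A) site at 7000
        d = (b + 0.5) * 10 - gene.polya_site
        assert track[b] == pytest.approx(e * f * np.exp(-d / L), rel=1e-9)


def test_minus_strand_readthrough_extends_to_lower_coordinates():
    gene, cfg, cov, _ = single_gene_setup(strand="-")
    track = cov.track("chrI", "-")
    assert track[: gene.polya_site // 10].sum() > 0
    assert track[gene.end // 10 + 1 :].sum() == 0


def test_no_termination_failure_means_no_downstream_signal():
    gene, cfg, cov, _ = single_gene_setup(f=0.0)
    track = cov.track("chrI", "+")
    assert track[gene.end // 10 :].sum() == 0.0
    # gene body carries the baseline expression
    assert track[gene.start // 10 + 1] == pytest.approx(10.0)


def test_zero_alpha_keeps_baseline_expression_exactly():
    cfg = SimulationConfig(n_genes=100, interference_alpha=0.0, seed=3)
    ann = generate_genome(cfg)
    _, truth = simulate_expected_coverage(ann, cfg, PLUS_AUXIN)
    assert (truth.table["e_effective"] == truth.table["e_baseline"]).all()


def test_alpha_zero_conserves_body_signal_between_conditions():
    cfg = SimulationConfig(n_genes=80, interference_alpha=0.0, seed=5)
    ann = generate_genome(cfg)
    b = baseline_expression(ann, cfg)
    _, t_minus = simulate_expected_coverage(ann, cfg, MINUS_AUXIN, b)
    _, t_plus = simulate_expected_coverage(ann, cfg, PLUS_AUXIN, b)
    pd.testing.assert_series_equal(
        t_minus.table["e_effective"], t_plus.table["e_effective"]
    )


def test_interference_reduces_effective_expression():
    cfg = SimulationConfig(n_genes=200, interference_alpha=0.5, seed=6)
    ann = generate_genome(cfg)
    _, truth = simulate_expected_coverage(ann, cfg, PLUS_AUXIN)
    t = truth.table[truth.table["f_true"] > 0]
    assert (t["e_effective"] <= t["e_baseline"]).all()
    assert (t["e_effective"] < t["e_baseline"]).any()
    # single pass from baselines: e' = e / (1 + alpha * I) exactly
    np.testing.assert_allclose(
        t["e_effective"],
        t["e_baseline"] / (1 + cfg.interference_alpha * t["interference_input"]),
    )


def test_nb_sampling_poisson_limit_mean():
    rng = np.random.default_rng(0)
    draws = _nb_draw(rng, np.full(10_000, 100.0), 0.0, poisson=True)
    # CLT: SE of the mean is 0.1, assert within 3 SE
    assert abs(draws.mean() - 100.0) < 0.3


def test_nb_sampling_dispersion():
    rng = np.random.default_rng(1)
    mu, phi = 200.0, 0.1
    draws = _nb_draw(rng, np.full(20_000, mu), phi, poisson=False)
    expected_var = mu + phi * mu**2
    assert draws.var() == pytest.approx(expected_var, rel=0.1)


def test_library_scale_doubles_spikein_counts():
    base = {"-auxin_rep1": 1.0, "+auxin_rep1": 2.0}
    cfg = SimulationConfig(
        n_genes=50, n_replicates=1, library_scale=base, seed=8,
        termination_failure={MINUS_AUXIN: 0.0, PLUS_AUXIN: 0.0},
    )
    _, _, table, _ = simulate_dataset(cfg)
    spikes = table.spikein_counts()
    ratio = spikes["+auxin_rep1"].sum() / spikes["-auxin_rep1"].sum()
    assert ratio == pytest.approx(2.0, rel=0.05)


def test_sampling_deterministic_for_fixed_seed():
    cfg = SimulationConfig(n_genes=60, seed=13)
    _, _, t1, o1 = simulate_dataset(cfg)
    _, _, t2, o2 = simulate_dataset(cfg)
    pd.testing.assert_frame_equal(t1.counts, t2.counts)
    for s in o1:
        for key in o1[s].values:
            np.testing.assert_array_equal(o1[s].values[key], o2[s].values[key])


def test_spikeins_condition_invariant_in_expectation():
    cfg = SimulationConfig(n_genes=60, seed=2)
    ann = generate_genome(cfg)
    b = baseline_expression(ann, cfg)
    cov_m, _ = simulate_expected_coverage(ann, cfg, MINUS_AUXIN, b)
    cov_p, _ = simulate_expected_coverage(ann, cfg, PLUS_AUXIN, b)
    np.testing.assert_array_equal(
        cov_m.track(SPIKE_CHROM, "+"), cov_p.track(SPIKE_CHROM, "+")
    )


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(termination_failure={MINUS_AUXIN: -0.1, PLUS_AUXIN: 0.5})
    with pytest.raises(ValueError):
        SimulationConfig(nb_dispersion=0.0)
    with pytest.raises(ValueError):
        SimulationConfig(readthrough_decay_L=-5)
    with pytest.raises(ValueError, match="alternate"):
        SimulationConfig(
            strand_scheme={"codirectional": 0.5, "convergent": 0.4, "divergent": 0.1}
        )


def test_cleavage_timecourse_model_values():
    y = simulate_cleavage_timecourse(83.42, 0.8474, 0.455292, [0.0], 0.0, 1, 0)
    assert y.frame["percent_cleaved"].iloc[0] == pytest.approx(0.8474)
    y = simulate_cleavage_timecourse(83.42, 0.8474, 0.455292, [200.0], 0.0, 1, 0)
    assert y.frame["percent_cleaved"].iloc[0] == pytest.approx(83.42)
    # rate derived by inverting the half-time expression for t50 = 1.5 min
    y = simulate_cleavage_timecourse(83.42, 0.8474, 0.455292, [1.5], 0.0, 1, 0)
    assert y.frame["percent_cleaved"].iloc[0] == pytest.approx(83.42 / 2, abs=5e-3)


def test_cleavage_timecourse_validation():
    with pytest.raises(ValueError):
        simulate_cleavage_timecourse(50.0, 60.0, 0.5, [0, 1, 2])
    with pytest.raises(ValueError):
        simulate_cleavage_timecourse(80.0, 0.0, -1.0, [0, 1, 2])


def test_simulate_qpcr_deterministic():
    args = ({"a": 2.0}, {"act-1": 15.0}, 0.3, 42)
    t1, t2 = simulate_qpcr(*args), simulate_qpcr(*args)
    pd.testing.assert_frame_equal(t1.frame, t2.frame)
    with pytest.raises(ValueError):
        simulate_qpcr({"a": -1.0}, {"act-1": 15.0})
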