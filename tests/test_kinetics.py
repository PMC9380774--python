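import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from termread.kinetics import (
    CleavageKinetics,
    SubstrateSequence,
    TimeCourseSet,
    fit_global_plateau,
    load_substrates,
    percent_cleaved,
    rate_from_t50,
    t50,
)
from termread.simulate import simulate_cleavage_timecourse

TIMEPOINTS = [0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0]


def test_percent_cleaved_arithmetic():
    np.testing.assert_allclose(
        percent_cleaved(np.array([100.0, 0.0, 25.0]), np.array([100.0, 100.0, 100.0])),
        [0.0, 100.0, 75.0],
    )
    with pytest.raises(ValueError, match="positive"):
        percent_cleaved(np.array([1.0]), np.array([0.0]))


def test_t50_half_life_limit():
    assert t50(80.0, 0.0, 0.2) == pytest.approx(math.log(2) / 0.2)


def test_t50_domain_errors():
    with pytest.raises(ValueError):
        t50(80.0, 0.0, -0.1)
    with pytest.raises(ValueError, match="half-maximum"):
        t50(80.0, 45.0, 0.5)


def test_t50_monotone_decreasing_in_k():
    ks = np.linspace(0.05, 2.0, 25)
    vals = [t50(83.42, 0.8474, k) for k in ks]
    assert all(a > b for a, b in zip(vals, vals[1:]))


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    y_max=st.floats(40.0, 99.0),
    y0_frac=st.floats(0.0, 0.4),
    k=st.floats(0.02, 2.0),
)
def test_t50_round_trip_property(y_max, y0_frac, k):
    """Fitting noiseless model output recovers the analytic half-time."""
    y_0 = y0_frac * y_max / 2 * 0.99
    expected = t50(y_max, y_0, k)
    data = simulate_cleavage_timecourse(
        y_max, y_0, k, np.linspace(0, 4 * expected, 10), 0.0, 1, 0
    )
    res = fit_global_plateau(data)
    assert res.t50.iloc[0] == pytest.approx(expected, rel=1e-5)
    assert rate_from_t50(y_max, y_0, expected) == pytest.approx(k, rel=1e-9)


def test_global_fit_recovers_noiseless_parameters():
    data = simulate_cleavage_timecourse(
        83.42, 0.8474, 0.455292, TIMEPOINTS, 0.0, 2, 0, "fast"
    ) + simulate_cleavage_timecourse(
        83.42, 0.8474, 0.0458347, TIMEPOINTS, 0.0, 2, 0, "slow"
    )
    res = fit_global_plateau(data)
    assert res.y_max == pytest.approx(83.42, rel=1e-6)
    assert res.y_0 == pytest.approx(0.8474, rel=1e-4)
    assert res.rates["fast"] == pytest.approx(0.455292, rel=1e-6)
    assert res.rates["slow"] == pytest.approx(0.0458347, rel=1e-6)
    assert (res.r_squared > 0.999999).all()


def test_identical_complexes_get_identical_rates():
    a = simulate_cleavage_timecourse(80.0, 1.0, 0.3, TIMEPOINTS, 0.0, 1, 0, "a")
    b = simulate_cleavage_timecourse(80.0, 1.0, 0.3, TIMEPOINTS, 0.0, 1, 0, "b")
    res = fit_global_plateau(a + b)
    assert res.rates["a"] == pytest.approx(res.rates["b"], rel=1e-9)


def test_flat_timecourse_hits_rate_bound():
    rows = [("flat", 1, t, 100.0 - 2.0, 100.0) for t in TIMEPOINTS]
    data = TimeCourseSet(
        pd.DataFrame(rows, columns=["complex", "replicate", "time_min", "intensity", "intensity_t0"])
    )
    with pytest.warns(UserWarning, match="lower bound or unidentifiable"):
        fit_global_plateau(data)


def test_too_few_timepoints_rejected():
    data = simulate_cleavage_timecourse(80.0, 1.0, 0.3, [0.0, 1.0], 0.0, 3, 0)
    with pytest.raises(ValueError, match="timepoints"):
        CleavageKinetics(data)


def test_bootstrap_ci_seeded_and_tight_when_noiseless():
    data = simulate_cleavage_timecourse(80.0, 1.0, 0.4, TIMEPOINTS, 0.0, 3, 0)
    res = fit_global_plateau(data)
    ci1 = res.bootstrap_ci(n_boot=100, seed=1)
    ci2 = fit_global_plateau(data).bootstrap_ci(n_boot=100, seed=1)
    pd.testing.assert_frame_equal(ci1, ci2)
    width = ci1.loc["t50[complex]", "ci_high"] - ci1.loc["t50[complex]", "ci_low"]
    assert width < 1e-6
    with pytest.raises(ValueError, match="n_boot"):
        res.bootstrap_ci(n_boot=10)


def test_bootstrap_residual_fallback_single_replicate():
    data = simulate_cleavage_timecourse(80.0, 1.0, 0.4, TIMEPOINTS, 2.0, 1, 3)
    res = fit_global_plateau(data)
    with pytest.warns(UserWarning, match="residual"):
        ci = res.bootstrap_ci(n_boot=100, seed=0, method="case")
    assert ci.loc["t50[complex]", "ci_low"] <= ci.loc["t50[complex]", "ci_high"]


def test_summary_reports_parameters():
    data = simulate_cleavage_timecourse(80.0, 1.0, 0.4, TIMEPOINTS, 0.0, 1, 0, "CPF")
    s = fit_global_plateau(data).summary()
    assert "Y_max" in s and "CPF" in s and "t50" in s


def test_packaged_substrates():
    subs = load_substrates()
    pc = subs["pcCYC1"]
    assert len(pc) == 42
    assert "AAGAA" in pc.sequence
    assert pc.pas_location == 20
    full = subs["CYC1"]
    assert full.sequence.startswith(pc.sequence)
    assert set(full.sequence) <= set("ACGU")


def test_substrate_validation():
    with pytest.raises(ValueError, match="RNA"):
        SubstrateSequence("x", "AAGAAT")
    with pytest.raises(ValueError, match="PAS"):
        SubstrateSequence("x", "CCCCCC")
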