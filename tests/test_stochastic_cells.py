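"""Single-cell pattern classification and telegraph-model simulation."""

import numpy as np
import pytest

from lrrsplice import stochastic_cells as sc

from oracles import detection_probability


def _call(FL, D5, S18, HPRT=True, cell="c1", donor="d1"):
    return sc.CellCall(cell_id=cell, donor_id=donor, FL=FL, D5=D5, HPRT=HPRT, S18=S18)


@pytest.mark.parametrize("fl, d5, s18, expected", [
    (True, True, True, "both"),
    (False, False, False, "dropout"),  # 18S absent overrides everything
    (True, False, True, "FL_only"),
    (False, True, True, "D5_only"),
    (False, False, True, "neither"),
    (True, True, False, "dropout"),
])
def test_classify_cell(fl, d5, s18, expected):
    assert sc.classify_cell(_call(fl, d5, s18)) == expected


def test_pattern_summary_single_cell():
    s = sc.pattern_summary([_call(True, False, True)])
    assert s.pooled_counts["FL_only"] == 1
    assert s.pooled_fractions["FL_only"] == 1.0
    assert s.n_cells == 1


def test_pattern_summary_counts_sum_to_n():
    calls, _ = sc.simulate_cells(500, seed=3)
    s = sc.pattern_summary(calls)
    assert sum(s.pooled_counts.values()) == 500
    assert s.counts.to_numpy().sum() == 500
    # fractions computed over non-dropout cells only
    nondrop = 500 - s.pooled_counts["dropout"]
    assert sum(s.pooled_fractions.values()) == pytest.approx(1.0)
    assert s.pooled_counts["both"] / nondrop == pytest.approx(
        s.pooled_fractions["both"]
    )


def test_pattern_summary_matches_direct_tally():
    calls, _ = sc.simulate_cells(300, seed=9)
    s = sc.pattern_summary(calls)
    direct = {c: 0 for c in sc.CATEGORIES}
    for call in calls:
        direct[sc.classify_cell(call)] += 1
    assert s.pooled_counts == direct


def test_all_dropout_donor_flagged():
    calls = [_call(False, False, False, cell=f"c{i}", donor="dX") for i in range(4)]
    s = sc.pattern_summary(calls)
    assert s.all_dropout_donors == ["dX"]
    assert np.isnan(s.fractions.loc["dX"]).all()


def test_independence_or_near_one_for_independent_isoforms():
    """With independent FL/D5 processes, log OR within 3 SE of 0 at 10,000 cells."""
    calls, _ = sc.simulate_cells(10_000, seed=11, technical_dropout=0.0)
    s = sc.pattern_summary(calls)
    odds, corrected = sc.independence_odds_ratio(s)
    assert not corrected
    c = s.pooled_counts
    se = np.sqrt(sum(1 / c[k] for k in ("both", "neither", "FL_only", "D5_only")))
    assert abs(np.log(odds)) < 3 * se


def test_perfectly_coupled_isoforms_flagged():
    calls = [_call(True, True, True, cell=f"a{i}") for i in range(50)]
    calls += [_call(False, False, True, cell=f"b{i}") for i in range(50)]
    odds, corrected = sc.independence_odds_ratio(sc.pattern_summary(calls))
    assert corrected
    assert odds > 1000  # Haldane-capped stand-in for a diverging ratio


def test_mutually_exclusive_isoforms_or_below_one():
    calls = [_call(True, False, True, cell=f"a{i}") for i in range(40)]
    calls += [_call(False, True, True, cell=f"b{i}") for i in range(40)]
    calls += [_call(True, True, True, cell="c0"), _call(False, False, True, cell="d0")]
    odds, _ = sc.independence_odds_ratio(sc.pattern_summary(calls))
    assert odds < 1


def test_saturating_parameters_detect_everything():
    params = {
        t: sc.TelegraphParams(k_on=50.0, k_off=0.01, k_syn=5000.0, capture_p=1.0)
        for t in sc.TARGETS
    }
    calls, _ = sc.simulate_cells(200, seed=5, params=params, technical_dropout=0.0)
    assert all(sc.classify_cell(c) == "both" for c in calls)


def test_silent_isoform_never_detected():
    params = dict(sc.DEFAULT_ISOFORM_PARAMS)
    params["D5"] = sc.TelegraphParams(k_on=0.5, k_off=5.0, k_syn=1e-9)
    with pytest.raises(ValueError):
        sc.TelegraphParams(k_on=0.5, k_off=5.0, k_syn=0.0)  # rates must be positive
    calls, _ = sc.simulate_cells(2000, seed=6, params=params, technical_dropout=0.0)
    s = sc.pattern_summary(calls)
    assert s.pooled_counts["D5_only"] == 0 and s.pooled_counts["both"] == 0


def test_detection_frequency_matches_integration_oracle():
    """Simulated FL detection rate within 3 MC SE of the beta-Poisson
    detection probability computed by numerical integration."""
    n = 10_000
    calls, _ = sc.simulate_cells(n, seed=11, technical_dropout=0.0)
    p = sc.DEFAULT_ISOFORM_PARAMS["FL"]
    expected = detection_probability(p.k_on, p.k_off, p.k_syn, p.k_deg, p.capture_p)
    observed = sum(c.FL for c in calls) / n
    se = np.sqrt(expected * (1 - expected) / n)
    assert abs(observed - expected) < 3 * se


def test_stationary_mean_matches_closed_form():
    """Mean simulated molecule count within 3 SE of k_syn*k_on/(k_deg*(k_on+k_off))."""
    n = 10_000
    _, truth = sc.simulate_cells(n, seed=21, technical_dropout=0.0)
    for t in sc.TARGETS:
        m = truth[f"{t}_molecules"].to_numpy()
        expected = sc.telegraph_stationary_mean(sc.DEFAULT_ISOFORM_PARAMS[t])
        se = m.std(ddof=1) / np.sqrt(n)
        assert abs(m.mean() - expected) < 3 * se, t


def test_default_parameters_reproduce_majority_pattern():
    """Cells detecting both isoforms are the minority: most informative cells
    show one isoform or neither."""
    calls, _ = sc.simulate_cells(5000, seed=13)
    c = sc.pattern_summary(calls).pooled_counts
    assert c["both"] < c["FL_only"] + c["D5_only"] + c["neither"]
    assert c["both"] > 0  # but co-expression does occur (non-deterministic splicing)


def test_simulation_deterministic_under_seed():
    a, ta = sc.simulate_cells(100, seed=42)
    b, tb = sc.simulate_cells(100, seed=42)
    assert a == b
    assert ta.equals(tb)


def test_calls_frame_roundtrip():
    calls, _ = sc.simulate_cells(50, seed=8)
    df = sc.calls_to_frame(calls)
    assert sc.frame_to_calls(df) == calls
    assert list(df.columns) == ["cell_id", "donor_id", "FL", "D5", "HPRT", "S18"]


def test_gillespie_trajectory_fluctuates_and_obeys_mean():
    p = sc.TelegraphParams(k_on=1.0, k_off=1.0, k_syn=20.0)
    traj = sc.simulate_trajectory(p, t_max=500.0, seed=2)
    m = traj.mrna.to_numpy()
    assert m.max() > m.min()  # bursting produces oscillation
    expected = sc.telegraph_stationary_mean(p)
    assert abs(m[len(m) // 5 :].mean() - expected) < 0.3 * expected
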