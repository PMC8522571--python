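"""Regression and matching estimators, and the clustered sandwich."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from didsim import (
    PanelData,
    RngSpec,
    cluster_robust_se,
    draw_panel,
    fit_ca,
    fit_estimator,
    fit_matched,
    fit_simple,
    fit_tva,
    make_scenario,
    match_units,
)
from didsim.estimators import _design_matrix
from didsim.exceptions import MatchingError, SingularDesignError


def _panel_from_wide(y, treated, t0, x=None):
    """Build a PanelData from an (n_units, n_times) outcome matrix."""
    y = np.asarray(y, dtype=float)
    n, T = y.shape
    x = np.zeros_like(y) if x is None else np.asarray(x, dtype=float)
    times = np.arange(1, T + 1)
    frame = pd.DataFrame(
        {
            "unit": np.repeat(np.arange(n), T),
            "time": np.tile(times, n),
            "treated": np.repeat(np.asarray(treated, dtype=int), T),
            "post": np.tile((times >= t0).astype(int), n),
            "x": x.ravel(),
            "y": y.ravel(),
        }
    )
    return PanelData(frame=frame, t0=t0)


# ----------------------------------------------------------------------
# regression estimators
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "sid, fitter, extra",
    [
        # the simple model omits x, so exactness also needs sigma_x = 0
        ("1", fit_simple, {"sigma_x": 0.0}),
        ("4a", fit_simple, {"sigma_x": 0.0}),
        # covariate-adjusted models keep sigma_x > 0 so x stays full rank
        ("1", fit_ca, {}),
        ("5a", fit_ca, {}),
        ("2", fit_tva, {}),
        ("5b", fit_tva, {}),
    ],
)
def test_noiseless_exact_recovery(sid, fitter, extra, noiseless_panel_factory):
    """With no outcome noise and the truth inside the model span, the
    treatment-by-post coefficient equals gamma exactly."""
    _, panel = noiseless_panel_factory(sid, **extra)
    assert fitter(panel).gamma_hat == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize("spec_name", ["simple", "ca", "tva"])
def test_ols_matches_normal_equations(spec_name):
    """Small-instance oracle: coefficients agree with an independent
    normal-equations solve on random 20-unit panels."""
    config = make_scenario("5b", {"n_units": 20})
    panel = draw_panel(config, RngSpec(21))
    fit = fit_estimator(spec_name, panel)
    X, names = _design_matrix(panel.frame, spec_name)
    y = panel.frame["y"].to_numpy()
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(fit.coefficients.to_numpy(), beta, atol=1e-8)
    assert fit.n_units_used == 20


def test_shift_and_scale_equivariance(small_panel):
    base = fit_simple(small_panel)
    shifted = PanelData(small_panel.frame.assign(y=small_panel.frame["y"] + 5.0),
                        t0=small_panel.t0)
    fs = fit_simple(shifted)
    assert fs.gamma_hat == pytest.approx(base.gamma_hat, abs=1e-10)
    assert fs.coefficients["const"] == pytest.approx(
        base.coefficients["const"] + 5.0, abs=1e-10
    )
    scaled = PanelData(small_panel.frame.assign(y=small_panel.frame["y"] * 3.0),
                       t0=small_panel.t0)
    fc = fit_simple(scaled)
    assert fc.gamma_hat == pytest.approx(3.0 * base.gamma_hat, abs=1e-9)
    assert fc.se_gamma == pytest.approx(3.0 * base.se_gamma, abs=1e-9)


def test_constant_covariate_is_singular(small_panel):
    degenerate = PanelData(small_panel.frame.assign(x=1.0), t0=small_panel.t0)
    with pytest.raises(SingularDesignError):
        fit_ca(degenerate)


def test_single_period_panel_rejected():
    rng = np.random.default_rng(0)
    panel = _panel_from_wide(rng.normal(size=(10, 1)), [1] * 5 + [0] * 5, t0=1)
    with pytest.raises(ValueError):
        fit_simple(panel)


def test_one_group_panel_rejected():
    rng = np.random.default_rng(0)
    panel = _panel_from_wide(rng.normal(size=(6, 4)), [1] * 6, t0=3)
    with pytest.raises(ValueError):
        fit_simple(panel)


# ----------------------------------------------------------------------
# cluster-robust sandwich
# ----------------------------------------------------------------------

def test_sandwich_matches_hand_computation():
    """3-unit, 2-time toy panel checked against an explicit per-cluster
    loop implementation of the CR1 sandwich."""
    X = np.array(
        [[1.0, 0.0], [1.0, 1.0], [1.0, 0.5], [1.0, 1.5], [1.0, 0.2], [1.0, 0.8]]
    )
    e = np.array([0.3, -0.1, 0.2, 0.4, -0.5, 0.1])
    w = np.array([1.0, 1.0, 2.0, 2.0, 1.0, 1.0])
    clusters = np.array([0, 0, 1, 1, 2, 2])

    bread = np.linalg.inv(X.T @ np.diag(w) @ X)
    meat = np.zeros((2, 2))
    for g in np.unique(clusters):
        rows = clusters == g
        s = X[rows].T @ np.diag(w[rows]) @ e[rows]
        meat += np.outer(s, s)
    G, (N, k) = 3, X.shape
    expected = np.sqrt(
        np.diag((G / (G - 1)) * ((N - 1) / (N - k)) * bread @ meat @ bread)
    )
    np.testing.assert_allclose(cluster_robust_se(X, e, w, clusters), expected, rtol=1e-12)


def test_singleton_clusters_reduce_to_hc1():
    rng = np.random.default_rng(4)
    X = np.column_stack([np.ones(40), rng.normal(size=40)])
    y = X @ np.array([1.0, 2.0]) + rng.normal(size=40)
    res = sm.OLS(y, X).fit(cov_type="HC1")
    ses = cluster_robust_se(X, y - X @ res.params, np.ones(40), np.arange(40))
    np.testing.assert_allclose(ses, res.bse, rtol=1e-10)


def test_sandwich_matches_statsmodels_cluster(small_panel):
    X, names = _design_matrix(small_panel.frame, "ca")
    y = small_panel.frame["y"].to_numpy()
    units = small_panel.frame["unit"].to_numpy()
    res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": units})
    ses = cluster_robust_se(X, y - X @ res.params, np.ones(len(y)), units)
    np.testing.assert_allclose(ses, res.bse, rtol=1e-10)


def test_single_cluster_rejected():
    X = np.column_stack([np.ones(4), np.arange(4.0)])
    with pytest.raises(ValueError):
        cluster_robust_se(X, np.ones(4), np.ones(4), np.zeros(4))


# ----------------------------------------------------------------------
# matching
# ----------------------------------------------------------------------

def test_exact_twin_matched_at_zero_distance():
    y = np.array(
        [[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 9.0], [5.0, 5.0, 2.0, 2.0]]
    )
    # unit 1 (control) equals unit 0 (treated) on the two pretreatment periods
    panel = _panel_from_wide(y, [1, 0, 0], t0=3)
    matched = match_units(panel, "level")
    assert matched.match_map == {0: 1}
    assert matched.weights.to_dict() == {0: 1.0, 1: 1.0}


def test_with_replacement_multiplicity():
    y = np.array([[0.0, 0.0, 1.0], [0.1, 0.1, 1.0], [0.0, 0.05, 0.0]])
    panel = _panel_from_wide(y, [1, 1, 0], t0=3)
    matched = match_units(panel, "level")
    assert matched.match_map == {0: 2, 1: 2}
    assert matched.weights[2] == 2.0
    assert matched.weights.sum() == 2 + 2  # treated weights + control multiplicity


def test_matching_agrees_with_exhaustive_search():
    rng = np.random.default_rng(11)
    x = rng.normal(size=(10, 1))
    y = rng.normal(size=(10, 6))
    panel = _panel_from_wide(y, [1] * 5 + [0] * 5, t0=4, x=np.repeat(x, 6, axis=1))
    matched = match_units(panel, "cov")
    # brute force over standardized scalar covariates
    z = (x[:, 0] - x[:, 0].mean()) / x[:, 0].std(ddof=1)
    for treated_id in range(5):
        dists = {c: abs(z[treated_id] - z[c]) for c in range(5, 10)}
        assert matched.match_map[treated_id] == min(dists, key=dists.get)


def test_distance_ties_break_to_lowest_control_id():
    y = np.array([[1.0, 1.0, 0.0], [2.0, 2.0, 0.0], [2.0, 2.0, 0.0], [0.0, 0.0, 0.0]])
    panel = _panel_from_wide(y, [1, 0, 0, 0], t0=3)
    matched = match_units(panel, "level")
    assert matched.match_map[0] in (1, 2)
    assert matched.match_map[0] == 1  # units 1 and 2 tie; lowest id wins


def test_self_matching_has_zero_distance():
    rng = np.random.default_rng(2)
    block = rng.normal(size=(6, 5))
    y = np.vstack([block, block])  # controls are exact copies of treated
    panel = _panel_from_wide(y, [1] * 6 + [0] * 6, t0=4)
    matched = match_units(panel, "level")
    for treated_id, control_id in matched.match_map.items():
        assert control_id == treated_id + 6


def test_trend_matching_needs_two_pre_periods():
    y = np.random.default_rng(0).normal(size=(6, 4))
    panel = _panel_from_wide(y, [1, 1, 1, 0, 0, 0], t0=2)
    with pytest.raises(MatchingError):
        match_units(panel, "trend")


def test_matching_needs_controls():
    y = np.random.default_rng(0).normal(size=(4, 4))
    panel = _panel_from_wide(y, [1, 1, 1, 1], t0=3)
    with pytest.raises(MatchingError):
        match_units(panel, "level")


def test_matched_fit_equals_row_duplication(small_panel):
    """Frequency-weighting reused controls gives the same point estimate as
    physically duplicating their rows."""
    fit_w = fit_matched(small_panel, "cov")
    matched = match_units(small_panel, "cov")
    # rebuild by duplication: every treated unit once, its matched control once per use
    df = small_panel.frame
    pieces = [df[df["treated"] == 1]]
    for k, (treated_id, control_id) in enumerate(matched.match_map.items()):
        sub = df[df["unit"] == control_id].copy()
        sub["unit"] = 10_000 + k  # fresh id per duplication
        pieces.append(sub)
    dup = pd.concat(pieces, ignore_index=True)
    fit_d = fit_simple(PanelData(frame=dup, t0=small_panel.t0))
    assert fit_w.gamma_hat == pytest.approx(fit_d.gamma_hat, abs=1e-10)


def test_unknown_estimator_name(small_panel):
    with pytest.raises(ValueError):
        fit_estimator("match_bogus", small_panel)
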