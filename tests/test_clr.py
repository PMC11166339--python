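"""Conditional logistic regression: analytic derivatives, oracles, crude ORs.

Oracles used here are independent of the fitted path: finite differences
for the derivatives, a dense grid search of the conditional likelihood,
the closed-form discordant-pair ratio for 1:1 binary designs, the
Mantel-Haenszel pooled OR (statsmodels) for stratified 2x2 data, and
statsmodels' ConditionalLogit as an external implementation.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nestedcc import (
    ConvergenceError,
    CrudeTable,
    StratifiedData,
    conditional_loglik,
    crude_or,
    fit_clr,
    profile_ci,
    run_subgroup,
    summarize_exposure_table,
)
from conftest import make_binary_strata


def _loglik_only(beta, data):
    return conditional_loglik(np.atleast_1d(beta), data)[0]


def test_uniform_loglik_at_zero():
    """At beta = 0 each stratum of size m contributes -log m."""
    X = np.array([[1.0], [0.0], [0.0], [1.0], [0.0]])
    y = np.array([1.0, 0.0, 0.0, 1.0, 0.0])
    s = np.array([0, 0, 0, 1, 1])
    data = StratifiedData(X, y, s)
    ll, score, info = conditional_loglik(np.zeros(1), data)
    assert ll == pytest.approx(-np.log(3) - np.log(2))


def test_concordant_strata_carry_no_information():
    X = np.array([[1.0], [1.0], [1.0]])
    y = np.array([1.0, 0.0, 0.0])
    s = np.array([0, 0, 0])
    data = StratifiedData(X, y, s)
    for b in (-2.0, 0.0, 3.0):
        ll, score, _ = conditional_loglik(np.array([b]), data)
        assert ll == pytest.approx(-np.log(3))
        assert score == pytest.approx(0.0)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), beta0=st.floats(-1.5, 1.5), beta1=st.floats(-1.5, 1.5))
def test_derivatives_match_finite_differences(seed, beta0, beta1):
    """Analytic score and information vs central differences (2 columns)."""
    rng = np.random.default_rng(seed)
    n_strata = 12
    X, y, s = [], [], []
    for i in range(n_strata):
        m = rng.integers(2, 6)
        X.extend(rng.integers(0, 2, size=(m, 2)).astype(float))
        yy = np.zeros(m)
        yy[0] = 1.0
        y.extend(yy)
        s.extend([i] * m)
    data = StratifiedData(np.array(X), np.array(y), np.array(s))
    beta = np.array([beta0, beta1])
    ll, score, info = conditional_loglik(beta, data)
    h = 1e-6
    for j in range(2):
        e = np.zeros(2)
        e[j] = h
        fd_score = (_loglik_only(beta + e, data) - _loglik_only(beta - e, data)) / (2 * h)
        assert score[j] == pytest.approx(fd_score, rel=1e-5, abs=1e-5)
        fd_info = -(
            conditional_loglik(beta + e, data)[1] - conditional_loglik(beta - e, data)[1]
        ) / (2 * h)
        np.testing.assert_allclose(info[:, j], fd_info, rtol=1e-5, atol=1e-5)


def test_discordant_pairs_closed_form():
    """1:1 binary data: OR = (case-exposed pairs)/(control-exposed pairs)."""
    X, y, s = [], [], []
    sid = 0
    for _ in range(10):  # case exposed, control not
        X += [[1.0], [0.0]]; y += [1.0, 0.0]; s += [sid, sid]; sid += 1
    for _ in range(5):  # control exposed, case not
        X += [[0.0], [1.0]]; y += [1.0, 0.0]; s += [sid, sid]; sid += 1
    for _ in range(7):  # concordant pairs: no information
        X += [[1.0], [1.0]]; y += [1.0, 0.0]; s += [sid, sid]; sid += 1
    fit = fit_clr(StratifiedData(np.array(X), np.array(y), np.array(s)))
    assert fit.or_estimates[0] == pytest.approx(2.0, abs=1e-8)
    assert fit.n_strata_dropped == 7
    assert fit.n_strata_used == 15


def test_fit_matches_grid_search_oracle():
    """Newton fit vs dense grid search on five hand-built 1:2 strata."""
    strata = [
        ([1, 0, 0], [1, 0, 0]),
        ([1, 0, 1], [1, 0, 0]),
        ([0, 1, 0], [1, 0, 0]),
        ([1, 1, 0], [1, 0, 0]),
        ([0, 0, 1], [1, 0, 0]),
    ]
    X, y, s = [], [], []
    for i, (xs, ys) in enumerate(strata):
        X += [[float(v)] for v in xs]
        y += [float(v) for v in ys]
        s += [i] * 3
    data = StratifiedData(np.array(X), np.array(y), np.array(s))

    # oracle: direct evaluation of prod_s exp(x_case b)/sum_j exp(x_j b)
    def oracle_ll(b):
        total = 0.0
        for xs, ys in strata:
            num = np.exp(b * xs[int(np.argmax(ys))])
            den = sum(np.exp(b * x) for x in xs)
            total += np.log(num / den)
        return total

    grid = np.arange(-5.0, 5.0, 1e-4)
    vals = np.array([oracle_ll(b) for b in grid])
    best = grid[np.argmax(vals)]
    fit = fit_clr(data)
    assert fit.beta[0] == pytest.approx(best, abs=1e-4)


def test_agreement_with_mantel_haenszel(rng):
    """CLR approaches the MH pooled OR on many single-exposure strata."""
    sm_ct = pytest.importorskip("statsmodels.stats.contingency_tables")
    X, y, s = make_binary_strata(rng, n_strata=500, stratum_size=6,
                                 p_case_exposed=0.55, p_ctrl_exposed=0.35)
    data = StratifiedData(X, y, s)
    fit = fit_clr(data)
    tables = []
    for i in range(500):
        xs = X[s == i, 0]
        ys = y[s == i]
        a = np.sum((xs == 1) & (ys == 1)); b = np.sum((xs == 1) & (ys == 0))
        c = np.sum((xs == 0) & (ys == 1)); d = np.sum((xs == 0) & (ys == 0))
        tables.append(np.array([[a, b], [c, d]]))
    mh = sm_ct.StratifiedTable(tables).oddsratio_pooled
    assert fit.or_estimates[0] == pytest.approx(mh, rel=0.10)


def test_agreement_with_statsmodels_conditional_logit(rng):
    """External implementation as an independent cross-check."""
    sm = pytest.importorskip("statsmodels.api")
    from statsmodels.discrete.conditional_models import ConditionalLogit

    X, y, s = make_binary_strata(rng, n_strata=150, stratum_size=4,
                                 p_case_exposed=0.6, p_ctrl_exposed=0.3)
    fit = fit_clr(StratifiedData(X, y, s))
    ext = ConditionalLogit(y, X, groups=s).fit(disp=False)
    # statsmodels stops at a looser BFGS gradient tolerance than our Newton
    assert fit.beta[0] == pytest.approx(ext.params[0], abs=5e-4)
    assert fit.se[0] == pytest.approx(ext.bse[0], rel=1e-3)


def test_invariance_to_stratum_relabelling_and_row_order(rng):
    X, y, s = make_binary_strata(rng, n_strata=60, stratum_size=5,
                                 p_case_exposed=0.5, p_ctrl_exposed=0.3)
    fit1 = fit_clr(StratifiedData(X, y, s))
    perm = rng.permutation(len(y))
    relabel = {old: new for new, old in enumerate(rng.permutation(60))}
    s2 = np.array([relabel[v] for v in s])
    fit2 = fit_clr(StratifiedData(X[perm], y[perm], s2[perm]))
    assert fit1.beta[0] == pytest.approx(fit2.beta[0], abs=1e-10)
    assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-10)


def test_complete_separation_raises():
    X, y, s = [], [], []
    for i in range(12):  # exposure perfectly predicts case status
        X += [[1.0], [0.0], [0.0]]
        y += [1.0, 0.0, 0.0]
        s += [i] * 3
    with pytest.raises(ConvergenceError):
        fit_clr(StratifiedData(np.array(X), np.array(y), np.array(s)))


def test_profile_ci_brackets_wald(rng):
    X, y, s = make_binary_strata(rng, n_strata=200, stratum_size=5,
                                 p_case_exposed=0.55, p_ctrl_exposed=0.35)
    data = StratifiedData(X, y, s)
    fit = fit_clr(data)
    lo, hi = profile_ci(data, fit, term=0)
    assert lo < fit.or_estimates[0] < hi
    wald = fit.wald_ci_95()[0]
    assert lo == pytest.approx(wald[0], rel=0.15)
    assert hi == pytest.approx(wald[1], rel=0.15)


# --- crude odds ratios ------------------------------------------------------

PRINTED_COUNTS = {  # study-shaped 3x2 table: (cases, controls)
    "non_user": (93, 724),
    "continuous_user": (52, 597),
    "irregular_user": (70, 195),
}


def test_crude_or_reproduces_published_values():
    table = CrudeTable(counts=dict(PRINTED_COUNTS))
    out = crude_or(table)
    or_c, (lo_c, hi_c) = out["continuous_user"]
    or_i, _ = out["irregular_user"]
    assert round(or_c, 2) == 0.68
    assert round(or_i, 2) == 2.79
    assert (round(lo_c, 2), round(hi_c, 2)) == (0.47, 0.97)


def test_crude_or_null_table():
    table = CrudeTable(
        counts={"non_user": (50, 500), "continuous_user": (20, 200), "irregular_user": (10, 100)}
    )
    out = crude_or(table)
    assert out["continuous_user"][0] == pytest.approx(1.0)
    assert out["irregular_user"][0] == pytest.approx(1.0)


def test_crude_or_zero_cell_raises():
    table = CrudeTable(
        counts={"non_user": (93, 724), "continuous_user": (0, 597), "irregular_user": (70, 195)}
    )
    with pytest.raises(ValueError, match="continuity"):
        crude_or(table)


def test_column_percentages():
    table = CrudeTable(counts=dict(PRINTED_COUNTS))
    pct = table.column_percentages()
    assert round(pct["non_user"][0], 1) == 43.3
    assert round(pct["continuous_user"][1], 1) == 39.4
    assert round(pct["irregular_user"][0], 1) == 32.6


def _toy_sets():
    """Tiny classified matched-set frame with known tallies."""
    rows = []
    cats = ["non_user", "continuous_user", "irregular_user"]
    rng = np.random.default_rng(5)
    for sid in range(40):
        rows.append({"set_id": sid, "role": "case", "category": cats[rng.integers(3)],
                     "age_at_t0": 60 + sid % 30, "index_nsaid_type": "loxoprofen"})
        for _ in range(3):
            rows.append({"set_id": sid, "role": "control", "category": cats[rng.integers(3)],
                         "age_at_t0": 60.0, "index_nsaid_type": "loxoprofen"})
    return pd.DataFrame(rows)


def test_summarize_counts_equal_brute_force_tally():
    sets = _toy_sets()
    res = summarize_exposure_table(sets)
    for cat in ("non_user", "continuous_user", "irregular_user"):
        expect_case = len(sets[(sets["category"] == cat) & (sets["role"] == "case")])
        expect_ctrl = len(sets[(sets["category"] == cat) & (sets["role"] == "control")])
        assert res.table.counts[cat] == (expect_case, expect_ctrl)
    assert res.frame["cases"].sum() == 40


def test_summarize_empty_category_marked_inestimable():
    sets = _toy_sets()
    sets = sets[sets["category"] != "irregular_user"].copy()
    res = summarize_exposure_table(sets)
    row = res.frame[res.frame["category"] == "irregular_user"].iloc[0]
    assert row["cases"] == 0 and row["controls"] == 0
    assert np.isnan(row["adj_or"])
    assert "inestimable" in res.report()


def test_subgroup_degenerate_partition_equals_full_fit():
    sets = _toy_sets()  # every case is loxoprofen and aged >= 65 or < 65 mix
    res_full = summarize_exposure_table(sets)
    by_drug = run_subgroup(sets, "index_nsaid")
    assert set(by_drug) == {"loxoprofen"}
    np.testing.assert_allclose(
        by_drug["loxoprofen"].fit.beta, res_full.fit.beta, atol=1e-10
    )
    by_age = run_subgroup(sets, "age")
    assert set(by_age) <= {"under_65", "65_plus"}
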