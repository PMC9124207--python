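"""Enrichment-ratio machinery: enumeration and closed-form oracles for the
permutation null, bootstrap intervals, stratified analysis and MetS
scoring."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metsom.multimorbidity import (
    MetsThresholds,
    bootstrap_er_ci,
    enrichment_ratio,
    expected_multimorbidity_independent,
    mets_classify,
    permutation_null,
    stratified_enrichment,
)

WORKED_PANEL = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])


def _enumerate_null_mean(X):
    """Exhaustive enumeration over all per-column arrangements."""
    n, k = X.shape
    col_perms = [set(itertools.permutations(X[:, j].tolist())) for j in range(k)]
    props = []
    for combo in itertools.product(*col_perms):
        tall = np.array(combo).sum(axis=0)
        props.append((tall >= 2).mean())
    return float(np.mean(props))


# ---------------------------------------------------------------------------
# closed form


@pytest.mark.parametrize(
    "p, expected",
    [
        ([1.0, 1.0], 1.0),
        ([0.5, 0.5], 0.25),
        ([0.1, 0.2, 0.3], 0.098),  # 1 - 0.504 - 0.398
    ],
)
def test_independence_closed_form(p, expected):
    assert expected_multimorbidity_independent(p) == pytest.approx(expected, abs=1e-12)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=5)
)
def test_closed_form_matches_brute_force_enumeration(p):
    """Sum over all 2^k outcome patterns with >= 2 positives."""
    k = len(p)
    total = 0.0
    for pattern in itertools.product([0, 1], repeat=k):
        if sum(pattern) >= 2:
            prob = 1.0
            for pj, bit in zip(p, pattern):
                prob *= pj if bit else (1.0 - pj)
            total += prob
    assert expected_multimorbidity_independent(p) == pytest.approx(total, abs=1e-9)


# ---------------------------------------------------------------------------
# permutation null


def test_zero_column_makes_null_identically_zero():
    panel = np.array([[0, 1], [0, 0], [0, 1], [0, 0]])
    null = permutation_null(panel, n_perm=200, seed=0)
    assert (null == 0).all()


def test_worked_panel_null_mean_matches_enumeration():
    """A=[1,1,0,0], B=[1,1,0,0]: enumeration over the 36 equally likely
    arrangements gives an expected multimorbid proportion of exactly 0.25."""
    assert _enumerate_null_mean(WORKED_PANEL) == pytest.approx(0.25, abs=1e-12)
    null = permutation_null(WORKED_PANEL, n_perm=10_000, seed=1)
    se = null.std(ddof=1) / np.sqrt(len(null))
    assert abs(null.mean() - 0.25) < 3 * se


def test_tally_and_shuffle_samplers_agree():
    """The fast tally-chain sampler and the literal column shuffle draw from
    the same distribution (means within 4 combined Monte-Carlo SEs)."""
    rng = np.random.default_rng(2)
    X = (rng.uniform(size=(300, 4)) < [0.2, 0.35, 0.1, 0.5]).astype(int)
    a = permutation_null(X, n_perm=4000, seed=3)
    b = permutation_null(X, n_perm=4000, seed=4, method="shuffle")
    se = np.hypot(a.std(ddof=1) / np.sqrt(len(a)), b.std(ddof=1) / np.sqrt(len(b)))
    assert abs(a.mean() - b.mean()) < 4 * se
    assert abs(a.std(ddof=1) - b.std(ddof=1)) / b.std(ddof=1) < 0.15


def test_small_panel_enumeration_oracle_tally_sampler():
    """<= 5 rows, 2 columns: sampled null mean matches exhaustive
    enumeration within 3 Monte-Carlo SEs."""
    rng = np.random.default_rng(5)
    for _ in range(3):
        X = (rng.uniform(size=(5, 2)) < 0.5).astype(int)
        exact = _enumerate_null_mean(X)
        null = permutation_null(X, n_perm=10_000, seed=6)
        se = max(null.std(ddof=1) / np.sqrt(len(null)), 1e-12)
        assert abs(null.mean() - exact) <= 3 * se + 1e-12


def test_shuffle_replicates_preserve_column_marginals_exactly():
    rng = np.random.default_rng(7)
    X = (rng.uniform(size=(50, 3)) < [0.3, 0.5, 0.1]).astype(int)
    # the property is intrinsic to permutation; verify on raw shuffles
    for _ in range(20):
        perm = np.column_stack([rng.permutation(X[:, j]) for j in range(3)])
        assert (perm.sum(axis=0) == X.sum(axis=0)).all()
    # and the tally sampler respects them by construction: null of a panel
    # with all-ones columns is deterministic
    ones = np.ones((10, 2), dtype=int)
    assert (permutation_null(ones, 100, seed=8) == 1.0).all()


def test_large_panel_null_mean_converges_to_closed_form():
    rng = np.random.default_rng(9)
    p = [0.1, 0.05, 0.2, 0.15]
    X = (rng.uniform(size=(10_000, 4)) < p).astype(int)
    null = permutation_null(X, n_perm=2000, seed=10)
    expected = expected_multimorbidity_independent(X.mean(axis=0))
    assert abs(null.mean() - expected) / expected < 0.01


def test_null_is_seed_reproducible():
    np.testing.assert_array_equal(
        permutation_null(WORKED_PANEL, 500, seed=11),
        permutation_null(WORKED_PANEL, 500, seed=11),
    )


def test_single_row_panel_warns_degenerate():
    with pytest.warns(UserWarning, match="degenerate"):
        permutation_null(np.array([[1, 1]]), n_perm=10, seed=0)


# ---------------------------------------------------------------------------
# enrichment ratio


def test_worked_panel_enrichment_ratio_is_two():
    res = enrichment_ratio(WORKED_PANEL, n_perm=10_000, seed=12)
    assert res.observed_prop == 0.5
    assert res.er == pytest.approx(2.0, rel=0.05)


def test_independent_panel_er_near_one():
    rng = np.random.default_rng(13)
    X = (rng.uniform(size=(10_000, 4)) < [0.1, 0.05, 0.2, 0.15]).astype(int)
    res = enrichment_ratio(X, n_perm=2000, seed=14)
    assert 0.9 < res.er < 1.1


def test_duplicating_rows_leaves_er_invariant_in_expectation():
    rng = np.random.default_rng(15)
    X = (rng.uniform(size=(2000, 3)) < [0.2, 0.3, 0.25]).astype(int)
    r1 = enrichment_ratio(X, n_perm=2000, seed=16)
    r2 = enrichment_ratio(np.vstack([X, X]), n_perm=2000, seed=17)
    assert r2.er == pytest.approx(r1.er, rel=0.05)


def test_degenerate_er_flags():
    zero = np.zeros((20, 2), dtype=int)
    res = enrichment_ratio(zero, n_perm=100, seed=18)
    assert res.er == 1.0 and any("degenerate" in f for f in res.flags)
    one_hot = np.zeros((20, 2), dtype=int)
    one_hot[0] = [1, 1]
    one_hot[:, 1] = 0  # second column empty -> null mean 0, observed 0
    res2 = enrichment_ratio(one_hot, n_perm=100, seed=19)
    assert res2.er == 1.0 or np.isinf(res2.er)


def test_er_p_value_detects_planted_cooccurrence():
    rng = np.random.default_rng(20)
    frail = rng.normal(0, 1.2, 3000)
    from scipy.special import expit

    X = np.column_stack(
        [(rng.uniform(size=3000) < expit(-2.2 + frail)).astype(int) for _ in range(4)]
    )
    res = enrichment_ratio(X, n_perm=1000, seed=21)
    assert res.er > 1.0 and res.p_value < 0.01


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_interval_ordered_and_covers_planted_enrichment():
    rng = np.random.default_rng(22)
    from scipy.special import expit

    frail = rng.normal(0, 1.5, 2000)
    X = np.column_stack(
        [(rng.uniform(size=2000) < expit(-2.0 + frail)).astype(int) for _ in range(4)]
    )
    lo, hi = bootstrap_er_ci(X, n_boot=400, n_perm_inner=400, seed=23)
    assert lo <= hi
    assert lo > 1.0  # strong planted co-occurrence excludes independence


def test_bootstrap_covers_one_for_independent_panels():
    rng = np.random.default_rng(24)
    hits = 0
    for rep in range(10):
        X = (rng.uniform(size=(1500, 4)) < [0.15, 0.1, 0.2, 0.12]).astype(int)
        lo, hi = bootstrap_er_ci(X, n_boot=200, n_perm_inner=200, seed=25 + rep)
        hits += lo <= 1.0 <= hi
    assert hits >= 8


# ---------------------------------------------------------------------------
# stratified


def test_identical_strata_get_similar_ers():
    rng = np.random.default_rng(26)
    X = (rng.uniform(size=(4000, 4)) < [0.2, 0.15, 0.25, 0.1]).astype(int)
    panel = pd.DataFrame(np.vstack([X, X]), index=[f"p{i}" for i in range(8000)],
                         columns=list("abcd"))
    strata = pd.Series(["s1"] * 4000 + ["s2"] * 4000, index=panel.index)
    res = stratified_enrichment(panel, strata, n_perm=1000, seed=27)
    assert res["s1"].er == pytest.approx(res["s2"].er, abs=0.1)


def test_doubling_marginals_raises_raw_multimorbidity_not_er():
    """Higher disease frequency alone inflates co-occurrence; the ER keeps
    tracking only the excess beyond chance."""
    rng = np.random.default_rng(28)
    p = np.array([0.06, 0.04, 0.1, 0.08])
    X1 = (rng.uniform(size=(10_000, 4)) < p).astype(int)
    X2 = (rng.uniform(size=(10_000, 4)) < 2 * p).astype(int)
    r1 = enrichment_ratio(X1, n_perm=2000, seed=29)
    r2 = enrichment_ratio(X2, n_perm=2000, seed=30)
    assert r2.observed_prop > 2 * r1.observed_prop  # raw burden rises super-linearly
    assert 0.9 < r1.er < 1.1 and 0.9 < r2.er < 1.1


def test_small_stratum_skipped_with_warning():
    rng = np.random.default_rng(31)
    panel = pd.DataFrame(
        (rng.uniform(size=(200, 3)) < 0.3).astype(int), index=[f"p{i}" for i in range(200)]
    )
    strata = pd.Series(["big"] * 190 + ["tiny"] * 10, index=panel.index)
    with pytest.warns(UserWarning, match="tiny"):
        res = stratified_enrichment(panel, strata, n_perm=200, seed=32)
    assert "tiny" not in res and "big" in res


def test_higher_frailty_variance_in_low_prevalence_stratum_gives_higher_er():
    """Mirror of the paradoxical pattern: the stratum with lower disease
    frequency but stronger shared susceptibility shows the larger ER."""
    rng = np.random.default_rng(33)
    from scipy.special import expit

    n = 6000
    frail_low = rng.normal(0, 1.5, n)    # low prevalence, strong frailty
    frail_high = rng.normal(0, 0.3, n)   # high prevalence, weak frailty
    Xlow = np.column_stack(
        [(rng.uniform(size=n) < expit(-3.2 + frail_low)).astype(int) for _ in range(4)]
    )
    Xhigh = np.column_stack(
        [(rng.uniform(size=n) < expit(-1.6 + frail_high)).astype(int) for _ in range(4)]
    )
    panel = pd.DataFrame(np.vstack([Xlow, Xhigh]), index=[f"p{i}" for i in range(2 * n)])
    strata = pd.Series(["low_prev"] * n + ["high_prev"] * n, index=panel.index)
    res = stratified_enrichment(panel, strata, n_perm=1000, seed=34)
    assert (
        res["low_prev"].observed_prop < res["high_prev"].observed_prop
    )  # lower absolute burden...
    assert res["low_prev"].er > res["high_prev"].er  # ...but larger enrichment


# ---------------------------------------------------------------------------
# metabolic syndrome


def _measures(**kw):
    base = {
        "sex": "male", "waist_cm": 90.0, "triglycerides_mmol_l": 1.0,
        "hdl_mmol_l": 1.3, "sbp_mmhg": 120.0, "dbp_mmhg": 75.0,
        "glucose_mmol_l": 5.0, "on_bp_meds": 0,
    }
    base.update(kw)
    return pd.DataFrame([base])


def test_mets_three_points_positive_two_negative():
    three = _measures(waist_cm=110.0, triglycerides_mmol_l=2.0, glucose_mmol_l=6.0)
    out = mets_classify(three)
    assert out["points"].iloc[0] == 3 and out["mets"].iloc[0] == 1
    two = _measures(waist_cm=110.0, triglycerides_mmol_l=2.0)
    out2 = mets_classify(two)
    assert out2["points"].iloc[0] == 2 and out2["mets"].iloc[0] == 0


def test_mets_all_five_and_sex_specific_cuts():
    all5 = _measures(
        sex="female", waist_cm=95.0, triglycerides_mmol_l=1.8, hdl_mmol_l=1.1,
        sbp_mmhg=135.0, glucose_mmol_l=5.8,
    )
    out = mets_classify(all5)
    assert out["points"].iloc[0] == 5 and out["mets"].iloc[0] == 1
    # the same waist/HDL values score no point for a man
    man = _measures(waist_cm=95.0, hdl_mmol_l=1.1)
    assert mets_classify(man)["points"].iloc[0] == 0


def test_mets_bp_meds_count_as_hypertensive_component():
    out = mets_classify(_measures(on_bp_meds=1))
    assert out["blood_pressure"].iloc[0] == 1


def test_mets_missing_component_flagged_partial():
    m = _measures()
    m["glucose_mmol_l"] = np.nan
    out = mets_classify(m)
    assert out["partially_scored"].iloc[0]
    assert out["n_scored"].iloc[0] == 4


def test_mets_negative_measurement_rejected():
    with pytest.raises(ValueError, match="waist"):
        mets_classify(_measures(waist_cm=-1.0))


def test_mets_glucose_threshold_configurable():
    m = _measures(glucose_mmol_l=5.8)
    assert mets_classify(m)["glucose"].iloc[0] == 1
    strict = MetsThresholds(glucose_mmol_l=6.1)
    assert mets_classify(m, strict)["glucose"].iloc[0] == 0
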