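import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, special, stats

from molfc.clinical import (
    adjusted_group_test,
    average_baseline_vas,
    bayes_pearson_bf01,
    classify_responders,
    covariate_residualize,
    interpret_bf,
    jzs_bf10_from_t,
    jzs_ttest_bf01,
    levene_test,
    pearson_bf10_from_r,
    pearson_with_bootstrap,
    posthoc_simple_effects,
    two_sample_t,
)

# ---------------------------------------------------- independent oracles


def oracle_jzs_bf01(t, n1, n2, r=0.707, npts=40001):
    """Brute-force trapezoid over the Cauchy effect-size prior, using the
    noncentral-t likelihood (a different route than the g-integral)."""
    N = n1 * n2 / (n1 + n2)
    nu = n1 + n2 - 2
    theta = np.linspace(-np.pi / 2 + 1e-9, np.pi / 2 - 1e-9, npts)
    delta = r * np.tan(theta)  # Cauchy(0, r) prior becomes uniform in theta
    lik = np.nan_to_num(stats.nct.pdf(t, nu, delta * np.sqrt(N)), nan=0.0)
    bf10 = np.trapezoid(lik, theta) / np.pi / stats.t.pdf(t, nu)
    return 1.0 / bf10


def _hyp2f1_series(a, b, c, z, tol=1e-16, maxk=200000):
    term, s, k = 1.0, 1.0, 0
    while abs(term) > tol * abs(s) and k < maxk:
        term *= (a + k) * (b + k) / ((c + k) * (1.0 + k)) * z
        s += term
        k += 1
    return s


def oracle_pearson_bf01(r, n, npts=20001):
    """Trapezoid over a uniform prior on rho with a hand-coded
    hypergeometric series for the sampling density of r."""
    rho = np.linspace(-1 + 1e-9, 1 - 1e-9, npts)

    def logf(rh):
        lg = (
            np.log(n - 2)
            + special.gammaln(n - 1)
            + 0.5 * (n - 1) * np.log1p(-(rh**2))
            + 0.5 * (n - 4) * np.log1p(-(r**2))
            - 0.5 * np.log(2 * np.pi)
            - special.gammaln(n - 0.5)
            - (n - 1.5) * np.log1p(-rh * r)
        )
        return lg + np.log(_hyp2f1_series(0.5, 0.5, n - 0.5, (rh * r + 1) / 2))

    dens = np.array([np.exp(logf(x)) for x in rho])
    bf10 = np.trapezoid(dens * 0.5, rho) / np.exp(logf(0.0))
    return 1.0 / bf10


# --------------------------------------------------------------- baseline
def test_baseline_average_closed_form():
    assert average_baseline_vas([6, 7, 8]) == 7.0


def test_baseline_single_value():
    assert average_baseline_vas([4.2]) == 4.2


def test_baseline_random_triple_matches_sum_over_three(rng):
    triple = rng.uniform(0, 10, size=3)
    assert average_baseline_vas(triple) == pytest.approx(triple.sum() / 3.0, abs=1e-12)


def test_baseline_empty_fails():
    with pytest.raises(ValueError):
        average_baseline_vas([])
    with pytest.raises(ValueError):
        average_baseline_vas([11.0])


# --------------------------------------------------------------- responders
def _table(baselines, posts):
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(len(baselines))],
            "vas_baseline": baselines,
            "vas_post": posts,
        }
    )


def test_exactly_20_percent_is_responder():
    out = classify_responders(_table([10.0], [8.0]))
    assert out["pct_analgesia"][0] == pytest.approx(20.0)
    assert bool(out["responder"][0])


def test_fifteen_percent_is_non_responder():
    out = classify_responders(_table([10.0], [8.5]))
    assert out["pct_analgesia"][0] == pytest.approx(15.0)
    assert not bool(out["responder"][0])


def test_seventeen_subject_split_recount():
    # constructed to yield 8 responders / 9 non-responders
    baselines = [5.0] * 17
    posts = [3.0] * 8 + [4.5] * 9  # 40% vs 10% analgesia
    out = classify_responders(_table(baselines, posts))
    assert int(out["responder"].sum()) == 8
    assert int((~out["responder"]).sum()) == 9
    hand = 100.0 * (np.array(baselines) - np.array(posts)) / np.array(baselines)
    assert np.allclose(out["pct_analgesia"], hand)


def test_zero_baseline_fails():
    with pytest.raises(ValueError, match="baseline"):
        classify_responders(_table([0.0, 5.0], [0.0, 4.0]))


# ------------------------------------------------------- adjusted group test
def test_orthogonal_covariates_reduce_to_pooled_t(rng):
    n = 20
    g = np.repeat([1.0, 0.0], n // 2)
    y = rng.normal(size=n) + 0.8 * g
    cov = rng.normal(size=(n, 2))
    # orthogonalize covariates against [1, g, y] so they carry no information
    basis = np.column_stack([np.ones(n), g, y])
    cov = cov - basis @ np.linalg.lstsq(basis, cov, rcond=None)[0]
    res = adjusted_group_test(y, g, cov)
    t_plain, df_plain = two_sample_t(y[g == 1], y[g == 0])
    # identical estimate and residuals; t differs only by the df ratio in
    # the variance estimate (n-2 vs n-4)
    assert res.group_beta == pytest.approx(y[g == 1].mean() - y[g == 0].mean(), abs=1e-10)
    assert res.group_t == pytest.approx(
        t_plain * np.sqrt(res.df_resid / df_plain), rel=1e-10
    )


def test_twelve_row_ols_oracle(rng):
    n = 12
    g = np.repeat([1.0, 0.0], 6)
    cov = rng.normal(size=(n, 2))
    y = 1.0 + 0.5 * g + cov @ [0.3, -0.2] + rng.normal(size=n)
    res = adjusted_group_test(y, g, cov)
    X = np.column_stack([np.ones(n), g, cov])
    beta = np.linalg.solve(X.T @ X, X.T @ y)  # independent normal equations
    resid = y - X @ beta
    df = n - 4
    se = np.sqrt(resid @ resid / df * np.linalg.inv(X.T @ X)[1, 1])
    assert res.group_beta == pytest.approx(beta[1], abs=1e-8)
    assert res.group_t == pytest.approx(beta[1] / se, abs=1e-8)
    ss_tot = ((y - y.mean()) ** 2).sum()
    f_oracle = ((ss_tot - resid @ resid) / 3) / ((resid @ resid) / df)
    assert res.model_f == pytest.approx(f_oracle, abs=1e-8)
    assert res.model_f_df == (3, 8)


def test_null_group_effect_p_uniform():
    rng = np.random.default_rng(0)
    ps = []
    for _ in range(200):
        n = 20
        g = np.repeat([1.0, 0.0], n // 2)
        y = rng.normal(size=n)
        cov = rng.normal(size=(n, 2))
        ps.append(adjusted_group_test(y, g, cov).group_p)
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 1e-3


def test_rank_deficiency_fails(rng):
    n = 10
    g = np.repeat([1.0, 0.0], 5)
    with pytest.raises(ValueError, match="rank"):
        adjusted_group_test(rng.normal(size=n), g, np.column_stack([g, g]))


# --------------------------------------------------------------- JZS BF
def test_bf01_favours_null_at_t_zero():
    for n in (5, 20, 80):
        res_bf01 = 1.0 / jzs_bf10_from_t(0.0, n, n)[0]
        assert res_bf01 > 1.0


def test_bf01_monotone_decreasing_in_abs_t():
    ts = [0.0, 0.5, 1.0, 2.0, 3.0, 4.0]
    vals = [1.0 / jzs_bf10_from_t(t, 20, 20)[0] for t in ts]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    # symmetric in sign
    assert 1.0 / jzs_bf10_from_t(-2.0, 20, 20)[0] == pytest.approx(
        1.0 / jzs_bf10_from_t(2.0, 20, 20)[0], rel=1e-10
    )


def test_bf01_matches_brute_force_quadrature():
    mine = 1.0 / jzs_bf10_from_t(2.5, 20, 20)[0]
    assert mine == pytest.approx(oracle_jzs_bf01(2.5, 20, 20), abs=1e-6)


def test_jzs_from_data_end_to_end(rng):
    x = rng.normal(0.8, 1.0, size=25)
    y = rng.normal(0.0, 1.0, size=25)
    res = jzs_ttest_bf01(x, y)
    t, _ = two_sample_t(x, y)
    assert res.bf01 == pytest.approx(oracle_jzs_bf01(t, 25, 25), abs=1e-6)
    assert res.bf10 == pytest.approx(1.0 / res.bf01)


def test_jzs_zero_variance_fails():
    with pytest.raises(ValueError, match="variance"):
        jzs_ttest_bf01([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])


def test_bf_consistency_with_growing_n(rng):
    # fixed true effect: evidence against the null accumulates
    vals = []
    for n in (10, 40, 160):
        x = rng.standard_normal(n) + 1.0
        y = rng.standard_normal(n)
        vals.append(jzs_ttest_bf01(x, y).bf01)
    assert vals[-1] < vals[0]
    assert vals[-1] < 1.0 / 3.0
    # true null: evidence for the null grows
    nulls = []
    for n in (10, 160):
        rng2 = np.random.default_rng(1)
        x = rng2.standard_normal(n)
        y = rng2.standard_normal(n)
        nulls.append(jzs_ttest_bf01(x, y).bf01)
    assert nulls[-1] > nulls[0]


# ------------------------------------------------------------- bands
def test_band_reproduction_published_values():
    assert interpret_bf(3.29) == "moderate evidence in favour of the null hypothesis"
    assert interpret_bf(2.46) == "anecdotal evidence in favour of the null hypothesis"
    assert interpret_bf(0.05) == "strong evidence for an alternative hypothesis"


def test_bands_partition():
    for bf, expect in [
        (0.2, "moderate evidence for an alternative"),
        (0.5, "anecdotal evidence for an alternative"),
        (1.0, "anecdotal evidence in favour of the null"),
        (3.0, "moderate evidence in favour of the null"),
        (10.0, "strong evidence in favour of the null"),
        (50.0, "strong evidence in favour of the null"),
    ]:
        assert interpret_bf(bf).startswith(expect)


def test_band_invalid_input():
    with pytest.raises(ValueError):
        interpret_bf(0.0)
    with pytest.raises(ValueError):
        interpret_bf(-1.0)


# ------------------------------------------------------------- Pearson
def test_identity_correlation_degenerate_ci(rng):
    x = rng.normal(size=12)
    res = pearson_with_bootstrap(x, x.copy(), n_boot=200, seed=0)
    assert res["r"] == pytest.approx(1.0)
    assert res["ci"] == (pytest.approx(1.0), pytest.approx(1.0))


def test_bootstrap_ci_coverage_under_independence():
    cover = 0
    n_rep = 100
    for s in range(n_rep):
        rng = np.random.default_rng(s)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        lo, hi = pearson_with_bootstrap(x, y, n_boot=300, seed=s)["ci"]
        cover += lo <= 0.0 <= hi
    assert cover >= 88  # ~95% nominal with bootstrap/simulation slack


def test_pearson_eight_point_formula_oracle():
    x = np.array([1.0, 2.0, 3.5, 4.0, 5.5, 6.0, 7.2, 8.0])
    y = np.array([2.1, 1.9, 3.8, 3.2, 5.9, 5.1, 6.8, 8.4])
    res = pearson_with_bootstrap(x, y, n_boot=100, seed=1)
    # closed-form covariance / SD oracle
    r_oracle = ((x - x.mean()) * (y - y.mean())).mean() / (x.std() * y.std())
    assert res["r"] == pytest.approx(r_oracle, abs=1e-12)


def test_pearson_validation():
    with pytest.raises(ValueError):
        pearson_with_bootstrap([1, 2, 3], [1, 2, 3])
    with pytest.raises(ValueError, match="variance"):
        pearson_with_bootstrap([1, 1, 1, 1], [1, 2, 3, 4])


def test_pearson_bf01_favours_null_at_zero_r(rng):
    x = rng.normal(size=30)
    # construct y exactly uncorrelated with x
    y = rng.normal(size=30)
    y = y - x * (x @ y) / (x @ x)
    res = bayes_pearson_bf01(x, y)
    assert res.bf01 > 1.0


def test_pearson_bf01_monotone_in_abs_r():
    vals = [1.0 / pearson_bf10_from_r(r, 30)[0] for r in (0.0, 0.2, 0.4, 0.6, 0.8)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_pearson_bf01_matches_series_oracle():
    mine = 1.0 / pearson_bf10_from_r(0.5, 30)[0]
    assert mine == pytest.approx(oracle_pearson_bf01(0.5, 30), abs=1e-6)


# ------------------------------------------------------------- post hoc
def _posthoc_data(rng, delta_drug=0.0, delta_placebo=0.0, n_cell=8):
    arm = np.array(["placebo"] * (2 * n_cell) + ["duloxetine"] * (2 * n_cell))
    resp = np.array((["NR"] * n_cell + ["R"] * n_cell) * 2)
    y = rng.normal(size=4 * n_cell)
    y[(arm == "duloxetine") & (resp == "R")] += delta_drug
    y[(arm == "placebo") & (resp == "R")] += delta_placebo
    cov = rng.normal(size=(4 * n_cell, 2))
    return y, arm, resp, cov


def test_identical_cells_give_null_contrast(rng):
    y, arm, resp, cov = _posthoc_data(rng)
    y[(arm == "placebo") & (resp == "R")] = 1.0
    y[(arm == "placebo") & (resp == "NR")] = 1.0
    out = posthoc_simple_effects(y, arm, resp)
    row = out[out["arm"] == "placebo"].iloc[0]
    assert row["estimate"] == pytest.approx(0.0, abs=1e-12)
    assert row["p_tukey"] > 0.99


def test_planted_effect_only_in_drug_arm():
    rng = np.random.default_rng(7)
    y, arm, resp, cov = _posthoc_data(rng, delta_drug=3.0, n_cell=10)
    out = posthoc_simple_effects(y, arm, resp, cov)
    p_drug = out.loc[out["arm"] == "duloxetine", "p_tukey"].iloc[0]
    p_plac = out.loc[out["arm"] == "placebo", "p_tukey"].iloc[0]
    assert p_drug < 0.05
    assert p_plac > 0.05


def test_tukey_never_below_unadjusted(rng):
    for s in range(5):
        r = np.random.default_rng(s)
        y, arm, resp, cov = _posthoc_data(r, delta_drug=r.uniform(0, 2))
        out = posthoc_simple_effects(y, arm, resp, cov)
        assert np.all(out["p_tukey"] >= out["p_unadjusted"] - 1e-12)


def test_posthoc_small_cell_fails(rng):
    y = rng.normal(size=5)
    arm = np.array(["a", "a", "a", "b", "b"])
    resp = np.array(["R", "NR", "NR", "R", "NR"])
    with pytest.raises(ValueError, match="fewer than 2"):
        posthoc_simple_effects(y, arm, resp)


# ------------------------------------------------------------- Levene
def test_levene_identical_groups_zero():
    v = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
    g = np.array(["a"] * 3 + ["b"] * 3)
    W, p = levene_test(v, g)
    assert W == pytest.approx(0.0)


def test_levene_matches_scipy_oracle(rng):
    x = rng.normal(0, 1, size=15)
    y = rng.normal(0, 3, size=12)
    v = np.concatenate([x, y])
    g = np.array(["a"] * 15 + ["b"] * 12)
    W, p = levene_test(v, g, center="mean")
    W_ref, p_ref = stats.levene(x, y, center="mean")
    assert W == pytest.approx(W_ref, abs=1e-10)
    assert p == pytest.approx(p_ref, abs=1e-10)
    # median variant too
    W2, p2 = levene_test(v, g, center="median")
    W2_ref, p2_ref = stats.levene(x, y, center="median")
    assert W2 == pytest.approx(W2_ref, abs=1e-10)


def test_levene_equal_variance_p_uniform():
    ps = []
    for s in range(200):
        rng = np.random.default_rng(s)
        v = rng.normal(size=24)
        g = np.array(["a"] * 12 + ["b"] * 12)
        ps.append(levene_test(v, g)[1])
    assert stats.kstest(ps, "uniform").pvalue > 1e-3


def test_levene_validation(rng):
    with pytest.raises(ValueError):
        levene_test(rng.normal(size=5), np.array(["a"] * 5))
    with pytest.raises(ValueError, match="fewer than 2"):
        levene_test(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "b"]))


# ----------------------------------------------- frequentist/Bayesian sign
def test_direction_agreement_on_separated_data(rng):
    g = np.repeat([1.0, 0.0], 15)
    cov = rng.normal(size=(30, 2))
    y = rng.normal(size=30) + 3.0 * g
    freq = adjusted_group_test(y, g, cov)
    resid = covariate_residualize(y, cov)
    bayes = jzs_ttest_bf01(resid[g == 1], resid[g == 0])
    assert freq.group_t > 0
    assert bayes.bf01 < 1.0 / 3.0  # evidence for a (positive) effect
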