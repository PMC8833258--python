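"""Responder classification and ROI-level frequentist / Bayesian statistics.

Implements the hypothesis-driven analysis layer: triple-baseline VAS
averaging, the >= 20% analgesia responder rule, covariate-adjusted group
tests, JZS Bayes-factor t-tests and stretched-beta Bayes-factor
correlations by numerical integration, bootstrap Pearson correlations,
covariate-adjusted simple-effect post hoc tests with Tukey correction,
and Levene's homogeneity-of-variance test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

DEFAULT_CAUCHY_SCALE = 0.707  # JZS two-sample t default prior scale
DEFAULT_BETA_WIDTH = 1.0  # stretched-beta prior width for correlations

#: Evidence bands (Lee–Wagenmakers scheme, regularized to a partition of
#: BF01 values): (upper bound, label); bands are left-closed from the
#: previous bound.
_BF_BANDS = [
    (1.0 / 10.0, "strong evidence for an alternative hypothesis"),
    (1.0 / 3.0, "moderate evidence for an alternative hypothesis"),
    (1.0, "anecdotal evidence for an alternative hypothesis"),
    (3.0, "anecdotal evidence in favour of the null hypothesis"),
    (10.0, "moderate evidence in favour of the null hypothesis"),
    (np.inf, "strong evidence in favour of the null hypothesis"),
]


@dataclass
class BayesFactorResult:
    bf01: float
    prior_spec: str
    method: str
    interpretation: str
    integration_error: float = np.nan

    @property
    def bf10(self) -> float:
        return 1.0 / self.bf01


@dataclass
class AdjustedGroupTest:
    group_beta: float
    group_t: float
    group_p: float
    df_resid: int
    model_f: float
    model_f_df: tuple
    model_f_p: float


def average_baseline_vas(repeats) -> float:
    """Arithmetic mean of 1–3 repeated baseline VAS measurements."""
    vals = np.asarray(list(repeats), dtype=float)
    if vals.size == 0:
        raise ValueError("no baseline VAS measurements given")
    if vals.size > 3:
        raise ValueError("at most 3 baseline measurements expected")
    if not np.all(np.isfinite(vals)) or np.any((vals < 0) | (vals > 10)):
        raise ValueError("baseline VAS must be finite and in [0, 10]")
    return float(vals.mean())


def classify_responders(table: pd.DataFrame, threshold_pct: float = 20.0) -> pd.DataFrame:
    """Label each subject responder / non-responder by percentage analgesia.

    pct_analgesia = 100 * (baseline - post) / baseline; responder iff
    pct_analgesia >= ``threshold_pct``.  Fails if any baseline is zero
    (percent change undefined).
    """
    baseline = np.asarray(table["vas_baseline"], dtype=float)
    post = np.asarray(table["vas_post"], dtype=float)
    if np.any(baseline <= 0):
        bad = table.loc[baseline <= 0, "subject_id"].tolist()
        raise ValueError(f"baseline VAS must be > 0 (subjects {bad})")
    pct = 100.0 * (baseline - post) / baseline
    return pd.DataFrame(
        {
            "subject_id": table["subject_id"].to_numpy(),
            "pct_analgesia": pct,
            "responder": pct >= threshold_pct,
        }
    )


def _design_with_covariates(group, covariates) -> np.ndarray:
    n = len(group)
    cols = [np.ones(n), np.asarray(group, dtype=float)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float).reshape(n, -1)
        cols.extend(cov[:, j] for j in range(cov.shape[1]))
    return np.column_stack(cols)


def adjusted_group_test(values, group, covariates=None) -> AdjustedGroupTest:
    """Linear model ``value ~ group + covariates`` (age, gender, ...).

    Reports the group-coefficient t-test (two-sided) and the omnibus
    model F with (p, n - p - 1) degrees of freedom.
    """
    y = np.asarray(values, dtype=float)
    X = _design_with_covariates(group, covariates)
    n, p1 = X.shape
    if n <= p1:
        raise ValueError("more parameters than observations")
    if np.linalg.matrix_rank(X) < p1:
        raise ValueError("design is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - p1
    sigma2 = float(resid @ resid) / df_resid
    XtXinv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * XtXinv[1, 1])
    t = float(beta[1] / se)
    p_group = 2.0 * float(stats.t.sf(abs(t), df_resid))
    # omnibus F against intercept-only model
    ss_tot = float(((y - y.mean()) ** 2).sum())
    ss_res = float(resid @ resid)
    df_model = p1 - 1
    f = ((ss_tot - ss_res) / df_model) / (ss_res / df_resid) if ss_res > 0 else np.inf
    p_f = float(stats.f.sf(f, df_model, df_resid))
    return AdjustedGroupTest(
        group_beta=float(beta[1]),
        group_t=t,
        group_p=p_group,
        df_resid=df_resid,
        model_f=float(f),
        model_f_df=(df_model, df_resid),
        model_f_p=p_f,
    )


def covariate_residualize(values, covariates) -> np.ndarray:
    """Residuals of values against [1, covariates] (for Bayesian tests run
    on covariate-adjusted data)."""
    y = np.asarray(values, dtype=float)
    X = np.column_stack([np.ones(len(y)), np.asarray(covariates, dtype=float)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def two_sample_t(x, y) -> tuple[float, int]:
    """Pooled-variance two-sample t and its df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    sp2 = (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum()) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance; t statistic undefined")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), df


def jzs_bf10_from_t(
    t: float, n1: int, n2: int | None = None, cauchy_scale: float = DEFAULT_CAUCHY_SCALE
) -> tuple[float, float]:
    """JZS Bayes factor BF10 for a t statistic, by adaptive quadrature.

    The effect-size prior is a zero-centred Cauchy with the given scale,
    equivalently a normal prior with variance g integrated over an
    inverse-gamma(1/2, scale^2/2) on g.  For a one-sample test pass
    ``n2=None``.  Returns (bf10, integration error estimate).
    """
    if n2 is None:
        N = float(n1)
        nu = n1 - 1
    else:
        N = n1 * n2 / (n1 + n2)
        nu = n1 + n2 - 2
    if nu < 1:
        raise ValueError("not enough observations for a t-test")
    r2 = cauchy_scale**2
    t2 = float(t) ** 2

    def log_h1_integrand(g: float) -> float:
        # marginal likelihood under H1 at prior variance g, times the
        # inverse-gamma(1/2, r^2/2) prior density
        log_lik = -0.5 * np.log1p(N * g) - 0.5 * (nu + 1) * np.log1p(
            t2 / ((1.0 + N * g) * nu)
        )
        log_prior = (
            0.5 * np.log(r2 / 2.0)
            - special.gammaln(0.5)
            - 1.5 * np.log(g)
            - r2 / (2.0 * g)
        )
        return log_lik + log_prior

    log_h0 = -0.5 * (nu + 1) * np.log1p(t2 / nu)

    def integrand(g: float) -> float:
        return np.exp(log_h1_integrand(g) - log_h0)

    val, err = integrate.quad(integrand, 0.0, np.inf, limit=400, epsabs=1e-12, epsrel=1e-12)
    return float(val), float(err)


def jzs_ttest_bf01(
    x, y, cauchy_scale: float = DEFAULT_CAUCHY_SCALE
) -> BayesFactorResult:
    """Two-sample JZS Bayes factor in favour of the null (BF01)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    t, _ = two_sample_t(x, y)
    bf10, err = jzs_bf10_from_t(t, len(x), len(y), cauchy_scale)
    bf01 = 1.0 / bf10
    return BayesFactorResult(
        bf01=bf01,
        prior_spec=f"JZS Cauchy(scale={cauchy_scale})",
        method="adaptive quadrature over g",
        interpretation=interpret_bf(bf01),
        integration_error=err / bf10**2,
    )


def interpret_bf(bf01: float) -> str:
    """Evidence-band label for a BF01 value (partitioned bands)."""
    if not np.isfinite(bf01) or bf01 <= 0:
        raise ValueError("bf01 must be a positive finite number")
    for upper, label in _BF_BANDS:
        if bf01 < upper:
            return label
    return _BF_BANDS[-1][1]  # pragma: no cover


def pearson_with_bootstrap(
    x, y, n_boot: int = 1000, seed: int = 0, ci: float = 95.0
) -> dict:
    """Pearson r with two-sided p and a seeded percentile bootstrap CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = stats.pearsonr(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.full(n_boot, np.nan)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.std(xb) == 0 or np.std(yb) == 0:
            continue  # degenerate resample carries no correlation information
        boots[b] = np.corrcoef(xb, yb)[0, 1]
    valid = boots[np.isfinite(boots)]
    alpha = (100.0 - ci) / 2.0
    lo, hi = np.percentile(valid, [alpha, 100.0 - alpha])
    return {
        "r": float(r),
        "p": float(p),
        "ci": (float(lo), float(hi)),
        "n_boot": int(len(valid)),
    }


def _log_r_density(r: float, rho: float, n: int) -> float:
    """Log sampling density of the Pearson correlation r given rho."""
    lg = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        + 0.5 * (n - 1) * np.log1p(-(rho**2))
        + 0.5 * (n - 4) * np.log1p(-(r**2))
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    h = special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1.0) / 2.0)
    return lg + np.log(h)


def pearson_bf10_from_r(r: float, n: int, beta_width: float = DEFAULT_BETA_WIDTH) -> tuple[float, float]:
    """BF10 for rho != 0 under a stretched-beta(1/width) prior on rho.

    Computed by quadrature of the exact sampling density of r over the
    prior.  Width 1 corresponds to a uniform prior on (-1, 1).
    """
    if n < 4:
        raise ValueError("need n >= 4")
    a = 1.0 / beta_width
    log_f0 = _log_r_density(r, 0.0, n)

    def integrand(rho: float) -> float:
        log_prior = (
            stats.beta.logpdf((rho + 1.0) / 2.0, a, a) - np.log(2.0)
        )
        return np.exp(_log_r_density(r, rho, n) + log_prior - log_f0)

    val, err = integrate.quad(integrand, -1.0, 1.0, limit=400, epsabs=1e-12, epsrel=1e-12)
    return float(val), float(err)


def bayes_pearson_bf01(x, y, beta_width: float = DEFAULT_BETA_WIDTH) -> BayesFactorResult:
    """Bayes factor in favour of rho = 0 for a Pearson correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r = float(np.corrcoef(x, y)[0, 1])
    bf10, err = pearson_bf10_from_r(r, len(x), beta_width)
    bf01 = 1.0 / bf10
    return BayesFactorResult(
        bf01=bf01,
        prior_spec=f"stretched-beta(width={beta_width})",
        method="adaptive quadrature over rho",
        interpretation=interpret_bf(bf01),
        integration_error=err / bf10**2,
    )


def posthoc_simple_effects(
    values, arm, response, covariates=None, n_cells: int | None = None
) -> pd.DataFrame:
    """Covariate-adjusted responder-vs-non-responder contrast within each arm.

    A single cell-means model (one dummy per arm x response cell, plus
    centred covariates) is fit to all data; within each arm the R - NR
    contrast is tested and Tukey-corrected across the family of cell
    comparisons via the studentized range distribution.
    """
    values = np.asarray(values, dtype=float)
    arm = np.asarray(arm)
    response = np.asarray(response)
    arms = sorted(set(arm.tolist()))
    resps = sorted(set(response.tolist()))
    if len(resps) != 2:
        raise ValueError("response must have exactly two levels")
    cells = [(a, r) for a in arms for r in resps]
    for a, r in cells:
        if ((arm == a) & (response == r)).sum() < 2:
            raise ValueError(f"cell ({a}, {r}) has fewer than 2 subjects")
    X_cells = np.column_stack(
        [((arm == a) & (response == r)).astype(float) for a, r in cells]
    )
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        cov = cov.reshape(len(values), -1)
        cov = cov - cov.mean(axis=0)
        X = np.column_stack([X_cells, cov])
    else:
        X = X_cells
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    df = n - np.linalg.matrix_rank(X)
    sigma2 = float(resid @ resid) / df
    XtXinv = np.linalg.pinv(X.T @ X)
    k = n_cells or len(cells)
    rows = []
    for a in arms:
        c = np.zeros(p)
        c[cells.index((a, resps[1]))] = 1.0  # e.g. R
        c[cells.index((a, resps[0]))] = -1.0  # minus NR
        est = float(c @ beta)
        se = float(np.sqrt(sigma2 * (c @ XtXinv @ c)))
        t = est / se if se > 0 else 0.0
        p_unadj = 2.0 * float(stats.t.sf(abs(t), df))
        p_tukey = float(stats.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
        rows.append(
            {
                "arm": a,
                "contrast": f"{resps[1]} - {resps[0]}",
                "estimate": est,
                "t": t,
                "df": df,
                "p_unadjusted": p_unadj,
                "p_tukey": min(1.0, max(p_tukey, p_unadj)),
            }
        )
    return pd.DataFrame(rows)


def levene_test(values, groups, center: str = "mean") -> tuple[float, float]:
    """Levene's W for homogeneity of variances across groups.

    One-way ANOVA on absolute deviations from the group centre (mean by
    default, median for the Brown–Forsythe variant).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    devs, labels = [], []
    for g in levels:
        v = values[groups == g]
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
        centre = np.mean(v) if center == "mean" else np.median(v)
        devs.append(np.abs(v - centre))
        labels.append(np.full(len(v), g))
    z = np.concatenate(devs)
    lab = np.concatenate(labels)
    n, k = len(z), len(levels)
    zbar = z.mean()
    ss_between = sum(
        len(z[lab == g]) * (z[lab == g].mean() - zbar) ** 2 for g in levels
    )
    ss_within = sum(((z[lab == g] - z[lab == g].mean()) ** 2).sum() for g in levels)
    if ss_within == 0:
        return 0.0 if ss_between == 0 else np.inf, 1.0 if ss_between == 0 else 0.0
    W = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = float(stats.f.sf(W, k - 1, n - k))
    return float(W), p
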