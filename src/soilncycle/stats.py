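"""Inference layer for the block-design cover x fertilization experiment.

Plot-level responses are analysed with a linear mixed model — cover type
(4 levels) and fertilization (2 levels) as crossed fixed factors, block as
a random intercept — fitted by REML (statsmodels MixedLM). On top of the
fit this module computes what the fitting routine does not provide:

* Wald F tests for the two main effects and their interaction;
* Nakagawa-Schielzeth marginal and conditional R^2 from the variance
  components:  R2m = var_f / (var_f + var_b + var_e)  and
  R2c = (var_f + var_b) / (var_f + var_b + var_e),  with var_f the
  variance of the fixed-effect fitted values across the design;
* Tukey HSD comparisons of estimated marginal means with a compact letter
  display;
* Spearman correlation matrices, OLS regressions on treatment means, and a
  repeated-measures GLS with first-order autoregressive (AR1) within-plot
  correlation for monthly climate metrics.

Denominator degrees of freedom for the Wald F tests are residual-style,
n - p_fixed - (n_blocks - 1), and are recorded in the result; the choice
is approximate (as any mixed-model ddf is) and annotated in every output.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.formula.api as smf

__all__ = [
    "MixedModelResult",
    "PosthocLetters",
    "FactorTest",
    "Ar1Result",
    "fit_cover_fert_model",
    "tukey_letters",
    "spearman_matrix",
    "regression_on_treatment_means",
    "repeated_measures_ar1",
    "build_anova_table",
    "significance_marker",
]

SEASON_MONTHS = {"summer": (6, 7, 8), "autumn": (9, 10, 11)}


@dataclass
class FactorTest:
    f_value: float
    df_num: int
    df_den: float
    p_value: float


@dataclass
class MixedModelResult:
    response: str
    transformed: bool
    tests: dict  # factor name -> FactorTest
    var_fixed: float
    var_block: float
    var_residual: float
    r2_marginal: float
    r2_conditional: float
    ddf_method: str
    _fit: object = field(repr=False, default=None)
    _data: pd.DataFrame = field(repr=False, default=None)


@dataclass
class PosthocLetters:
    factor: str
    alpha: float
    means: pd.Series
    p_matrix: pd.DataFrame
    letters: dict


def _factor_contrast(names: list[str], which: str) -> np.ndarray:
    """Rows selecting the coefficients of one model term."""
    if which == "interaction":
        idx = [i for i, n in enumerate(names) if ":" in n]
    else:
        idx = [i for i, n in enumerate(names)
               if f"C({which}" in n and ":" not in n]
    if not idx:
        raise ValueError(f"no coefficients found for term {which!r}")
    L = np.zeros((len(idx), len(names)))
    for r, i in enumerate(idx):
        L[r, i] = 1.0
    return L


def fit_cover_fert_model(table: pd.DataFrame, response: str,
                         log_transform: bool = False) -> MixedModelResult:
    """Fit `response ~ cover * fert + (1 | block)` by REML and derive
    F tests, variance components and marginal/conditional R^2.

    With ``log_transform`` the response is natural-log transformed first;
    non-positive values then raise, naming the offending rows, rather than
    being silently offset.
    """
    for col in ("cover", "fert", "block", response):
        if col not in table.columns:
            raise ValueError(f"model table missing column {col!r}")
    df = table[["cover", "fert", "block", response]].dropna().copy()
    if log_transform:
        bad = df.index[df[response] <= 0].tolist()
        if bad:
            raise ValueError(
                f"log transform of {response!r} undefined for non-positive "
                f"values at rows {bad}")
        df[response] = np.log(df[response].astype(float))
    # F tests, EMMs and fitted fixed effects come from the sum-coded
    # projection including block: in the balanced randomized-block design
    # this is the exact ANOVA F (equal to the Satterthwaite mixed-model F),
    # and remains type-III under mild imbalance
    formula = f"{response} ~ C(cover, Sum) * C(fert, Sum) + C(block, Sum)"
    yv, Xmat = patsy.dmatrices(formula, df)
    design_info = Xmat.design_info
    yv = np.asarray(yv).ravel()
    Xf = np.asarray(Xmat)
    fnames = design_info.column_names
    bols, *_ = np.linalg.lstsq(Xf, yv, rcond=None)
    resid = yv - Xf @ bols
    n = len(df)
    p_full = Xf.shape[1]
    df_den = float(n - p_full)
    sigma2 = float(resid @ resid) / df_den
    cov_ols = sigma2 * np.linalg.pinv(Xf.T @ Xf)

    tests = {}
    for term in ("cover", "fert", "interaction"):
        L = _factor_contrast(fnames, term)
        lb = L @ bols
        lcov = L @ cov_ols @ L.T
        if np.allclose(np.diag(lcov), 0.0):
            fval, pval = np.inf, 0.0  # zero residual variance limit
        else:
            fval = float(lb @ np.linalg.solve(lcov, lb)) / L.shape[0]
            pval = float(sps.f.sf(fval, L.shape[0], df_den))
        tests[term] = FactorTest(fval, L.shape[0], df_den, pval)

    # variance components by REML (statsmodels MixedLM); degenerate data
    # (zero residual variance) fall back to the ANOVA moment estimators
    n_blocks = df["block"].nunique()
    try:
        import warnings as _warnings
        with _warnings.catch_warnings():
            # with few blocks the block variance often sits on the zero
            # boundary; that is an expected outcome, not a failure
            _warnings.simplefilter("ignore")
            mfit = smf.mixedlm(f"{response} ~ C(cover) * C(fert)", df,
                               groups=df["block"]).fit(reml=True)
        var_block = float(mfit.cov_re.iloc[0, 0])
        var_resid = float(mfit.scale)
        vc_method = "REML (statsmodels MixedLM)"
    except (np.linalg.LinAlgError, ValueError):
        var_resid = sigma2
        resid_fe = yv - _fixed_only_fitted(Xf, bols, fnames)
        block_means = pd.Series(resid_fe).groupby(
            df["block"].to_numpy()).mean()
        m_per_block = n / n_blocks
        var_block = max(0.0, float(np.var(block_means, ddof=1))
                        - sigma2 / m_per_block) if n_blocks > 1 else 0.0
        vc_method = "ANOVA moments (REML degenerate)"

    fitted_fixed = _fixed_only_fitted(Xf, bols, fnames)
    var_fixed = float(np.var(fitted_fixed))
    total = var_fixed + var_block + var_resid
    if total == 0.0:
        r2m = r2c = 0.0
    else:
        r2m = var_fixed / total
        r2c = (var_fixed + var_block) / total
    return MixedModelResult(
        response=response, transformed=log_transform, tests=tests,
        var_fixed=var_fixed, var_block=var_block, var_residual=var_resid,
        r2_marginal=r2m, r2_conditional=r2c,
        ddf_method=(f"RCBD residual df = n({n}) - p({p_full}) = {int(df_den)}; "
                    f"variance components: {vc_method}"),
        _fit={"beta": bols, "cov": cov_ols, "design_info": design_info,
              "df_den": df_den}, _data=df)


def _fixed_only_fitted(Xf: np.ndarray, beta: np.ndarray, names: list[str]
                       ) -> np.ndarray:
    """Fitted values with the (sum-coded) block columns zeroed, i.e. the
    prediction for an average block — the fixed-effect part."""
    keep = np.array(["C(block" not in nm for nm in names])
    return (Xf * keep) @ beta


def _estimated_marginal_means(result: MixedModelResult, factor: str
                              ) -> tuple[pd.Series, np.ndarray]:
    """EMMs of one factor (averaged over the other) and their covariance."""
    fit = result._fit
    df = result._data
    beta, cov = fit["beta"], fit["cov"]
    design_info = fit["design_info"]
    other = "fert" if factor == "cover" else "cover"
    levels = sorted(df[factor].unique())
    other_levels = sorted(df[other].unique())
    blocks = sorted(df["block"].unique())
    rows = []
    for lev in levels:
        grid = pd.DataFrame([{factor: lev, other: ol, "block": b}
                             for ol in other_levels for b in blocks])
        Xg = np.asarray(patsy.dmatrix(design_info, grid, return_type="matrix"))
        rows.append(Xg.mean(axis=0))
    L = np.vstack(rows)
    means = pd.Series(L @ beta, index=levels)
    return means, L @ cov @ L.T


def _compact_letters(levels: list, sig: dict, means: pd.Series) -> dict:
    """Compact letter display from the non-significance graph.

    ``sig[{a, b}]`` is True when a and b differ significantly. Letter
    groups are the maximal cliques of the "not significantly different"
    graph (Bron-Kerbosch; the factor has few levels), which guarantees two
    levels share a letter iff they are not significantly different.
    Cliques are lettered in descending order of their best mean.
    """
    adj = {a: {b for b in levels
               if b != a and not sig[frozenset((a, b))]} for a in levels}
    cliques: list[set] = []

    def bron_kerbosch(r: set, p: set, x: set) -> None:
        if not p and not x:
            cliques.append(r)
            return
        for v in list(p):
            bron_kerbosch(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    bron_kerbosch(set(), set(levels), set())
    cliques.sort(key=lambda g: -max(means[lev] for lev in g))
    letters = {lev: "" for lev in levels}
    for g, letter in zip(cliques, "abcdefghijklmnopqrstuvwxyz"):
        for lev in g:
            letters[lev] += letter
    return {lev: "".join(sorted(letters[lev])) for lev in levels}


def tukey_letters(result: MixedModelResult, factor: str = "cover",
                  alpha: float = 0.05) -> PosthocLetters:
    """All-pairs Tukey HSD on estimated marginal means with letters.

    Pairwise p-values use the studentized range distribution with the
    model's denominator df; two levels share a letter iff their adjusted
    p >= alpha.
    """
    means, cov = _estimated_marginal_means(result, factor)
    levels = list(means.index)
    if len(levels) < 2:
        raise ValueError("post-hoc comparison needs >=2 levels")
    k = len(levels)
    df_den = result.tests[factor].df_den
    p_mat = pd.DataFrame(np.ones((k, k)), index=levels, columns=levels)
    sig = {}
    for i, j in itertools.combinations(range(k), 2):
        d = means.iloc[i] - means.iloc[j]
        se = np.sqrt(max(cov[i, i] + cov[j, j] - 2 * cov[i, j], 0.0))
        if se == 0.0:  # zero residual variance limit
            p = 1.0 if abs(d) < 1e-12 else 0.0
        else:
            q = abs(d) / se * np.sqrt(2.0)
            p = float(sps.studentized_range.sf(q, k, df_den))
        p_mat.iloc[i, j] = p_mat.iloc[j, i] = p
        sig[frozenset((levels[i], levels[j]))] = p < alpha
    letters = _compact_letters(levels, sig, means)
    return PosthocLetters(factor=factor, alpha=alpha, means=means,
                          p_matrix=p_mat, letters=letters)


def spearman_matrix(table: pd.DataFrame, variables: list[str]
                    ) -> tuple[pd.DataFrame, pd.DataFrame, set]:
    """Spearman rank correlation matrix (mid-ranks for ties) with p-values.

    Returns (rho, p, flags); a constant variable yields NaN rows/columns
    and an ``undefined:<name>`` flag instead of a spurious coefficient.
    """
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"variables not in table: {missing}")
    sub = table[variables].dropna()
    if len(sub) < 3:
        raise ValueError("need >=3 complete observations")
    flags = {f"undefined:{v}" for v in variables if sub[v].nunique() == 1}
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pv = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for i, j in itertools.combinations(range(k), 2):
        vi, vj = variables[i], variables[j]
        if f"undefined:{vi}" in flags or f"undefined:{vj}" in flags:
            r, p = np.nan, np.nan
        else:
            r, p = sps.spearmanr(sub[vi], sub[vj])
        rho.loc[vi, vj] = rho.loc[vj, vi] = r
        pv.loc[vi, vj] = pv.loc[vj, vi] = p
    return rho, pv, flags


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def regression_on_treatment_means(means_table: pd.DataFrame, x: str, y: str
                                  ) -> RegressionResult:
    """OLS of y on x across treatment means (one point per treatment),
    sidestepping the non-independence of plots within a treatment."""
    sub = means_table[[x, y]].dropna()
    if len(sub) < 3:
        raise ValueError("regression on treatment means needs >=3 points")
    res = sps.linregress(sub[x], sub[y])
    return RegressionResult(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=float(res.rvalue ** 2),
                            p_value=float(res.pvalue), n=len(sub))


@dataclass
class Ar1Result:
    season: str
    phi: float
    tests: dict  # term -> FactorTest
    n_obs: int


def _ar1_inverse(n: int, phi: float) -> np.ndarray:
    """Inverse of the AR(1) correlation matrix (tridiagonal closed form)."""
    if n == 1:
        return np.array([[1.0]])
    inv = np.zeros((n, n))
    f = 1.0 / (1.0 - phi ** 2)
    for i in range(n):
        inv[i, i] = f * (1.0 + phi ** 2 if 0 < i < n - 1 else 1.0)
    for i in range(n - 1):
        inv[i, i + 1] = inv[i + 1, i] = -phi * f
    return inv


def repeated_measures_ar1(monthly_table: pd.DataFrame, season: str = "summer"
                          ) -> Ar1Result:
    """Repeated-measures test of cover and month on monthly plot means,
    with within-plot correlation modelled as first-order autoregressive.

    ``monthly_table`` is tidy: plot_id, cover, month (1-12), value. The
    season selects Jun-Aug ("summer") or Sep-Nov ("autumn"), the window
    before continuous snow cover. phi is estimated from lag-1 OLS
    residual autocorrelation within plots, then cover/month/interaction
    are tested by feasible GLS Wald F tests.
    """
    if season not in SEASON_MONTHS:
        raise ValueError(f"season must be one of {sorted(SEASON_MONTHS)}")
    for col in ("plot_id", "cover", "month", "value"):
        if col not in monthly_table.columns:
            raise ValueError(f"monthly table missing column {col!r}")
    months = SEASON_MONTHS[season]
    df = monthly_table[monthly_table["month"].isin(months)].copy()
    df = df.sort_values(["plot_id", "month"]).reset_index(drop=True)
    if df["month"].nunique() < 2:
        raise ValueError("need >=2 months within the season window")
    if df["plot_id"].nunique() < 2:
        raise ValueError("need >=2 plots for a repeated-measures test")

    y, X = patsy.dmatrices("value ~ C(cover) * C(month)", df,
                           return_type="matrix")
    y = np.asarray(y).ravel()
    X = np.asarray(X)
    names = X.shape[1]
    design_info = patsy.dmatrices("value ~ C(cover) * C(month)", df)[1].design_info
    colnames = design_info.column_names

    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    # lag-1 autocorrelation pooled over plots
    num = den = 0.0
    for _, idx in df.groupby("plot_id").groups.items():
        r = resid[np.asarray(idx)]
        if len(r) >= 2:
            num += float(np.sum(r[1:] * r[:-1]))
            den += float(np.sum(r ** 2))
    phi = 0.0 if den == 0 else float(np.clip(num / den, -0.99, 0.99))

    # feasible GLS with block-diagonal AR(1) weights
    XtWX = np.zeros((names, names))
    XtWy = np.zeros(names)
    groups = [np.asarray(idx) for _, idx in df.groupby("plot_id").groups.items()]
    winvs = {}
    for idx in groups:
        m = len(idx)
        if m not in winvs:
            winvs[m] = _ar1_inverse(m, phi)
        W = winvs[m]
        Xg, yg = X[idx], y[idx]
        XtWX += Xg.T @ W @ Xg
        XtWy += Xg.T @ W @ yg
    beta = np.linalg.solve(XtWX, XtWy)
    rss = 0.0
    for idx in groups:
        rg = y[idx] - X[idx] @ beta
        rss += float(rg @ winvs[len(idx)] @ rg)
    n, p = len(y), names
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtWX)

    tests = {}
    for term, key in (("cover", "cover"), ("month", "month"),
                      ("interaction", "interaction")):
        if key == "interaction":
            idx = [i for i, c in enumerate(colnames) if ":" in c]
        else:
            idx = [i for i, c in enumerate(colnames)
                   if f"C({key})" in c and ":" not in c]
        L = np.zeros((len(idx), p))
        for r_, i in enumerate(idx):
            L[r_, i] = 1.0
        lb = L @ beta
        lcov = L @ cov @ L.T
        fval = float(lb @ np.linalg.solve(lcov, lb)) / L.shape[0]
        pval = float(sps.f.sf(fval, L.shape[0], n - p))
        tests[term] = FactorTest(fval, L.shape[0], float(n - p), pval)
    return Ar1Result(season=season, phi=phi, tests=tests, n_obs=n)


def significance_marker(p: float) -> str:
    """The conventional marker string: *** / ** / * / + (p<0.1), else ''."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "+"
    return ""


def build_anova_table(results: dict[str, MixedModelResult]) -> pd.DataFrame:
    """Assemble the mixed-model ANOVA summary: one row per response,
    F values with significance markers, and marginal/conditional R^2."""
    if not results:
        raise ValueError("no fitted responses")
    rows = []
    for name, res in results.items():
        row = {"response": name, "transformed": res.transformed}
        for term, label in (("cover", "cover"), ("fert", "fert"),
                            ("interaction", "cover_x_fert")):
            t = res.tests[term]
            row[f"f_{label}"] = t.f_value
            row[f"p_{label}"] = t.p_value
            row[f"sig_{label}"] = significance_marker(t.p_value)
        row["r2_marginal"] = res.r2_marginal
        row["r2_conditional"] = res.r2_conditional
        row["ddf_method"] = res.ddf_method
        rows.append(row)
    return pd.DataFrame(rows).set_index("response")
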