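"""Linear mixed models for the stratified index table.

One Gaussian LMM per response (VSC, DEWD, GAI, undesired proportion) with
five binary fixed factors — group size (5 vs 7), sex ratio (all-male vs
mixed-sex), seasonality (cold vs warm), sex (M vs F), origin (wild-caught
vs captive-born) — and a per-individual random intercept for the repeated
measures.  The likelihood maximisation is delegated to
:class:`statsmodels.regression.mixed_linear_model.MixedLM`; everything
around it is computed here:

* per-factor F tests (1 numerator df) with Satterthwaite denominator df,
  obtained from the REML information matrix of the two variance
  parameters — the between-subject factors (sex, origin) land near the
  number of individuals, the within-subject factors near the residual df;
* a full-vs-null likelihood-ratio test (both models fit with ML, since
  likelihoods under REML are not comparable across fixed-effect
  structures);
* Bonferroni-adjusted post hoc contrasts between the two levels of each
  factor (the family defaults to the factors tested within one model);
* Cohen's d per factor from the raw response values (pooled SD);
* variance inflation factors, both the classical design-based form
  1/(1 - R^2) and a model-based form from the fixed-effect coefficient
  correlation under the fitted variance components;
* normal QQ quantile pairs of the conditional residuals with a summary
  correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("groomnet")

#: Fixed factors, model order.
FACTORS = ("group_size", "sex_ratio", "seasonality", "sex", "origin")

#: factor -> (index-table column, reference level, alternative level);
#: the indicator is 1 at the alternative level.
FACTOR_CODING: dict[str, tuple[str, object, object]] = {
    "group_size": ("group_size", 5, 7),
    "sex_ratio": ("sex_ratio", "all_male", "mixed_sex"),
    "seasonality": ("season", "warm", "cold"),
    "sex": ("sex", "M", "F"),
    "origin": ("origin", "captive_born", "wild_caught"),
}

RESPONSES = ("vsc", "dewd", "gai", "undesired")


@dataclass(frozen=True)
class ModelSpec:
    """Which response to model and with which binary factors."""

    response: str
    factors: tuple[str, ...] = FACTORS
    random_grouping: str = "individual"
    bonferroni_family: int | None = None  # None -> len(factors)

    def __post_init__(self) -> None:
        unknown = [f for f in self.factors if f not in FACTOR_CODING]
        if unknown:
            raise ValueError(f"unknown factors: {unknown}")

    @property
    def family(self) -> int:
        return self.bonferroni_family if self.bonferroni_family is not None else len(self.factors)


@dataclass
class LRTResult:
    statistic: float
    df: int
    p: float


@dataclass
class QQDiagnostic:
    """Sorted standardized residuals paired with normal theoretical quantiles."""

    pairs: np.ndarray  # (n, 2): theoretical, observed
    correlation: float


@dataclass
class ModelResult:
    """Fitted-model bundle for one response."""

    spec: ModelSpec
    n_used: int
    n_dropped: int
    converged: bool
    degenerate: bool = False
    message: str = ""
    method: str = "REML"
    coefficients: pd.DataFrame | None = None  # term, estimate, se
    tau2: float = float("nan")  # random-intercept variance
    sigma2: float = float("nan")  # residual variance
    anova_table: pd.DataFrame | None = None  # factor, F, df_num, df_den, p
    lrt: LRTResult | None = None
    contrasts: pd.DataFrame | None = None
    effect_sizes: dict[str, float | None] = field(default_factory=dict)
    vif: pd.Series | None = None
    residuals: np.ndarray | None = None
    qq: QQDiagnostic | None = None

    def summary_text(self) -> str:
        """Plain-text report, one 'F(df1,df2) = x, p, d' line per factor."""
        lines = [f"response: {self.spec.response}  (n = {self.n_used}, "
                 f"{self.n_dropped} rows dropped, method = {self.method})"]
        if self.degenerate or self.anova_table is None:
            lines.append(f"  degenerate fit: {self.message}")
            return "\n".join(lines) + "\n"
        if not self.converged:
            lines.append("  WARNING: fit did not converge cleanly")
        if self.lrt is not None:
            lines.append(
                f"  full vs null: chi2({self.lrt.df}) = {self.lrt.statistic:.2f}, "
                f"p = {self.lrt.p:.4g}"
            )
        lines.append(f"  variance components: individual = {self.tau2:.4g}, "
                     f"residual = {self.sigma2:.4g}")
        for _, r in self.anova_table.iterrows():
            d = self.effect_sizes.get(r["factor"])
            d_txt = f", d = {d:.2f}" if d is not None else ""
            lines.append(
                f"  {r['factor']}: F({int(r['df_num'])},{r['df_den']:.1f}) = "
                f"{r['F']:.2f}, p = {r['p']:.4g}{d_txt}"
            )
        if self.qq is not None:
            lines.append(f"  QQ normality correlation: {self.qq.correlation:.4f}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Design encoding
# ---------------------------------------------------------------------------


def encode_design(
    table: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, pd.DataFrame, np.ndarray, int]:
    """(y, X with intercept + 0/1 indicators, group codes, n dropped).

    Rows with a missing response are dropped (count returned); each factor's
    indicator is 1 at the alternative level of :data:`FACTOR_CODING`.
    """
    if spec.response not in table.columns:
        raise ValueError(f"response column {spec.response!r} not in table")
    keep = table[spec.response].notna()
    n_dropped = int((~keep).sum())
    sub = table.loc[keep]
    y = sub[spec.response].to_numpy(float)
    X = pd.DataFrame({"const": np.ones(len(sub))}, index=sub.index)
    for f in spec.factors:
        col, ref, alt = FACTOR_CODING[f]
        values = sub[col]
        levels = set(values.unique())
        if not levels <= {ref, alt}:
            raise ValueError(f"factor {f}: unexpected levels {levels - {ref, alt}}")
        if len(levels) < 2:
            raise ValueError(f"factor {f}: only one level observed")
        X[f] = (values == alt).astype(float)
    groups = sub[spec.random_grouping].to_numpy()
    return y, X, groups, n_dropped


def _group_matrix(groups: np.ndarray) -> np.ndarray:
    labels = pd.unique(groups)
    index = {g: k for k, g in enumerate(labels)}
    Z = np.zeros((len(groups), len(labels)))
    for row, g in enumerate(groups):
        Z[row, index[g]] = 1.0
    return Z


# ---------------------------------------------------------------------------
# Profiled REML refinement
# ---------------------------------------------------------------------------


def _reml_criterion(
    y: np.ndarray, X: np.ndarray, Z: np.ndarray, lam: float
) -> tuple[float, float, np.ndarray]:
    """Profiled REML criterion at variance ratio lam = tau2/sigma2.

    Returns (criterion up to a constant, profiled sigma2, GLS beta).
    """
    n, p = X.shape
    V = np.eye(n) + lam * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    _, ldV = np.linalg.slogdet(V)
    M = X.T @ Vi @ X
    _, ldM = np.linalg.slogdet(M)
    beta = np.linalg.solve(M, X.T @ Vi @ y)
    r = y - X @ beta
    s2 = float(r @ Vi @ r) / (n - p)
    return -0.5 * ((n - p) * np.log(s2) + ldV + ldM), s2, beta


def _refine_reml(
    y: np.ndarray, X: np.ndarray, Z: np.ndarray, lam0: float
) -> tuple[float, float, np.ndarray]:
    """Polish a REML fit by maximizing the profiled criterion in 1-D.

    The variance structure has a single free ratio lam = tau2/sigma2, so
    the REML surface can be searched exactly; the boundary lam = 0 is an
    explicit candidate, which matters because optimizers frequently stall
    at tiny positive ratios when the true optimum is singular.
    Returns (tau2, sigma2, beta).
    """
    from scipy.optimize import minimize_scalar

    def neg(loglam: float) -> float:
        return -_reml_criterion(y, X, Z, float(np.exp(loglam)))[0]

    res = minimize_scalar(neg, bounds=(-14.0, 7.0), method="bounded",
                          options={"xatol": 1e-10})
    candidates = [0.0, max(lam0, 0.0), float(np.exp(res.x))]
    best = max(candidates, key=lambda l: _reml_criterion(y, X, Z, l)[0])
    _, s2, beta = _reml_criterion(y, X, Z, best)
    if best < 1e-8:
        best = 0.0
    return best * s2, s2, beta


# ---------------------------------------------------------------------------
# Satterthwaite denominator df
# ---------------------------------------------------------------------------


def _satterthwaite(
    X: np.ndarray, Z: np.ndarray, tau2: float, sigma2: float, c: np.ndarray
) -> tuple[float, float]:
    """(contrast variance, denominator df) for contrast c under REML.

    df = 2 g^2 / Var(g) with g = c'(X'V^-1 X)^-1 c and Var(g) from the
    delta method using the inverse REML information of (tau2, sigma2).
    """
    n, p = X.shape
    tau2 = max(tau2, 0.0)
    if tau2 <= 1e-8 * sigma2:
        # singular (boundary) fit: the model degenerates to OLS and the
        # contrast variance no longer depends on tau2; residual df applies
        Vi0 = np.eye(n) / sigma2
        C0 = np.linalg.inv(X.T @ Vi0 @ X)
        return float(c @ C0 @ c), float(n - p)
    V = sigma2 * np.eye(n) + tau2 * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    C = np.linalg.inv(X.T @ Vi @ X)
    g = float(c @ C @ c)
    dVs = (Z @ Z.T, np.eye(n))
    P = Vi - Vi @ X @ C @ X.T @ Vi
    grad = np.empty(2)
    info = np.empty((2, 2))
    for a, dVa in enumerate(dVs):
        B = C @ X.T @ Vi @ dVa @ Vi @ X @ C
        grad[a] = float(c @ B @ c)
        for b, dVb in enumerate(dVs):
            info[a, b] = 0.5 * np.trace(P @ dVa @ P @ dVb)
    var_g = float(grad @ np.linalg.pinv(info) @ grad)
    if var_g <= 0 or not np.isfinite(var_g):
        return g, float(n - p)
    df = 2.0 * g * g / var_g
    return g, float(np.clip(df, 1.0, n - p))


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _fit_mixedlm(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray, reml: bool):
    from statsmodels.regression.mixed_linear_model import MixedLM

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = MixedLM(y, X.to_numpy(), groups=groups)
        try:
            res = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            res = model.fit(reml=reml, method="powell")
    noisy = any("onverge" in str(w.message) for w in caught)
    return res, (res.converged and not noisy)


def fit_lmm(
    table: pd.DataFrame,
    spec: ModelSpec,
    zero_random_variance: bool = False,
) -> ModelResult:
    """Fit the LMM for one response and assemble the full result bundle.

    REML estimates are reported (coefficients, variance components, F
    tests); the embedded full-vs-null comparison refits both models with
    ML.  ``zero_random_variance`` forces the random-intercept variance to
    zero, reducing the fit to ordinary least squares on the same design
    (useful as an algebraic cross-check).

    A response with (numerically) zero variance is flagged as degenerate
    and returned without test statistics rather than crashing.
    """
    y, X, groups, n_dropped = encode_design(table, spec)
    if n_dropped:
        logger.info("%s: dropped %d rows with missing response", spec.response, n_dropped)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"{spec.response}: too few rows ({n}) for {p} fixed effects")
    if float(np.var(y)) < 1e-12:
        logger.warning("%s: response has zero variance; degenerate fit", spec.response)
        return ModelResult(
            spec, n, n_dropped, converged=False, degenerate=True,
            message="response constant: zero residual variance",
        )

    Xm = X.to_numpy()
    Z = _group_matrix(groups)
    if zero_random_variance:
        beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
        resid_ols = y - Xm @ beta
        sigma2 = float(resid_ols @ resid_ols / (n - p))
        tau2 = 0.0
        cov_beta = sigma2 * np.linalg.inv(Xm.T @ Xm)
        converged = True
        method = "OLS (random-intercept variance forced to 0)"
    else:
        res, converged = _fit_mixedlm(y, X, groups, reml=True)
        tau2 = float(np.asarray(res.cov_re)[0, 0])
        sigma2 = float(res.scale)
        lam0 = tau2 / sigma2 if sigma2 > 0 else 0.0
        tau2, sigma2, beta = _refine_reml(y, Xm, Z, lam0)
        V = sigma2 * np.eye(n) + tau2 * (Z @ Z.T)
        Vi = np.linalg.inv(V)
        cov_beta = np.linalg.inv(Xm.T @ Vi @ Xm)
        method = "REML"

    terms = list(X.columns)
    coefficients = pd.DataFrame(
        {
            "term": terms,
            "estimate": beta,
            "se": np.sqrt(np.diag(cov_beta)),
        }
    )

    # per-factor Wald F with Satterthwaite denominator df
    rows, contrast_rows = [], []
    for k, f in enumerate(spec.factors, start=1):
        c = np.zeros(p)
        c[k] = 1.0
        if zero_random_variance:
            g, df_den = float(c @ cov_beta @ c), float(n - p)
        else:
            g, df_den = _satterthwaite(Xm, Z, tau2, sigma2, c)
        est = float(c @ beta)
        F = est * est / g
        p_raw = float(stats.f.sf(F, 1, df_den))
        rows.append({"factor": f, "F": F, "df_num": 1, "df_den": df_den, "p": p_raw})
        contrast_rows.append(
            {
                "factor": f,
                "levels": f"{FACTOR_CODING[f][2]} - {FACTOR_CODING[f][1]}",
                "difference": est,
                "se": float(np.sqrt(g)),
                "df": df_den,
                "t": est / float(np.sqrt(g)),
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, spec.family * p_raw),
            }
        )
    anova_table = pd.DataFrame(rows)
    contrasts = pd.DataFrame(contrast_rows)

    lrt = compare_full_null(table, spec) if not zero_random_variance else None

    effect_sizes = {f: cohens_d(table, spec.response, f) for f in spec.factors}
    vif_series = vif(table, spec.factors)

    # conditional residuals: y - X beta - Z bhat
    marginal = y - Xm @ beta
    if tau2 > 0:
        V = sigma2 * np.eye(n) + tau2 * (Z @ Z.T)
        bhat = tau2 * Z.T @ np.linalg.solve(V, marginal)
        residuals = marginal - Z @ bhat
    else:
        residuals = marginal
    qq = qq_diagnostic(residuals)

    return ModelResult(
        spec=spec,
        n_used=n,
        n_dropped=n_dropped,
        converged=converged,
        method=method,
        coefficients=coefficients,
        tau2=tau2,
        sigma2=sigma2,
        anova_table=anova_table,
        lrt=lrt,
        contrasts=contrasts,
        effect_sizes=effect_sizes,
        vif=vif_series,
        residuals=residuals,
        qq=qq,
    )


def compare_full_null(table: pd.DataFrame, spec: ModelSpec) -> LRTResult:
    """Likelihood-ratio test of all fixed factors jointly, both fits ML.

    lambda = 2(l_full - l_null) >= 0 (clipped at the boundary), p from a
    chi-square with one df per factor.  Both models keep the random
    intercept and use exactly the same rows.
    """
    y, X, groups, _ = encode_design(table, spec)
    X_null = X[["const"]]
    res_full, _ = _fit_mixedlm(y, X, groups, reml=False)
    res_null, _ = _fit_mixedlm(y, X_null, groups, reml=False)
    lam = max(0.0, 2.0 * (float(res_full.llf) - float(res_null.llf)))
    df = len(spec.factors)
    return LRTResult(lam, df, float(stats.chi2.sf(lam, df)))


def anova_factors(result: ModelResult) -> pd.DataFrame:
    """The per-factor F table (1 numerator df; Satterthwaite denominator df)."""
    if result.anova_table is None:
        raise ValueError("no F table: degenerate or unfitted model")
    return result.anova_table.copy()


def posthoc_contrasts(result: ModelResult, factor: str) -> pd.DataFrame:
    """Marginal-mean difference between the factor's two levels.

    With binary treatment-coded factors and no interactions the difference
    of the level-wise marginal means equals the coefficient; the Bonferroni
    family is the number of factors tested in the model.
    """
    if result.contrasts is None:
        raise ValueError("no contrasts: degenerate or unfitted model")
    if factor not in set(result.spec.factors):
        raise KeyError(f"unknown factor {factor!r}")
    return result.contrasts[result.contrasts["factor"] == factor].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Effect sizes, collinearity, residual diagnostics
# ---------------------------------------------------------------------------


def cohens_d(table: pd.DataFrame, response: str, factor: str) -> float | None:
    """Pooled-SD standardized mean difference, alternative minus reference.

    None (logged) when the pooled SD is zero; raises when either level has
    fewer than two non-missing rows.
    """
    col, ref, alt = FACTOR_CODING[factor]
    sub = table[table[response].notna()]
    a = sub.loc[sub[col] == alt, response].to_numpy(float)
    b = sub.loc[sub[col] == ref, response].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"factor {factor}: both levels need >= 2 rows")
    pooled = np.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    if pooled == 0:
        logger.warning("Cohen's d undefined for %s on %s: zero pooled SD", factor, response)
        return None
    return float((a.mean() - b.mean()) / pooled)


def vif(table: pd.DataFrame, factors: Sequence[str] = FACTORS) -> pd.Series:
    """Design-based variance inflation factors of the binary indicators.

    VIF_k = 1/(1 - R^2_k) from regressing factor k's indicator on the other
    indicators plus an intercept.  Perfect collinearity yields ``inf`` (with
    a logged error message) rather than an exception.
    """
    X = np.column_stack(
        [
            (table[FACTOR_CODING[f][0]] == FACTOR_CODING[f][2]).astype(float)
            for f in factors
        ]
    )
    out = {}
    n = len(X)
    for k, f in enumerate(factors):
        yk = X[:, k]
        others = np.column_stack([np.ones(n), np.delete(X, k, axis=1)])
        bhat, *_ = np.linalg.lstsq(others, yk, rcond=None)
        resid = yk - others @ bhat
        tss = float(((yk - yk.mean()) ** 2).sum())
        rss = float((resid**2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            logger.error("factor %s is perfectly collinear with the others", f)
            out[f] = np.inf
        else:
            out[f] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def model_based_vif(
    table: pd.DataFrame,
    factors: Sequence[str],
    groups: np.ndarray,
    tau2: float,
    sigma2: float,
) -> pd.Series:
    """VIF from the fixed-effect coefficient correlation under the LMM.

    This is what generalized-VIF diagnostics report on a fitted mixed
    model: with a positive random-intercept variance the between-subject
    collinearity shrinks relative to the design-based value.
    """
    X = np.column_stack(
        [np.ones(len(table))]
        + [
            (table[FACTOR_CODING[f][0]] == FACTOR_CODING[f][2]).astype(float)
            for f in factors
        ]
    )
    Z = _group_matrix(np.asarray(groups))
    V = sigma2 * np.eye(len(X)) + max(tau2, 0.0) * (Z @ Z.T)
    C = np.linalg.inv(X.T @ np.linalg.solve(V, X))[1:, 1:]
    R = C / np.sqrt(np.outer(np.diag(C), np.diag(C)))
    Rinv = np.linalg.inv(R)
    return pd.Series({f: float(Rinv[k, k]) for k, f in enumerate(factors)}, name="vif")


def qq_diagnostic(residuals: np.ndarray) -> QQDiagnostic:
    """Normal QQ pairs (Blom plotting positions) plus their correlation."""
    r = np.sort(np.asarray(residuals, float))
    n = len(r)
    if n < 3:
        raise ValueError("need at least 3 residuals for a QQ diagnostic")
    sd = r.std(ddof=1)
    observed = (r - r.mean()) / (sd if sd > 0 else 1.0)
    theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    corr = float(np.corrcoef(theoretical, observed)[0, 1])
    return QQDiagnostic(np.column_stack([theoretical, observed]), corr)


def fit_all_models(
    table: pd.DataFrame, responses: Sequence[str] = RESPONSES
) -> dict[str, ModelResult]:
    """One LMM per response column."""
    return {r: fit_lmm(table, ModelSpec(r)) for r in responses}
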