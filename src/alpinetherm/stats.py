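"""Statistical layer: PCA of microclimate drivers, penalized additive smooth
model of plant temperature, sequential-SS variance partitioning of thermal
decoupling, group tests, rank correlation and residual diagnostics.

Conventions used throughout: two-sided p-values, alpha = 0.05, no
multiple-testing correction.  The variance partition is the sequential
(Type-I) decomposition in the declared term order — each term's sum of
squares is the reduction in residual SS when the term is added after all the
terms before it, so term SS plus residual SS always reconstruct the total SS
and the "explained variance" column is simply term SS / total SS.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.gam.api import BSplines
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import het_breuschpagan

__all__ = [
    "PCAResult",
    "SmoothModelFit",
    "TestResult",
    "DiagnosticsReport",
    "pca_environment",
    "fit_smooth_model",
    "anova_variance_partition",
    "anova_table_from_ss",
    "paired_decoupling_test",
    "mann_whitney",
    "oneway_anova_lt50",
    "spearman",
    "residual_diagnostics",
    "ANOVA_COLUMNS",
]

#: Serialized column set of the variance-partition table.
ANOVA_COLUMNS = ["numDF", "denDF", "Sum Sq", "Mean Sq", "F", "p", "explained_%"]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    """Correlation-matrix PCA of the standardized environmental drivers."""

    loadings: pd.DataFrame  # variables x components, orthonormal columns
    scores: pd.DataFrame  # observations x components
    variance_fractions: np.ndarray  # per component, sums to 1
    contributions: pd.DataFrame  # % contribution of each variable per component


@dataclass
class SmoothModelFit:
    """Penalized additive (Gaussian, identity link) fit of PT on PC scores."""

    terms: pd.DataFrame  # per-smooth edf, ref_df, F, p
    edf_total: float
    adjusted_r2: float
    fitted: np.ndarray
    residuals: np.ndarray
    alpha: np.ndarray  # selected penalty weights
    exog_linear: np.ndarray = field(repr=False, default=None)


@dataclass
class TestResult:
    """Outcome of a classical test (t, U, F, H or rank correlation)."""

    name: str
    statistic: float
    p_value: float
    df: float | tuple | None = None
    estimate: float | None = None  # mean difference or correlation


@dataclass
class DiagnosticsReport:
    """Shapiro-Wilk normality and studentized Breusch-Pagan heteroscedasticity."""

    shapiro_w: float
    shapiro_p: float
    bp_stat: float
    bp_p: float
    alpha: float = 0.05

    @property
    def normality_ok(self) -> bool:
        return self.shapiro_p > self.alpha

    @property
    def homoscedastic_ok(self) -> bool:
        return self.bp_p > self.alpha


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_environment(env: pd.DataFrame) -> PCAResult:
    """PCA of standardized (zero-mean, unit-variance) environmental variables.

    The correlation-matrix convention is forced because the drivers carry
    mixed units (degrees C, %, km/h, umol m-2 s-1).  Components are ordered
    by decreasing variance; each component's sign is fixed so that its
    largest-|loading| variable loads positively.
    """
    if env.shape[1] < 2:
        raise ValueError("PCA needs at least 2 variables")
    x = env.to_numpy(dtype=float)
    if np.isnan(x).any():
        x = x[~np.isnan(x).any(axis=1)]
    if x.shape[0] < 3:
        raise ValueError("PCA needs at least 3 complete observations")
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = list(env.columns[np.flatnonzero(sd == 0)])
        raise ValueError(f"constant column(s) with zero variance: {bad}")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    # sign convention: largest-|loading| variable positive in each component
    for j in range(vt.shape[0]):
        k = np.argmax(np.abs(vt[j]))
        if vt[j, k] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    eigvals = s**2 / (z.shape[0] - 1)
    frac = eigvals / eigvals.sum()
    comp_names = [f"PC{j + 1}" for j in range(len(s))]
    loadings = pd.DataFrame(vt.T, index=env.columns, columns=comp_names)
    scores = pd.DataFrame(u * s, columns=comp_names)
    contributions = loadings**2 * 100.0
    return PCAResult(loadings, scores, frac, contributions)


# ---------------------------------------------------------------------------
# penalized additive smooth model
# ---------------------------------------------------------------------------

def _penalized_gaussian_fit(x, y, penalty):
    """Solve the penalized normal equations and return fit summaries.

    ``penalty`` is the full block-diagonal penalty matrix (already scaled by
    the per-smooth weights).  Returns (beta, fitted, rss, edf_vector) where
    ``edf_vector`` holds the per-coefficient effective degrees of freedom,
    diag((X'X + P)^-1 X'X), whose sum is the trace of the hat matrix.
    """
    xtx = x.T @ x
    a = np.linalg.solve(xtx + penalty, np.column_stack([x.T @ y, xtx]))
    beta = a[:, 0]
    edf_vec = np.diag(a[:, 1:])
    fitted = x @ beta
    resid = y - fitted
    return beta, fitted, float(resid @ resid), edf_vec


def fit_smooth_model(
    response: np.ndarray,
    predictors: pd.DataFrame | np.ndarray,
    k: int = 10,
) -> SmoothModelFit:
    """Gaussian additive model with one penalized B-spline smooth per predictor.

    Each column of ``predictors`` enters as a cubic B-spline smooth with basis
    dimension ``k`` and an integrated-squared-second-derivative penalty whose
    weight is selected by minimizing the generalized cross-validation score
    (Gaussian identity-link case, solved in closed form — no IRLS).  The
    penalty null space is the linear trend, so a noise-free linear signal
    shrinks to edf = 1 per smooth.  Per-smooth significance uses the Wald
    statistic of the smooth's coefficients referred to an F distribution with
    (edf, n - total edf) degrees of freedom, the usual approximation for
    penalized fits.
    """
    from scipy import optimize

    y = np.asarray(response, dtype=float)
    xmat = (
        predictors.to_numpy(dtype=float)
        if isinstance(predictors, pd.DataFrame)
        else np.atleast_2d(np.asarray(predictors, dtype=float))
    )
    if xmat.ndim == 1:
        xmat = xmat[:, None]
    if xmat.shape[0] != y.size:
        xmat = xmat.T
    n, n_smooth = xmat.shape
    if n < 20:
        raise ValueError("additive fit needs at least 20 observations")
    names = (
        list(predictors.columns)
        if isinstance(predictors, pd.DataFrame)
        else [f"x{j + 1}" for j in range(n_smooth)]
    )
    for j in range(n_smooth):
        if np.unique(xmat[:, j]).size <= k:
            raise ValueError(
                f"basis dimension k={k} exceeds unique values of {names[j]}"
            )

    smoother = BSplines(xmat, df=[k] * n_smooth, degree=[3] * n_smooth)
    x = np.column_stack([np.ones(n)] + [s.basis for s in smoother.smoothers])
    blocks = [s.cov_der2 for s in smoother.smoothers]
    slices = []
    offset = 1
    for s in smoother.smoothers:
        slices.append(slice(offset, offset + s.dim_basis))
        offset += s.dim_basis

    tss = float(((y - y.mean()) ** 2).sum())

    def full_penalty(log_alpha):
        p = np.zeros((x.shape[1], x.shape[1]))
        # clip keeps the normal equations finite and well conditioned
        for sl, block, la in zip(slices, blocks, np.clip(log_alpha, -8.0, 12.0)):
            p[sl, sl] = 10.0**la * block
        return p

    def gcv(log_alpha):
        _, _, rss, edf_vec = _penalized_gaussian_fit(x, y, full_penalty(log_alpha))
        tr = edf_vec.sum()
        # log scale; the tiny additive term breaks the tie between exact fits
        # of different roughness in favor of the smoother one (noise-free case)
        return float(
            np.log(n * (rss + 1e-12 * tss)) - 2.0 * np.log(max(n - tr, 1e-6))
        )

    res = optimize.minimize(
        gcv, np.zeros(n_smooth), method="Nelder-Mead",
        options={"maxiter": 400, "xatol": 1e-4, "fatol": 1e-10},
    )
    log_alpha = np.clip(res.x, -8.0, 12.0)
    alpha = 10.0**log_alpha

    beta, fitted, rss, edf_vec = _penalized_gaussian_fit(
        x, y, full_penalty(log_alpha)
    )
    edf_total = float(edf_vec.sum())
    resid = y - fitted
    adj_r2 = 1.0 - (rss / (n - edf_total)) / (tss / (n - 1))
    scale = rss / max(n - edf_total, 1.0)

    # Wald covariance of the penalized estimator (frequentist sandwich)
    xtx = x.T @ x
    inv_pen = np.linalg.inv(xtx + full_penalty(log_alpha))
    cov_beta = scale * inv_pen @ xtx @ inv_pen

    rows = []
    for name, sl, s in zip(names, slices, smoother.smoothers):
        edf_j = float(edf_vec[sl].sum())
        b_j = beta[sl]
        contribution = float(np.square(x[:, sl] @ b_j).sum())
        if scale <= 1e-12 * max(tss / n, 1e-300):
            # perfect fit: a term is significant iff it contributes signal
            f_stat = np.inf if contribution > 1e-10 * tss else 0.0
            p = 0.0 if contribution > 1e-10 * tss else 1.0
        else:
            # Wald on the smooth's coefficients with the covariance truncated
            # at rank ~edf (the usual approximate test for penalized smooths)
            cov_j = cov_beta[sl, sl]
            rank = max(1, int(round(edf_j)))
            w, v = np.linalg.eigh(cov_j)
            keep = np.argsort(w)[::-1][:rank]
            proj = v[:, keep].T @ b_j
            chi2 = float(proj @ (proj / w[keep]))
            f_stat = chi2 / rank
            p = float(sps.f.sf(f_stat, rank, max(n - edf_total, 1.0)))
        rows.append(
            {"term": name, "edf": edf_j, "ref_df": float(s.dim_basis),
             "F": f_stat, "p": p}
        )
    return SmoothModelFit(
        terms=pd.DataFrame(rows).set_index("term"),
        edf_total=edf_total,
        adjusted_r2=float(adj_r2),
        fitted=fitted,
        residuals=resid,
        alpha=alpha,
        exog_linear=xmat,
    )


# ---------------------------------------------------------------------------
# sequential (Type-I) variance partition
# ---------------------------------------------------------------------------

def anova_variance_partition(
    data: pd.DataFrame,
    formula: str = "TD ~ PH + CI + PI + PH:CI + date",
) -> pd.DataFrame:
    """Sequential-SS ANOVA of a linear model with an explained-variance column.

    Terms are decomposed in the order they appear in ``formula`` (Type-I SS),
    so the partition is order-dependent whenever predictors are correlated.
    The returned table carries one row per term plus a Residuals row, with
    columns ``numDF, denDF, Sum Sq, Mean Sq, F, p, explained_%`` where
    ``explained_% = 100 * Sum Sq / total SS``; total SS is stored in
    ``table.attrs["total_ss"]``.
    """
    fit = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("model matrix is rank deficient")
    if fit.df_resid < 1:
        raise ValueError("fewer than 1 residual degree of freedom")
    raw = anova_lm(fit, typ=1)
    total_ss = float(raw["sum_sq"].sum())
    # constant response: numerically-zero total SS reports 0 % everywhere
    y_scale = float(np.mean(np.square(fit.model.endog))) + 1.0
    share_denom = total_ss if total_ss > 1e-10 * y_scale else np.inf
    resid_df = float(raw.loc["Residual", "df"])
    resid_ms = float(raw.loc["Residual", "sum_sq"]) / resid_df
    rows = []
    for term, row in raw.iterrows():
        is_resid = term == "Residual"
        ss = float(row["sum_sq"])
        df_t = float(row["df"])
        rows.append(
            {
                "term": "Residuals" if is_resid else term,
                "numDF": int(df_t),
                "denDF": np.nan if is_resid else int(resid_df),
                "Sum Sq": ss,
                "Mean Sq": ss / df_t,
                "F": np.nan if is_resid else float(row["F"]),
                "p": np.nan if is_resid else float(row["PR(>F)"]),
                "explained_%": 100.0 * ss / share_denom,
            }
        )
    table = pd.DataFrame(rows).set_index("term")[ANOVA_COLUMNS]
    table.attrs["total_ss"] = total_ss
    return table


def anova_table_from_ss(
    term_names: list[str],
    term_ss: list[float],
    residual_ss: float,
    residual_df: int,
    term_df: list[int] | None = None,
) -> pd.DataFrame:
    """Rebuild the variance-partition table from sums of squares alone.

    This is the replay path for published ANOVA tables: given the per-term
    sequential SS and the residual SS/df, it recomputes mean squares,
    F = term MS / residual MS, p-values and explained-variance percentages
    (term SS / total SS).  Total SS is the sum of all entries.
    """
    term_ss = [float(s) for s in term_ss]
    if term_df is None:
        term_df = [1] * len(term_ss)
    if len(term_names) != len(term_ss) or len(term_df) != len(term_ss):
        raise ValueError("term_names, term_ss and term_df lengths differ")
    total_ss = sum(term_ss) + float(residual_ss)
    resid_ms = float(residual_ss) / residual_df
    rows = []
    for name, ss, df_t in zip(term_names, term_ss, term_df):
        ms = ss / df_t
        f = ms / resid_ms
        rows.append(
            {
                "term": name,
                "numDF": df_t,
                "denDF": residual_df,
                "Sum Sq": ss,
                "Mean Sq": ms,
                "F": f,
                "p": float(sps.f.sf(f, df_t, residual_df)),
                "explained_%": 100.0 * ss / total_ss,
            }
        )
    rows.append(
        {
            "term": "Residuals",
            "numDF": residual_df,
            "denDF": np.nan,
            "Sum Sq": float(residual_ss),
            "Mean Sq": resid_ms,
            "F": np.nan,
            "p": np.nan,
            "explained_%": 100.0 * residual_ss / total_ss,
        }
    )
    table = pd.DataFrame(rows).set_index("term")[ANOVA_COLUMNS]
    table.attrs["total_ss"] = total_ss
    return table


# ---------------------------------------------------------------------------
# classical tests
# ---------------------------------------------------------------------------

def paired_decoupling_test(pt: np.ndarray, at: np.ndarray) -> TestResult:
    """Paired t-test of PT against AT (i.e. one-sample t on TD = PT - AT)."""
    pt = np.asarray(pt, dtype=float)
    at = np.asarray(at, dtype=float)
    if pt.size != at.size:
        raise ValueError("PT and AT must be paired (equal lengths)")
    if pt.size < 3:
        raise ValueError("paired t-test needs n >= 3")
    d = pt - at
    if np.allclose(d.std(ddof=1), 0) and not np.allclose(d, 0):
        raise ValueError("zero variance of paired differences")
    t, p = sps.ttest_rel(pt, at)
    return TestResult(
        "paired_t", float(t), float(p), df=pt.size - 1, estimate=float(d.mean())
    )


def mann_whitney(group_a, group_b) -> TestResult:
    """Mann-Whitney U with exact p for small untied samples.

    The p-value is exact when min(n_a, n_b) <= 8 and the pooled sample has no
    ties, otherwise the tie-corrected normal approximation with continuity
    correction is used.  Two-sided throughout.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    return TestResult("mann_whitney_U", float(res.statistic), float(res.pvalue))


def oneway_anova_lt50(groups: dict[str, np.ndarray] | list) -> TestResult:
    """One-way ANOVA across species groups (F with k-1, N-k df)."""
    arrays = [np.asarray(g, dtype=float) for g in
              (groups.values() if isinstance(groups, dict) else groups)]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in arrays):
        raise ValueError("each group needs at least 2 observations")
    n_tot = sum(g.size for g in arrays)
    k = len(arrays)
    within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if within == 0:
        raise ValueError("zero within-group variance: F undefined")
    f, p = sps.f_oneway(*arrays)
    return TestResult("oneway_F", float(f), float(p), df=(k - 1, n_tot - k))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input vector: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return TestResult("spearman_rho", float(rho), float(p), estimate=float(rho))


def residual_diagnostics(
    residuals: np.ndarray,
    exog: np.ndarray | None = None,
    fitted: np.ndarray | None = None,
    alpha: float = 0.05,
) -> DiagnosticsReport:
    """Shapiro-Wilk normality and studentized Breusch-Pagan tests on residuals.

    The Breusch-Pagan auxiliary regression uses ``exog`` when supplied,
    otherwise the fitted values (the standard mgcv/lmtest default for a
    single-equation check).
    """
    resid = np.asarray(residuals, dtype=float)
    if resid.size < 3 or resid.size > 5000:
        raise ValueError("Shapiro-Wilk valid for 3 <= n <= 5000")
    w, p_sw = sps.shapiro(resid)
    if exog is None:
        if fitted is None:
            raise ValueError("need exog or fitted values for Breusch-Pagan")
        exog = np.column_stack([np.ones(resid.size), np.asarray(fitted, float)])
    else:
        exog = np.asarray(exog, dtype=float)
        if exog.ndim == 1:
            exog = exog[:, None]
        if not np.allclose(exog[:, 0], 1.0):
            exog = np.column_stack([np.ones(resid.size), exog])
    bp_stat, bp_p, _, _ = het_breuschpagan(resid, exog)
    return DiagnosticsReport(float(w), float(p_sw), float(bp_stat), float(bp_p), alpha)
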