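"""Per-gene hypothesis tests, FDR estimation, covariate screens.

Tests run on the log2 scale; fold changes are reported as case/control
ratios of linear-scale means.  The significance screen used throughout the
pipeline is the per-gene Welch t-test at a nominal p < 0.001, with Storey
q-values attached for FDR reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import UnivariateSpline

from .core import ExpressionMatrix, ValidationError


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

def welch_t(x_case, x_control):
    """Two-sided Welch t-test with Satterthwaite degrees of freedom.

    Returns ``(t, df, p)``.  Requires at least two observations per group and
    nonzero variance in at least one group.
    """
    a = np.asarray(x_case, dtype=float)
    b = np.asarray(x_control, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 samples")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValidationError("both groups are constant; Welch statistic undefined")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def welch_t_matrix(a: np.ndarray, b: np.ndarray):
    """Vectorized Welch test across rows (genes): ``a``, ``b`` genes x samples.

    Degenerate rows (both groups constant) get t = 0, p = 1 when the means
    agree and p = 0 otherwise.
    """
    na, nb = a.shape[1], b.shape[1]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    se2 = va / na + vb / nb
    diff = ma - mb
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    zero = se2 == 0
    t[zero] = np.where(diff[zero] == 0, 0.0, np.sign(diff[zero]) * np.inf)
    df[zero] = 1.0
    p = 2 * stats.t.sf(np.abs(t), df)
    p[zero & (diff == 0)] = 1.0
    return t, df, p


# ---------------------------------------------------------------------------
# Dunnett many-to-one comparisons
# ---------------------------------------------------------------------------

def oneway_dunnett(groups: dict, control, n_draws: int = 100_000,
                   seed: int = 0) -> pd.DataFrame:
    """Pooled-variance many-to-one t statistics with Dunnett adjustment.

    Compares each treatment group against the shared control.  The
    familywise-adjusted p-value is the probability, under the joint null
    multivariate-t distribution of the comparison statistics, that the
    largest absolute statistic exceeds the observed one; it is evaluated by
    seeded Monte Carlo so the dimension (number of comparisons) is arbitrary.
    Returns a DataFrame with columns ``t, p_raw, p_adjusted`` per group.
    """
    control = np.asarray(control, dtype=float)
    if control.size < 2:
        raise ValidationError("control group needs at least 2 samples")
    names = list(groups)
    arrs = [np.asarray(groups[k], dtype=float) for k in names]
    if any(a.size < 2 for a in arrs):
        empty = names[[a.size < 2 for a in arrs].index(True)]
        raise ValidationError(f"group {empty!r} needs at least 2 samples")
    n0 = control.size
    ns = np.array([a.size for a in arrs])
    k = len(arrs)
    ntot = n0 + ns.sum()
    nu = ntot - (k + 1)
    ss = ((control - control.mean()) ** 2).sum() + sum(
        ((a - a.mean()) ** 2).sum() for a in arrs)
    s2 = ss / nu
    if s2 == 0:
        raise ValidationError("zero pooled variance; statistics undefined")
    t_obs = np.array([(a.mean() - control.mean()) / np.sqrt(s2 * (1 / a.size + 1 / n0))
                      for a in arrs])
    p_raw = 2 * stats.t.sf(np.abs(t_obs), nu)

    lam = np.sqrt(ns / (ns + n0))
    corr = np.outer(lam, lam)
    np.fill_diagonal(corr, 1.0)
    rng = np.random.default_rng(seed)
    chol = np.linalg.cholesky(corr)
    z = rng.standard_normal((n_draws, k)) @ chol.T
    w = np.sqrt(rng.chisquare(nu, size=n_draws) / nu)
    maxabs = np.abs(z / w[:, None]).max(axis=1)
    p_adj = np.array([(maxabs >= abs(t)).mean() for t in t_obs])
    p_adj = np.maximum(p_adj, p_raw)  # adjustment can only be less significant
    return pd.DataFrame({"t": t_obs, "p_raw": p_raw, "p_adjusted": p_adj},
                        index=names)


# ---------------------------------------------------------------------------
# Two-way ANOVA (diagnosis x sex)
# ---------------------------------------------------------------------------

def twoway_anova(values, diagnosis, sex):
    """Type II two-way ANOVA of one gene's expression on diagnosis and sex.

    Returns ``(p_dx, p_sex, p_interaction)``.  Type II sums of squares are
    used so main effects are well-defined under the observational imbalance
    typical of case/control cohorts; with a balanced design they coincide
    with the sequential decomposition.  All four diagnosis-by-sex cells must
    be nonempty.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "y": np.asarray(values, dtype=float),
        "dx": np.asarray(diagnosis).astype(str),
        "sex": np.asarray(sex).astype(str),
    })
    cells = df.groupby(["dx", "sex"]).size()
    if len(cells) < 4 or (cells == 0).any():
        raise ValidationError("every diagnosis x sex cell must be nonempty")
    fit = smf.ols("y ~ C(dx) * C(sex)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    return (float(tab.loc["C(dx)", "PR(>F)"]),
            float(tab.loc["C(sex)", "PR(>F)"]),
            float(tab.loc["C(dx):C(sex)", "PR(>F)"]))


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

@dataclass
class QValueResult:
    pi0: float
    qvalues: np.ndarray
    lambdas: np.ndarray


def storey_qvalues(p, lambdas=None, pi0: float | None = None) -> QValueResult:
    """Storey FDR q-values with smoothed pi0 estimation.

    pi0 is estimated on the grid lambda = 0.05..0.95 (step 0.05) and
    extrapolated to lambda = 1 with a cubic smoother; forcing ``pi0=1``
    reduces the q-values to Benjamini–Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    lambdas = np.asarray(lambdas)
    if pi0 is None:
        pi0_lam = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
        if m < 100 or np.allclose(pi0_lam, pi0_lam[0]):
            pi0_hat = float(np.minimum(pi0_lam, 1.0).min())
        else:
            spline = UnivariateSpline(lambdas, pi0_lam, k=3)
            pi0_hat = float(spline(1.0))
        pi0 = float(np.clip(pi0_hat, 1.0 / m, 1.0))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q_sorted = pi0 * m * ranked / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(pi0=pi0, qvalues=q, lambdas=lambdas)


# ---------------------------------------------------------------------------
# Spearman age screen
# ---------------------------------------------------------------------------

_ATANH_CLAMP = 1 - 1e-12


def spearman_age_screen(x: ExpressionMatrix, age) -> pd.DataFrame:
    """Per-gene Spearman correlation with age, tested via Fisher's r-to-z.

    Ties take midranks; p-values come from z = atanh(rho) * sqrt(n - 3),
    two-sided.  |rho| = 1 is clamped just inside the open interval before
    atanh, mapping to p = 0 numerically.  Genes with constant expression
    cannot be ranked and are flagged ``excluded`` with rho/p set to NaN.
    """
    age = np.asarray(age, dtype=float)
    n = age.size
    if n < 4:
        raise ValidationError("Spearman screen needs n >= 4")
    if np.ptp(age) == 0:
        raise ValidationError("age vector is constant; correlation undefined")
    y = x.log2()
    ranks = stats.rankdata(y, axis=1)
    age_r = stats.rankdata(age)
    excluded = np.ptp(y, axis=1) == 0
    rc = ranks - ranks.mean(axis=1, keepdims=True)
    ac = age_r - age_r.mean()
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rc @ ac) / np.sqrt((rc ** 2).sum(axis=1) * (ac ** 2).sum())
    rho[excluded] = np.nan
    z = np.arctanh(np.clip(rho, -_ATANH_CLAMP, _ATANH_CLAMP)) * np.sqrt(n - 3)
    p = 2 * stats.norm.sf(np.abs(z))
    p[excluded] = np.nan
    return pd.DataFrame({"rho": rho, "p_value": p, "excluded": excluded},
                        index=x.feature_ids)


# ---------------------------------------------------------------------------
# Per-gene AUC + the combined DE table
# ---------------------------------------------------------------------------

def gene_aucs(values: np.ndarray, is_case: np.ndarray) -> np.ndarray:
    """Per-gene case-vs-control AUC (Mann-Whitney with half credit for ties)."""
    is_case = np.asarray(is_case, dtype=bool)
    n1 = int(is_case.sum())
    n2 = int((~is_case).sum())
    if n1 == 0 or n2 == 0:
        raise ValidationError("both classes must be present to compute AUC")
    ranks = stats.rankdata(values, axis=1)
    r1 = ranks[:, is_case].sum(axis=1)
    return (r1 - n1 * (n1 + 1) / 2) / (n1 * n2)


def de_table(x: ExpressionMatrix, is_case, alpha: float = 0.001) -> pd.DataFrame:
    """Per-gene Welch screen: statistics, fold changes, AUC, Storey q-values.

    ``fold_change`` is the case/control ratio of linear-scale means; the
    ``significant`` column marks genes with nominal p below ``alpha``.
    """
    if not 0 < alpha <= 1:
        raise ValidationError("alpha must lie in (0, 1]")
    is_case = np.asarray(is_case, dtype=bool)
    if is_case.shape[0] != x.shape[1]:
        raise ValidationError("labels not aligned to samples")
    y = x.log2()
    lin = x.values
    t, df, p = welch_t_matrix(y[:, is_case], y[:, ~is_case])
    q = storey_qvalues(p).qvalues
    auc = gene_aucs(y, is_case)
    mean_case = lin[:, is_case].mean(axis=1)
    mean_control = lin[:, ~is_case].mean(axis=1)
    return pd.DataFrame({
        "mean_case": mean_case,
        "mean_control": mean_control,
        "fold_change": mean_case / mean_control,
        "statistic": t,
        "df": df,
        "p_value": p,
        "q_value": q,
        "auc": auc,
        "min_expression": lin.min(axis=1),
        "mean_expression": lin.mean(axis=1),
        "significant": p < alpha,
    }, index=x.feature_ids)
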