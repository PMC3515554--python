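"""Robust multivariate outlier detection over pathway gene sets.

Per-sample robust Mahalanobis distances (RDs) are computed from the minimum
covariance determinant (MCD) location/scatter estimate, fit jointly on cases
and controls.  Squared distances are approximately chi-squared for
multivariate normal data, so the outlier cutoff for a d-dimensional subspace
is the square root of a chi-squared quantile (97.5% by default).  Samples
are assigned to quadrants by their outlier status in two pathway subspaces:
quadrant I = outlying in both, II = second set only, IV = first set only,
III = neither.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ValidationError
from .overlap import fisher_exact_2x2


def _cstep(x: np.ndarray, subset: np.ndarray, h: int, max_iter: int = 100):
    """Concentration steps from a starting subset to a local determinant minimum."""
    n, p = x.shape
    for _ in range(max_iter):
        loc = x[subset].mean(axis=0)
        cov = np.cov(x[subset], rowvar=False, ddof=0)
        cov = np.atleast_2d(cov)
        sign, logdet = np.linalg.slogdet(cov)
        if sign <= 0:
            return subset, np.inf
        d2 = _sq_mahalanobis(x, loc, cov)
        new = np.sort(np.argsort(d2, kind="mergesort")[:h])
        if np.array_equal(new, subset):
            return subset, logdet
        subset = new
    return subset, logdet


def _sq_mahalanobis(x, loc, cov):
    centered = x - loc
    sol = np.linalg.solve(cov, centered.T)
    return np.einsum("ij,ji->i", centered, sol)


def fast_mcd(x: np.ndarray, seed: int = 0, n_starts: int = 500,
             reweight_quantile: float = 0.975):
    """Minimum covariance determinant location/scatter (FAST-MCD).

    Many seeded random (p+1)-point starts are concentrated for two steps
    each; the ten most promising are iterated to convergence and the
    h-subset (h = (n+p+1)//2, maximal breakdown) with the smallest
    covariance determinant wins.  The raw estimate gets the chi-squared
    consistency factor, then one reweighting step discards points beyond
    the ``reweight_quantile`` chi-squared cutoff and the reweighted scatter
    is consistency-corrected again.  Returns ``(location, covariance, h,
    support_mask)``.
    """
    x = np.asarray(x, dtype=float)
    n, p = x.shape
    h = (n + p + 1) // 2
    if h >= n:
        raise ValidationError("too few samples for an MCD subset")
    rng = np.random.default_rng(seed)
    trials = []
    for _ in range(n_starts):
        start = rng.choice(n, size=p + 1, replace=False)
        loc = x[start].mean(axis=0)
        cov = np.atleast_2d(np.cov(x[start], rowvar=False, ddof=0))
        k = p + 1
        while np.linalg.matrix_rank(cov) < p and k < n:
            k += 1
            start = rng.choice(n, size=k, replace=False)
            loc = x[start].mean(axis=0)
            cov = np.atleast_2d(np.cov(x[start], rowvar=False, ddof=0))
        if np.linalg.matrix_rank(cov) < p:
            raise ValidationError("data are rank-deficient; MCD scatter singular")
        d2 = _sq_mahalanobis(x, loc, cov)
        subset = np.sort(np.argsort(d2, kind="mergesort")[:h])
        for _ in range(2):  # two concentration steps per start
            loc = x[subset].mean(axis=0)
            cov = np.atleast_2d(np.cov(x[subset], rowvar=False, ddof=0))
            if np.linalg.slogdet(cov)[0] <= 0:
                break
            d2 = _sq_mahalanobis(x, loc, cov)
            subset = np.sort(np.argsort(d2, kind="mergesort")[:h])
        cov = np.atleast_2d(np.cov(x[subset], rowvar=False, ddof=0))
        sign, logdet = np.linalg.slogdet(cov)
        trials.append((logdet if sign > 0 else np.inf, subset))
    trials.sort(key=lambda t: t[0])
    best_logdet, best_subset = np.inf, None
    for _, subset in trials[:10]:
        subset, logdet = _cstep(x, subset, h)
        if logdet < best_logdet:
            best_logdet, best_subset = logdet, subset
    if best_subset is None or not np.isfinite(best_logdet):
        raise ValidationError("MCD failed: all candidate subsets singular")

    loc = x[best_subset].mean(axis=0)
    cov = np.atleast_2d(np.cov(x[best_subset], rowvar=False, ddof=0))
    alpha = h / n
    cov *= alpha / stats.chi2.cdf(stats.chi2.ppf(alpha, p), p + 2)
    # one-step reweighting with its own consistency factor
    d2 = _sq_mahalanobis(x, loc, cov)
    q = stats.chi2.ppf(reweight_quantile, p)
    w = d2 <= q
    if w.sum() <= p:
        w = np.ones(n, dtype=bool)
    loc = x[w].mean(axis=0)
    cov = np.atleast_2d(np.cov(x[w], rowvar=False, ddof=0))
    cov *= reweight_quantile / stats.chi2.cdf(q, p + 2)
    return loc, cov, h, w


@dataclass
class RobustDistanceResult:
    rd: np.ndarray          # per-sample robust distance
    df: int                 # dimension used for the chi-squared reference
    h: int                  # MCD subset size (0 for the classical estimate)
    used_pca: bool
    n_components: int
    location: np.ndarray
    covariance: np.ndarray


def mcd_robust_distance(x: np.ndarray, seed: int = 0, robust: bool = True,
                        pca_var_target: float = 0.90,
                        min_sample_ratio: int = 10) -> RobustDistanceResult:
    """Robust Mahalanobis distance of each sample from the common centroid.

    ``x`` is samples x genes for one pathway subspace.  When the dimension is
    too high for a calibrated MCD fit (n < ``min_sample_ratio`` * p) the
    subspace is first reduced by PCA to the fewest components explaining at
    least ``pca_var_target`` of the variance, capped so the ratio holds, and
    the chi-squared reference dimension becomes the number of retained
    components.  The default ratio of 10 keeps the chi-squared tail
    approximation for the squared distances usable; at smaller ratios the
    distances of points outside the MCD subset are markedly heavier-tailed
    than chi-squared and the nominal outlier rate inflates severely.
    ``robust=False`` falls back to the classical mean/sample-covariance
    estimate (same distance formula, no reweighting).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValidationError("expected a samples x genes matrix")
    n, p = x.shape
    if n < 4:
        raise ValidationError("need at least 4 samples for a scatter estimate")

    used_pca = False
    if n < min_sample_ratio * p:
        centered = x - x.mean(axis=0)
        u, s, vt = np.linalg.svd(centered, full_matrices=False)
        var = s ** 2
        frac = np.cumsum(var) / var.sum()
        k = int(np.searchsorted(frac, pca_var_target) + 1)
        k = min(k, max(1, n // min_sample_ratio))
        x = centered @ vt[:k].T
        p = k
        used_pca = True
    if p >= n:
        raise ValidationError("dimension still exceeds sample count after reduction")

    if robust:
        loc, cov, h, _ = fast_mcd(x, seed=seed)
    else:
        loc = x.mean(axis=0)
        cov = np.cov(x, rowvar=False, ddof=1)
        cov = np.atleast_2d(cov)
        h = 0
    sign, logdet = np.linalg.slogdet(np.atleast_2d(cov))
    if sign <= 0 or not np.isfinite(logdet):
        raise ValidationError("singular scatter estimate; cannot invert")
    prec = np.linalg.inv(np.atleast_2d(cov))
    centered = x - loc
    rd2 = np.einsum("ij,jk,ik->i", centered, prec, centered)
    return RobustDistanceResult(rd=np.sqrt(np.maximum(rd2, 0.0)), df=p, h=h,
                                used_pca=used_pca, n_components=p,
                                location=loc, covariance=np.atleast_2d(cov))


QUADRANTS = {(True, True): "I", (False, True): "II",
             (False, False): "III", (True, False): "IV"}


def quadrant_assign(rd1, rd2, df1: int, df2: int, q: float = 0.975,
                    sample_ids=None) -> pd.DataFrame:
    """Outlier flags and quadrant labels from two robust-distance axes.

    The cutoff on axis j is sqrt of the chi-squared q-quantile with df_j
    degrees of freedom.  Returns a per-sample frame with rd1, rd2, the two
    flags, and the quadrant; cutoffs are attached as ``frame.attrs``.
    """
    if df1 <= 0 or df2 <= 0:
        raise ValidationError("degrees of freedom must be positive")
    rd1 = np.asarray(rd1, dtype=float)
    rd2 = np.asarray(rd2, dtype=float)
    if rd1.shape != rd2.shape:
        raise ValidationError("distance vectors differ in length")
    c1 = float(np.sqrt(stats.chi2.ppf(q, df1)))
    c2 = float(np.sqrt(stats.chi2.ppf(q, df2)))
    out1 = rd1 > c1
    out2 = rd2 > c2
    quad = [QUADRANTS[(bool(a), bool(b))] for a, b in zip(out1, out2)]
    idx = sample_ids if sample_ids is not None else range(len(rd1))
    df = pd.DataFrame({"rd1": rd1, "rd2": rd2, "outlier1": out1,
                       "outlier2": out2, "quadrant": quad}, index=idx)
    df.attrs["cutoff1"] = c1
    df.attrs["cutoff2"] = c2
    df.attrs["quantile"] = q
    return df


def outlier_rate_test(flags, is_case) -> dict:
    """Fisher exact test of outlier rates between cases and controls."""
    flags = np.asarray(flags, dtype=bool)
    is_case = np.asarray(is_case, dtype=bool)
    if flags.shape != is_case.shape:
        raise ValidationError("flags and diagnosis vectors differ in length")
    table = np.array([
        [int((flags & is_case).sum()), int((~flags & is_case).sum())],
        [int((flags & ~is_case).sum()), int((~flags & ~is_case).sum())],
    ])
    odds, p = fisher_exact_2x2(table)
    return {"table": table.tolist(), "odds_ratio": odds, "p_value": p,
            "case_rate": table[0, 0] / max(table[0].sum(), 1),
            "control_rate": table[1, 0] / max(table[1].sum(), 1)}
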