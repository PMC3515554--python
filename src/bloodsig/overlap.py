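"""Cross-cohort gene-list overlap significance and the generic 2x2 exact test.

The headline operation shuffles case/control labels independently in two
cohorts, recomputes both per-gene Welch screens, and counts how often the
number of genes significant in both cohorts reaches the observed overlap.
The permutation p-value is reported with the plain exceedances/n convention
(so 2 hits in 200,000 shuffles prints exactly 1e-5); the add-one variant is
available behind a flag for users who prefer a never-zero estimator.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ExpressionMatrix, ValidationError
from .diffstats import welch_t_matrix

logger = logging.getLogger("bloodsig")


def fisher_exact_2x2(table) -> tuple:
    """Two-sided Fisher exact test on a 2x2 count table.

    The two-sided p-value sums the hypergeometric point probabilities of all
    tables (with the observed margins) no more probable than the observed
    one — the probability-mass rule.  Returns ``(odds_ratio, p)`` with the
    sample odds ratio ad/bc.  A zero margin makes association untestable:
    p = 1 is returned with a warning.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValidationError("table must be 2x2")
    if (t < 0).any() or not np.issubdtype(t.dtype, np.integer):
        raise ValidationError("table entries must be nonnegative integers")
    if 0 in t.sum(axis=0) or 0 in t.sum(axis=1):
        warnings.warn("2x2 table has a zero margin; association is untestable",
                      stacklevel=2)
        a, b, c, d = t.ravel()
        odds = np.nan if b * c == 0 else a * d / (b * c)
        return float(odds), 1.0
    res = stats.fisher_exact(t, alternative="two-sided")
    return float(res[0]), float(min(res[1], 1.0))


def hypergeom_overlap_tail(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail overlap probability P(X >= k), X ~ Hypergeom(N, K, n).

    ``N`` is the universe size, ``K`` and ``n`` the two list sizes, ``k`` the
    observed intersection.  The tail is summed by the survival function of
    the hypergeometric distribution, which accumulates from the short end
    for numerical stability.
    """
    if not (0 <= k <= min(K, n) <= max(K, n) <= N):
        raise ValidationError(
            f"inconsistent counts: need 0 <= k <= min(K, n) <= N, "
            f"got N={N}, K={K}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class OverlapPermutationResult:
    observed_overlap: int
    exceedances: int
    n_perm: int
    p_value: float
    overlap_genes: list


def permutation_p(exceedances: int, n_perm: int, add_one: bool = False) -> float:
    """Permutation p-value from a (exceedances, n_perm) summary.

    The default r/n convention returns exactly ``exceedances / n_perm``
    (2 / 200,000 = 1e-5).  ``add_one=True`` gives the (r+1)/(n+1) estimator,
    which is never zero and is the strictly valid p-value when the observed
    statistic is counted among the permutations.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be at least 1")
    if not 0 <= exceedances <= n_perm:
        raise ValidationError("exceedances must lie in [0, n_perm]")
    if add_one:
        return (exceedances + 1) / (n_perm + 1)
    return exceedances / n_perm


def _significant_rows(y: np.ndarray, is_case: np.ndarray, alpha: float) -> np.ndarray:
    _, _, p = welch_t_matrix(y[:, is_case], y[:, ~is_case])
    return p < alpha


def overlap_permutation_test(x1: ExpressionMatrix, labels1,
                             x2: ExpressionMatrix, labels2,
                             alpha: float = 0.001, n_perm: int = 1000,
                             seed: int = 0,
                             add_one: bool = False) -> OverlapPermutationResult:
    """Label-shuffle null for the overlap of two cohorts' significant genes.

    Both matrices must share a feature space.  Each permutation shuffles
    case/control labels independently within each cohort, recomputes the two
    Welch screens at ``alpha``, and counts the intersection of significant
    feature sets; the p-value is the fraction of permutations with at least
    the observed overlap.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    if x1.feature_ids != x2.feature_ids:
        shared = [f for f in x1.feature_ids if f in set(x2.feature_ids)]
        if not shared:
            raise ValidationError("matrices share no features")
        x1 = x1.subset_features(shared)
        x2 = x2.subset_features(shared)
    l1 = np.asarray(labels1, dtype=bool)
    l2 = np.asarray(labels2, dtype=bool)
    y1, y2 = x1.log2(), x2.log2()
    sig1 = _significant_rows(y1, l1, alpha)
    sig2 = _significant_rows(y2, l2, alpha)
    observed = int((sig1 & sig2).sum())
    genes = [f for f, s in zip(x1.feature_ids, sig1 & sig2) if s]

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        p1 = rng.permutation(l1)
        p2 = rng.permutation(l2)
        ov = int((_significant_rows(y1, p1, alpha)
                  & _significant_rows(y2, p2, alpha)).sum())
        if ov >= observed:
            exceed += 1
    p = permutation_p(exceed, n_perm, add_one=add_one)
    logger.info("overlap %d genes; %d/%d permutations met or beat it (p=%g)",
                observed, exceed, n_perm, p)
    return OverlapPermutationResult(observed, exceed, n_perm, p, genes)
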