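"""Cross-platform harmonization, batch adjustment, expression filters, PCA.

All statistics here operate on the log2 scale; matrices enter and leave on
the positive linear intensity scale.  The batch adjustment is the parametric
empirical-Bayes location/scale model (normal prior on per-batch gene means,
inverse-gamma prior on per-batch gene variances, method-of-moments
hyperparameters, iterative joint solution) with the biological covariate of
interest protected in the standardization design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, PlatformMap, ValidationError

logger = logging.getLogger("bloodsig")


# ---------------------------------------------------------------------------
# Cross-platform collapse
# ---------------------------------------------------------------------------

def collapse_to_common_features(src: ExpressionMatrix, pmap: PlatformMap,
                                is_case: np.ndarray) -> ExpressionMatrix:
    """Collapse source probesets to the target (gene-level) feature space.

    Genes represented by two or more source probesets are retained only when
    every probeset's case-minus-control mean difference (log2 scale) shares
    one direction; discordant genes are dropped.  Retained genes take the
    median intensity across their probesets.  Features already on the target
    space pass through unchanged, which makes the operation idempotent.
    """
    is_case = np.asarray(is_case, dtype=bool)
    if is_case.shape[0] != src.shape[1]:
        raise ValidationError("case/control labels not aligned to samples")
    feat_index = {f: i for i, f in enumerate(src.feature_ids)}
    src_in = [f for f in pmap.source_ids if f in feat_index]
    target_set = set(pmap.target_ids)
    passthrough = [f for f in src.feature_ids if f in target_set]
    if not src_in and not passthrough:
        raise ValidationError("no overlap between matrix features and platform map")

    log2 = src.log2()
    diffs = log2[:, is_case].mean(axis=1) - log2[:, ~is_case].mean(axis=1)

    by_target = pmap.sources_for_target()
    rows, out_ids = [], []
    seen_targets = set()
    for f in passthrough:
        out_ids.append(f)
        rows.append(src.values[feat_index[f]])
        seen_targets.add(f)
    for tgt, sources in by_target.items():
        if tgt in seen_targets:
            continue
        present = [s for s in sources if s in feat_index]
        if not present:
            continue
        idx = [feat_index[s] for s in present]
        if len(idx) >= 2:
            d = diffs[idx]
            if not ((d >= 0).all() or (d <= 0).all()):
                continue  # probesets disagree on direction
        out_ids.append(tgt)
        rows.append(np.median(src.values[idx], axis=0))
    if not out_ids:
        raise ValidationError("no features survived the direction-consistency collapse")
    out = ExpressionMatrix(pd.DataFrame(
        np.vstack(rows), index=out_ids, columns=src.sample_ids))
    logger.info("collapsed %d source features to %d target features",
                len(src_in), len(out_ids))
    return out


# ---------------------------------------------------------------------------
# Empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------

@dataclass
class CombatModel:
    """Fitted empirical-Bayes batch model (log2 scale).

    ``gamma_star`` and ``delta2_star`` are the shrunken per-batch location and
    squared-scale adjustments (batches x genes); ``stand_mean`` is the
    per-gene, per-sample standardization mean (grand mean plus protected
    covariate contribution); ``var_pooled`` the per-gene pooled variance.
    """

    batch_levels: list
    sample_ids: list
    gamma_star: np.ndarray
    delta2_star: np.ndarray
    stand_mean: np.ndarray  # genes x samples
    var_pooled: np.ndarray
    gamma_bar: np.ndarray
    tau2: np.ndarray
    a_prior: np.ndarray
    b_prior: np.ndarray
    batch_of_sample: np.ndarray

    @property
    def is_identity(self) -> bool:
        return len(self.batch_levels) == 1


def _design_matrix(batches: np.ndarray, covariates) -> tuple:
    batches = np.asarray(batches).astype(str)
    levels = list(pd.unique(batches))
    B = np.column_stack([(batches == lev).astype(float) for lev in levels])
    cov_cols = []
    if covariates is not None:
        cov = pd.DataFrame(covariates).copy()
        for col in cov.columns:
            if cov[col].dtype.kind in "OUSb":
                dummies = pd.get_dummies(cov[col].astype(str), drop_first=True)
                for dcol in dummies.columns:
                    cov_cols.append(dummies[dcol].to_numpy(dtype=float))
            else:
                cov_cols.append(cov[col].to_numpy(dtype=float))
    X = np.column_stack([B] + [c[:, None] for c in cov_cols]) if cov_cols else B
    return X, B, levels, batches


def combat_fit(x: ExpressionMatrix, batches, covariates=None,
               eb_tol: float = 1e-6, eb_maxiter: int = 500) -> CombatModel:
    """Fit the parametric empirical-Bayes batch model.

    ``batches`` is a per-sample batch label vector; ``covariates`` an optional
    table of biological covariates (e.g. diagnosis) to protect during
    standardization.  Requires at least two samples per batch and a
    non-singular joint design (batch must not be perfectly confounded with a
    covariate column).
    """
    y = x.log2()
    g, n = y.shape
    X, B, levels, batches = _design_matrix(batches, covariates)
    n_per = B.sum(axis=0)
    if (n_per < 2).any():
        lev = levels[int(np.argmin(n_per))]
        raise ValidationError(f"batch {lev!r} has fewer than 2 samples")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError(
            "singular design: batch is confounded with a covariate column")

    if len(levels) == 1:
        zero = np.zeros((1, g))
        return CombatModel(levels, x.sample_ids, zero, np.ones((1, g)),
                           np.repeat(y.mean(axis=1)[:, None], n, axis=1),
                           y.var(axis=1, ddof=0) + 1e-300, np.zeros(1),
                           np.ones(1), np.ones(1), np.ones(1),
                           np.zeros(n, dtype=int))

    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)  # (k params) x genes
    nb = len(levels)
    grand = (n_per / n) @ beta[:nb, :]  # weighted grand mean per gene
    fitted = X @ beta
    var_pooled = ((y.T - fitted) ** 2).mean(axis=0)  # per gene, 1/n
    var_pooled = np.maximum(var_pooled, 1e-300)

    stand_mean = np.repeat(grand[None, :], n, axis=0)  # samples x genes
    if X.shape[1] > nb:
        Xcov = X.copy()
        Xcov[:, :nb] = 0.0
        stand_mean = stand_mean + Xcov @ beta
    z = (y.T - stand_mean) / np.sqrt(var_pooled)[None, :]  # samples x genes

    batch_of_sample = np.array([levels.index(b) for b in batches])
    gamma_hat = np.vstack([z[batch_of_sample == i].mean(axis=0) for i in range(nb)])
    delta2_hat = np.vstack([z[batch_of_sample == i].var(axis=0, ddof=1)
                            for i in range(nb)])

    gamma_bar = gamma_hat.mean(axis=1)
    tau2 = gamma_hat.var(axis=1, ddof=1)
    d_mean = delta2_hat.mean(axis=1)
    d_var = delta2_hat.var(axis=1, ddof=1)
    a_prior = (2 * d_var + d_mean ** 2) / d_var
    b_prior = (d_mean * d_var + d_mean ** 3) / d_var

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    for i in range(nb):
        zi = z[batch_of_sample == i]
        ni = zi.shape[0]
        g_old = gamma_hat[i].copy()
        d_old = delta2_hat[i].copy()
        for _ in range(eb_maxiter):
            g_new = (ni * tau2[i] * gamma_hat[i] + d_old * gamma_bar[i]) / (
                ni * tau2[i] + d_old)
            ssq = ((zi - g_new[None, :]) ** 2).sum(axis=0)
            d_new = (b_prior[i] + 0.5 * ssq) / (ni / 2 + a_prior[i] - 1)
            change = max(np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-30)),
                         np.max(np.abs(d_new - d_old) / d_old))
            g_old, d_old = g_new, d_new
            if change < eb_tol:
                break
        gamma_star[i], delta2_star[i] = g_old, d_old
    if (delta2_star <= 0).any():
        raise ValidationError("non-positive shrunken scale adjustment")

    return CombatModel(levels, x.sample_ids, gamma_star, delta2_star,
                       stand_mean.T, var_pooled, gamma_bar, tau2,
                       a_prior, b_prior, batch_of_sample)


def combat_apply(model: CombatModel, x: ExpressionMatrix) -> ExpressionMatrix:
    """Remove the fitted batch effects; returns a matrix on the linear scale."""
    if x.sample_ids != model.sample_ids:
        raise ValidationError("matrix samples differ from the ones the model was fit on")
    y = x.log2()
    if model.is_identity:
        return x
    z = (y - model.stand_mean) / np.sqrt(model.var_pooled)[:, None]
    for i in range(len(model.batch_levels)):
        cols = model.batch_of_sample == i
        z[:, cols] = ((z[:, cols] - model.gamma_star[i][:, None])
                      / np.sqrt(model.delta2_star[i])[:, None])
    adj = z * np.sqrt(model.var_pooled)[:, None] + model.stand_mean
    return ExpressionMatrix.from_log2(adj, x.feature_ids, x.sample_ids)


def combat_adjust(x: ExpressionMatrix, batches, covariates=None) -> ExpressionMatrix:
    """Convenience fit-and-apply on one matrix."""
    return combat_apply(combat_fit(x, batches, covariates), x)


# ---------------------------------------------------------------------------
# Expression filters
# ---------------------------------------------------------------------------

def expression_floor_filter(x: ExpressionMatrix, floor: float,
                            mode: str = "min") -> list:
    """Features passing an intensity floor on the linear scale.

    ``mode="min"`` keeps genes whose minimum across samples is at least the
    floor; ``mode="mean"`` keeps genes whose mean exceeds it.
    """
    if floor <= 0:
        raise ValidationError("floor must be positive")
    v = x.values
    if mode == "min":
        keep = v.min(axis=1) >= floor
    elif mode == "mean":
        keep = v.mean(axis=1) > floor
    else:
        raise ValidationError(f"unknown floor mode {mode!r}")
    return [f for f, k in zip(x.feature_ids, keep) if k]


def fold_change_filter(de: pd.DataFrame, min_fc: float) -> list:
    """Features with direction-agnostic fold change above ``min_fc``.

    Fold changes are case/control ratios of linear-scale means; a gene at
    fc = 0.5 is kept at threshold 1.5 because its reciprocal is 2.0.
    """
    fc = de["fold_change"].to_numpy(dtype=float)
    sym = np.maximum(fc, 1.0 / fc)
    return [f for f, s in zip(de.index, sym) if s > min_fc]


# ---------------------------------------------------------------------------
# PCA projection
# ---------------------------------------------------------------------------

def pca_project(x: ExpressionMatrix, cohorts=None, center: bool = True,
                scale: bool = True, n_components: int = 2):
    """Project samples onto principal components of the log2 expression.

    Centering and scaling are applied within each cohort before the combined
    projection, so platform-level location/scale differences do not dominate
    the leading components.  Constant genes are dropped (with a warning) when
    scaling is requested.  Returns ``(coords, explained_variance_ratio)``
    where coords is a samples x n_components DataFrame and the ratio covers
    the full spectrum.
    """
    if x.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    y = x.log2().T  # samples x genes
    cohorts = (np.zeros(y.shape[0], dtype=int) if cohorts is None
               else np.asarray(cohorts))
    feature_ids = np.array(x.feature_ids)
    if scale:
        drop = np.zeros(y.shape[1], dtype=bool)
        for c in pd.unique(cohorts):
            drop |= y[cohorts == c].std(axis=0) == 0
        if drop.any():
            logger.warning("dropping %d constant gene(s) before scaled PCA",
                           int(drop.sum()))
            y = y[:, ~drop]
            feature_ids = feature_ids[~drop]
    for c in pd.unique(cohorts):
        rows = cohorts == c
        block = y[rows]
        if center:
            block = block - block.mean(axis=0)
        if scale:
            block = block / block.std(axis=0)
        y[rows] = block
    _, s, vt = np.linalg.svd(y, full_matrices=False)
    evr = s ** 2 / (s ** 2).sum()
    k = min(n_components, len(s))
    coords = pd.DataFrame(
        y @ vt[:k].T, index=x.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)])
    return coords, evr
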