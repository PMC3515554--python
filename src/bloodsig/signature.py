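"""Expression-signature classifier: AUC ranking, PLS, nested LGOCV, nulls.

The classifier is partial least squares regression (NIPALS, single response)
on a 0/1 diagnosis code.  Model size is chosen by a stability criterion:
genes are ranked by per-gene AUC, the top-N sweep is evaluated with repeated
stratified 80/20 leave-group-out splits (an inner layer of identical splits
tunes the PLS component count), and the N whose outer AUC distribution has
the smallest coefficient of variation wins.  A random-gene-set null puts the
selected signature's held-out AUC in context.

Two ranking modes exist.  The default ranks genes once on the full training
cohort, which mirrors the protocol this pipeline reproduces but leaks the
ranking into the outer estimates; ``rank_in_fold=True`` re-ranks inside each
outer training split and is the honest-performance mode recommended for new
analyses (see docs/methods.md).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .core import ExpressionMatrix, ValidationError
from .diffstats import gene_aucs

logger = logging.getLogger("bloodsig")


# ---------------------------------------------------------------------------
# Per-gene AUC ranking
# ---------------------------------------------------------------------------

def gene_auc_rank(x: ExpressionMatrix, is_case) -> pd.DataFrame:
    """Rank genes by discriminative AUC (direction-agnostic).

    AUC is the Mann-Whitney statistic scaled to [0, 1] with half credit for
    ties; ranking is by max(auc, 1 - auc) descending, ties broken by feature
    ID so the order is reproducible.
    """
    is_case = np.asarray(is_case, dtype=bool)
    auc = gene_aucs(x.log2(), is_case)
    df = pd.DataFrame({"auc": auc, "folded_auc": np.maximum(auc, 1 - auc)},
                      index=x.feature_ids)
    df = df.sort_values(["folded_auc"], ascending=False, kind="mergesort")
    # mergesort on a single key keeps lexicographic index order within ties
    df = df.iloc[np.lexsort((df.index, -df["folded_auc"].to_numpy()))]
    df["rank"] = np.arange(1, len(df) + 1)
    return df


# ---------------------------------------------------------------------------
# NIPALS PLS1
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """A fitted single-response PLS model on standardized predictors."""

    feature_ids: list
    mean_x: np.ndarray
    scale_x: np.ndarray
    mean_y: float
    weights: np.ndarray    # p x A
    loadings: np.ndarray   # p x A
    q: np.ndarray          # A response loadings
    scores: np.ndarray     # n x A training scores
    n_components: int
    coef: np.ndarray       # p regression vector for n_components

    def coef_for(self, a: int) -> np.ndarray:
        ptw = self.loadings.T @ self.weights
        return self.weights[:, :a] @ np.linalg.solve(ptw[:a, :a], self.q[:a])


def _standardize_train(x: np.ndarray):
    mean = x.mean(axis=0)
    scale = x.std(axis=0, ddof=1)
    keep = scale > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance gene(s) "
                      "from the PLS training matrix", stacklevel=3)
    return mean, scale, keep


def pls_fit(x: np.ndarray, y01, n_components: int,
            feature_ids=None) -> PLSModel:
    """Fit NIPALS PLS1 on samples-x-genes data against a 0/1 class code.

    Predictors are centered and unit-scaled by training statistics; the
    response is centered.  Zero-variance genes are dropped with a warning.
    Raises if the class code is constant or the requested number of
    components exceeds what the data can support.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y01, dtype=float)
    n, p = x.shape
    if np.ptp(y) == 0:
        raise ValidationError("class code is constant; nothing to fit")
    if n_components < 1:
        raise ValidationError("need at least one PLS component")
    if n_components > min(n - 1, p):
        raise ValidationError(
            f"A={n_components} exceeds the data rank bound min(n-1, p)="
            f"{min(n - 1, p)}")
    mean, scale, keep = _standardize_train(x)
    ids = list(feature_ids) if feature_ids is not None else list(range(p))
    ids = [i for i, k in zip(ids, keep) if k]
    xs = (x[:, keep] - mean[keep]) / scale[keep]
    yc = y - y.mean()

    pk = xs.shape[1]
    a_max = min(n_components, pk)
    W = np.zeros((pk, a_max))
    P = np.zeros((pk, a_max))
    T = np.zeros((n, a_max))
    q = np.zeros(a_max)
    Xd, yd = xs.copy(), yc.copy()
    for a in range(a_max):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            a_max = a
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            a_max = a
            break
        pl = Xd.T @ t / tt
        qa = yd @ t / tt
        Xd = Xd - np.outer(t, pl)
        yd = yd - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pl, t, qa
    if a_max == 0:
        raise ValidationError("no informative PLS component could be extracted")
    W, P, T, q = W[:, :a_max], P[:, :a_max], T[:, :a_max], q[:a_max]
    model = PLSModel(feature_ids=ids, mean_x=mean[keep], scale_x=scale[keep],
                     mean_y=float(y.mean()), weights=W, loadings=P, q=q,
                     scores=T, n_components=a_max, coef=np.zeros(pk))
    model.coef = model.coef_for(a_max)
    return model


def pls_predict(model: PLSModel, x: np.ndarray, n_components=None) -> np.ndarray:
    """Continuous class score for new samples (class call at score >= 0.5)."""
    x = np.asarray(x, dtype=float)
    xs = (x - model.mean_x) / model.scale_x
    coef = (model.coef if n_components is None
            else model.coef_for(min(n_components, model.n_components)))
    return model.mean_y + xs @ coef


def _auc(scores: np.ndarray, is_case: np.ndarray) -> float:
    r = stats.rankdata(scores)
    n1 = int(is_case.sum())
    n2 = len(scores) - n1
    return float((r[is_case].sum() - n1 * (n1 + 1) / 2) / (n1 * n2))


def _pls_test_aucs_by_components(x_tr, y_tr, x_te, y_te, a_max: int) -> np.ndarray:
    """Test AUC for every component count 1..a_max from a single NIPALS fit."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = pls_fit(x_tr, y_tr, a_max)
    xs = (x_te - model.mean_x) / model.scale_x
    ptw = model.loadings.T @ model.weights
    out = np.full(a_max, np.nan)
    for a in range(1, model.n_components + 1):
        coef = model.weights[:, :a] @ np.linalg.solve(ptw[:a, :a], model.q[:a])
        out[a - 1] = _auc(model.mean_y + xs @ coef, y_te.astype(bool))
    if model.n_components < a_max:
        out[model.n_components:] = out[model.n_components - 1]
    return out


# ---------------------------------------------------------------------------
# Stratified leave-group-out splits
# ---------------------------------------------------------------------------

def _stratified_split(is_case: np.ndarray, frac: float,
                      rng: np.random.Generator):
    """One stratified train/test split preserving the class proportion."""
    train, test = [], []
    for cls in (True, False):
        idx = np.where(is_case == cls)[0]
        rng.shuffle(idx)
        n_test = max(1, int(round((1 - frac) * idx.size)))
        test.extend(idx[:n_test])
        train.extend(idx[n_test:])
    return np.array(sorted(train)), np.array(sorted(test))


def _valid_split(is_case, frac, rng, max_redraws: int = 100):
    for _ in range(max_redraws):
        tr, te = _stratified_split(is_case, frac, rng)
        if 0 < is_case[te].sum() < te.size and 0 < is_case[tr].sum() < tr.size:
            return tr, te
        logger.info("redrawing a split with a single-class subset")
    raise ValidationError("could not draw a two-class split; check class sizes")


# ---------------------------------------------------------------------------
# Nested repeated LGOCV with stability model-size selection
# ---------------------------------------------------------------------------

@dataclass
class CVReport:
    sizes: np.ndarray
    outer_aucs: np.ndarray          # n_sizes x outer
    mean_auc: np.ndarray
    cv_of_auc: np.ndarray           # sd/mean per size
    selected_n: int
    selected_genes: list
    chosen_components: np.ndarray   # n_sizes x outer
    ranking: pd.DataFrame
    seed: int
    rank_in_fold: bool
    outer: int
    inner: int
    frac: float

    def to_dict(self) -> dict:
        return {
            "sizes": self.sizes.tolist(),
            "mean_auc": np.round(self.mean_auc, 6).tolist(),
            "cv_of_auc": np.round(self.cv_of_auc, 6).tolist(),
            "selected_n": int(self.selected_n),
            "selected_genes": list(self.selected_genes),
            "seed": int(self.seed),
            "rank_in_fold": bool(self.rank_in_fold),
            "outer": int(self.outer),
            "inner": int(self.inner),
            "frac": float(self.frac),
        }


def nested_lgocv(x: ExpressionMatrix, is_case, sweep=(10, 390, 5),
                 outer: int = 100, inner: int = 100, frac: float = 0.8,
                 component_grid=range(1, 11), seed: int = 0,
                 rank_in_fold: bool = False) -> CVReport:
    """Nested repeated stratified 80/20 cross-validation over a top-N sweep.

    For each candidate size N, the same ``outer`` stratified splits are
    evaluated: an inner layer of ``inner`` stratified splits of the outer
    training set picks the PLS component count maximizing mean inner test
    AUC, the model is refit on the outer training set, and the outer test
    AUC is recorded.  The selected N minimizes the coefficient of variation
    (sd/mean) of the outer AUCs, ties going to the smaller N.  With the
    default protocol the gene ranking is computed once on the full cohort;
    ``rank_in_fold=True`` re-ranks within each outer training split instead.
    """
    is_case = np.asarray(is_case, dtype=bool)
    lo, hi, step = sweep
    sizes = np.arange(lo, hi + 1, step)
    if sizes.size == 0 or sizes[0] < 1:
        raise ValidationError("empty or invalid model-size sweep")
    if sizes[-1] > x.shape[0]:
        raise ValidationError(
            f"sweep upper bound {sizes[-1]} exceeds the {x.shape[0]} available genes")
    if not 0 < frac < 1:
        raise ValidationError("train fraction must lie in (0, 1)")
    grid = list(component_grid)
    a_cap = max(grid)

    y_all = x.log2().T  # samples x genes
    ranking = gene_auc_rank(x, is_case)
    feat_pos = {f: i for i, f in enumerate(x.feature_ids)}

    rng = np.random.default_rng(seed)
    splits = [_valid_split(is_case, frac, rng) for _ in range(outer)]
    inner_seeds = rng.integers(2 ** 31, size=outer)

    fold_rankings = []
    if rank_in_fold:
        for tr, _ in splits:
            sub = ExpressionMatrix(x.frame.iloc[:, tr])
            fold_rankings.append(gene_auc_rank(sub, is_case[tr]))

    outer_aucs = np.zeros((sizes.size, outer))
    chosen = np.zeros((sizes.size, outer), dtype=int)
    for si, n_genes in enumerate(sizes):
        for oi, (tr, te) in enumerate(splits):
            rank_src = fold_rankings[oi] if rank_in_fold else ranking
            cols = [feat_pos[f] for f in rank_src.index[:n_genes]]
            xg = y_all[:, cols]
            a_max = min(a_cap, len(tr) - 1, n_genes)
            irng = np.random.default_rng(inner_seeds[oi])
            inner_mat = np.zeros((inner, a_max))
            for ii in range(inner):
                itr, ite = _valid_split(is_case[tr], frac, irng)
                inner_mat[ii] = _pls_test_aucs_by_components(
                    xg[tr][itr], is_case[tr][itr].astype(float),
                    xg[tr][ite], is_case[tr][ite].astype(float), a_max)
            grid_here = [a for a in grid if a <= a_max]
            mean_inner = np.nanmean(inner_mat, axis=0)
            best_a = grid_here[int(np.argmax(mean_inner[[a - 1 for a in grid_here]]))]
            chosen[si, oi] = best_a
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = pls_fit(xg[tr], is_case[tr].astype(float), best_a)
            scores = pls_predict(model, xg[te])
            outer_aucs[si, oi] = _auc(scores, is_case[te])
        logger.info("sweep N=%d: mean outer AUC %.3f", n_genes,
                    outer_aucs[si].mean())

    mean_auc = outer_aucs.mean(axis=1)
    sd = outer_aucs.std(axis=1, ddof=1)
    cv = np.where(mean_auc > 0, sd / mean_auc, np.inf)
    selected_idx = int(np.argmin(cv))  # argmin takes the first (smallest N) on ties
    selected_n = int(sizes[selected_idx])
    selected_genes = list(ranking.index[:selected_n])
    return CVReport(sizes=sizes, outer_aucs=outer_aucs, mean_auc=mean_auc,
                    cv_of_auc=cv, selected_n=selected_n,
                    selected_genes=selected_genes, chosen_components=chosen,
                    ranking=ranking, seed=seed, rank_in_fold=rank_in_fold,
                    outer=outer, inner=inner, frac=frac)


def compare_model_sizes(auc_a, auc_b) -> float:
    """One-sided Welch t-test that model B's AUCs exceed model A's.

    Both vectors must come from the same outer split sequence and have equal
    length.  Identical vectors give p = 0.5.
    """
    a = np.asarray(auc_a, dtype=float)
    b = np.asarray(auc_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("AUC vectors differ in length")
    if np.array_equal(a, b):
        return 0.5
    res = stats.ttest_ind(b, a, equal_var=False, alternative="greater")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Random-gene-set null benchmark
# ---------------------------------------------------------------------------

def random_geneset_null(x_train: ExpressionMatrix, labels_train,
                        x_test: ExpressionMatrix, labels_test,
                        observed_auc: float, k: int = 55,
                        n_draws: int = 2000, n_components: int = 3,
                        seed: int = 0) -> dict:
    """Held-out AUC distribution of randomly drawn k-gene PLS signatures.

    Each draw samples k genes uniformly from the training matrix, fits the
    PLS classifier on the training cohort, and scores the test cohort; the
    permutation p is the fraction of draws with AUC at least the observed
    signature's.  Features of the two matrices must align.
    """
    if k > x_train.shape[0]:
        raise ValidationError(f"k={k} exceeds the {x_train.shape[0]} available genes")
    shared = [f for f in x_train.feature_ids if f in set(x_test.feature_ids)]
    if len(shared) < k:
        raise ValidationError("too few shared features between train and test")
    xtr = x_train.subset_features(shared)
    xte = x_test.subset_features(shared)
    ytr = np.asarray(labels_train, dtype=bool)
    yte = np.asarray(labels_test, dtype=bool)
    tr_log, te_log = xtr.log2().T, xte.log2().T
    rng = np.random.default_rng(seed)
    null_aucs = np.empty(n_draws)
    for d in range(n_draws):
        cols = rng.choice(len(shared), size=k, replace=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = pls_fit(tr_log[:, cols], ytr.astype(float),
                            min(n_components, k, len(ytr) - 1))
        null_aucs[d] = _auc(pls_predict(model, te_log[:, cols]), yte)
    p = float((null_aucs >= observed_auc).mean())
    return {"null_aucs": null_aucs, "observed_auc": float(observed_auc),
            "p_value": p, "n_draws": n_draws, "k": k}


# ---------------------------------------------------------------------------
# Performance metrics with DeLong AUC confidence interval
# ---------------------------------------------------------------------------

@dataclass
class PerfMetrics:
    auc: float
    auc_ci: tuple
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    balanced_accuracy: float
    threshold: float
    confusion: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: (round(v, 6) if isinstance(v, float) else v)
             for k, v in self.__dict__.items() if k != "auc_ci"}
        d["auc_ci"] = [round(self.auc_ci[0], 6), round(self.auc_ci[1], 6)]
        return d


def _delong_auc_ci(scores: np.ndarray, is_case: np.ndarray,
                   level: float = 0.95) -> tuple:
    """DeLong variance of the empirical AUC via placement values."""
    pos = scores[is_case]
    neg = scores[~is_case]
    m, n = pos.size, neg.size
    # placement of each positive among negatives and vice versa (midranks)
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    auc = v10.mean()
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    z = stats.norm.ppf(0.5 + level / 2)
    return (float(np.clip(auc - z * se, 0, 1)), float(np.clip(auc + z * se, 0, 1)))


def evaluate(scores, labels, threshold: float = 0.5) -> PerfMetrics:
    """Confusion-matrix metrics at a threshold plus AUC with a DeLong CI.

    ``labels`` is the boolean case indicator.  Accuracy is
    (TP + TN) / N; balanced accuracy the mean of sensitivity and
    specificity, which equals 0.5 for any predictor that ignores the input.
    """
    scores = np.asarray(scores, dtype=float)
    is_case = np.asarray(labels, dtype=bool)
    if is_case.all() or not is_case.any():
        raise ValidationError("both classes required; AUC undefined otherwise")
    calls = scores >= threshold
    tp = int((calls & is_case).sum())
    tn = int((~calls & ~is_case).sum())
    fp = int((calls & ~is_case).sum())
    fn = int((~calls & is_case).sum())
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return PerfMetrics(
        auc=_auc(scores, is_case),
        auc_ci=_delong_auc_ci(scores, is_case),
        accuracy=(tp + tn) / len(scores),
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        balanced_accuracy=(sens + spec) / 2,
        threshold=threshold,
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    )


# ---------------------------------------------------------------------------
# Fisher linear discriminant and hierarchical clustering views
# ---------------------------------------------------------------------------

def fisher_lda_score(x: ExpressionMatrix, is_case, genes=None,
                     ridge: float = 1e-8) -> pd.Series:
    """Per-sample Fisher linear discriminant score on the given genes.

    w is proportional to S_w^{-1} (mu_case - mu_control) with the pooled
    within-class scatter S_w; a small ridge (scaled by the mean diagonal) is
    added when S_w is singular.  Scores are oriented so cases sit higher.
    """
    is_case = np.asarray(is_case, dtype=bool)
    sub = x if genes is None else x.subset_features(genes)
    y = sub.log2().T
    mu1 = y[is_case].mean(axis=0)
    mu0 = y[~is_case].mean(axis=0)
    d1 = y[is_case] - mu1
    d0 = y[~is_case] - mu0
    sw = d1.T @ d1 + d0.T @ d0
    try:
        w = np.linalg.solve(sw, mu1 - mu0)
    except np.linalg.LinAlgError:
        lam = ridge * np.trace(sw) / sw.shape[0]
        w = np.linalg.solve(sw + lam * np.eye(sw.shape[0]), mu1 - mu0)
    scores = y @ w
    if scores[is_case].mean() < scores[~is_case].mean():
        scores = -scores
    return pd.Series(scores, index=sub.sample_ids, name="lda_score")


def hcluster_heatmap(x: ExpressionMatrix, genes=None, linkage: str = "average",
                     metric: str = "correlation", n_clusters: int = 2,
                     standardize: bool = True) -> dict:
    """Agglomerative clustering of samples for a heatmap-style display.

    Genes are z-scored first (the heatmap convention — otherwise absolute
    baseline expression dominates every between-sample correlation), then
    samples are clustered on 1 - Pearson correlation with average linkage.
    Returns the scipy linkage matrix, the deterministic dendrogram leaf
    order, and a flat ``n_clusters``-way cut.
    """
    sub = x if genes is None else x.subset_features(genes)
    if sub.shape[1] < 2:
        raise ValidationError("clustering needs at least 2 samples")
    y = sub.log2().T
    if standardize:
        sd = y.std(axis=0)
        keep = sd > 0
        y = (y[:, keep] - y[:, keep].mean(axis=0)) / sd[keep]
    d = pdist(y, metric=metric)
    z = hierarchy.linkage(d, method=linkage)
    order = hierarchy.leaves_list(z)
    labels = hierarchy.fcluster(z, t=n_clusters, criterion="maxclust")
    return {"linkage": z,
            "order": [sub.sample_ids[i] for i in order],
            "clusters": dict(zip(sub.sample_ids, labels.tolist()))}
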