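"""Gene-set over-representation by EASE score and kappa clustering of hits.

The EASE score is the conservative variant of the one-tailed Fisher exact
over-representation p-value: one gene is removed from the list-and-set
(hit) cell before the test, which penalizes sets supported by very few
genes (a single-hit set scores p = 1).  Enriched sets are then grouped by
the chance-corrected agreement (Cohen's kappa) of their gene-membership
vectors, with a greedy seed-and-merge rule that allows one set to belong
to more than one final cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GeneSetCollection, ValidationError


def _fisher_one_tailed(hits: int, list_size: int, set_size: int,
                       background_size: int) -> float:
    # over-representation tail: P(X >= hits), X ~ Hypergeom(bg, set, list)
    if hits <= 0:
        return 1.0
    return float(stats.hypergeom.sf(hits - 1, background_size, set_size, list_size))


def ease_score(gene_list, gene_set, background) -> tuple:
    """EASE and Fisher over-representation p-values for one set.

    Both the list and the set are intersected with the background before
    counting.  Returns ``(ease_p, fisher_p, counts)`` where counts is a dict
    with hits / list_size / set_size / background_size.  The EASE p decrements
    the hit cell by one, so it is always at least the Fisher p.
    """
    background = frozenset(background)
    gene_list = frozenset(gene_list)
    gene_set = frozenset(gene_set)
    if not gene_list or not gene_set:
        raise ValidationError("gene list and gene set must be nonempty")
    stray = gene_list - background
    if stray:
        raise ValidationError(
            f"list genes outside the background: {sorted(stray)[:5]}")
    gene_set = gene_set & background
    hits = len(gene_list & gene_set)
    counts = {
        "hits": hits,
        "list_size": len(gene_list),
        "set_size": len(gene_set),
        "background_size": len(background),
    }
    fisher_p = _fisher_one_tailed(hits, len(gene_list), len(gene_set), len(background))
    ease_p = _fisher_one_tailed(hits - 1, len(gene_list), len(gene_set), len(background))
    return ease_p, fisher_p, counts


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum(np.minimum.accumulate(adj[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def enrich_all(gene_list, collection: GeneSetCollection, alpha: float = 0.05,
               min_hits: int = 3) -> pd.DataFrame:
    """EASE over-representation of every set in the collection.

    Sets with fewer than ``min_hits`` list genes are skipped (the EASE
    decrement makes 1- and 2-hit sets uninformative).  BH adjustment runs
    across the tested sets; rows are sorted by EASE p.  The ``enriched``
    column marks sets with EASE p below ``alpha``.
    """
    gene_list = frozenset(gene_list)
    rows = []
    for name in collection.names:
        members = collection[name]
        hits = gene_list & members
        if len(hits) < min_hits:
            continue
        ease_p, fisher_p, counts = ease_score(gene_list, members,
                                              collection.background)
        rows.append({
            "set": name,
            "hits": counts["hits"],
            "list_size": counts["list_size"],
            "set_size": counts["set_size"],
            "background_size": counts["background_size"],
            "ease_p": ease_p,
            "fisher_p": fisher_p,
            "members": ",".join(sorted(hits)),
        })
    if not rows:
        return pd.DataFrame(columns=[
            "set", "hits", "list_size", "set_size", "background_size",
            "ease_p", "fisher_p", "fdr", "enriched", "members"]).set_index("set")
    df = pd.DataFrame(rows).set_index("set")
    df["fdr"] = bh_adjust(df["ease_p"].to_numpy())
    df["enriched"] = df["ease_p"] < alpha
    return df.sort_values(["ease_p", "fdr"]).loc[
        :, ["hits", "list_size", "set_size", "background_size",
            "ease_p", "fisher_p", "fdr", "enriched", "members"]]


# ---------------------------------------------------------------------------
# Cohen's kappa clustering of enriched sets
# ---------------------------------------------------------------------------

def cohen_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Chance-corrected agreement of two binary membership vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("membership vectors differ in length")
    n = a.size
    po = (a == b).mean()
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)


@dataclass
class KappaClusters:
    clusters: list       # list of sorted lists of set names (may overlap)
    unclustered: list    # singleton sets
    kappa: pd.DataFrame  # pairwise kappa matrix


def kappa_cluster(memberships: pd.DataFrame, kappa_threshold: float = 0.5,
                  merge_fraction: float = 0.5) -> KappaClusters:
    """Group sets by the kappa agreement of their gene-membership vectors.

    ``memberships`` is a sets x genes 0/1 frame (typically: enriched sets
    over the union of list genes hit by any of them).  Each set seeds a
    candidate cluster containing every set whose kappa with it exceeds the
    threshold; candidates sharing more than ``merge_fraction`` of their
    members are merged.  A set may appear in several final clusters, and
    sets with no partner above threshold are reported unclustered.  Output
    is deterministic and invariant to the input row order.
    """
    if not 0 < kappa_threshold < 1:
        raise ValidationError("kappa threshold must lie in (0, 1)")
    names = sorted(memberships.index)
    mat = memberships.loc[names].to_numpy(dtype=bool)
    k = len(names)
    kap = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            kap[i, j] = kap[j, i] = cohen_kappa(mat[i], mat[j])
    kappa_df = pd.DataFrame(kap, index=names, columns=names)

    candidates = []
    for i in range(k):
        members = frozenset(j for j in range(k)
                            if j == i or kap[i, j] > kappa_threshold)
        if len(members) > 1:
            candidates.append(members)
    candidates = sorted(set(candidates), key=lambda s: sorted(s))

    merged = True
    while merged:
        merged = False
        out: list[frozenset] = []
        for cand in candidates:
            for idx, existing in enumerate(out):
                inter = len(cand & existing)
                if (inter > merge_fraction * len(cand)
                        or inter > merge_fraction * len(existing)):
                    out[idx] = existing | cand
                    merged = True
                    break
            else:
                out.append(cand)
        candidates = sorted(set(out), key=lambda s: sorted(s))

    clusters = [sorted(names[j] for j in c) for c in candidates]
    clustered = set().union(*candidates) if candidates else set()
    unclustered = [names[j] for j in range(k) if j not in clustered]
    return KappaClusters(clusters=clusters, unclustered=unclustered,
                         kappa=kappa_df)


def membership_matrix(enrichment: pd.DataFrame) -> pd.DataFrame:
    """Sets x genes 0/1 membership over the union of hit genes (DAVID-style)."""
    hit_lists = {name: set(row["members"].split(","))
                 for name, row in enrichment.iterrows() if row["members"]}
    universe = sorted(set().union(*hit_lists.values())) if hit_lists else []
    return pd.DataFrame(
        [[g in hit_lists[name] for g in universe] for name in hit_lists],
        index=list(hit_lists), columns=universe, dtype=int)
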