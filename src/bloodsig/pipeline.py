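"""End-to-end orchestration of the analysis stages on one run directory.

A run is configured by a YAML file (or an equivalent dict) with a mandatory
global seed and an optional block per stage.  Stage seeds are derived
deterministically from the global seed and the stage name, so any stage can
be re-run in isolation and the whole run is bit-reproducible for a fixed
config.  Stage outputs are plain TSV/JSON files under a run directory, and
a manifest records the config hash, seeds, package version, and per-stage
wall time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    ExpressionMatrix,
    ValidationError,
    write_expression,
    write_gmt,
    write_phenotype,
    write_platform_map,
)
from .diffstats import de_table
from .enrich import enrich_all, kappa_cluster, membership_matrix
from .overlap import hypergeom_overlap_tail, overlap_permutation_test
from .preprocess import collapse_to_common_features, combat_adjust, expression_floor_filter
from .signature import (
    evaluate,
    nested_lgocv,
    pls_fit,
    pls_predict,
    random_geneset_null,
)
from .subgroup import mcd_robust_distance, outlier_rate_test, quadrant_assign
from .synthdata import CLUSTER1_SET, CLUSTER2_SET, SimConfig, simulate

logger = logging.getLogger("bloodsig")

STAGES = ("simulate", "preprocess", "de", "overlap", "enrich", "subgroup",
          "train", "evaluate")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


DEFAULTS = {
    "simulate": {},
    "preprocess": {"floor": 150.0, "combat": True},
    "de": {"alpha": 0.001},
    "overlap": {"n_perm": 200, "alpha": 0.001},
    "enrich": {"alpha": 0.05, "kappa": 0.5},
    "subgroup": {"quantile": 0.975},
    "train": {"sweep": [10, 80, 10], "outer": 20, "inner": 10, "frac": 0.8,
              "rank_in_fold": False, "null_draws": 100},
    "evaluate": {"threshold": 0.5},
}


def _merge(stage: str, config: dict) -> dict:
    out = dict(DEFAULTS[stage])
    out.update(config.get(stage, {}) or {})
    return out


def validate_config(config: dict) -> None:
    """Fail fast on inconsistent configuration, before any compute."""
    if "seed" not in config:
        raise ValidationError("config must set a global seed")
    sim = SimConfig(**(config.get("simulate", {}) or {}),
                    seed=int(config["seed"]))
    sim.validate()
    train = _merge("train", config)
    lo, hi, step = train["sweep"]
    if hi > sim.n_genes:
        raise ValidationError(
            f"train.sweep upper bound {hi} exceeds the {sim.n_genes} simulated genes")
    if lo < 1 or step < 1 or hi < lo:
        raise ValidationError("train.sweep must be (low, high, step) with low>=1")


def run_pipeline(config, out_dir) -> dict:
    """Run all stages on a simulated study; returns the manifest dict.

    ``config`` is a dict or a path to a YAML file.  The run directory gets
    one report per stage plus the simulated input bundle and a manifest.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    validate_config(config)
    seed = int(config["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()).hexdigest(),
        "stage_seconds": {},
        "stage_seeds": {s: stage_seed(seed, s) for s in STAGES},
    }
    clock = [time.time()]

    def tick(stage):
        now = time.time()
        manifest["stage_seconds"][stage] = round(now - clock[0], 3)
        clock[0] = now

    # --- simulate -----------------------------------------------------------
    sim_cfg = SimConfig(**(config.get("simulate", {}) or {}),
                        seed=stage_seed(seed, "simulate"))
    x1, x2, samples, pmap, gene_sets, truth = simulate(sim_cfg)
    write_expression(x1, out / "cohort1_expression.tsv")
    write_expression(x2, out / "cohort2_expression.tsv")
    write_phenotype(samples, out / "phenotype.csv")
    write_platform_map(pmap, out / "platform_map.tsv")
    write_gmt(gene_sets, out / "gene_sets.gmt")
    truth.to_json(out / "sim_truth.json")
    tick("simulate")

    p1_ids = [s for s in samples.sample_ids
              if samples.frame.loc[s, "cohort"] == "P1like"]
    p2_ids = [s for s in samples.sample_ids
              if samples.frame.loc[s, "cohort"] == "P2like"]
    case1 = samples.is_case(p1_ids)
    case2 = samples.is_case(p2_ids)

    # --- preprocess ---------------------------------------------------------
    pp = _merge("preprocess", config)
    c1 = collapse_to_common_features(x1, pmap, case1)
    c2 = collapse_to_common_features(x2, pmap, case2)
    shared = [f for f in c1.feature_ids if f in set(c2.feature_ids)]
    c1, c2 = c1.subset_features(shared), c2.subset_features(shared)
    if pp["combat"]:
        c1 = combat_adjust(c1, samples.column("batch", p1_ids),
                           {"diagnosis": samples.column("diagnosis", p1_ids)})
        c2 = combat_adjust(c2, samples.column("batch", p2_ids),
                           {"diagnosis": samples.column("diagnosis", p2_ids)})
    write_expression(c1, out / "cohort1_collapsed.tsv")
    write_expression(c2, out / "cohort2_collapsed.tsv")
    floored = expression_floor_filter(c1, pp["floor"], mode="min")
    with open(out / "preprocess_report.json", "w") as fh:
        json.dump({"collapsed_features": len(shared),
                   "floor": pp["floor"],
                   "features_above_floor": len(floored),
                   "combat": bool(pp["combat"])}, fh, indent=1)
    tick("preprocess")

    # --- differential expression -------------------------------------------
    de_cfg = _merge("de", config)
    de1 = de_table(c1, case1, alpha=de_cfg["alpha"])
    de2 = de_table(c2, case2, alpha=de_cfg["alpha"])
    de1.to_csv(out / "de_cohort1.tsv", sep="\t")
    de2.to_csv(out / "de_cohort2.tsv", sep="\t")
    sig1 = list(de1.index[de1["significant"]])
    sig2 = list(de2.index[de2["significant"]])
    tick("de")

    # --- cross-cohort overlap ----------------------------------------------
    ov_cfg = _merge("overlap", config)
    ov = overlap_permutation_test(
        c1, case1, c2, case2, alpha=ov_cfg["alpha"],
        n_perm=ov_cfg["n_perm"], seed=stage_seed(seed, "overlap"))
    hyper_p = hypergeom_overlap_tail(len(shared), len(sig1), len(sig2),
                                     ov.observed_overlap)
    with open(out / "overlap_report.json", "w") as fh:
        json.dump({"significant_cohort1": len(sig1),
                   "significant_cohort2": len(sig2),
                   "observed_overlap": ov.observed_overlap,
                   "exceedances": ov.exceedances,
                   "n_perm": ov.n_perm,
                   "permutation_p": ov.p_value,
                   "hypergeometric_p": hyper_p,
                   "universe": len(shared),
                   "overlap_genes": ov.overlap_genes}, fh, indent=1)
    tick("overlap")

    # --- enrichment + kappa clustering --------------------------------------
    en_cfg = _merge("enrich", config)
    gene_list = [g for g in sig1 if g in gene_sets.background]
    enr = enrich_all(gene_list, gene_sets, alpha=en_cfg["alpha"])
    enr.to_csv(out / "enrichment.tsv", sep="\t")
    enriched = enr[enr["enriched"]]
    clusters = None
    if len(enriched) >= 2:
        clusters = kappa_cluster(membership_matrix(enriched),
                                 kappa_threshold=en_cfg["kappa"])
    with open(out / "enrich_report.json", "w") as fh:
        json.dump({"n_tested": len(enr),
                   "n_enriched": int(enr["enriched"].sum()),
                   "top_set": enr.index[0] if len(enr) else None,
                   "clusters": clusters.clusters if clusters else [],
                   "unclustered": clusters.unclustered if clusters else []},
                  fh, indent=1)
    tick("enrich")

    # --- subgroup discovery --------------------------------------------------
    sg_cfg = _merge("subgroup", config)
    sg_seed = stage_seed(seed, "subgroup")
    res = {}
    for axis, set_name in (("rd1", CLUSTER1_SET), ("rd2", CLUSTER2_SET)):
        genes = [g for g in gene_sets[set_name] if g in set(c1.feature_ids)]
        res[axis] = mcd_robust_distance(
            c1.subset_features(sorted(genes)).log2().T, seed=sg_seed)
    quad = quadrant_assign(res["rd1"].rd, res["rd2"].rd,
                           res["rd1"].df, res["rd2"].df,
                           q=sg_cfg["quantile"], sample_ids=p1_ids)
    quad.to_csv(out / "subgroup_distances.tsv", sep="\t")
    test2 = outlier_rate_test(quad["outlier2"].to_numpy(), case1)
    test1 = outlier_rate_test(quad["outlier1"].to_numpy(), case1)
    with open(out / "subgroup_report.json", "w") as fh:
        json.dump({"quadrant_counts": quad["quadrant"].value_counts().to_dict(),
                   "cluster1_outlier_test": test1,
                   "cluster2_outlier_test": test2,
                   "pca_fallback": {a: res[a].used_pca for a in res},
                   "df": {a: res[a].df for a in res}}, fh, indent=1)
    tick("subgroup")

    # --- signature training ---------------------------------------------------
    tr_cfg = _merge("train", config)
    lo, hi, step = tr_cfg["sweep"]
    candidates = [g for g in sig1 if g in set(floored)]
    if len(candidates) < lo:
        # under-powered screen: fall back to every floor-passing gene and
        # let the AUC ranking inside the sweep do the selection
        logger.warning("only %d genes passed the DE screen; sweeping over "
                       "all %d floor-passing genes instead",
                       len(candidates), len(floored))
        candidates = list(floored)
    hi = min(hi, len(candidates))
    if hi < lo:
        raise ValidationError(
            f"only {len(candidates)} candidate genes available; "
            f"sweep starts at {lo}")
    xc = c1.subset_features(candidates)
    report = nested_lgocv(xc, case1, sweep=(lo, hi, step),
                          outer=tr_cfg["outer"], inner=tr_cfg["inner"],
                          frac=tr_cfg["frac"],
                          seed=stage_seed(seed, "train"),
                          rank_in_fold=tr_cfg["rank_in_fold"])
    with open(out / "cv_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1)
    tick("train")

    # --- held-out evaluation + random-signature null -------------------------
    ev_cfg = _merge("evaluate", config)
    sel = report.selected_genes
    si = int(np.where(report.sizes == report.selected_n)[0][0])
    a_star = int(np.bincount(report.chosen_components[si]).argmax())
    model = pls_fit(c1.subset_features(sel).log2().T, case1.astype(float),
                    max(a_star, 1), feature_ids=sel)
    scores = pls_predict(model, c2.subset_features(sel).log2().T)
    perf = evaluate(scores, case2, threshold=ev_cfg["threshold"])
    null = random_geneset_null(
        xc, case1, c2.subset_features(candidates), case2,
        observed_auc=perf.auc, k=report.selected_n,
        n_draws=tr_cfg["null_draws"], seed=stage_seed(seed, "nullbench"))
    pd.DataFrame({"sample_id": p2_ids, "score": scores,
                  "is_case": case2}).to_csv(
        out / "heldout_scores.tsv", sep="\t", index=False)
    with open(out / "evaluate_report.json", "w") as fh:
        json.dump({"selected_n": report.selected_n,
                   "components": a_star,
                   "heldout": perf.to_dict(),
                   "null_p": null["p_value"],
                   "null_auc_mean": float(np.mean(null["null_aucs"])),
                   "null_draws": null["n_draws"]}, fh, indent=1)
    tick("evaluate")

    manifest["stages"] = list(STAGES)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
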