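"""Two-cohort synthetic expression data with the structure the analysis assumes.

The generator emulates a two-cohort blood expression study: a first cohort
profiled on an older array whose genes are represented by one to three source
probesets, and a second cohort profiled on a newer array on the collapsed
(gene-level) feature space, linked by a many-to-one probeset map.  Planted
structure includes differential-signal genes (additive case effect on the
log2 scale, in units of each gene's own standard deviation), batch
location/scale shifts, near-binary sex-dimorphic genes, age-sloped genes,
and case subgroups perturbed in one, both, or neither of two designated
pathway gene clusters.  Ground truth is returned alongside the data so every
downstream stage can be tested for recovery without any external download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import (
    ExpressionMatrix,
    GeneSetCollection,
    PlatformMap,
    SampleTable,
    ValidationError,
)

CLUSTER1_SET = "CLUSTER1"
CLUSTER2_SET = "CLUSTER2"


@dataclass
class SimConfig:
    """Parameters of the synthetic two-cohort study.

    Defaults are desk scale: 2,000 genes and the real study's cohort sizes
    (66 cases / 33 controls in the training-like cohort, 104 / 82 in the
    validation-like cohort), two batches per cohort, and a case effect of
    one within-gene standard deviation on the log2 scale.
    """

    n_genes: int = 2000
    cohort1_cases: int = 66
    cohort1_controls: int = 33
    cohort2_cases: int = 104
    cohort2_controls: int = 82
    n_signal_genes: int = 55
    effect_size: float = 1.0  # delta, in per-gene log2-sd units
    # per-gene baseline hyper-ranges (log2 scale)
    log2_mean_range: tuple = (5.0, 12.0)
    log2_sd_range: tuple = (0.3, 0.8)
    # batch structure (per cohort)
    n_batches: int = 2
    batch_shift_sd: float = 0.3  # log2 location shift magnitude per batch
    batch_scale_range: tuple = (0.8, 1.25)  # multiplier on within-batch deviations
    # covariate-dependent genes
    n_sex_genes: int = 5
    n_age_genes: int = 30
    age_slope_range: tuple = (0.02, 0.06)  # log2 units per year
    female_extra_sd: float = 0.0  # optional extra noise sd for female samples
    # sex composition: cohort 1 is all male; cohort 2 mixes in females
    cohort2_female_case_frac: float = 0.23
    cohort2_female_control_frac: float = 0.41
    age_range: tuple = (4.0, 13.0)
    # platform map: fraction of genes carried by 2-3 source probesets
    multi_probe_frac: float = 0.3
    probe_noise_sd: float = 0.1  # per-probe log2 noise
    # pathway structure
    n_sets: int = 15
    set_size_range: tuple = (10, 40)
    signal_in_clusters_frac: float = 0.8
    # case subgroups: fractions perturbed in cluster1 only / cluster2 only / both
    frac_cluster1_only: float = 0.15
    frac_cluster2_only: float = 0.10
    frac_both: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_genes,
            self.cohort1_cases,
            self.cohort1_controls,
            self.cohort2_cases,
            self.cohort2_controls,
        )
        if any(c <= 0 for c in counts):
            raise ValidationError("all gene and cohort counts must be positive")
        if self.n_signal_genes > self.n_genes:
            raise ValidationError("n_signal_genes exceeds n_genes")
        if self.effect_size < 0:
            raise ValidationError("effect size must be nonnegative")
        fracs = (self.frac_cluster1_only, self.frac_cluster2_only, self.frac_both)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValidationError("subgroup fractions must lie in [0, 1]")
        if sum(fracs) > 1 + 1e-12:
            raise ValidationError("subgroup fractions sum to more than 1")
        for name in ("multi_probe_frac", "signal_in_clusters_frac"):
            v = getattr(self, name)
            if v < 0 or v > 1:
                raise ValidationError(f"{name} must lie in [0, 1]")


@dataclass
class SimTruth:
    """Planted ground truth: which genes and samples carry which structure."""

    signal_genes: list
    cluster1_signal_genes: list
    cluster2_signal_genes: list
    sex_genes: list
    age_genes: list
    subgroup: dict  # sample_id -> cluster1_only | cluster2_only | both | neither | control
    batches: dict  # sample_id -> batch label

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def _subgroup_labels(n_cases: int, cfg: SimConfig, rng: np.random.Generator):
    labels = np.array(["neither"] * n_cases, dtype=object)
    order = rng.permutation(n_cases)
    n1 = int(round(cfg.frac_cluster1_only * n_cases))
    n2 = int(round(cfg.frac_cluster2_only * n_cases))
    nb = int(round(cfg.frac_both * n_cases))
    labels[order[:n1]] = "cluster1_only"
    labels[order[n1:n1 + n2]] = "cluster2_only"
    labels[order[n1 + n2:n1 + n2 + nb]] = "both"
    return labels


def simulate(config: SimConfig):
    """Draw one synthetic study.

    Returns ``(x1, x2, samples, platform_map, gene_sets, truth)``: the two
    cohort expression matrices on the linear scale (cohort 1 on the source
    probeset space, cohort 2 on the gene-level target space), the combined
    phenotype table, the many-to-one probeset map, the pathway collection,
    and the planted truth.  Identical config and seed give bit-identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    genes = [f"G{i:05d}" for i in range(g)]

    base_mean = rng.uniform(*config.log2_mean_range, size=g)
    base_sd = rng.uniform(*config.log2_sd_range, size=g)

    # gene roles (disjoint by construction: draw signal, sex, age genes apart)
    perm = rng.permutation(g)
    signal_idx = perm[: config.n_signal_genes]
    sex_idx = perm[config.n_signal_genes: config.n_signal_genes + config.n_sex_genes]
    age_idx = perm[
        config.n_signal_genes + config.n_sex_genes:
        config.n_signal_genes + config.n_sex_genes + config.n_age_genes
    ]
    age_slopes = rng.uniform(*config.age_slope_range, size=len(age_idx))
    age_slopes *= rng.choice([-1.0, 1.0], size=len(age_idx))

    # split the in-cluster share of signal genes between the two cluster sets
    n_in_clusters = int(round(config.signal_in_clusters_frac * len(signal_idx)))
    in_cluster = signal_idx[:n_in_clusters]
    half = (len(in_cluster) + 1) // 2
    c1_sig, c2_sig = in_cluster[:half], in_cluster[half:]

    gene_sets, background = _make_gene_sets(config, rng, genes, c1_sig, c2_sig)
    pmap = _make_platform_map(config, rng, genes)

    rows = []
    truth_subgroup: dict[str, str] = {}
    truth_batches: dict[str, str] = {}
    mats = {}
    for cohort, n_cases, n_ctrl in (
        ("P1like", config.cohort1_cases, config.cohort1_controls),
        ("P2like", config.cohort2_cases, config.cohort2_controls),
    ):
        n = n_cases + n_ctrl
        tag = "p1" if cohort == "P1like" else "p2"
        sample_ids = [f"{tag}_s{i:03d}" for i in range(n)]
        is_case = np.array([True] * n_cases + [False] * n_ctrl)
        age = rng.uniform(*config.age_range, size=n)
        if cohort == "P1like":
            sex = np.array(["male"] * n)
        else:
            sex = np.array(["male"] * n, dtype=object)
            f_case = rng.random(n_cases) < config.cohort2_female_case_frac
            f_ctrl = rng.random(n_ctrl) < config.cohort2_female_control_frac
            sex[np.concatenate([f_case, f_ctrl])] = "female"
        subtypes = np.where(
            is_case, rng.choice(["AUT", "PDDNOS", "ASP"], size=n, p=[0.45, 0.4, 0.15]),
            "none",
        )
        batch = rng.integers(config.n_batches, size=n)
        batch_labels = np.array([f"{tag}_b{b}" for b in batch], dtype=object)

        sub = np.array(["control"] * n, dtype=object)
        sub[:n_cases] = _subgroup_labels(n_cases, config, rng)

        # log2-scale expression: baseline + planted effects + noise
        z = rng.standard_normal((g, n))
        if config.female_extra_sd > 0:
            z[:, sex == "female"] += config.female_extra_sd * rng.standard_normal(
                (g, int((sex == "female").sum()))
            )
        y = base_mean[:, None] + base_sd[:, None] * z

        delta = config.effect_size * base_sd
        hit1 = np.isin(sub, ["cluster1_only", "both"])
        hit2 = np.isin(sub, ["cluster2_only", "both"])
        hit_any = sub != "control"
        hit_any &= sub != "neither"
        y[np.ix_(c1_sig, np.where(hit1)[0])] += delta[c1_sig, None]
        y[np.ix_(c2_sig, np.where(hit2)[0])] += delta[c2_sig, None]
        out_cluster = signal_idx[n_in_clusters:]
        y[np.ix_(out_cluster, np.where(hit_any)[0])] += delta[out_cluster, None]

        # sex genes: near-binary male-high expression (XIST/UTY-like behavior)
        y[np.ix_(sex_idx, np.where(sex == "female")[0])] -= 4.0
        # age genes: linear trend around the cohort mean age
        y[age_idx, :] += age_slopes[:, None] * (age - age.mean())[None, :]

        # batch effects: per-batch location shift and deviation rescaling (log2)
        shifts = rng.normal(0.0, config.batch_shift_sd, size=config.n_batches)
        scales = rng.uniform(*config.batch_scale_range, size=config.n_batches)
        for b in range(config.n_batches):
            cols = np.where(batch == b)[0]
            if cols.size == 0:
                continue
            dev = y[:, cols] - base_mean[:, None]
            y[:, cols] = base_mean[:, None] + scales[b] * dev + shifts[b]

        if cohort == "P1like":
            mats[cohort] = _to_source_space(config, rng, y, genes, pmap, sample_ids)
        else:
            y = y + config.probe_noise_sd * rng.standard_normal(y.shape)
            mats[cohort] = ExpressionMatrix.from_log2(y, genes, sample_ids)

        for i, sid in enumerate(sample_ids):
            truth_subgroup[sid] = str(sub[i])
            truth_batches[sid] = str(batch_labels[i])
        rows.append(pd.DataFrame({
            "sample_id": sample_ids,
            "diagnosis": np.where(is_case, "case", "control"),
            "subtype": subtypes,
            "sex": sex,
            "age_years": np.round(age, 2),
            "batch": batch_labels,
            "cohort": cohort,
        }))

    samples = SampleTable(pd.concat(rows, ignore_index=True))
    truth = SimTruth(
        signal_genes=[genes[i] for i in signal_idx],
        cluster1_signal_genes=[genes[i] for i in c1_sig],
        cluster2_signal_genes=[genes[i] for i in c2_sig],
        sex_genes=[genes[i] for i in sex_idx],
        age_genes=[genes[i] for i in age_idx],
        subgroup=truth_subgroup,
        batches=truth_batches,
    )
    return mats["P1like"], mats["P2like"], samples, pmap, gene_sets, truth


def _make_platform_map(config: SimConfig, rng: np.random.Generator, genes):
    multi = rng.random(len(genes)) < config.multi_probe_frac
    n_probes = np.where(multi, rng.integers(2, 4, size=len(genes)), 1)
    rec = []
    for gi, gene in enumerate(genes):
        for p in range(n_probes[gi]):
            rec.append((f"src_{gene}_{chr(97 + p)}", gene, gene))
    return PlatformMap(pd.DataFrame(
        rec, columns=["source_probeset", "target_probeset", "gene_symbol"]
    ))


def _to_source_space(config, rng, y_log2, genes, pmap: PlatformMap,
                     sample_ids) -> ExpressionMatrix:
    """Expand gene-level log2 values to source probesets with per-probe noise."""
    gene_pos = {gene: i for i, gene in enumerate(genes)}
    src_ids = pmap.records["source_probeset"].to_numpy()
    tgt = pmap.records["target_probeset"].to_numpy()
    rows = np.array([gene_pos[t] for t in tgt])
    offsets = rng.uniform(-0.3, 0.3, size=len(src_ids))  # fixed per-probe affinity
    noise = config.probe_noise_sd * rng.standard_normal((len(src_ids), y_log2.shape[1]))
    probe_log2 = y_log2[rows, :] + offsets[:, None] + noise
    return ExpressionMatrix.from_log2(probe_log2, list(src_ids), sample_ids)


def _make_gene_sets(config, rng, genes, c1_sig, c2_sig):
    """Pathway collection: two designated cluster sets plus random filler sets."""
    background = frozenset(genes)
    lo, hi = config.set_size_range
    sets: dict[str, frozenset] = {}
    descriptions: dict[str, str] = {}
    used = set(c1_sig) | set(c2_sig)
    free = [i for i in range(len(genes)) if i not in used]
    for name, sig in ((CLUSTER1_SET, c1_sig), (CLUSTER2_SET, c2_sig)):
        size = max(int(rng.integers(lo, hi + 1)), len(sig))
        filler = rng.choice(free, size=size - len(sig), replace=False)
        sets[name] = frozenset(genes[i] for i in np.concatenate([sig, filler]))
        descriptions[name] = f"designated signal cluster ({name.lower()})"
    for k in range(config.n_sets - 2):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        name = f"SET{k:03d}"
        sets[name] = frozenset(genes[i] for i in members)
        descriptions[name] = "random filler pathway"
    return GeneSetCollection(background=background, sets=sets,
                             descriptions=descriptions), background


# ---------------------------------------------------------------------------
# Worked fixtures: contingency tables and permutation summaries used by the
# acceptance checks, packaged as plain JSON-serializable data.
# ---------------------------------------------------------------------------

def make_worked_fixtures() -> dict:
    """In-text worked examples: 2x2 tables and the overlap permutation summary.

    ``synaptic_outlier_table`` counts pathway-outlier vs non-outlier samples
    among 66 cases and 33 controls; ``sex_by_diagnosis_table`` counts males
    vs females among the validation cohort's cases and controls;
    ``overlap_permutation`` records 2 exceedances out of 200,000 label
    shuffles for the cross-cohort overlap of significant genes.
    """
    return {
        "synaptic_outlier_table": [[23, 43], [4, 29]],
        "sex_by_diagnosis_table": [[80, 24], [48, 34]],
        "overlap_permutation": {"exceedances": 2, "n_perm": 200000},
    }


def write_worked_fixtures(path) -> dict:
    bundle = make_worked_fixtures()
    with open(path, "w") as fh:
        json.dump(bundle, fh, indent=1)
    return bundle
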