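import numpy as np
import pandas as pd
import pytest

from bloodsig.core import ExpressionMatrix
from bloodsig.synthdata import SimConfig, simulate


def expr_matrix(values, genes=None, samples=None) -> ExpressionMatrix:
    """Build a small linear-scale matrix from a 2-D array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def expr_from_log2(log2_values, genes=None, samples=None) -> ExpressionMatrix:
    log2_values = np.asarray(log2_values, dtype=float)
    genes = genes or [f"g{i}" for i in range(log2_values.shape[0])]
    samples = samples or [f"s{i}" for i in range(log2_values.shape[1])]
    return ExpressionMatrix.from_log2(log2_values, genes, samples)


def gaussian_matrix(rng, n_genes, n_samples, mean_range=(6.0, 10.0),
                    sd=0.5) -> ExpressionMatrix:
    """Null log2-normal expression with per-gene baselines."""
    base = rng.uniform(*mean_range, size=n_genes)
    y = base[:, None] + sd * rng.standard_normal((n_genes, n_samples))
    return expr_from_log2(y, samples=[f"s{i}" for i in range(n_samples)])


def planted_config(seed, effect_size=1.0, **kw) -> SimConfig:
    """Study config with the case effect planted in every case sample.

    Used by recovery tests that state a per-gene effect size: the planted
    differential signal is carried by all cases (no subgroup dilution), and
    batch structure is off unless the test asks for it.
    """
    defaults = dict(frac_both=1.0, frac_cluster1_only=0.0,
                    frac_cluster2_only=0.0, n_batches=1, batch_shift_sd=0.0,
                    batch_scale_range=(1.0, 1.0))
    defaults.update(kw)
    return SimConfig(seed=seed, effect_size=effect_size, **defaults)


@pytest.fixture(scope="session")
def small_study():
    """One desk-scale simulated two-cohort study, shared across tests."""
    cfg = SimConfig(n_genes=600, seed=7)
    x1, x2, samples, pmap, sets, truth = simulate(cfg)
    p1 = [s for s in samples.sample_ids if s.startswith("p1")]
    p2 = [s for s in samples.sample_ids if s.startswith("p2")]
    return {
        "config": cfg, "x1": x1, "x2": x2, "samples": samples,
        "pmap": pmap, "sets": sets, "truth": truth,
        "p1_ids": p1, "p2_ids": p2,
        "case1": samples.is_case(p1), "case2": samples.is_case(p2),
    }
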