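"""Desk-scale reproduction of the benchmark summary statistics.

These helpers regenerate the two headline benchmark numbers — the adjusted
R^2 of estimated vs true delta_psi, and the median per-instance MAE of the
delta_M estimates — from a single seed, at a batch size of 50 instances
drawn from one seeded synthetic pool (200 taxa, 100 pool samples). The
quantities reported here do not depend on per-taxon p-values, so the
pipeline runs with the asymptotic Mann-Whitney option for speed; the
estimator itself is identical.
"""

from __future__ import annotations

import numpy as np

from .benchmark import run_benchmark, synth_pool
from .da_test import QmdConfig

POOL_N_TAXA = 200
POOL_N_SAMPLES = 100
N_INSTANCES = 50

_FAST_CONFIG = QmdConfig(test="asymptotic")


def _pool_and_seeds(seed):
    ss = np.random.SeedSequence(seed)
    pool_seed, reg_seed, mae_seed = ss.spawn(3)
    pool = synth_pool(POOL_N_TAXA, POOL_N_SAMPLES, seed=pool_seed)
    return pool, reg_seed, mae_seed


def delta_psi_regression(seed, n_instances: int = N_INSTANCES) -> dict:
    """Regress estimated on true delta_psi over a seeded instance batch.

    Returns the OLS summary dict (slope, intercept, r2, adj_r2, n) for the
    benchmark's default draws (per-group n ~ U(6,100), DA proportion
    ~ U(0.05,0.95), effects ~ U(-10,10)).
    """
    pool, reg_seed, _ = _pool_and_seeds(seed)
    result = run_benchmark(pool, n_instances, seed=reg_seed,
                           methods=("qmd",), config=_FAST_CONFIG)
    return result.regression


def quantification_error(seed, n_instances: int = N_INSTANCES) -> dict:
    """Median per-instance MAE of the delta_M estimates, DA proportion <= 0.90.

    Returns ``{"median_mae": ..., "n": ...}`` over a seeded batch whose DA
    proportion is drawn from U(0.05, 0.90).
    """
    pool, _, mae_seed = _pool_and_seeds(seed)
    result = run_benchmark(pool, n_instances, seed=mae_seed,
                           methods=("qmd",), config=_FAST_CONFIG,
                           prop_range=(0.05, 0.90))
    q = result.metrics[result.metrics["method"] == "qmd"]
    return {"median_mae": float(q["mae"].median()), "n": int(len(q))}
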