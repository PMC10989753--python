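"""Simulation benchmark: pool-based instance generation, evaluation metrics, baselines.

An instance generator turns a pool of relative-abundance profiles into
artificial two-group absolute-abundance data: each resampled sample j gets a
total load Psi_j drawn uniformly, absolute abundances a_ij = Psi_j * o_ij, a
random subset of taxa (proportion ~ U(5%, 95%)) has its treatment absolute
abundances multiplied by 2^{c_i} with c_i ~ U(-10, 10), and the observed
treatment relative abundances are re-normalized from the perturbed data.
Per-group sample sizes are drawn from U(6, 100). The perturbation itself
shifts the treatment totals, so the true delta_psi is nonzero and varies
across instances.

Ground truth mirrors the estimator's conventions: the true delta_psi is the
difference of group means of log2 total load, and each taxon's true delta_M
is the difference of group means of log2 absolute abundance over detected
samples, so the mean absolute error measures estimation error rather than
convention mismatch.

Evaluation: MAE = (1/n) sum_i |delta_M_hat_i - delta_M_i| for quantification
accuracy, and FNR/FPR from the 2x2 decision table of predicted vs truly
perturbed taxa for identification power. Two baselines are included: RAC
(the log2 relative-abundance change itself as the delta_M estimate) and MWU
(the Mann-Whitney U test applied directly to logged relative abundances,
i.e. the shifted test with delta_psi forced to 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import core
from .da_test import QmdConfig, bh_adjust, run_qmd_rel, per_taxon_tests
from .data_io import CONTROL, TREATMENT, ParseError, RelAbundanceTable

logger = logging.getLogger(__name__)

DEFAULT_PSI_RANGE = (1e10, 1e11)
DEFAULT_N_RANGE = (6, 100)
DEFAULT_PROP_RANGE = (0.05, 0.95)
DEFAULT_EFFECT_RANGE = (-10.0, 10.0)


@dataclass(frozen=True)
class AbundancePool:
    """Pool of relative-abundance profiles (taxa x pool samples) to resample from."""

    profiles: pd.DataFrame
    provenance: str = "unspecified"

    def __post_init__(self) -> None:
        vals = self.profiles.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ParseError("pool profiles must be non-negative")
        if not np.allclose(vals.sum(axis=0), 1.0, atol=1e-9):
            raise ParseError("pool profile columns must sum to 1")

    @property
    def n_taxa(self) -> int:
        return self.profiles.shape[0]


@dataclass(frozen=True)
class SimulationInstance:
    """One synthetic two-group instance with full ground truth attached."""

    rel: RelAbundanceTable
    psi: pd.Series  # per-sample total load after perturbation
    abs_abund: pd.DataFrame  # a_ij after perturbation (taxa x samples)
    abs_abund_pre: pd.DataFrame  # a_ij before perturbation
    perturbed_set: frozenset[str]
    effects: pd.Series  # log2 effect c_i per perturbed taxon
    true_delta_psi: float
    true_delta_M: pd.Series  # NaN where a group has no detected sample
    n_per_group: int
    prop_da: float
    seed_record: object = field(compare=False, default=None)


def synth_pool(
    n_taxa: int = 200,
    n_pool_samples: int = 100,
    sparsity: float = 0.3,
    dispersion: float = 1.0,
    base_sigma: float = 3.0,
    seed=None,
    max_retries: int = 10,
) -> AbundancePool:
    """Generate a synthetic abundance pool with log-normal taxon profiles.

    Each taxon has a log-normal base abundance (between-taxon spread
    ``base_sigma``, in natural-log units) jittered per sample by
    ``dispersion``; within each pool sample the lowest ``sparsity`` fraction
    of entries falls below the detection floor and is zeroed, then columns
    are renormalized. Fully reproducible from ``seed``.
    """
    if n_taxa < 2 or n_pool_samples < 2:
        raise ValueError("need at least 2 taxa and 2 pool samples")
    if not 0 <= sparsity < 1:
        raise ValueError("sparsity must be in [0, 1)")
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        mu = rng.normal(0.0, base_sigma, size=n_taxa)
        vals = np.exp(mu[:, None] + rng.normal(0.0, dispersion, size=(n_taxa, n_pool_samples)))
        if sparsity > 0:
            floor = np.quantile(vals, sparsity, axis=0, keepdims=True)
            vals = np.where(vals < floor, 0.0, vals)
        totals = vals.sum(axis=0)
        if (totals > 0).all():
            vals = vals / totals
            taxa = [f"taxon_{i:04d}" for i in range(n_taxa)]
            samples = [f"pool_{j:04d}" for j in range(n_pool_samples)]
            return AbundancePool(
                profiles=pd.DataFrame(vals, index=taxa, columns=samples),
                provenance=(
                    f"synthetic(n_taxa={n_taxa}, n_pool_samples={n_pool_samples}, "
                    f"sparsity={sparsity}, dispersion={dispersion}, base_sigma={base_sigma})"
                ),
            )
    raise RuntimeError("could not generate a pool without all-zero samples")


def load_pool(path) -> AbundancePool:
    """Read a user-supplied pool TSV (counts or proportions, taxa in rows).

    Proportions are detected by column sums approximately 1; counts are
    normalized per column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    vals = df.to_numpy(dtype=float)
    sums = vals.sum(axis=0)
    if (sums <= 0).any():
        raise ParseError("pool file contains an all-zero sample column")
    if not np.allclose(sums, 1.0, atol=1e-6):
        df = df / sums
    return AbundancePool(profiles=df.astype(float), provenance=str(path))


def _mean_log2_detected(matrix: np.ndarray) -> np.ndarray:
    """Row means of log2 over strictly positive entries; NaN for all-zero rows."""
    with np.errstate(divide="ignore"):
        logs = np.where(matrix > 0, np.log2(np.where(matrix > 0, matrix, 1.0)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(logs, axis=1)


def simulate_instance(
    pool: AbundancePool,
    seed=None,
    *,
    n_per_group: int | None = None,
    prop_da: float | None = None,
    perturbed_taxa=None,
    effects=None,
    psi_T=None,
    psi_C=None,
    sample_idx_T=None,
    sample_idx_C=None,
    psi_range=DEFAULT_PSI_RANGE,
    n_range=DEFAULT_N_RANGE,
    prop_range=DEFAULT_PROP_RANGE,
    effect_range=DEFAULT_EFFECT_RANGE,
    group_offset_log2: float | tuple[float, float] = 0.0,
) -> SimulationInstance:
    """Draw one two-group instance from a pool, recording complete ground truth.

    All keyword overrides pin individual draws (sample size, DA proportion,
    perturbed taxon set, effects, per-sample loads, resampled pool columns)
    for hand-checkable instances; unset quantities are drawn from the
    configured uniform ranges. ``group_offset_log2`` multiplies every
    treatment load by 2**offset, injecting a deliberate total-load change on
    top of what the taxon perturbations induce (a (lo, hi) tuple draws the
    offset uniformly per instance).
    """
    rng = np.random.default_rng(seed)
    if isinstance(group_offset_log2, (tuple, list)):
        group_offset_log2 = float(rng.uniform(*group_offset_log2))
    n_taxa = pool.n_taxa
    if n_per_group is None:
        n_per_group = int(rng.integers(n_range[0], n_range[1] + 1))
    if n_per_group < 3:
        raise ValueError("need at least 3 samples per group")

    npool = pool.profiles.shape[1]
    idx_T = (np.asarray(sample_idx_T) if sample_idx_T is not None
             else rng.integers(0, npool, size=n_per_group))
    idx_C = (np.asarray(sample_idx_C) if sample_idx_C is not None
             else rng.integers(0, npool, size=n_per_group))
    o_T = pool.profiles.to_numpy(dtype=float)[:, idx_T]
    o_C = pool.profiles.to_numpy(dtype=float)[:, idx_C]

    psi_T = (np.asarray(psi_T, dtype=float) if psi_T is not None
             else rng.uniform(*psi_range, size=len(idx_T)))
    psi_C = (np.asarray(psi_C, dtype=float) if psi_C is not None
             else rng.uniform(*psi_range, size=len(idx_C)))
    psi_T = psi_T * 2.0 ** group_offset_log2

    a_C = psi_C * o_C
    a_T_pre = psi_T * o_T

    if prop_da is None:
        prop_da = float(rng.uniform(*prop_range))
    taxa = np.array(pool.profiles.index)
    if perturbed_taxa is None:
        k = int(np.ceil(prop_da * n_taxa))
        perturbed_idx = rng.choice(n_taxa, size=k, replace=False) if k else np.array([], dtype=int)
    else:
        pos = {t: i for i, t in enumerate(taxa)}
        perturbed_idx = np.array([pos[t] for t in perturbed_taxa], dtype=int)
        prop_da = len(perturbed_idx) / n_taxa
    if effects is None:
        c = rng.uniform(*effect_range, size=len(perturbed_idx))
    else:
        c = np.asarray(effects, dtype=float)
        if len(c) != len(perturbed_idx):
            raise ValueError("effects length must match the perturbed taxon set")

    a_T = a_T_pre.copy()
    a_T[perturbed_idx, :] *= 2.0 ** c[:, None]

    psi_T_true = a_T.sum(axis=0)
    psi_C_true = a_C.sum(axis=0)
    o_T_obs = a_T / psi_T_true
    true_delta_psi = float(np.mean(np.log2(psi_T_true)) - np.mean(np.log2(psi_C_true)))
    true_delta_M = pd.Series(
        _mean_log2_detected(a_T) - _mean_log2_detected(a_C), index=taxa, name="true_delta_M"
    )

    samples_T = [f"T{j + 1:03d}" for j in range(n_per_group)]
    samples_C = [f"C{j + 1:03d}" for j in range(n_per_group)]
    rel = RelAbundanceTable(
        rel=pd.DataFrame(
            np.hstack([o_T_obs, o_C]), index=taxa, columns=samples_T + samples_C
        ),
        group_of={**{s: TREATMENT for s in samples_T}, **{s: CONTROL for s in samples_C}},
    )
    columns = samples_T + samples_C
    return SimulationInstance(
        rel=rel,
        psi=pd.Series(np.concatenate([psi_T_true, psi_C_true]), index=columns, name="psi"),
        abs_abund=pd.DataFrame(np.hstack([a_T, a_C]), index=taxa, columns=columns),
        abs_abund_pre=pd.DataFrame(np.hstack([a_T_pre, a_C]), index=taxa, columns=columns),
        perturbed_set=frozenset(taxa[perturbed_idx]),
        effects=pd.Series(c, index=taxa[perturbed_idx], name="log2_effect"),
        true_delta_psi=true_delta_psi,
        true_delta_M=true_delta_M,
        n_per_group=n_per_group,
        prop_da=float(prop_da),
        seed_record=seed,
    )


def mae(estimated: pd.Series, truth: pd.Series) -> float:
    """Mean absolute error (1/n) sum |delta_M_hat - delta_M| over taxa defined in both."""
    joined = pd.concat([estimated.rename("est"), truth.rename("truth")], axis=1, join="inner")
    joined = joined.dropna()
    if joined.empty:
        raise ValueError("no taxa with both an estimate and a defined truth")
    return float((joined["est"] - joined["truth"]).abs().mean())


@dataclass(frozen=True)
class EvalMetrics:
    """2x2 decision-table counts and the derived FNR/FPR."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def fnr(self) -> float | None:
        return self.fn / (self.tp + self.fn) if (self.tp + self.fn) else None

    @property
    def fpr(self) -> float | None:
        return self.fp / (self.fp + self.tn) if (self.fp + self.tn) else None


def confusion_metrics(predicted, truth, evaluated) -> EvalMetrics:
    """Fill the decision table for a predicted DA set against the truly perturbed set.

    Both sets must be subsets of ``evaluated``, the taxa the method actually
    assessed (taxa lost to filtering are not counted against any method).
    """
    evaluated = set(evaluated)
    predicted = set(predicted)
    truth = set(truth)
    if not predicted <= evaluated or not truth <= evaluated:
        raise ValueError("predicted and true sets must be subsets of the evaluated taxa")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(evaluated) - tp - fp - fn
    return EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def baseline_rac(rel: RelAbundanceTable) -> pd.Series:
    """Relative-abundance-change baseline: d_i itself as the delta_M estimate."""
    summaries = core.taxon_log_changes(rel)
    out = summaries.set_index("taxon_id")["d"].rename("delta_M_rac")
    return out


def baseline_mwu(rel: RelAbundanceTable, config: QmdConfig = QmdConfig()) -> pd.DataFrame:
    """Unshifted Mann-Whitney U baseline: the shifted test with delta_psi forced to 0."""
    tests = per_taxon_tests(rel, 0.0, config)
    testable = tests["testable"].to_numpy()
    crit = tests["p_value"].to_numpy()
    tests["significant"] = pd.array(np.where(testable, crit < config.alpha, None),
                                    dtype="boolean")
    return tests


def _filter_rel(rel: RelAbundanceTable, min_detected: int) -> RelAbundanceTable:
    """Exclude-mode low-detection filtering directly on a relative table,
    renormalizing columns (equivalent to filtering counts then normalizing)."""
    mask = (rel.rel.to_numpy() > 0).sum(axis=1) >= min_detected
    if not mask.any():
        raise ValueError("all taxa filtered out")
    sub = rel.rel.loc[mask]
    sub = sub / sub.sum(axis=0)
    return RelAbundanceTable(rel=sub, group_of=rel.group_of)


@dataclass(frozen=True)
class BenchmarkResult:
    """Tidy per-instance/per-method metrics plus summary statistics."""

    metrics: pd.DataFrame
    medians: pd.DataFrame
    regression: dict
    n_failed: int = 0


KNOWN_METHODS = ("qmd", "qmd_fdr", "rac", "mwu")


def run_benchmark(
    pool: AbundancePool,
    n_instances: int,
    seed=None,
    methods=("qmd", "qmd_fdr", "rac", "mwu"),
    config: QmdConfig = QmdConfig(),
    **instance_kwargs,
) -> BenchmarkResult:
    """Simulate instances, run each method, and collect MAE / FNR / FPR.

    Per-instance seeds are spawned from the master ``seed``. The summary holds
    per-method medians and an OLS regression of the estimated on the true
    delta_psi (slope and adjusted R^2). Failing instances are logged, skipped
    and counted.
    """
    if n_instances < 1:
        raise ValueError("n_instances must be >= 1")
    unknown = set(methods) - set(KNOWN_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    children = seed.spawn(n_instances)
    rows = []
    n_failed = 0
    for i, child in enumerate(children):
        try:
            rows.extend(
                _run_one(i, pool, child, methods, config, instance_kwargs)
            )
        except Exception:
            n_failed += 1
            logger.exception("benchmark instance %d failed; skipping", i)
    if not rows:
        raise RuntimeError("every benchmark instance failed")
    metrics = pd.DataFrame(rows)

    medians = (
        metrics.groupby("method")[["mae", "fnr", "fpr"]].median().reset_index()
    )
    qmd_rows = metrics[metrics["method"] == "qmd"]
    regression = {}
    if len(qmd_rows) >= 3:
        X = sm.add_constant(qmd_rows["true_delta_psi"].to_numpy())
        fit = sm.OLS(qmd_rows["est_delta_psi"].to_numpy(), X).fit()
        regression = {
            "slope": float(fit.params[1]),
            "intercept": float(fit.params[0]),
            "r2": float(fit.rsquared),
            "adj_r2": float(fit.rsquared_adj),
            "n": int(fit.nobs),
        }
    return BenchmarkResult(metrics=metrics, medians=medians,
                           regression=regression, n_failed=n_failed)


def _run_one(i, pool, child, methods, config, instance_kwargs):
    inst = simulate_instance(pool, seed=child, **instance_kwargs)
    inst_seed = int(child.generate_state(1)[0] % (2**31))
    rel = _filter_rel(inst.rel, config.min_detected)

    base = {
        "instance_id": i,
        "seed": inst_seed,
        "n_per_group": inst.n_per_group,
        "prop_DA": inst.prop_da,
        "true_delta_psi": inst.true_delta_psi,
    }
    rows = []
    need_qmd = any(m in methods for m in ("qmd", "qmd_fdr"))
    result = None
    if need_qmd:
        result = run_qmd_rel(rel, replace(config, fdr="off", seed=inst_seed))
    evaluated = None
    truth_set = None
    if result is not None:
        testable = result.taxa["testable"].fillna(False)
        evaluated = set(result.taxa.loc[testable, "taxon_id"])
        truth_set = inst.perturbed_set & evaluated

    for method in methods:
        row = dict(base, method=method, est_delta_psi=np.nan,
                   mae=np.nan, fnr=np.nan, fpr=np.nan)
        if method in ("qmd", "qmd_fdr"):
            est = result.taxa.set_index("taxon_id")["delta_M_log2"]
            row["est_delta_psi"] = result.delta_psi_hat
            row["mae"] = mae(est, inst.true_delta_M)
            p = result.taxa.loc[result.taxa["testable"].fillna(False)]
            if method == "qmd_fdr":
                q = pd.Series(bh_adjust(p["p_value"].to_numpy()), index=p["taxon_id"])
                predicted = set(q[q < config.alpha].index)
            else:
                predicted = set(p.loc[p["p_value"] < config.alpha, "taxon_id"])
            cm = confusion_metrics(predicted, truth_set, evaluated)
            row["fnr"] = np.nan if cm.fnr is None else cm.fnr
            row["fpr"] = np.nan if cm.fpr is None else cm.fpr
        elif method == "rac":
            row["mae"] = mae(baseline_rac(rel), inst.true_delta_M)
        elif method == "mwu":
            tests = baseline_mwu(rel, replace(config, seed=inst_seed))
            testable = tests["testable"].fillna(False)
            ev = set(tests.loc[testable, "taxon_id"])
            predicted = set(tests.loc[testable & (tests["p_value"] < config.alpha),
                                      "taxon_id"])
            cm = confusion_metrics(predicted, inst.perturbed_set & ev, ev)
            row["fnr"] = np.nan if cm.fnr is None else cm.fnr
            row["fpr"] = np.nan if cm.fpr is None else cm.fpr
        rows.append(row)
    return rows
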