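"""Shifted-null differential abundance testing and the full pipeline.

The null hypothesis for taxon i is that its absolute abundance is unchanged,
H0: delta_M_i = delta_psi + d_i = 0, i.e. the treatment log2 relative
abundances, shifted by the estimated delta_psi, have the same location as the
control log2 relative abundances. The test is a two-sided Mann-Whitney U
comparison of {x + delta_psi_hat : x in logvals_T} against logvals_C.

p-values come from the permutation null that reshuffles group labels over the
pooled shifted values. Whenever the number of distinct label assignments
C(n_T+n_C, n_T) is at most the permutation budget the null is enumerated
exhaustively (an exact test); otherwise Monte Carlo with the add-one
estimator p = (1 + #{|U* - E[U]| >= |U - E[U]|}) / (1 + B), so p > 0 always.
A tie-corrected normal-approximation option is provided for speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import core, data_io
from .data_io import CONTROL, TREATMENT, FeatureTable, RelAbundanceTable


@dataclass(frozen=True)
class MwuResult:
    """Outcome of one shifted Mann-Whitney U test."""

    U: float
    p: float
    n_T: int
    n_C: int
    testable: bool = True


@dataclass(frozen=True)
class QmdConfig:
    """Run configuration; defaults mirror the method's published settings."""

    min_detected: int = 5
    filter_mode: str = "exclude"
    lo: float = -10.0
    hi: float = 10.0
    step: float = 0.01
    alpha: float = 0.05
    fdr: str = "auto"  # {auto, on, off}; auto: on iff min group size > 50
    n_permutations: int = 500
    test: str = "permutation"  # {permutation, asymptotic}
    seed: int | None = None
    per_group_detection: bool = False

    def fdr_enabled(self, n_T: int, n_C: int) -> bool:
        if self.fdr == "on":
            return True
        if self.fdr == "off":
            return False
        if self.fdr == "auto":
            return min(n_T, n_C) > 50
        raise data_io.ConfigError(f"unknown fdr policy {self.fdr!r}")


@dataclass(frozen=True)
class QmdResult:
    """Per-taxon table plus the delta_psi estimate and the configuration echo."""

    taxa: pd.DataFrame
    estimate: core.DeltaPsiEstimate
    config: QmdConfig
    filter_report: data_io.FilterReport | None = field(default=None, compare=False)

    @property
    def delta_psi_hat(self) -> float:
        return self.estimate.delta_psi_hat

    @property
    def significant_taxa(self) -> list[str]:
        return list(self.taxa.loc[self.taxa["significant"].fillna(False), "taxon_id"])


def _u_statistic(ranks: np.ndarray, n_T: int) -> float:
    return float(ranks[:n_T].sum() - n_T * (n_T + 1) / 2.0)


def shifted_mwu(
    logvals_T,
    logvals_C,
    delta_psi_hat: float,
    n_permutations: int = 500,
    seed=None,
    method: str = "permutation",
) -> MwuResult:
    """Two-sided Mann-Whitney U test of shifted treatment vs control log2 values.

    ``logvals_T``/``logvals_C`` are the detected-sample log2 relative
    abundances of one taxon. An empty side yields an untestable marker
    (``testable=False``, p = NaN) rather than an exception, so a whole-table
    run is never aborted by one degenerate taxon.
    """
    x = np.asarray(logvals_T, dtype=float) + delta_psi_hat
    y = np.asarray(logvals_C, dtype=float)
    n_T, n_C = len(x), len(y)
    if n_T < 1 or n_C < 1:
        return MwuResult(U=np.nan, p=np.nan, n_T=n_T, n_C=n_C, testable=False)

    if method == "asymptotic":
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        return MwuResult(U=float(res.statistic), p=float(res.pvalue), n_T=n_T, n_C=n_C)
    if method != "permutation":
        raise data_io.ConfigError(f"unknown test method {method!r}")

    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u_obs = _u_statistic(ranks, n_T)
    mu = n_T * n_C / 2.0
    dev_obs = abs(u_obs - mu)
    n = n_T + n_C
    offset = n_T * (n_T + 1) / 2.0

    n_exact = math.comb(n, n_T)
    if n_exact <= n_permutations:
        # exhaustive enumeration of label assignments: an exact test
        count = 0
        for idx in combinations(range(n), n_T):
            u = ranks[list(idx)].sum() - offset
            if abs(u - mu) >= dev_obs - 1e-12:
                count += 1
        p = count / n_exact
    else:
        rng = np.random.default_rng(seed)
        # each row of the argsorted uniform matrix is a random label assignment
        draws = rng.random((n_permutations, n))
        idx = np.argsort(draws, axis=1)[:, :n_T]
        u_perm = ranks[idx].sum(axis=1) - offset
        count = int((np.abs(u_perm - mu) >= dev_obs - 1e-12).sum())
        p = (1 + count) / (1 + n_permutations)
    return MwuResult(U=u_obs, p=float(p), n_T=n_T, n_C=n_C)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini/Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _detected_logs(rel: RelAbundanceTable) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    cols_T = rel.samples_in_group(TREATMENT)
    cols_C = rel.samples_in_group(CONTROL)
    return (
        rel.rel[cols_T].to_numpy(dtype=float),
        rel.rel[cols_C].to_numpy(dtype=float),
        cols_T,
        cols_C,
    )


def per_taxon_tests(
    rel: RelAbundanceTable,
    delta_psi_hat: float,
    config: QmdConfig,
) -> pd.DataFrame:
    """Run the shifted MWU test for every taxon of a relative-abundance table.

    Zeros are excluded from each group's sample (consistent with the
    zero-removal convention of the estimator), so n_T/n_C are detected
    counts. Per-taxon RNG streams are spawned from ``config.seed`` so
    p-values are reproducible and independent of evaluation order.
    """
    mat_T, mat_C, _, _ = _detected_logs(rel)
    children = np.random.SeedSequence(config.seed).spawn(mat_T.shape[0])
    rows = []
    for i, taxon in enumerate(rel.taxon_ids):
        t = mat_T[i]
        c = mat_C[i]
        res = shifted_mwu(
            np.log2(t[t > 0]),
            np.log2(c[c > 0]),
            delta_psi_hat,
            n_permutations=config.n_permutations,
            seed=children[i],
            method=config.test,
        )
        rows.append(
            {"taxon_id": taxon, "U": res.U, "p_value": res.p,
             "n_T": res.n_T, "n_C": res.n_C, "testable": res.testable}
        )
    return pd.DataFrame(rows)


def run_qmd_rel(rel: RelAbundanceTable, config: QmdConfig = QmdConfig(),
                filter_report: data_io.FilterReport | None = None) -> QmdResult:
    """QMD pipeline on an already-normalized relative-abundance table."""
    summaries = core.taxon_log_changes(rel)
    estimate = core.quantify_delta_psi(summaries, config.lo, config.hi, config.step)
    delta_m = core.absolute_changes(summaries, estimate)

    tests = per_taxon_tests(rel, estimate.delta_psi_hat, config)
    taxa = summaries.rename(
        columns={"D_T": "detection_T", "D_C": "detection_C", "d": "rel_change_log2"}
    )
    taxa["delta_M_log2"] = delta_m.to_numpy()
    taxa = taxa.merge(tests, on="taxon_id")

    n_T = len(rel.samples_in_group(TREATMENT))
    n_C = len(rel.samples_in_group(CONTROL))
    use_fdr = config.fdr_enabled(n_T, n_C)
    testable = taxa["testable"].to_numpy()
    qvals = np.full(len(taxa), np.nan)
    if testable.any():
        if use_fdr:
            qvals[testable] = bh_adjust(taxa.loc[testable, "p_value"].to_numpy())
        crit = qvals if use_fdr else taxa["p_value"].to_numpy()
        taxa["q_value"] = qvals
        taxa["significant"] = pd.array(
            np.where(testable, crit < config.alpha, None), dtype="boolean"
        )
    else:
        taxa["q_value"] = qvals
        taxa["significant"] = pd.array([None] * len(taxa), dtype="boolean")
    return QmdResult(taxa=taxa, estimate=estimate, config=config, filter_report=filter_report)


def run_qmd(table: FeatureTable, config: QmdConfig = QmdConfig()) -> QmdResult:
    """Full pipeline from raw counts: filter -> normalize -> estimate -> test.

    Stages: low-detection filtering (threshold ``min_detected``, mode
    ``exclude`` or ``aggregate``), relative-abundance normalization,
    delta_psi grid traversal, per-taxon delta_M, shifted MWU tests, and
    optional BH adjustment (policy ``fdr``, significance level ``alpha``).
    """
    if table.group_of is None:
        raise data_io.ConfigError("run_qmd: feature table needs group labels attached")
    try:
        filtered = data_io.filter_low_detection(
            table, config.min_detected, config.filter_mode,
            per_group=config.per_group_detection,
        )
    except Exception as exc:
        raise type(exc)(f"[filter stage] {exc}") from exc
    try:
        rel = data_io.to_relative(filtered)
    except Exception as exc:
        raise type(exc)(f"[normalize stage] {exc}") from exc
    return run_qmd_rel(rel, config, filter_report=filtered.filter_report)
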