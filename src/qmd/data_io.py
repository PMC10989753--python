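"""Feature-table and metadata I/O, detection filtering, and relative-abundance normalization.

Feature tables are plain TSV with taxa in rows and one column per sample
(the common QIIME 2 export dialect); metadata is a TSV mapping samples to
exactly two group labels, which are recoded internally to ``T`` (treatment)
and ``C`` (control) so that every downstream sign convention
(delta_psi = T - C) is fixed once at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Name of the synthetic taxon created by aggregate-mode filtering.
FILTERED_TAXON_ID = "filtered-out-taxa"

TREATMENT = "T"
CONTROL = "C"


class ParseError(ValueError):
    """Raised when an input file violates the feature-table/metadata contract."""


class ConfigError(ValueError):
    """Raised when metadata or configuration is inconsistent with the feature table."""


@dataclass(frozen=True)
class FilterReport:
    """Per-taxon record of what low-detection filtering did."""

    entries: pd.DataFrame  # columns: taxon_id, n_detected, action
    min_detected: int
    mode: str

    @property
    def dropped(self) -> list[str]:
        mask = self.entries["action"] != "kept"
        return list(self.entries.loc[mask, "taxon_id"])

    def write(self, path) -> None:
        self.entries.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class FeatureTable:
    """Raw count table (taxa x samples) with optional sample->group labels.

    ``counts`` is a pandas DataFrame indexed by taxon id with sample ids as
    columns; cells are non-negative integers. ``group_of`` maps every sample
    id to ``"T"`` or ``"C"`` once metadata has been attached.
    """

    counts: pd.DataFrame
    group_of: dict[str, str] | None = None
    filter_report: FilterReport | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.counts.shape[0] == 0 or self.counts.shape[1] == 0:
            raise ParseError("empty feature table")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ParseError(f"duplicate taxon ids: {dups}")
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ParseError(f"duplicate sample ids: {dups}")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.allclose(vals, np.round(vals), atol=0):
                raise ParseError("counts must be integral")
            object.__setattr__(self, "counts", self.counts.astype(np.int64))
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            i, j = np.argwhere(vals < 0)[0]
            raise ParseError(
                f"negative count at taxon {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )
        if self.group_of is not None:
            missing = [s for s in self.sample_ids if s not in self.group_of]
            if missing:
                raise ConfigError(f"samples without group label: {missing}")
            labels = {self.group_of[s] for s in self.sample_ids}
            if labels != {TREATMENT, CONTROL}:
                raise ConfigError(
                    f"expected exactly the two groups {{'T', 'C'}}, got {sorted(labels)}"
                )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def with_groups(self, group_of: dict[str, str]) -> "FeatureTable":
        """Return a copy with group labels attached (restricted to table samples)."""
        sub = {s: group_of[s] for s in self.sample_ids if s in group_of}
        return replace(self, group_of=sub)

    def samples_in_group(self, group: str) -> list[str]:
        if self.group_of is None:
            raise ConfigError("feature table has no group labels attached")
        return [s for s in self.sample_ids if self.group_of[s] == group]


@dataclass(frozen=True)
class RelAbundanceTable:
    """Per-sample relative abundances; every sample column sums to 1."""

    rel: pd.DataFrame
    group_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        vals = self.rel.to_numpy(dtype=float)
        if (vals < 0).any():
            raise ParseError("negative relative abundance")
        sums = vals.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            bad = self.rel.columns[np.argmax(np.abs(sums - 1.0))]
            raise ParseError(f"sample {bad!r} column does not sum to 1")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.rel.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.rel.columns)

    def samples_in_group(self, group: str) -> list[str]:
        if self.group_of is None:
            raise ConfigError("relative-abundance table has no group labels attached")
        return [s for s in self.sample_ids if self.group_of[s] == group]


def read_feature_table(path, *, transpose: bool = False) -> FeatureTable:
    """Read a taxa-in-rows TSV count table (no group labels attached).

    The first column holds taxon ids; the header row holds sample ids. Pass
    ``transpose=True`` for samples-in-rows files. Row and column order of the
    input is preserved.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"could not parse feature table {path}: {exc}") from exc
    if transpose:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        bad = df[col].isna()
        if bad.any():
            raise ParseError(f"missing value in sample column {col!r}, row {df.index[bad.argmax()]!r}")
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = df.index[numeric.isna().argmax()]
            raise ParseError(f"non-numeric cell at taxon {row!r}, sample {col!r}")
        df[col] = numeric
    return FeatureTable(counts=df)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table in the same TSV dialect ``read_feature_table`` accepts."""
    out = table.counts.copy()
    out.index.name = out.index.name or "taxon_id"
    out.to_csv(path, sep="\t")


def read_metadata(
    path,
    sample_col: str,
    group_col: str,
    treatment_label: str,
    control_label: str,
    *,
    table: FeatureTable | None = None,
) -> dict[str, str]:
    """Read a sample->group map from a metadata TSV, recoding labels to T/C.

    When ``table`` is given the map is validated against (and restricted to)
    the table's samples; metadata rows for unrelated samples are ignored with
    a warning. Every table sample must appear exactly once and carry one of
    the two stated labels.
    """
    meta = pd.read_csv(path, sep="\t", dtype=str)
    for col in (sample_col, group_col):
        if col not in meta.columns:
            raise ConfigError(f"metadata {path} lacks column {col!r}")
    if meta[sample_col].duplicated().any():
        dups = meta.loc[meta[sample_col].duplicated(), sample_col].tolist()
        raise ConfigError(f"duplicate metadata rows for samples: {dups}")
    recode = {treatment_label: TREATMENT, control_label: CONTROL}
    mapping: dict[str, str] = {}
    for sample, label in zip(meta[sample_col], meta[group_col]):
        mapping[str(sample)] = recode.get(label, label)

    if table is not None:
        missing = [s for s in table.sample_ids if s not in mapping]
        if missing:
            raise ConfigError(f"feature-table samples absent from metadata: {missing}")
        extra = [s for s in mapping if s not in set(table.sample_ids)]
        if extra:
            logger.warning("ignoring %d metadata samples not in the feature table", len(extra))
        mapping = {s: mapping[s] for s in table.sample_ids}
        bad = {s: g for s, g in mapping.items() if g not in (TREATMENT, CONTROL)}
        if bad:
            raise ConfigError(
                f"samples with group labels other than {treatment_label!r}/"
                f"{control_label!r}: {bad}"
            )
    return mapping


def detection_counts(matrix: pd.DataFrame) -> pd.Series:
    """Number of samples (columns) in which each taxon has a nonzero value."""
    return (matrix.to_numpy() > 0).sum(axis=1)


def filter_low_detection(
    table: FeatureTable,
    min_detected: int = 5,
    mode: str = "exclude",
    *,
    per_group: bool = False,
) -> FeatureTable:
    """Drop (or aggregate) taxa detected in fewer than ``min_detected`` samples.

    Detection means a nonzero count, tallied across all samples of both
    groups (``per_group=True`` instead requires the threshold within each
    group separately). ``mode="exclude"`` drops failing taxa;
    ``mode="aggregate"`` replaces them with a single synthetic taxon named
    ``filtered-out-taxa`` holding their column-wise count sums, so per-sample
    totals are conserved. A :class:`FilterReport` is attached to the result.
    """
    if min_detected < 0:
        raise ConfigError("min_detected must be >= 0")
    if mode not in ("exclude", "aggregate"):
        raise ConfigError(f"unknown filter mode {mode!r}")

    counts = table.counts
    if per_group:
        if table.group_of is None:
            raise ConfigError("per-group filtering requires group labels")
        keep_mask = np.ones(counts.shape[0], dtype=bool)
        for g in (TREATMENT, CONTROL):
            cols = table.samples_in_group(g)
            keep_mask &= detection_counts(counts[cols]) >= min_detected
        n_det = detection_counts(counts)
    else:
        n_det = detection_counts(counts)
        keep_mask = n_det >= min_detected

    dropped = counts.index[~keep_mask]
    action = np.where(keep_mask, "kept", mode + "d" if mode == "exclude" else "aggregated")
    report = FilterReport(
        entries=pd.DataFrame(
            {"taxon_id": counts.index, "n_detected": n_det, "action": action}
        ).reset_index(drop=True),
        min_detected=min_detected,
        mode=mode,
    )

    if len(dropped) == 0:
        return replace(table, filter_report=report)
    kept = counts.loc[keep_mask]
    if kept.shape[0] == 0 and mode == "exclude":
        raise ConfigError("all taxa filtered out; nothing left to analyze")
    if mode == "aggregate":
        if FILTERED_TAXON_ID in kept.index:
            raise ConfigError(
                f"taxon id {FILTERED_TAXON_ID!r} already present; cannot aggregate"
            )
        agg = counts.loc[dropped].sum(axis=0).to_frame(FILTERED_TAXON_ID).T
        kept = pd.concat([kept, agg])
    return replace(table, counts=kept, filter_report=report)


def to_relative(table: FeatureTable) -> RelAbundanceTable:
    """Normalize counts to per-sample proportions (no pseudocount anywhere).

    Zeros stay exactly zero; a zero-total sample is an error because the
    normalization is undefined and silently dropping it would distort
    detection rates.
    """
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ParseError(f"sample {zero.index[0]!r} has zero total count")
    rel = table.counts.astype(float) / totals
    return RelAbundanceTable(rel=rel, group_of=table.group_of)
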