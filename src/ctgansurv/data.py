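"""Domain datasets: expression + survival containers, TSV I/O, preprocessing.

A *domain* is one cancer cohort: an expression matrix (samples x genes) and
a survival table (time in days, event indicator) aligned 1:1 by sample ID.
Expression is FPKM on input and log2(FPKM + 1) after :func:`preprocess`.
Survival statistics always operate on times in days; the log2(t + 1) value
used as the network's extra input feature is derived on the fly
(:meth:`DomainDataset.model_matrix`).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("ctgansurv")

__all__ = [
    "SurvivalRecord",
    "ExpressionMatrix",
    "DomainDataset",
    "CohortSummary",
    "read_domain",
    "write_domain",
    "preprocess",
    "filter_cohorts",
]


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    time: float  # days
    event: int  # 1 = event observed, 0 = right-censored

    def __post_init__(self):
        if self.event not in (0, 1):
            raise DataError(f"event for {self.sample_id!r} must be 0 or 1, got {self.event}")
        if not np.isfinite(self.time) or self.time < 0:
            raise DataError(f"time for {self.sample_id!r} must be a nonnegative real, got {self.time}")


@dataclass
class ExpressionMatrix:
    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # n_samples x n_genes
    normalized: bool = False  # True once values are log2(x + 1)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise DataError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains missing or non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.gene_ids)
        pos = idx.get_indexer(gene_ids)
        if (pos < 0).any():
            missing = [g for g, p in zip(gene_ids, pos) if p < 0]
            raise DataError(f"genes not present in matrix: {missing[:5]}")
        return ExpressionMatrix(list(self.sample_ids), list(gene_ids),
                                self.values[:, pos], self.normalized)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class DomainDataset:
    """One cohort; expression rows and survival entries share order."""

    name: str
    expression: ExpressionMatrix
    times: np.ndarray = field(default=None)  # days
    events: np.ndarray = field(default=None)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.events = np.asarray(self.events, dtype=np.int64)
        n = len(self.expression.sample_ids)
        if self.times.shape != (n,) or self.events.shape != (n,):
            raise DataError(f"survival arrays must have length {n}")
        if not np.isin(self.events, (0, 1)).all():
            raise DataError("event indicator must be 0 or 1")
        if (self.times < 0).any() or not np.all(np.isfinite(self.times)):
            raise DataError("survival times must be nonnegative reals")

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def survival(self) -> list[SurvivalRecord]:
        return [SurvivalRecord(s, float(t), int(e))
                for s, t, e in zip(self.sample_ids, self.times, self.events)]

    def summary(self) -> "CohortSummary":
        return CohortSummary(self.name, self.n_samples, int(self.events.sum()))

    def subset(self, mask_or_idx) -> "DomainDataset":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        expr = ExpressionMatrix([self.expression.sample_ids[i] for i in idx],
                                list(self.expression.gene_ids),
                                self.expression.values[idx],
                                self.expression.normalized)
        return DomainDataset(self.name, expr, self.times[idx], self.events[idx])

    def subset_genes(self, gene_ids: list[str]) -> "DomainDataset":
        return dataclasses.replace(self, expression=self.expression.subset_genes(gene_ids))

    def model_matrix(self) -> np.ndarray:
        """Network input: expression columns plus log2(time + 1) as last feature."""
        if not self.expression.normalized:
            raise DataError("preprocess the dataset before building model input")
        return np.column_stack([self.expression.values, np.log2(self.times + 1.0)])


@dataclass(frozen=True)
class CohortSummary:
    name: str
    n_samples: int
    n_events: int

    def __post_init__(self):
        if not 0 <= self.n_events <= self.n_samples:
            raise DataError(f"{self.name}: n_events must lie in [0, n_samples]")


def _read_tsv(path, what: str) -> pd.DataFrame:
    try:
        # round_trip parsing keeps read -> write -> read bit-identical
        return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    except Exception as exc:  # pandas names the offending line in its message
        raise DataError(f"could not parse {what} file {path}: {exc}") from exc


def read_domain(expression_path, survival_path, *, name: str = "domain",
                genes_as_rows: bool = False, whitelist=None) -> DomainDataset:
    """Read an expression TSV and a survival TSV and align them by sample ID.

    Only samples present in both files (and in ``whitelist`` if given) are
    kept, sorted lexicographically for a deterministic order. Values are
    retained raw; call :func:`preprocess` afterwards.
    """
    expr = _read_tsv(expression_path, "expression")
    if genes_as_rows:
        expr = expr.T
    surv = pd.read_csv(survival_path, sep="\t", dtype={0: str},
                       float_precision="round_trip")
    required = {"sample_id", "time", "event"}
    if not required.issubset(surv.columns):
        raise DataError(f"survival file {survival_path} must have columns {sorted(required)}")
    surv = surv.set_index("sample_id")
    for i, (sid, row) in enumerate(surv.iterrows(), start=2):
        if row["event"] not in (0, 1):
            raise DataError(f"{survival_path} line {i}: event must be 0 or 1, got {row['event']}")
        if not np.isfinite(row["time"]) or row["time"] < 0:
            raise DataError(f"{survival_path} line {i}: invalid time {row['time']}")

    common = sorted(set(expr.index.astype(str)) & set(surv.index))
    if whitelist is not None:
        common = [s for s in common if s in set(whitelist)]
    if not common:
        raise DataError("no overlapping sample IDs between expression and survival files")
    expr = expr.loc[common]
    surv = surv.loc[common]
    em = ExpressionMatrix(common, [str(g) for g in expr.columns], expr.to_numpy(float))
    return DomainDataset(name, em, surv["time"].to_numpy(float), surv["event"].to_numpy(int))


def write_domain(dataset: DomainDataset, expression_path, survival_path) -> None:
    """Write the two TSV dialects read by :func:`read_domain`."""
    # %.17g keeps the read->write->read cycle bit-identical
    dataset.expression.to_frame().to_csv(expression_path, sep="\t",
                                         index_label="sample_id", float_format="%.17g")
    pd.DataFrame({"sample_id": dataset.sample_ids,
                  "time": dataset.times,
                  "event": dataset.events}).to_csv(survival_path, sep="\t", index=False,
                                                   float_format="%.17g")


def preprocess(dataset: DomainDataset) -> DomainDataset:
    """Remove 0-day samples and log-normalise expression: x -> log2(x + 1).

    Times stay in days; the log2(t + 1) model feature is derived when the
    network input is assembled. Guarded against double application via the
    ``normalized`` flag.
    """
    if dataset.expression.normalized:
        raise DataError(f"{dataset.name}: dataset is already log-normalized")
    if (dataset.expression.values < 0).any():
        raise DataError(f"{dataset.name}: negative expression values")
    keep = dataset.times > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("%s: removed %d samples with 0 survival days", dataset.name, dropped)
    ds = dataset.subset(keep)
    expr = ExpressionMatrix(ds.expression.sample_ids, ds.expression.gene_ids,
                            np.log2(ds.expression.values + 1.0), normalized=True)
    return DomainDataset(ds.name, expr, ds.times, ds.events)


def filter_cohorts(summaries: list[CohortSummary], min_samples: int = 300,
                   min_events: int = 50) -> list[CohortSummary]:
    """Keep cohorts with >= ``min_samples`` samples and >= ``min_events`` events."""
    if not summaries:
        raise DataError("no cohort summaries given")
    return [s for s in summaries
            if s.n_samples >= min_samples and s.n_events >= min_events]
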