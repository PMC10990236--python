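"""Per-group outlier detection and removal for reference genes.

A sample is flagged when its value deviates from its group mean by more
than ``t`` group sample standard deviations (default t = 2), evaluated
per reference gene (mode ``all``) or on the MeanRef pseudo-gene only
(mode ``mean``).  Removal is whole-sample and iterative: deleting a
flagged sample shrinks its group SD, which may expose further outliers,
so detection and removal repeat until a round finds nothing or the round
cap is hit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ContractError, ParameterError
from .panel import MEANREF, GenePanel, mean_reference_profile
from .tabio import CqTable

__all__ = [
    "OutlierParams",
    "OutlierRecord",
    "OutlierReport",
    "detect_outliers",
    "remove_samples",
    "iterate_outlier_removal",
]

MODES = ("all", "mean")

#: groups smaller than this are skipped: with n = 2 every point sits at
#: exactly 1 SD from the mean, so SD thresholding is meaningless
MIN_GROUP_SIZE = 3


@dataclass(frozen=True)
class OutlierParams:
    """Threshold (SD multiples), detection mode and iteration cap."""

    threshold: float = 2.0
    mode: str = "all"
    max_rounds: int = 10

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ParameterError(f"SD threshold must be > 0, got {self.threshold}")
        if self.mode not in MODES:
            raise ParameterError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.max_rounds < 0:
            raise ParameterError("max_rounds must be >= 0")


@dataclass(frozen=True)
class OutlierRecord:
    """One flagged (sample, analyte) pair with its triggering statistics."""

    sample_id: str
    gene: str  # a reference gene name or "MeanRef"
    group: str
    value: float
    group_mean: float
    group_sd: float
    round_index: int  # 1-based
    removed: bool = False


@dataclass
class OutlierReport:
    """Accumulated flags across detection rounds."""

    records: list[OutlierRecord] = field(default_factory=list)

    @property
    def flagged_samples(self) -> list[str]:
        """Unique flagged sample ids, in first-flag order."""
        return list(dict.fromkeys(r.sample_id for r in self.records))

    @property
    def n_rounds(self) -> int:
        return max((r.round_index for r in self.records), default=0)

    def to_frame(self) -> pd.DataFrame:
        cols = ["sample_id", "gene", "group", "value", "group_mean",
                "group_sd", "round", "removed"]
        rows = [
            (r.sample_id, r.gene, r.group, r.value, r.group_mean,
             r.group_sd, r.round_index, r.removed)
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=cols)


def _flag_series(values: pd.Series, groups: pd.Series, gene: str,
                 threshold: float, round_index: int) -> list[OutlierRecord]:
    """Flag values strictly beyond threshold x group sample SD (ddof=1).

    Constant groups (SD = 0) yield no flags; groups with fewer than
    MIN_GROUP_SIZE usable values are skipped with a warning.
    """
    records: list[OutlierRecord] = []
    for grp, idx in groups.groupby(groups, sort=False).groups.items():
        vals = values.loc[idx].dropna()
        if len(vals) < MIN_GROUP_SIZE:
            warnings.warn(
                f"group {grp!r} has {len(vals)} usable values for {gene!r}; "
                f"outlier detection needs >= {MIN_GROUP_SIZE}, skipping",
                stacklevel=3,
            )
            continue
        mean = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd == 0.0:
            continue
        dev = (vals - mean).abs()
        for sid in vals.index[dev > threshold * sd]:
            records.append(OutlierRecord(
                sample_id=str(sid), gene=gene, group=str(grp),
                value=float(values.loc[sid]), group_mean=mean, group_sd=sd,
                round_index=round_index,
            ))
    return records


def detect_outliers(table: CqTable, panel: GenePanel,
                    params: OutlierParams | None = None,
                    *, round_index: int = 1) -> OutlierReport:
    """Flag per-group outliers in the reference genes (or MeanRef only).

    Statistics are the group mean and sample SD computed on the table as
    given; flags are reported, nothing is removed.
    """
    params = params or OutlierParams()
    if not panel.reference_genes:
        raise ContractError("no reference genes to screen for outliers")
    records: list[OutlierRecord] = []
    if params.mode == "mean":
        series = mean_reference_profile(table, panel)
        records = _flag_series(series, table.group, MEANREF,
                               params.threshold, round_index)
    else:
        for gene in panel.reference_genes:
            records.extend(_flag_series(table.cq[gene], table.group, gene,
                                        params.threshold, round_index))
    return OutlierReport(records=records)


def remove_samples(table: CqTable, sample_ids: list[str]) -> CqTable:
    """Return a table without the given samples (whole-row removal).

    The original table is left untouched, so a removal can always be
    undone by keeping the input.
    """
    if not sample_ids:
        return CqTable(table.cq.copy(), table.group.copy())
    unknown = [s for s in sample_ids if s not in table.cq.index]
    if unknown:
        raise ContractError(f"unknown sample ids: {unknown}")
    keep = [s for s in table.cq.index if s not in set(sample_ids)]
    return CqTable(table.cq.loc[keep], table.group.loc[keep])


def iterate_outlier_removal(
    table: CqTable, panel: GenePanel, params: OutlierParams | None = None
) -> tuple[CqTable, OutlierReport]:
    """Repeat detect-and-remove until a clean round or ``max_rounds``.

    All samples flagged within a round are removed together using the
    statistics computed before any removal that round, so the result does
    not depend on sample order.  Each removing round strictly decreases
    the sample count, so the loop always terminates.
    """
    params = params or OutlierParams()
    current = table
    report = OutlierReport()
    for round_index in range(1, params.max_rounds + 1):
        found = detect_outliers(current, panel, params, round_index=round_index)
        if not found.records:
            break
        flagged = found.flagged_samples
        current = remove_samples(current, flagged)
        report.records.extend(
            replace(r, removed=True) for r in found.records
        )
    return current, report
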