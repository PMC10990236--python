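"""Differential expression of target genes via dCq and 2^-ddCq.

dCq is a sample's target Cq minus its MeanRef (the mean Cq of the
reference genes); larger dCq means *less* expression.  For a pair of
groups, ddCq is the difference of group-mean dCq and the fold change of
group A relative to the calibrator group B is 2^-ddCq.

Location tests are chosen by group count: two groups use a t test
(Welch by default) or Wilcoxon-Mann-Whitney; three or more use one-way
ANOVA with Tukey HSD or Kruskal-Wallis with Dunn's test.  Each group is
screened with Shapiro-Wilk; ``method="auto"`` goes parametric only when
every group passes (p > 0.05).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError, ParameterError
from .panel import GenePanel, mean_reference_profile
from .refstats import dunn_test
from .tabio import CqTable

__all__ = [
    "DeltaCqTable",
    "DiffExprResult",
    "delta_cq",
    "fold_change",
    "differential_tests",
    "diffexpr_report",
]

METHODS = ("auto", "parametric", "nonparametric")


@dataclass
class DeltaCqTable:
    """Per-sample dCq values for each target gene, with group labels."""

    values: pd.DataFrame  # samples x targets
    group: pd.Series

    def target_values(self, target: str, group: str | None = None) -> np.ndarray:
        if target not in self.values.columns:
            raise ContractError(f"unknown target gene {target!r}")
        col = self.values[target]
        if group is not None:
            if group not in set(self.group):
                raise ContractError(f"unknown group {group!r}")
            col = col[self.group == group]
        return col.dropna().to_numpy(dtype=float)

    @property
    def groups(self) -> list[str]:
        return list(dict.fromkeys(self.group))


@dataclass
class DiffExprResult:
    """Outcome of the group comparison for one target gene."""

    target: str
    method: str                 # "parametric" or "nonparametric" as applied
    test: str
    statistic: float
    p_value: float
    shapiro_p: dict[str, float]
    posthoc: pd.DataFrame | None = None


def delta_cq(table: CqTable, panel: GenePanel,
             subset: Sequence[str] | None = None) -> DeltaCqTable:
    """dCq = target Cq - MeanRef, per sample and target gene."""
    if not panel.target_genes:
        raise ContractError("panel has no target genes")
    if not panel.reference_genes:
        raise ContractError("panel has no reference genes")
    meanref = mean_reference_profile(table, panel, subset=subset)
    values = table.cq[list(panel.target_genes)].sub(meanref, axis=0)
    return DeltaCqTable(values=values, group=table.group.copy())


def fold_change(dct: DeltaCqTable, target: str, group_a: str,
                group_b: str) -> tuple[float, float]:
    """(ddCq, 2^-ddCq) of ``group_a`` relative to calibrator ``group_b``.

    ddCq = mean dCq(A) - mean dCq(B); fold change above 1 means higher
    expression in A than in the calibrator.
    """
    a = dct.target_values(target, group_a)
    b = dct.target_values(target, group_b)
    if len(a) == 0 or len(b) == 0:
        raise ContractError(
            f"empty group for fold change: {group_a!r} n={len(a)}, "
            f"{group_b!r} n={len(b)}"
        )
    ddcq = float(a.mean() - b.mean())
    return ddcq, float(2.0 ** (-ddcq))


def _shapiro_p(arr: np.ndarray) -> float:
    if np.ptp(arr) == 0:
        return 0.0  # degenerate: constant data is not plausibly normal
    return float(stats.shapiro(arr).pvalue)


def differential_tests(dct: DeltaCqTable, target: str,
                       method: str = "auto",
                       groups: Sequence[str] | None = None,
                       equal_var: bool = False) -> DiffExprResult:
    """Compare dCq of one target across groups.

    ``method`` is "parametric" (t test / ANOVA+Tukey), "nonparametric"
    (Wilcoxon-Mann-Whitney / Kruskal-Wallis+Dunn), or "auto", which goes
    parametric only when every group's Shapiro-Wilk p exceeds 0.05.  The
    two-group t test is Welch's by default; ``equal_var=True`` selects
    the pooled-variance Student's t.  Groups with n < 3 force a
    nonparametric fallback under auto (Shapiro needs n >= 3).
    """
    if method not in METHODS:
        raise ParameterError(f"method must be one of {METHODS}, got {method!r}")
    labels = list(groups) if groups is not None else dct.groups
    if len(labels) < 2:
        raise ContractError("differential testing needs >= 2 groups")
    arrays = [dct.target_values(target, g) for g in labels]
    empty = [g for g, a in zip(labels, arrays) if len(a) < 2]
    if empty:
        raise ContractError(f"group(s) with <2 usable dCq values: {empty}")

    shapiro: dict[str, float] = {}
    for g, arr in zip(labels, arrays):
        shapiro[g] = _shapiro_p(arr) if len(arr) >= 3 else float("nan")

    chosen = method
    if method == "auto":
        if any(len(a) < 3 for a in arrays):
            warnings.warn(
                "group with n < 3 under method='auto': falling back to "
                "nonparametric tests", stacklevel=2,
            )
            chosen = "nonparametric"
        elif all(p > 0.05 for p in shapiro.values()):
            chosen = "parametric"
        else:
            chosen = "nonparametric"

    posthoc = None
    if len(labels) == 2:
        a, b = arrays
        if chosen == "parametric":
            if np.ptp(np.concatenate(arrays)) == 0:
                stat, p = 0.0, 1.0
            else:
                res = stats.ttest_ind(a, b, equal_var=equal_var)
                stat, p = float(res.statistic), float(res.pvalue)
            name = "student-t" if equal_var else "welch-t"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
            name = "wilcoxon-mann-whitney"
    else:
        if chosen == "parametric":
            if np.ptp(np.concatenate(arrays)) == 0:
                stat, p = 0.0, 1.0
                pairs = [(ga, gb, 0.0, 1.0) for ga, gb
                         in itertools.combinations(labels, 2)]
                posthoc = pd.DataFrame(
                    pairs, columns=["group_a", "group_b", "statistic", "p"])
            else:
                res = stats.f_oneway(*arrays)
                stat, p = float(res.statistic), float(res.pvalue)
                tk = stats.tukey_hsd(*arrays)
                pairs = [
                    (labels[i], labels[j], float(tk.statistic[i, j]),
                     float(tk.pvalue[i, j]))
                    for i, j in itertools.combinations(range(len(labels)), 2)
                ]
                posthoc = pd.DataFrame(
                    pairs, columns=["group_a", "group_b", "statistic", "p"])
            name = "anova"
        else:
            if np.ptp(np.concatenate(arrays)) == 0:
                stat, p = 0.0, 1.0
            else:
                res = stats.kruskal(*arrays)
                stat, p = float(res.statistic), float(res.pvalue)
            name = "kruskal-wallis"
            posthoc = dunn_test(arrays, labels).rename(
                columns={"z": "statistic"})
    return DiffExprResult(target=target, method=chosen, test=name,
                          statistic=stat, p_value=p, shapiro_p=shapiro,
                          posthoc=posthoc)


def diffexpr_report(dct: DeltaCqTable, targets: Sequence[str] | None = None,
                    group_a: str | None = None, group_b: str | None = None,
                    method: str = "auto", equal_var: bool = False
                    ) -> pd.DataFrame:
    """Pairwise differential-expression table for the report bundle.

    One row per target and group pair: group sizes, mean dCq per group,
    ddCq, fold change (group_a vs calibrator group_b), Shapiro p per
    group, the applied test and its p-value.  When no pair is named all
    group pairs are reported.
    """
    targets = list(targets) if targets is not None else list(dct.values.columns)
    if (group_a is None) != (group_b is None):
        raise ParameterError("name both groups of the comparison or neither")
    pairs = ([(group_a, group_b)] if group_a is not None
             else list(itertools.combinations(dct.groups, 2)))
    rows = []
    for target in targets:
        for ga, gb in pairs:
            a = dct.target_values(target, ga)
            b = dct.target_values(target, gb)
            ddcq, fc = fold_change(dct, target, ga, gb)
            res = differential_tests(dct, target, method=method,
                                     groups=[ga, gb], equal_var=equal_var)
            rows.append({
                "target": target, "group_a": ga, "group_b": gb,
                "n_a": len(a), "n_b": len(b),
                "mean_dCq_a": float(a.mean()), "mean_dCq_b": float(b.mean()),
                "ddCq": ddcq, "fold_change": fc,
                "shapiro_p_a": res.shapiro_p.get(ga, float("nan")),
                "shapiro_p_b": res.shapiro_p.get(gb, float("nan")),
                "test": res.test, "statistic": res.statistic,
                "p_value": res.p_value,
            })
    return pd.DataFrame(rows)
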