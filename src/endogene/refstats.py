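"""Group-difference tests and descriptive stability statistics for
reference genes.

Two report tables are produced.  "Gene reference by group" asks whether
each candidate (and the MeanRef pseudo-gene) differs between the studied
groups: Wilcoxon-Mann-Whitney for two groups, Kruskal-Wallis with Dunn's
pairwise z-tests for three or more.  A good reference gene should show
no significant group effect (p > 0.05).

"Descriptive statistics" summarises per-analyte spread with three
quantities (lower is better):

* ``Standard.Deviation`` — the pooled sample SD of the analyte,
* ``sum.mean.square.diff`` = sum over groups of (group mean - gene mean)^2,
* ``sum.SD.square.diff``   = sum over groups of (group SD - gene SD)^2.

Each group contributes one unweighted term regardless of its size.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ContractError
from .panel import MEANREF, GenePanel, mean_reference_profile
from .tabio import CqTable

__all__ = [
    "GroupTestResult",
    "group_location_tests",
    "descriptive_stability",
    "leave_one_out_evaluation",
    "dunn_test",
]

SIGNIFICANCE = 0.05  # flag threshold: reference genes should sit above it


# ---------------------------------------------------------------------------
# Dunn's post-hoc test
# ---------------------------------------------------------------------------

def dunn_test(samples: Sequence[np.ndarray], labels: Sequence[str],
              adjust: str | None = None) -> pd.DataFrame:
    """Dunn's pairwise z-tests on joint ranks with tie correction.

    For groups a, b with mean joint ranks Rbar_a, Rbar_b over N pooled
    observations,

        z = (Rbar_a - Rbar_b) / sqrt((N(N+1)/12 - T) (1/n_a + 1/n_b))

    where T = sum(t^3 - t) / (12 (N - 1)) over tie groups of size t.
    Two-sided p-values, unadjusted by default (the convention of the R
    ``dunn.test`` package); ``adjust`` may be "holm" or "bh".
    """
    if len(samples) < 3:
        raise ContractError("Dunn's test requires >= 3 groups")
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction over the pooled sample
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    rank_groups: list[np.ndarray] = []
    offset = 0
    for s in samples:
        rank_groups.append(ranks[offset:offset + len(s)])
        offset += len(s)
    rows = []
    for (i, a), (j, b) in itertools.combinations(enumerate(labels), 2):
        n_a, n_b = len(rank_groups[i]), len(rank_groups[j])
        var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / n_a + 1.0 / n_b)
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (rank_groups[i].mean() - rank_groups[j].mean()) / np.sqrt(var)
            p = float(2.0 * stats.norm.sf(abs(z)))
        rows.append((a, b, float(z), min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p"])
    if adjust is not None:
        from statsmodels.stats.multitest import multipletests

        method = {"holm": "holm", "bh": "fdr_bh"}[adjust]
        out["p"] = multipletests(out["p"], method=method)[1]
    return out


# ---------------------------------------------------------------------------
# Group-difference tests
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    """Per-analyte omnibus test with optional pairwise post-hoc table."""

    analyte: str
    test: str
    statistic: float
    p_value: float
    flagged: bool  # True when p <= 0.05: unsuitable as-is
    posthoc: pd.DataFrame | None = None


def _group_values(values: pd.Series, groups: pd.Series) -> tuple[list[np.ndarray], list[str]]:
    arrays, labels = [], []
    for grp, idx in groups.groupby(groups, sort=False).groups.items():
        arr = values.loc[idx].dropna().to_numpy(dtype=float)
        arrays.append(arr)
        labels.append(str(grp))
    return arrays, labels


def _test_one(values: pd.Series, groups: pd.Series, analyte: str,
              posthoc_adjust: str | None) -> GroupTestResult:
    arrays, labels = _group_values(values, groups)
    small = [lab for lab, arr in zip(labels, arrays) if len(arr) < 2]
    if small:
        raise ContractError(
            f"group(s) {small} have <2 usable values for {analyte!r}"
        )
    if len(arrays) == 2:
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided",
                                 method="auto")
        result = GroupTestResult(analyte, "wilcoxon-mann-whitney",
                                 float(res.statistic), float(res.pvalue),
                                 flagged=bool(res.pvalue <= SIGNIFICANCE))
    else:
        if np.ptp(np.concatenate(arrays)) == 0:
            # all values identical: H is 0 by convention, scipy errors out
            result = GroupTestResult(analyte, "kruskal-wallis", 0.0, 1.0, False)
        else:
            res = stats.kruskal(*arrays)
            result = GroupTestResult(analyte, "kruskal-wallis",
                                     float(res.statistic), float(res.pvalue),
                                     flagged=bool(res.pvalue <= SIGNIFICANCE))
        result.posthoc = dunn_test(arrays, labels, adjust=posthoc_adjust)
    return result


def group_location_tests(table: CqTable, panel: GenePanel,
                         subset: Sequence[str] | None = None,
                         posthoc_adjust: str | None = None
                         ) -> list[GroupTestResult]:
    """Test every reference gene in ``subset`` and MeanRef for group effects.

    Two groups use the two-sided Wilcoxon-Mann-Whitney rank-sum test
    (exact distribution for small tie-free samples, normal approximation
    with tie and continuity corrections otherwise); three or more use
    Kruskal-Wallis plus Dunn's pairwise comparisons.  An analyte with
    p <= 0.05 is flagged as unsuitable as-is.
    """
    if len(table.groups) < 2:
        raise ContractError(
            "group tests need >= 2 groups; with a single group only the "
            "descriptive statistics are defined"
        )
    refs = list(subset) if subset is not None else list(panel.reference_genes)
    results = [
        _test_one(table.cq[g], table.group, g, posthoc_adjust) for g in refs
    ]
    meanref = mean_reference_profile(table, panel, subset=refs)
    results.append(_test_one(meanref, table.group, MEANREF, posthoc_adjust))
    return results


def group_tests_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    """Flatten test results into the gene_reference_by_group report table."""
    return pd.DataFrame(
        [(r.analyte, r.test, r.statistic, r.p_value, r.flagged) for r in results],
        columns=["analyte", "test", "statistic", "p_value", "significant"],
    )


# ---------------------------------------------------------------------------
# Descriptive stability statistics
# ---------------------------------------------------------------------------

def _stability_row(values: pd.Series, groups: pd.Series) -> dict[str, float] | None:
    vals = values.dropna()
    if vals.empty:
        return None
    sigma_g = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    mu_g = float(vals.mean())
    sum_mean_sq = 0.0
    sum_sd_sq = 0.0
    for _, idx in groups.groupby(groups, sort=False).groups.items():
        gvals = values.loc[idx].dropna()
        if gvals.empty:
            continue
        mu_i = float(gvals.mean())
        sigma_i = float(gvals.std(ddof=1)) if len(gvals) > 1 else 0.0
        sum_mean_sq += (mu_i - mu_g) ** 2
        sum_sd_sq += (sigma_i - sigma_g) ** 2
    return {
        "Standard.Deviation": sigma_g,
        "sum.mean.square.diff": sum_mean_sq,
        "sum.SD.square.diff": sum_sd_sq,
    }


def descriptive_stability(table: CqTable, panel: GenePanel,
                          subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-analyte pooled SD and the two sum-of-squares spread statistics.

    Rows: each reference gene in ``subset`` plus MeanRef.  The gene mean
    and gene SD are pooled over all samples; each group then contributes
    one squared deviation to each sum.  Lower values indicate a better
    reference gene.  Analytes with no usable values are dropped with a
    warning.
    """
    refs = list(subset) if subset is not None else list(panel.reference_genes)
    if not refs:
        raise ContractError("no reference genes for descriptive statistics")
    rows: dict[str, dict[str, float]] = {}
    for gene in refs:
        row = _stability_row(table.cq[gene], table.group)
        if row is None:
            warnings.warn(f"analyte {gene!r} has no usable values; dropped",
                          stacklevel=2)
            continue
        rows[gene] = row
    meanref = mean_reference_profile(table, panel, subset=refs)
    row = _stability_row(meanref, table.group)
    if row is not None:
        rows[MEANREF] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "analyte"
    return out.reset_index()


# ---------------------------------------------------------------------------
# Leave-one-out evaluation of the reference set
# ---------------------------------------------------------------------------

def leave_one_out_evaluation(table: CqTable, panel: GenePanel) -> pd.DataFrame:
    """Score the full reference set and every leave-one-out subset.

    For each subset the MeanRef group-test p-value and MeanRef
    descriptive statistics are recomputed.  Subsets are ranked with
    non-significant MeanRef group tests (p > 0.05) first, then by
    ascending ``sum.mean.square.diff``: dropping one gene that carries a
    group effect should both rescue the p-value and shrink the spread.
    """
    refs = list(panel.reference_genes)
    if len(refs) < 2:
        subsets = [tuple(refs)]
    else:
        subsets = [tuple(refs)] + [
            tuple(g for g in refs if g != left_out) for left_out in refs
        ]
    rows = []
    for sub in subsets:
        tests = group_location_tests(table, panel, subset=list(sub))
        meanref_p = next(r.p_value for r in tests if r.analyte == MEANREF)
        desc = descriptive_stability(table, panel, subset=list(sub))
        mrow = desc.loc[desc["analyte"] == MEANREF].iloc[0]
        left_out = (set(refs) - set(sub)).pop() if len(sub) < len(refs) else ""
        rows.append({
            "subset": "+".join(sub),
            "left_out": left_out,
            "n_genes": len(sub),
            "meanref_p": meanref_p,
            "meanref_sd": float(mrow["Standard.Deviation"]),
            "sum.mean.square.diff": float(mrow["sum.mean.square.diff"]),
            "sum.SD.square.diff": float(mrow["sum.SD.square.diff"]),
        })
    out = pd.DataFrame(rows)
    out["acceptable"] = out["meanref_p"] > SIGNIFICANCE
    out = out.sort_values(
        by=["acceptable", "sum.mean.square.diff"], ascending=[False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))
    return out
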