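"""Gene-role assignment and the mean-reference pseudo-gene ("MeanRef").

Genes not named as targets are reference candidates; there is no
name-based heuristic.  The MeanRef profile is each sample's arithmetic
mean Cq over a chosen reference subset, with missing values excluded
pairwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import PanelError
from .tabio import CqTable

__all__ = ["GenePanel", "assign_roles", "mean_reference_profile", "MEANREF"]

#: label used for the mean-reference pseudo-gene in every report
MEANREF = "MeanRef"


@dataclass(frozen=True)
class GenePanel:
    """Partition of the gene columns into reference candidates and targets."""

    reference_genes: tuple[str, ...]
    target_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.reference_genes) & set(self.target_genes)
        if overlap:
            raise PanelError(f"genes assigned both roles: {sorted(overlap)}")


def assign_roles(table: CqTable, targets: Sequence[str]) -> GenePanel:
    """Mark ``targets`` as target genes; everything else is a reference candidate.

    An empty target list yields a stability-only panel (all genes are
    reference candidates).  Naming every gene as a target is an error:
    no reference candidates would remain.
    """
    genes = table.gene_names
    unknown = [t for t in targets if t not in genes]
    if unknown:
        raise PanelError(f"unknown target gene(s): {unknown}; table has {genes}")
    target_set = set(targets)
    refs = tuple(g for g in genes if g not in target_set)
    if not refs:
        raise PanelError("all genes named as targets: no reference candidates left")
    ordered_targets = tuple(g for g in genes if g in target_set)
    return GenePanel(reference_genes=refs, target_genes=ordered_targets)


def mean_reference_profile(table: CqTable, panel: GenePanel,
                           subset: Sequence[str] | None = None) -> pd.Series:
    """Per-sample arithmetic mean Cq over the chosen reference genes.

    ``subset`` defaults to all reference candidates and must be a
    non-empty subset of them.  Missing values are excluded pairwise; a
    sample with no usable reference value at all yields NaN and is listed
    in the result's ``attrs["failed_samples"]`` (with a warning) rather
    than silently dropped.
    """
    refs = list(subset) if subset is not None else list(panel.reference_genes)
    if not refs:
        raise PanelError("empty reference subset")
    bad = [g for g in refs if g not in panel.reference_genes]
    if bad:
        raise PanelError(f"subset genes not reference candidates: {bad}")
    profile = table.cq[refs].mean(axis=1, skipna=True)
    profile.name = MEANREF
    failed = [str(s) for s in profile.index[profile.isna()]]
    profile.attrs["failed_samples"] = failed
    if failed:
        warnings.warn(
            f"samples with no usable reference Cq value: {failed}", stacklevel=2
        )
    return profile
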