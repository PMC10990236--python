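"""ANOVA-based reference-gene stability model (NormFinder-style).

The model decomposes log-scale expression (Cq is already a log quantity)
as

    y_igj = alpha_ig + beta_gj + eps_igj,   eps ~ N(0, sigma^2_ig)

for gene i, group g, sample j, where beta_gj is a sample-specific amount
term common to all genes.  Centering each sample across the k candidate
genes removes beta.  From the centered values z the model estimates, per
gene and group:

* the intragroup variance sigma^2_ig, decoupling the bias the centering
  introduces (Var(z_i) = sigma^2_i (1 - 2/k) + sum(sigma^2)/k^2);
* the intergroup difference d_ig (group mean of z minus overall mean),
  shrunk toward zero by an empirical-Bayes factor
  gamma^2 / (gamma^2 + sigma^2_ig / n_g), where gamma^2 is the variance
  of the d's across genes and groups in excess of their sampling noise.

Each gene is then scored:

* ``GroupDif``  = range over groups of the shrunken differences,
* ``GroupSD``   = sqrt(mean over groups of sigma^2_ig),
* ``Stability`` = mean over groups of |d~_ig| + sqrt(sigma^2_ig / n_g),
  the shrunken bias plus the standard error of the group difference.

Lower Stability means more stably expressed.  The model needs k >= 3
candidate genes (the variance decoupling divides by k - 2) and G >= 2
groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from .tabio import CqTable

__all__ = [
    "NormFinderResult",
    "center_by_sample",
    "estimate_intragroup_variance",
    "estimate_intergroup",
    "normfinder_stability",
]


@dataclass
class NormFinderResult:
    """Stability table plus the model internals it was computed from."""

    table: pd.DataFrame  # columns Gene, GroupDif, GroupSD, Stability; sorted
    genes: list[str]
    groups: list[str]
    group_sizes: dict[str, int]
    z: np.ndarray              # genes x samples, sample-centered
    d_raw: np.ndarray          # genes x groups intergroup differences
    d_shrunk: np.ndarray       # shrunken intergroup differences
    sigma2: np.ndarray         # genes x groups intragroup variances
    gamma2: float              # variance of intergroup differences


def center_by_sample(y: np.ndarray) -> np.ndarray:
    """Subtract each sample's mean over the k candidate genes.

    ``y`` is genes x samples.  Centering removes per-sample amount
    effects; each column of the result sums to zero.  Requires k >= 3:
    with fewer genes the downstream variance decoupling is singular.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 2:
        raise ContractError("expected a genes x samples matrix")
    k = y.shape[0]
    if k < 3:
        raise ContractError(f"need >= 3 candidate genes, got {k}")
    if np.isnan(y).any():
        raise ContractError("stability model requires complete Cq values for "
                            "the candidate genes")
    return y - y.mean(axis=0, keepdims=True)


def estimate_intragroup_variance(z: np.ndarray,
                                 group_index: Sequence[int],
                                 n_groups: int) -> np.ndarray:
    """Per-(gene, group) intragroup variance from centered values.

    Centering couples the genes: E[var(z_i)] = sigma^2_i (1 - 2/k)
    + sum_i' sigma^2_i' / k^2.  Summing over genes inverts the coupling,
    giving

        sigma^2_ig = max(0, (s^2_ig - sum_i' s^2_i'g / (k (k-1))) * k/(k-2))

    with s^2_ig the within-group sample variance of z.  Negative
    estimates are clamped to zero.
    """
    z = np.asarray(z, dtype=float)
    k = z.shape[0]
    group_index = np.asarray(group_index)
    sigma2 = np.empty((k, n_groups))
    for g in range(n_groups):
        cols = z[:, group_index == g]
        if cols.shape[1] < 2:
            raise ContractError(f"group index {g} has fewer than 2 samples")
        s2 = cols.var(axis=1, ddof=1)
        sigma2[:, g] = (s2 - s2.sum() / (k * (k - 1))) * k / (k - 2)
    return np.maximum(sigma2, 0.0)


def estimate_intergroup(z: np.ndarray, group_index: Sequence[int],
                        n_groups: int, sigma2: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray, float]:
    """Raw and shrunken intergroup differences and their variance.

    d_ig is the group mean of z minus the gene's overall mean of z; the
    d's sum to zero over genes within each group and (weighted) over
    groups within each gene.  gamma^2 estimates the true spread of the
    d's in excess of sampling noise, on (k-1)(G-1) degrees of freedom;
    each d is then shrunk by gamma^2 / (gamma^2 + sigma^2_ig / n_g), so
    noisier estimates are pulled harder toward zero.
    """
    z = np.asarray(z, dtype=float)
    k = z.shape[0]
    if n_groups < 2:
        raise ContractError("intergroup estimation needs >= 2 groups")
    group_index = np.asarray(group_index)
    n_g = np.array([(group_index == g).sum() for g in range(n_groups)])
    overall = z.mean(axis=1, keepdims=True)
    d_raw = np.empty((k, n_groups))
    for g in range(n_groups):
        d_raw[:, g] = z[:, group_index == g].mean(axis=1) - overall[:, 0]
    noise = sigma2 / n_g[np.newaxis, :]
    gamma2 = max(
        0.0,
        float((d_raw**2).sum()) / ((k - 1) * (n_groups - 1)) - float(noise.mean()),
    )
    if gamma2 == 0.0:
        d_shrunk = np.zeros_like(d_raw)
    else:
        d_shrunk = d_raw * gamma2 / (gamma2 + noise)
    return d_raw, d_shrunk, gamma2


def normfinder_stability(table: CqTable,
                         candidates: Sequence[str] | None = None) -> NormFinderResult:
    """Score candidate reference genes by intra/intergroup stability.

    ``candidates`` defaults to all genes in the table.  Returns the
    Gene/GroupDif/GroupSD/Stability table sorted ascending by Stability
    (most stable first) together with the model internals.
    """
    genes = list(candidates) if candidates is not None else table.gene_names
    unknown = [g for g in genes if g not in table.gene_names]
    if unknown:
        raise ContractError(f"unknown candidate gene(s): {unknown}")
    groups = table.groups
    if len(groups) < 2:
        raise ContractError("grouped stability analysis needs >= 2 groups")
    sizes = table.group.value_counts()
    small = [g for g in groups if sizes[g] < 2]
    if small:
        warnings.warn(f"excluding group(s) with n < 2: {small}", stacklevel=2)
        keep = table.group[~table.group.isin(small)].index
        table = table.subset_samples(list(keep))
        groups = table.groups
        if len(groups) < 2:
            raise ContractError("fewer than 2 usable groups after exclusion")

    y = table.cq[genes].to_numpy(dtype=float).T  # genes x samples
    group_index = np.array([groups.index(g) for g in table.group])
    n_groups = len(groups)
    n_g = np.array([(group_index == g).sum() for g in range(n_groups)])

    z = center_by_sample(y)
    sigma2 = estimate_intragroup_variance(z, group_index, n_groups)
    d_raw, d_shrunk, gamma2 = estimate_intergroup(z, group_index, n_groups, sigma2)

    # |shrunken bias| plus the standard error of the group difference; the
    # SE term is left unshrunken so the intragroup component survives when
    # gamma^2 clamps to zero (otherwise every score degenerates to 0)
    noise = sigma2 / n_g[np.newaxis, :]
    stability = (np.abs(d_shrunk) + np.sqrt(noise)).mean(axis=1)
    group_dif = d_shrunk.max(axis=1) - d_shrunk.min(axis=1)
    group_sd = np.sqrt(sigma2.mean(axis=1))

    out = pd.DataFrame({
        "Gene": genes,
        "GroupDif": group_dif,
        "GroupSD": group_sd,
        "Stability": stability,
    }).sort_values("Stability", kind="mergesort").reset_index(drop=True)

    return NormFinderResult(
        table=out, genes=genes, groups=groups,
        group_sizes={g: int(n) for g, n in zip(groups, n_g)},
        z=z, d_raw=d_raw, d_shrunk=d_shrunk, sigma2=sigma2, gamma2=gamma2,
    )
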