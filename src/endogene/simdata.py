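"""Synthetic Cq tables with known ground truth.

The generator draws from the same additive model the stability analysis
assumes:

    Cq_igj = a_i + d_ig + b_gj + eps_igj

with gene baselines a_i, gene x group effects d_ig, per-sample amount
effects b_gj ~ N(0, tau^2) shared by all genes of a sample, and
heteroscedastic Gaussian noise eps ~ N(0, sigma^2_ig).  Cq is a
log-scale quantity, so Gaussian noise on this scale corresponds to
log-normal variation in expression.  Outliers are injected separately
as shifts expressed in multiples of the affected cell's group SD, so
detection thresholds in SD units translate directly.

Defaults emulate a small clinical RT-qPCR panel: baselines in the
20-26 Cq range, per-sample effects tau = 0.5 Cq (sample loading
differences), technical noise 0.3 Cq, two groups of 20 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError, ParameterError
from .tabio import CqTable

__all__ = ["SimConfig", "OutlierSpec", "GroundTruth", "simulate_cq",
           "inject_outliers"]


@dataclass(frozen=True)
class OutlierSpec:
    """How many cells to corrupt and by how much (in group-SD multiples)."""

    fraction: float = 0.0
    magnitude: float = 5.0
    genes: tuple[str, ...] | None = None  # None: any gene may be hit

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction < 1.0:
            raise ParameterError("outlier fraction must be in [0, 1)")
        if self.magnitude <= 0:
            raise ParameterError("outlier magnitude must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of the additive Cq model."""

    n_genes: int = 6
    group_sizes: tuple[int, ...] = (20, 20)
    baselines: tuple[float, ...] | None = None       # a_i; default 20..26 spread
    group_effects: np.ndarray | None = None          # d_ig, genes x groups
    sample_effect_sd: float = 0.5                    # tau, Cq units
    noise_sd: float | np.ndarray = 0.3               # sigma_ig, Cq units
    outliers: OutlierSpec = field(default_factory=OutlierSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ParameterError("need at least one gene")
        if len(self.group_sizes) < 1 or any(n < 1 for n in self.group_sizes):
            raise ParameterError("every group needs >= 1 sample")
        if self.baselines is not None and len(self.baselines) != self.n_genes:
            raise ParameterError("baselines length must equal n_genes")
        if self.sample_effect_sd < 0:
            raise ParameterError("sample_effect_sd must be >= 0")


@dataclass
class GroundTruth:
    """Realized parameters behind a simulated table."""

    baselines: np.ndarray            # a_i
    group_effects: np.ndarray        # d_ig, genes x groups
    sample_effects: np.ndarray       # b_gj, one per sample (table order)
    noise_sd: np.ndarray             # sigma_ig, genes x groups
    outlier_cells: list[tuple[str, str, float]]  # (sample, gene, shift)


def _expand_noise(noise_sd: float | np.ndarray, k: int, g: int) -> np.ndarray:
    arr = np.asarray(noise_sd, dtype=float)
    if arr.ndim == 0:
        arr = np.full((k, g), float(arr))
    if arr.shape != (k, g):
        raise ParameterError(f"noise_sd must be scalar or shape ({k}, {g})")
    if (arr < 0).any():
        raise ParameterError("noise SDs must be >= 0")
    return arr


def simulate_cq(config: SimConfig) -> tuple[CqTable, GroundTruth]:
    """Draw one Cq table from the additive model; deterministic per seed.

    Groups are labelled G1..GG and samples S001... in group order.  When
    the config carries an outlier spec with a positive fraction, the
    corrupted table is returned and the injected cells are listed in the
    ground truth.
    """
    rng = np.random.default_rng(config.seed)
    k = config.n_genes
    g = len(config.group_sizes)
    n_total = int(sum(config.group_sizes))

    if config.baselines is not None:
        a = np.asarray(config.baselines, dtype=float)
    else:
        a = np.linspace(20.0, 26.0, k)
    if config.group_effects is not None:
        d = np.asarray(config.group_effects, dtype=float)
        if d.shape != (k, g):
            raise ParameterError(f"group_effects must have shape ({k}, {g})")
    else:
        d = np.zeros((k, g))
    sigma = _expand_noise(config.noise_sd, k, g)

    b = rng.normal(0.0, config.sample_effect_sd, size=n_total)
    group_index = np.repeat(np.arange(g), config.group_sizes)
    eps = rng.normal(0.0, 1.0, size=(n_total, k)) * sigma.T[group_index, :]
    cq = a[np.newaxis, :] + d.T[group_index, :] + b[:, np.newaxis] + eps

    sample_ids = [f"S{i+1:03d}" for i in range(n_total)]
    gene_names = [f"Gene{i+1}" for i in range(k)]
    groups = [f"G{gi+1}" for gi in group_index]
    table = CqTable(
        pd.DataFrame(cq, index=pd.Index(sample_ids, name="Sample"),
                     columns=gene_names),
        pd.Series(groups, index=sample_ids, name="Group"),
    )
    truth = GroundTruth(baselines=a, group_effects=d, sample_effects=b,
                        noise_sd=sigma, outlier_cells=[])
    if config.outliers.fraction > 0:
        table, injected = inject_outliers(table, config.outliers,
                                          seed=int(rng.integers(2**31)))
        truth.outlier_cells = injected
    return table, truth


def inject_outliers(table: CqTable, spec: OutlierSpec,
                    seed: int = 0) -> tuple[CqTable, list[tuple[str, str, float]]]:
    """Shift randomly chosen cells by ``magnitude`` x their group SD.

    At most ``fraction`` of each group's samples are corrupted, and each
    group must keep at least 3 clean samples so detection statistics
    remain defined.  Returns the corrupted copy and the list of
    (sample, gene, shift) triples for recall scoring.  The sign of each
    shift is random.
    """
    rng = np.random.default_rng(seed)
    genes = list(spec.genes) if spec.genes is not None else table.gene_names
    unknown = [g for g in genes if g not in table.gene_names]
    if unknown:
        raise ContractError(f"unknown genes in outlier spec: {unknown}")
    cq = table.cq.copy()
    injected: list[tuple[str, str, float]] = []
    for grp, idx in table.group.groupby(table.group, sort=False).groups.items():
        n = len(idx)
        n_out = int(round(spec.fraction * n))
        if n_out == 0:
            continue
        if n - n_out < 3:
            raise ParameterError(
                f"outlier fraction {spec.fraction} leaves fewer than 3 clean "
                f"samples in group {grp!r} (n={n})"
            )
        hit_samples = rng.choice(np.asarray(idx), size=n_out, replace=False)
        for sid in hit_samples:
            gene = genes[rng.integers(len(genes))]
            group_sd = float(table.cq.loc[idx, gene].std(ddof=1))
            if group_sd == 0.0:
                group_sd = 1.0  # degenerate constant group: shift in raw Cq
            sign = 1.0 if rng.random() < 0.5 else -1.0
            shift = sign * spec.magnitude * group_sd
            cq.loc[sid, gene] += shift
            injected.append((str(sid), gene, float(shift)))
    return CqTable(cq, table.group.copy()), injected
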