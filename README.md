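# endogene

Selection and validation of reference (housekeeping) genes for RT-qPCR
studies, as a scriptable Python library and CLI.

Relative quantification by RT-qPCR normalizes a target gene's
quantification cycle (Cq) against reference genes assumed stable across
the studied conditions. That assumption regularly fails — classics such
as *GAPDH* or *ACTB* can vary strongly between tissues and disease
states — and an unstable reference silently biases every downstream fold
change. `endogene` screens a candidate panel measured on the same
samples and conditions and reports which genes (alone or as a set) can
be trusted, then quantifies target-gene differential expression against
the chosen set.

## What it computes

Given a samples × genes table of mean Cq values with a group label per
sample:

* **Per-group outlier handling** — a sample is flagged when its Cq for a
  reference gene (or for *MeanRef*, the per-sample mean over reference
  genes) deviates from its group mean by more than *t* group standard
  deviations (default *t* = 2). Removal is whole-sample and iterative,
  since each removal shrinks the group SD and can expose further
  outliers.
* **Group-difference tests** — Wilcoxon–Mann–Whitney (2 groups) or
  Kruskal–Wallis with Dunn's pairwise z-tests (≥3 groups) per reference
  gene and for MeanRef; a good reference shows *p* > 0.05.
* **Descriptive stability** — per analyte the pooled SD σ_g and two
  spread statistics over the n groups (lower is better):

  `sum.mean.square.diff = Σᵢ (μᵢ − μ_g)²`  `sum.SD.square.diff = Σᵢ (σᵢ − σ_g)²`

* **ANOVA-based stability model** (NormFinder-style) — decomposes Cq as
  gene + sample + group×gene effects, estimates intragroup variances
  σ²_ig and empirically shrunken intergroup differences d̃_ig, and scores
  each gene with Stability = meanᵍ(|d̃_ig| + √(σ²_ig/n_g)); lower means
  more stably expressed. Reported as Gene / GroupDif / GroupSD /
  Stability.
* **Leave-one-out evaluation** — re-scores MeanRef for every
  drop-one-gene subset to show whether excluding a volatile gene rescues
  the reference set.
* **Differential expression** — ΔCq = target Cq − MeanRef, Shapiro–Wilk
  normality per group, t test / ANOVA+Tukey or their nonparametric
  counterparts, and fold change 2^(−ΔΔCq) against a calibrator group.

A synthetic-data generator (`endogene.simdata`) draws Cq tables from the
same additive model with known gene baselines, group effects, per-sample
loading effects, heteroscedastic noise and injected outliers, so every
stage is testable with ground truth.

## Worked example

Simulate a 5-gene, 2×15-sample panel in which `Gene1` carries a 2 Cq
intergroup shift, then analyze it with `Gene5` as the target:

```bash
endogene simulate --genes 5 --groups 2 --n-per-group 15 \
    --effect 2.0 --seed 42 --out demo_cq.csv
endogene analyze --input demo_cq.csv --targets Gene5 \
    --compare G1:G2 --out reports
```

`reports/normfinder.tsv` (sorted most-stable first):

```
Gene    GroupDif        GroupSD         Stability
Gene3   0.4333136305    0.1035068817    0.241006934
Gene2   0.4032286756    0.2321595731    0.2654517111
Gene4   0.5724310274    0.2881798378    0.3668831611
Gene1   1.397415426     0.3118539029    0.7880179415
```

The planted gene lands last with a clearly larger Stability and
GroupDif. The group tests agree — `Gene1` differs between groups
(*p* = 3.7e−05 in `gene_reference_by_group.tsv`) — and the leave-one-out
table ranks the subset without `Gene1` first:

```
rank  subset             left_out  meanref_p  sum.mean.square.diff  acceptable
1     Gene2+Gene3+Gene4  Gene1     0.0606     0.0277                True
2     Gene1+...+Gene4              0.0783     0.0286                True
```

`differential_expression.tsv` then reports the target against the clean
reference mean: ΔΔCq = 0.513, fold change 2^−0.513 = 0.70 (G1 expresses
`Gene5` at ~70 % of the G2 level; recall higher Cq = less transcript),
Welch's t *p* = 4.5e−04 after both groups pass Shapiro–Wilk.

The same workflow is available programmatically via
`endogene.run_analysis(RunConfig(...))` or the individual functions
(`detect_outliers`, `descriptive_stability`, `normfinder_stability`,
`delta_cq`, …).

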