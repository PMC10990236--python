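# Methods

## Data model and input contract

The pipeline's currency is a Cq table: one row per sample, one column
per gene, plus a group/condition label per sample. Role assignment in
input files is strictly positional — first column sample ids, last
column group labels, everything between a gene — so a gene that happens
to be named "Group" is still a gene. Technical replicates are assumed
pre-averaged (one row per sample). Cq values are real numbers in
cycles; empty cells are treated as missing and excluded pairwise from
every group statistic, erroring only when a computation is left with
fewer than two usable values. Text sources take a configurable
delimiter and decimal mark (which must differ); Excel sources carry
typed numbers and ignore both. Validation rejects duplicate sample
ids, empty group labels and non-numeric Cq cells, naming the offending
cell.

## Outlier rule

For each reference gene g and group c the rule flags samples with
|Cq − mean(c,g)| > t·SD(c,g), with t = 2 by default and SD the sample
standard deviation (n−1). In "mean" mode the same rule is applied to
the MeanRef series only, which is more conservative: opposite-signed
errors across genes cancel in the mean. The inequality is strict, so a
constant group (SD = 0) can never flag. Groups with fewer than 3
usable values are skipped with a warning — at n = 2 every point sits at
exactly one SD from the mean, so thresholding is vacuous. Within a
round all flags are computed from the pre-removal statistics and the
flagged samples are removed together, making the result independent of
sample order; rounds repeat until clean or until `max_rounds`
(default 10). Removal is whole-sample: a sample flagged in one gene
leaves all analyses, which is the conservative reading when the flag
indicates a sample-level handling error. Note that 2-SD thresholding
on Gaussian data is aggressive by construction (≈5 % of clean cells sit
outside ±2 SD), so iterative removal on clean data will typically
discard a few samples; raising t or using "mean" mode tempers this.

## Descriptive stability statistics

Per analyte (each reference gene and MeanRef): the pooled sample SD
σ_g, and the two sums over the n groups

    sum.mean.square.diff = Σᵢ (μᵢ − μ_g)²
    sum.SD.square.diff   = Σᵢ (σᵢ − σ_g)²

with μ_g, σ_g the analyte's overall (pooled) mean and SD. Each group
contributes one unweighted term regardless of size. Both sums are
invariant under adding a constant to the analyte and scale as a² under
Cq → a·Cq; sum.mean.square.diff is zero iff all group means coincide.
With one group both sums are identically zero and only σ_g is
informative.

## Group-difference tests

Two groups: two-sided Wilcoxon–Mann–Whitney, exact for small tie-free
samples and the tie/continuity-corrected normal approximation otherwise
(scipy's switching rule). Three or more: Kruskal–Wallis, followed by
Dunn's pairwise z-tests on the joint ranks with the pooled tie
correction Σ(t³−t)/(12(N−1)); pairwise p-values are unadjusted by
default (matching the common R implementation's default) with Holm or
Benjamini–Hochberg available. The "unsuitable" flag fires at p ≤ 0.05:
for a reference gene the desired outcome is the null. Tests run on raw
Cq values; per-sample loading effects therefore inflate their variance,
which is the main reason MeanRef — where independent gene noise
averages out but loading effects do not — is screened alongside the
individual genes.

## The stability model

Candidate genes are modelled as y_igj = α_ig + β_gj + ε_igj with a
sample-specific amount term β shared by all genes and
ε ~ N(0, σ²_ig). Centering each sample across the k candidates removes
β exactly (hence the model's invariance to per-sample shifts) but
couples the genes: E[var(z_i)] = σ²_i(1 − 2/k) + Σσ²/k². Summing the
within-group sample variances over genes inverts this coupling,

    σ̂²_ig = max(0, (ŝ²_ig − Σᵢ' ŝ²ᵢ'g /(k(k−1))) · k/(k−2)),

which requires k ≥ 3 and clamps negative estimates to zero. The
intergroup difference d̂_ig (group mean of z minus the gene's overall
mean) sums to zero over genes within each group by construction. Its
true spread in excess of sampling noise is estimated on the interaction
degrees of freedom,

    γ̂² = max(0, Σ d̂²_ig /((k−1)(G−1)) − mean(σ̂²_ig/n_g)),

and each d̂ is shrunk by the empirical-Bayes factor
γ̂²/(γ̂² + σ̂²_ig/n_g), so noisy differences are pulled toward zero and
shrinkage never inflates. Both estimators were validated by
simulation (mean σ̂² within 10 % of truth at n_g = 200; γ̂² → 0 under
the null), not taken on authority — see `tests/test_normfinder.py` and
`scripts/acceptance.py`.

Scores per gene: GroupDif is the range of d̃ over groups; GroupSD is
√(mean over groups of σ̂²_ig); Stability is the mean over groups of
|d̃_ig| + √(σ̂²_ig/n_g). The second term is deliberately the plain
standard error rather than the γ̂²-shrunken posterior SD: under the
shrunken form every score collapses to exactly zero whenever γ̂² clamps
to zero (which happens in over half of replicates when there is no true
intergroup variation), erasing the intragroup component from the
ranking entirely. With the SE term a gene that is merely noisy — no
group effect at all — is still ranked less stable, which is the
behaviour a reference-gene screen needs. Numerical identity with other
stability-model implementations is not claimed; the model is validated
by ranking recovery: a gene with a 2 Cq intergroup shift ranks least
stable in ~100 % of replicates, a gene with twice the noise SD in
≥ 95 % (k = 6, G = 2, n_g = 50, σ = 0.3). The grouped analysis requires
G ≥ 2; the single-group variant is out of scope.

## Leave-one-out evaluation

The full reference set and every drop-one subset are re-scored on the
MeanRef group test and MeanRef descriptive statistics. Subsets are
ranked with acceptable ones (MeanRef p > 0.05) first, then by ascending
sum.mean.square.diff. Dropping a gene that carries a group effect both
rescues the p-value and shrinks the spread, so that subset should
surface first.

## Differential expression

ΔCq = target Cq − MeanRef per sample; ΔΔCq is the difference of group
means and fold change is 2^(−ΔΔCq) with the second group as calibrator,
giving exact reciprocity FC(A,B)·FC(B,A) = 1. The two-group parametric
test is Welch's t by default — the pooled-variance Student's t is a
flag away — because unequal group variances are the norm in clinical
panels and Welch's test costs essentially nothing when they are equal.
`method="auto"` goes parametric only when every group passes
Shapiro–Wilk at p > 0.05 (and has n ≥ 3, Shapiro's minimum; otherwise
it falls back to nonparametric with a warning). The automatic switch is
a convenience addition; both families are directly selectable.

## Synthetic data

`simdata` draws Cq_igj = a_i + d_ig + b_gj + ε_igj with Gaussian noise
on the Cq scale (Cq is already log-expression, so this is log-normal
expression noise). Defaults emulate a small clinical panel: baselines
spread over 20–26 Cq, per-sample loading effects τ = 0.5 Cq, technical
noise 0.3 Cq, two groups of 20. Outliers are injected as shifts of m ×
the affected cell's group SD with random sign, so detection thresholds
in SD units translate directly; the injector refuses fractions that
leave fewer than 3 clean samples per group. One root seed drives all
draws. The generator omits amplification-efficiency differences,
plate/batch effects and missing-value mechanisms, so passing tests
demonstrate correctness of the statistics under the assumed additive
Gaussian model, not robustness to those real-data artefacts.

## Validation study sizes and choices

The simulation studies in `tests/test_acceptance.py` and
`scripts/acceptance.py` use: 200 tables (k = 4 references, 2×20
samples, σ = 0.3) for outlier recall/specificity; 200 replicates at
n_g = 200 for variance recovery and at n_g = 50 for ranking recovery;
100 replicates (k = 4, 2×15, σ = 0.2) for leave-one-out
discrimination. The leave-one-out study sets the per-sample effect to
τ = 0.1 rather than the generator default 0.5: loading effects do not
cancel in MeanRef, and at τ = 0.5 the standard error of the MeanRef
group-mean difference (√(2(τ²+σ²/k)/n) ≈ 0.19 Cq) is half the 0.375 Cq
MeanRef shift a single 1.5 Cq gene effect induces in a 4-gene set, so
no method could separate the subsets reliably; the study isolates the
gene-driven signal instead. Sign conventions, tie-breaks and degenerate
inputs: stability ties are resolved by input order (stable sort);
constant data yield p = 1 by convention in the omnibus tests; negative
variance estimates clamp to 0; SD = 0 groups produce no outlier flags.

## Known limitations

Raw-Cq group tests conflate loading effects with expression changes
(mitigated but not removed by MeanRef screening); the outlier rule
assumes roughly symmetric within-group distributions; no
efficiency-corrected quantification (Pfaffl) or multi-target FDR
control; no geNorm/BestKeeper statistics; the stability model needs
complete Cq values for the candidate genes (samples with missing
candidate values should be removed first).
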