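# Methods

This note documents the models, statistical procedures and design choices
behind the package, the parameters that matter, and what the synthetic
cohort does and does not establish.

## Cohort model

The synthetic cohort (`mutanome.synthetic`) is a pure function of a
`CohortConfig` and its seed. Defaults describe the emulated study: 42
patients, an expected even split between relapse ("poor" prognosis) and no
relapse ("good"), a minimal follow-up window with administrative censoring
at 60 months, and tumors profiled as paired tumor/adjacent-mucosa samples.

**Proteome and mutations.** One canonical isoform per synthetic gene
(default 300 genes, lengths uniform on 100–700 residues, uniform amino-acid
composition). Per-tumor functional SNV counts are Poisson with mean
`per_tumor_mutation_rate` (default 90, which puts per-tumor medians in the
high 80s to 90s, matching the emulated study's printed 86–98). Genes are
hit proportionally to protein length; positions are uniform along the
protein and the alternate residue uniform over the other 19 — the simplest
exchangeable model, deliberately free of trinucleotide signature structure.
Functional classes are drawn with missense dominating (55%), UTR classes
next, splice/stop rare; a second Poisson stream (half the functional rate)
of non-functional classes (intron, intergenic, ...) exists purely so the
downstream filter has something to remove.

**HLA.** Two HLA-A and two HLA-B alleles per patient, drawn with
replacement from a pool of ten common 4-digit alleles; duplicate draws are
recorded as homozygous. Allele frequencies are not modelled.

**Expression.** Log2-scale values, gene baselines ~N(8, 1.5) (immune panel
~N(10, 0.5)), a shared patient effect (sd 0.2) in both members of a pair,
and residual noise (sd 0.5, `expression_sd`). Two pieces of planted
structure: (i) a per-patient immune-activity factor (sd 1) loads with
weight 0.5 on the *tumor* expression of the presentation genes (HLA-A/B/C,
TAP1, TAP2) and CD8A, coupling antigen presentation to the T-cell
infiltration marker as observed in real tumors; (ii) HLA-A/B/C and CD8A
tumor columns carry an additive shift of −1.0 (`tumor_shift`) relative to
the paired mucosa, while TAP1/TAP2 are deliberately left unshifted — the
paired tumor-vs-mucosa tests should find class I and CD8A down and the
TAPs null. Because the immune factor enters tumor columns only, TAP
tumor−normal differences have extra variance and can drift a few tenths of
a log2 unit in a single 42-patient cohort; this is sampling noise around a
planted zero, not a planted effect.

**Outcomes.** Exponential proportional hazards: the linear predictor
applies `presentation_effect` (default −0.5 per SD of the standardized mean
presentation-gene z-score) and `neoantigen_effect` (default −0.10 per
predicted neoantigen, centered) — protective effects of presentation
capacity and neoantigen load. The baseline hazard is calibrated so the
marginal pre-censoring event fraction approximates `relapse_fraction`
(0.5). The prognosis group label is the realized outcome (relapse = poor),
so planted splits are close to, not exactly, 21/21. Because the hazards
need each patient's neoantigen load, the full epitope pipeline runs inside
the generator; downstream reanalysis therefore recovers exactly the
covariates the outcomes were built from.

## Mutation catalog

The functional filter retains exactly the ten annotation classes listed
above; unknown class strings are dropped with a warning rather than treated
as functional. Burden is counted per tumor at SNV level and as distinct
mutated genes (several SNVs in one gene in one tumor count once, which is
why gene counts are bounded by SNV counts). Group comparison uses a
two-sided Mann–Whitney test, exact when both groups have ≤ 8 tumors and a
tie-corrected normal approximation otherwise. A gene is group-exclusive at
threshold k (default 3, configurable) when mutated in ≥ k tumors of one
group and none of the other; a SNV is recurrent when its exact
gene/position/change appears in ≥ 2 tumors.

## Pathway burden

The per-tumor score divides the tumor's in-set functional SNV count by the
set size; multiple mutations in one set gene all count. Group scores are
**sums** over the group's tumors (so the group score equals the group's
total in-set mutations over the set size); a per-tumor mean is available
via `aggregator="mean"`. The sum was chosen because published group-score
magnitudes for ~100-gene sets over ~21 tumors are compatible with a total
and not with a per-tumor mean. The test statistic is |Δ| with
Δ = score(poor) − score(good), i.e. two-sided.

Significance comes from permuting tumor labels while preserving group
sizes. When the number of distinct assignments is at most 20 000 all of
them are enumerated and the p-value is an exact fraction (no add-one term).
Otherwise Monte-Carlo sampling is used with the add-one convention
p = (1 + #extreme)/(n+1), and n = max(999, ⌈m/α⌉ − 1) so that the smallest
attainable p-value clears the Bonferroni threshold α/m over the m sets
tested (m = 1186 at α = 0.05 gives n = 23 719).

## Interactome

Edges are kept when their confidence score is strictly greater than the
threshold (default 0.72); duplicates keep the maximum score and self-loops
are removed. Betweenness is unnormalized; closeness and eccentricity are
computed within each node's connected component, with closeness defined as
(n_c − 1)/Σd; eccentricity is undefined (reported missing) for isolated
nodes. Genes absent from the network are reported as unmapped, never
zero-filled. The group comparison summarizes each tumor by the mean
centrality of its mapped mutated genes and applies a per-measure
Mann–Whitney test; a pooled per-(tumor, gene) variant is available behind
`aggregation="pooled"` since the aggregation behind published per-measure
p-values is not canonical.

## Neoantigen calling

For a missense mutation at protein position p the wild-type window spans
residues max(1, p−10)..min(L, p+10) (21-mers in the interior, truncated at
termini); the mutant window substitutes the alternate residue. Records
whose annotated reference residue disagrees with the proteome raise
`RefMismatchError` and are skipped, not repaired — canonical isoform only.
All k-mers with k ∈ 8..11 overlapping the mutated residue are enumerated
(38 pairs for an interior mutation in a full window: 8+9+10+11).

The differential-affinity rule is applied per allele: a (peptide, allele)
call is immunogenic iff IC50(mutant) < 50 nM and IC50(wild type) > 500 nM
on the *same* allele — the immunologically standard reading; a cross-allele
mode is available (`same_allele=False`: best mutant IC50 strong while the
wild type is weak on every allele). Boundary comparisons are strict. The
per-tumor neoantigen count is the number of distinct immunogenic mutant
peptides (`count_mode="peptide"`); peptide×allele events and per-mutation
counting are exposed as alternatives because published counts do not state
their deduplication.

`ToyAffinityPredictor` is an explicit test double, not a binding model: it
hashes (peptide, allele) to a uniform deviate and maps it through a
log-normal IC50 (log-median 8.6 ≈ 5.4 µM, log-sd 1.4), with a deterministic
per-allele anchor shifting the log-median by up to ±0.7 so some alleles are
far more permissive than others. The anchors make per-patient loads
overdispersed (zero for some genotypes, >8 for others) the way real
cohorts are. Everything is bit-reproducible across runs and platforms.
External predictors plug in through `TabularPredictor` (NetMHCpan-style
peptide/allele/IC50 tables) or any object with a `predict` method.

The expression-aware variant drops epitopes whose source gene is at or
below a per-gene threshold in the tumor's expression column (default: the
cohort median for that gene, since no canonical cut exists); genes absent
from the matrix keep their epitopes, logged.

## Survival analyses

Kaplan–Meier estimation, the k-sample log-rank test and Cox
partial-likelihood fitting (Efron tie handling, Wald p-values) delegate to
lifelines. "Quartiles" are empirical quartiles of the distribution with
ties broken by stable sample order (group sizes differ by at most one); an
equal-width-bins variant is provided. Constant expression collapses to a
single stratum with a warning. The CD8A high/low stratifier defaults to
the upper quartile — matching a reported cluster of ~13 high expressors in
98 patients — with median and custom quantile rules available; group
boxplot comparisons use Welch's t-test. CMS-stratified analysis repeats
the quartile/log-rank/Cox battery within CMS2–4 and skips any subtype with
fewer than 10 patients (logged), mirroring the exclusion of a 6-tumor
MSI-like CMS1 group in an MSS cohort. Paired tumor-vs-mucosa comparisons
are two-sided paired t-tests on log expression. PCA standardizes the
feature block (neoantigen count + immune panel expression) and fixes signs
so each component's largest-magnitude loading is positive.

## Numerical and reproducibility choices

Every stochastic component draws from `numpy.random.default_rng` seeded
from the configuration; generators use distinct child streams so adding a
stage never perturbs another. Permutation tests compare with a 1e-12 slack
(`|Δ*| ≥ |Δ| − 1e-12`) to keep exhaustive enumeration robust to float
round-off. The pipeline writes a config hash into every output header and
its JSON summary is byte-identical across reruns of the same config.

## Problem sizes

Default analyses run at the emulated study scale (42 patients, 300 genes,
25 gene sets, 999+ permutations per set). Calibration suites use 1000 null
replicates (permutation type-I error), 500-patient cohorts (Cox parameter
recovery), 200 replicates of 98 pairs (paired-t power) and 100 random
graphs of ≤ 12 nodes (centrality versus a brute-force oracle); these sizes
give Monte-Carlo errors small enough for the stated checks while keeping a
full run in the low minutes on one CPU.

## Limitations

The synthetic cohort is exchangeable by construction: no mutational
signatures, no driver genes, no linkage between pathways and outcome, no
correlation structure in expression beyond the planted immune factor, and
an exponential (constant-hazard) outcome model. Passing tests therefore
demonstrate the correctness and calibration of the *procedures* — filters,
scores, tests, survival fits, and end-to-end plumbing — not the biological
conclusions of any particular cohort. The toy affinity predictor has no
peptide chemistry; analyses of real data must use an external class I
binding predictor through the adapter.
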