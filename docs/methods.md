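# Methods

This note documents the models implemented in `isletorigin`, the synthetic
study conditions its tests run under, the numerical choices, and what
passing tests do and do not establish about real data.

## Marker discovery (`array_dm`)

Methylation at each CpG is summarised by the beta value β = M/(U+M) from
the raw methylated/unmethylated array intensities; β ∈ [0,1] estimates the
methylated fraction of molecules at that site. QC removes cross-reactive
probes, SNP-containing probes, and probes whose detection p-value exceeds
0.05. The removal scope for detection failures is ambiguous in practice;
the default drops a probe that fails in *any* sample (conservative), with a
majority-rule alternative (`rule="majority"`).

Each retained CpG is tested islet-vs-control with a two-sided Mann–Whitney
U test — exact null when the combined sample size is ≤ 20 and the data are
tie-free, otherwise the normal approximation with tie and continuity
correction (constant probes return p = 1 by convention). P-values are
adjusted by Benjamini–Hochberg step-up across all tested probes. Markers
require |Δβ| > 0.5 and q < 0.001, where Δβ = mean(islet) − mean(control);
the sign of Δβ among survivors determines direction (positive →
islet-hypermethylated). This sign rule resolves an internal inconsistency
in the usual verbal statement of the threshold (an absolute-value filter
followed by a signed cutoff at the same number). "Top-K" ranking is by
|Δβ| descending, ties broken by ascending q, then probe id; the ranking
criterion is a package choice, since "top" is rarely defined precisely.

## Bisulfite layer (`bisulfite`)

Bisulfite chemistry converts unmethylated C to T while methylated CpG
cytosines are retained. `convert` applies this rule to the top strand of an
amplicon (a reverse-strand assay is represented by the reverse-complement
amplicon); an optional conversion-failure probability retains convertible
Cs at that rate (default 0 — conversion is treated as verified). Calling
counts C (methylated) vs T (unmethylated) per CpG across reads; other
bases are uninformative. Calibration against fully methylated/unmethylated
synthetic controls is two-point linear, (raw − u)/(m − u) clipped to [0,1],
flagged impossible when m ≤ u. Probe-pair validation checks that the two
allele probes of a methylation assay differ at exactly one position by the
bisulfite-discriminated substitution (C/T, or G/A on the opposite strand);
the three printed CHTOP probe pairs all validate. Positions are 1-based
throughout; genomic anchors are opaque labels (assumed hg19, never lifted
over).

## Droplet dPCR (`ddpcr`)

Template molecules partition over ~20,000 droplets as Poisson, so the mean
occupancy is λ = −ln(n_negative/n_total) and concentration = λ/volume. Per
channel, a droplet is negative iff its amplitude is below that channel's
threshold regardless of the other channel (standard multiplex treatment);
"rain" is handled purely by the threshold. Automatic thresholding uses a
two-pass scheme — a provisional mid-range cut, then negative-cluster
mean + 5·sd — and raises an error when the clusters are not bimodally
separated (means closer than twice the summed sds); an all-negative well
therefore requires explicit thresholds. Confidence intervals come from the
Clopper–Pearson binomial CI on the negative fraction propagated through
−ln(·)/volume. All-positive wells raise a saturation error. Defaults:
droplet volume 0.85 nL (8.5e-4 µL, standard for the droplet platform
class; not usually reported), linearity tolerance 25% relative error
(configurable; "linear" is rarely given a printed criterion). The
per-sample classifier feature is the unmethylated fraction u/(u+m), chosen
because it is scale-free.

## Tissue classifier (`tissue_classifier`)

Gaussian Naive Bayes: per class and feature a normal density with class
priors equal to training frequencies and per-class variances floored at
1e-6 (features are bounded fractions and per-class samples are few).
Posteriors are computed in log space. Binary tasks call the positive class
iff its posterior strictly exceeds 0.5 (a tie goes to the negative class);
the 3-class β/α/other task takes the argmax. Four tasks: β cell, islet
(β or α), pancreas (islet or non-islet pancreatic), and β vs α vs other.

Evaluation is stratified 5-fold CV repeated 100 times; folds are stratified
on the finest tissue-class composite so every task sees both classes in
every fold, and the same partition is reused across feature sets and tasks
within a repetition, making per-repetition accuracies paired. Feature sets
({INS}, {CHTOP-817}, {both}) are compared per task with a Friedman test on
the paired accuracies (midranks, tie correction) and a Nemenyi-style post
hoc on mean ranks against studentized-range quantiles — the rank-based
reading of a Tukey-type all-pairs comparison on repeated measures.

## Cohort statistics (`cohort_stats`)

Serum copies/µL of the four species (unmethylated/methylated ×
INS/CHTOP-817) are displayed as log10(x + 1); the offset keeps zero
measurable and the transform monotone, so the rank tests are unaffected by
whether raw or log levels are analysed. Group analysis is a Kruskal–Wallis
omnibus (tie-corrected) followed by many-to-one comparisons of each cohort
against healthy controls. A parametric Dunnett test after a nonparametric
omnibus is internally inconsistent, so the default post hoc is Dunn's
rank-based z on pooled midranks with Šidák adjustment over the g−1
comparisons — the standard behaviour of mainstream statistics packages
when a nonparametric omnibus is selected; a parametric Dunnett on log
levels is available via `method="dunnett"`. Cohort characteristics use
classical one-way ANOVA; an all-identical input returns (F, p) = (0, 1) by
convention.

## Synthetic data (`synthetic_data`)

The generators define the study conditions under which the pipeline is
validated.

**Beta matrices.** Default design 64 islet vs 27 control samples; spiked
CpGs differ by the requested effect in mean beta (half hyper, half hypo),
null CpGs share a per-probe Beta distribution. Per-probe noise is a Beta
distribution parameterised by mean and concentration (default 50), which
keeps draws in [0,1]. 2% of probes receive one detection-p failure;
1% + 1% of the *null* probes are flagged cross-reactive/SNP. Artifact
flags are confined to null probes so that the truth labels mean "genuinely
differential and assayable" — a flagged probe is removed by QC regardless
of its biology, and parameter-recovery sensitivity is measured against
markers the assay could in principle report.

**Tissue panel.** Sixteen profiles: flow-sorted β and α cells (each twice,
untreated and cytokine-treated with identical means — the methylation
pattern is unaltered by cytokine exposure), whole pancreas, and eleven
non-pancreatic tissues. Default means encode the complementary pattern:
every non-pancreatic tissue < 50% INS-unmethylated, adipose and skin at
55–60% INS methylation (and modelled as donor-variable at INS:
concentration 12 at that locus, 100 at CHTOP), skeletal muscle, brain and
heart ≤ 50% CHTOP-methylated with heart strongly so (0.80 unmethylated —
the reported bound is one-sided), β cells hypomethylated at both genes
(CHTOP within the 48–99% range), α cells INS-high but CHTOP-moderate
(0.62), sorted islet preparations tighter (concentration 250) than bulk
tissues. `TissueProfile.concentration` accepts a scalar or a per-marker
dict; the scalar default is 50. Default panel size is 12 samples per
profile (192 samples). These defaults were chosen, once, so the panel
realises the qualitative bounds and the separability structure the
two-marker strategy claims: in two dimensions islet tissue is linearly
separable from everything else, while each single marker has a structural
confuser (α cells sit in β's INS range; heart sits in β's CHTOP range;
adipose/skin INS tails cross the islet INS boundary). At the population
level the two-feature islet classifier makes 0 errors in 64,000 draws
while each single feature errs on every task; at the default panel size
this holds for typical draws (an occasional extreme adipose INS draw can
sit near the boundary).

**Droplet wells.** Occupancy Poisson(conc × 0.85 nL); occupied droplets
draw positive-cluster amplitudes (defaults ~5000 ± 300 over a negative
cluster 1000 ± 200), channels independent. No rain or volume variation is
modelled, so gating on synthetic wells is easier than on real instrument
exports; the Poisson estimator itself is exercised exactly.

**Serum cohorts.** Per-subject levels are log-normal (baseline log10-mean
1.0, log10-sd 0.4 copies/µL) times a per-cohort fold per species. Cohort
sizes mirror the study populations (control 10, FDR 23, T1D 43; lean 32,
obese subgroups 31/31/34/22; sepsis 10 vs 10). Only directions of effect
are reported for the real cohorts, not effect sizes; the default elevated
fold is 8 (a 0.9 log10 shift, ~2.3 sd), the magnitude required for the
smallest study (n = 10 controls) to reach rank-test significance reliably —
a fold of 3, for example, yields only ~40% detection at these sample
sizes. T1D and FDR are elevated in all four species, sepsis in the
methylated species only, obese subgroups in uINS, uCHTOP-817 and mINS but
not mCHTOP-817.

**Bisulfite reads.** Per-read Bernoulli methylation per CpG, conversion via
the bisulfite layer; no sequencing errors beyond the CpG substitution are
simulated.

## What passing tests show

Tests validate the *machinery* — estimator correctness against closed
forms and enumeration oracles, parameter recovery at the study's design
sizes, directional reproduction of the cohort effects under the stated
generative model. They do not validate the biological claims: real arrays
have probe-level artifacts beyond the flags modelled here, real droplet
exports have rain and volume drift, real tissue panels are smaller and not
Beta-distributed, and real serum effect sizes are unknown. Simulation
sizes (e.g. 100 wells, 100 CV repetitions, 100 cohort seeds, 20 null-array
seeds) were chosen to keep the full suite under a minute of compute while
leaving Monte-Carlo margins well inside the asserted tolerances.

## Reproducibility

Every generator takes an explicit seed; the pipeline derives one substream
per stage from the top-level seed via fixed spawn keys, so enabling or
disabling a stage never perturbs another stage's draws, and rerunning a
config reproduces every artifact byte-for-byte (verified by SHA-256 in the
run manifest).
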