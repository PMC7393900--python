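# isletorigin

Detecting islet β-cell death from circulating cell-free DNA (cfDNA) is a
central goal in diabetes research: dying cells shed DNA fragments whose CpG
methylation pattern carries a tissue-of-origin signature. The insulin gene
(*INS*) is unmethylated almost exclusively in β and α cells, but several
non-pancreatic tissues (notably adipose and skin) are only ~55–60%
methylated there, so unmethylated *INS* alone is not specific for islet
death. An intragenic CpG in *CHTOP* (chr1:153,610,817, "CHTOP-817") shows
the complementary pattern — hypomethylated in islet cells and in skeletal
muscle, brain and heart, but not in adipose or skin — so the two markers
together can identify the islet as the source of a cfDNA signal.

`isletorigin` implements the full analysis chain behind this two-marker
strategy, plus a synthetic-data layer that generates every input, so each
stage is testable without access to array repositories, dPCR instrument
exports, or clinical sera:

| module | what it does |
| --- | --- |
| `synthetic_data` | generators for beta matrices, tissue panels, droplet wells, serum cohorts, bisulfite reads |
| `array_dm` | CpG marker discovery: beta = M/(U+M), QC filters, Mann–Whitney U + Benjamini–Hochberg, \|Δβ\| > 0.5 & q < 0.001 selection, hyper/hypo calls, top-K ranking |
| `bisulfite` | in-silico bisulfite conversion, per-CpG methylation calling, two-point control calibration, allele-probe validation |
| `ddpcr` | droplet digital PCR: 2-D gating, Poisson quantification λ = −ln(n_neg/n_tot), concentration = λ/volume, unmethylated fraction u/(u+m), dilution linearity |
| `tissue_classifier` | Gaussian Naive Bayes tissue-of-origin over four tasks, 5-fold CV × 100 repetitions with shared folds, Friedman + Nemenyi feature-set comparison |
| `cohort_stats` | serum cohort statistics: Kruskal–Wallis, Dunn's many-to-one vs healthy controls (Šidák), one-way ANOVA for cohort characteristics |
| `pipeline` / `cli` | one-config orchestration with a seeded substream per stage and a hashed run manifest |

## Worked example

Run the whole chain from one seed:

```bash
isletorigin run --config run.yaml     # or, in Python:
```

```python
from isletorigin import pipeline
cfg = pipeline.RunConfig(seed=7, outdir="demo_run", cv_reps=100)
pipeline.run_all(cfg)
print(open("demo_run/summary.txt").read())
```

which prints (numbers produced by the code above):

```
marker discovery: 2117 probes tested, 97 hypermethylated, 100 hypomethylated
dPCR quantification: 2 wells, 2 channels each
classification accuracy (%, task x feature set):
feature_set  CHTOP817   INS  INS+CHTOP817
task
beta             92.6  96.2          99.9
celltype         85.6  97.8         100.0
islet            87.1  96.8         100.0
pancreas         82.1  85.6          92.7
cohort study 't1d': flagged ['u_CHTOP817:FDR:higher', 'u_CHTOP817:T1D:higher', ...]
cohort study 'sepsis': flagged ['m_CHTOP817:sepsis:higher', 'm_INS:sepsis:higher']
```

Reading the output: the simulated array experiment (64 islet vs 27 control
samples, 200 spiked CpGs among 2,200) recovers 197 of the 200 true markers
at |Δβ| > 0.5 and q < 0.001 (three are lost to detection-p QC). On the
tissue panel, either marker alone misclassifies some tissues, but the
two-feature Naive Bayes separates islet from non-islet tissue perfectly —
the panel's headline property. In the simulated serum studies, new-onset
T1D and autoantibody-negative first-degree relatives are flagged elevated
in all four DNA species, whereas sepsis elevates only the methylated
(non-tissue-specific) species.

Individual stages are also exposed as subcommands: `isletorigin simulate`,
`discover`, `quantify`, `classify-eval`, `cohorts` (see `--help`).

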