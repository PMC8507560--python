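# telorisk

Telomere-maintenance event calling and metastatic-risk modeling for
pheochromocytoma/paraganglioma (PPGL) cohorts.

About 15–20% of PPGL patients develop metastatic disease, and few molecular
markers predict who. Reactivation of telomere-maintenance machinery — TERT
upregulation, ATRX loss of function, and, as recently proposed, NOP10
overexpression — marks tumors at high risk of progression. `telorisk`
implements the full analysis chain that turns a targeted expression panel of
29 telomere-maintenance genes ("telomerome") plus orthogonal molecular assays
into per-patient risk calls, for computational biologists who want to run,
stress-test or extend this kind of marker screen. Because patient-level data
for such studies are not publicly deposited, the package ships a
synthetic-cohort generator with planted ground truth so every stage is
verifiable end to end.

## What it computes

**Expression processing** (`telorisk.counts`) — amplicon counts are randomly
down-sampled without replacement to 170k mapped reads (multivariate
hypergeometric), depth-filtered (total reads and ≥750 mean reads/amplicon),
converted to log2CPM with a 0.5 pseudocount, median-centered per sample, and
FFPE/frozen batch-adjusted. TERT expression positivity uses its three probes:
positive iff every probe has ≥3 raw counts and the probe mean is ≥4.

**Outlier calling** (`telorisk.events`) — per gene, boxplot fences are
estimated on the non-metastatic reference cohort with ≥8 years of follow-up:

    lower = Q1 − 1.5·IQR,  upper = Q3 + 1.5·IQR

(quartiles by linear interpolation). Samples strictly beyond a fence are
low/high expression outliers.

**Molecular event integration** — per sample,

* `tert_event` = TERT expression reactivation ∨ promoter hotspot mutation
  (chr5:1,295,228 / 1,295,250 C>T) ∨ promoter UTSS hypermethylation (mean
  methylation over the five UTSS CpGs ≥ 16.1%, from bisulfite C/T read
  counts; `telorisk.methylation`) ∨ 5p copy-number gain (score ≥ 4 frozen /
  ≥ 8 FFPE);
* `atrx_event` = low-expression outlier ∨ loss-of-function mutation;
* `nop10_event` = high-expression outlier.

**Candidate screening** (`telorisk.screening`) — per-gene outlier frequencies
compared between metastatic and reference groups with a two-sided Fisher
exact test, Bonferroni-corrected over the 29-gene panel (α = 0.05).

**Risk models** (`telorisk.risk`) — univariate and stepwise
(LR entry α = 0.05 / removal α = 0.10) logistic regression; ROC/AUC by the
Mann–Whitney statistic with a Hanley–McNeil confidence interval (for a
dichotomous marker AUC = (sensitivity + specificity)/2); time to progression
(days from primary surgery to first confirmed metastasis, non-metastatic
patients censored at last follow-up) by Kaplan–Meier, log-rank, and a
single-covariate Cox proportional-hazards fit (Newton–Raphson, Breslow ties).

**Q-FISH quantification** (`telorisk.qfish`, `telorisk.render`) — nucleus
segmentation (Otsu), telomere spot detection (top-hat + robust threshold),
per-nucleus mean telomere intensity as length proxy, P10/P90 short/long
classification against a reference condition, and PML–telomere (APB)
colocalization — validated against a synthetic ground-truth image renderer.

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
cohort (63 metastatic / 45 long-follow-up reference / 20 short-follow-up /
5 aggressive samples) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py      --seed 1
python analysis/02_normalize_expression.py --seed 1
python analysis/03_call_events.py
python analysis/04_screen_candidates.py    --seed 1
python analysis/05_risk_models.py
python analysis/06_qfish_quantification.py --seed 1
```

With seed 1 this prints (abridged):

```
candidate genes after Bonferroni (+forced ATRX): ['ATRX', 'FBXO4', 'NOP10', 'TERT']
stepwise_selected: ["tert_atrx", "nop10"]
auc: tert_atrx 0.784 [0.699, 0.869] | all_three 0.863 [0.796, 0.931]
ttp: hazard_ratio 16.38 [8.59, 31.24], log-rank p 1.10e-25
adding NOP10 to the TERT/ATRX classifier moved the AUC from 0.784 to 0.863
```

Reading: the screen recovers exactly the three genes that carry planted
outlier enrichment (TERT, NOP10, FBXO4; ATRX is carried as a forced
candidate on prior evidence); stepwise selection keeps the TERT/ATRX and
NOP10 markers and drops SDHB and FBXO4, which add no conditional
information; and the three-marker classifier beats the two-marker one, with
event-positive patients progressing much faster. The cohort-level hazard
ratio exceeds the per-patient planted value by construction — see
`docs/methods.md` for why.

A `telorisk` command-line interface exposes each stage for external TSV
inputs (`telorisk simulate|normalize|methylation|call-events|screen|model|
qfish-render|qfish`); run `telorisk --help`.

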