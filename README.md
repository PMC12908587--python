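# gmadapt

Analysis pipeline linking moderate-exercise response to gut-microbiome
structure and metabolic adaptation, exercised end-to-end on a synthetic
cohort generator with planted, recoverable effects.

The package covers:

- **`gmadapt.synth`** — synthetic study generator: participant cohort with
  planted responder labels, whole-room-calorimetry gas traces, doubly-labeled-
  water (DLW) isotope records (exact inverse of the energetics model), a
  random species phylogeny, and pre/post logistic-normal relative-abundance
  tables with planted predictor species, a responder beta-dispersion
  contrast, and copula-coupled Shannon-diversity/adaptation correlations.
- **`gmadapt.energetics`** — RMR from 60-minute gas traces (Weir equation,
  final-20-minute window), TDEE from DLW records (dilution spaces, two-point
  elimination, RQ 0.86), FFM-normalised energy expenditure, and the
  metabolic-adaptation statistic (measured minus body-composition-predicted
  change in energy expenditure).
- **`gmadapt.response`** — responder classification
  ((ΔFFM − ΔFM) > 0, strict) and baseline balance tests (Fisher exact,
  exact Wilcoxon rank-sum, BH FDR).
- **`gmadapt.diversity`** — Shannon, Faith's PD, Bray–Curtis, weighted
  UniFrac, PCoA (Gower double centering), PERMANOVA, a beta-dispersion
  homogeneity test, and centroid-distance comparisons.
- **`gmadapt.screen`** — abundance/prevalence species filter and a
  10-repeat 3-fold cross-validated univariate logistic AUROC screen with
  Mann–Whitney p-values, bootstrap CIs, BH FDR, plus an L1-regularised
  multivariate check and predictor-group AUROC comparison.
- **`gmadapt.stats`** — shared exact statistics: Wilcoxon rank-sum and
  signed-rank with full exact null distributions for small n, Fisher exact
  2×2, Pearson correlation with t-based p, Benjamini–Hochberg q-values, and
  the diversity/adaptation association battery.

## CLI

The console script `gmadapt` exposes each stage and an end-to-end driver:

```sh
gmadapt run-all --out run/ --seed 1 --nperm 999
```

which executes simulate → energetics → classify → diversity → screen →
associate and writes plain-text outputs (CSV/TSV/JSON/Newick) plus a run
manifest under `run/`. Individual stages:

```sh
gmadapt simulate   --out inputs/ --seed 1
gmadapt energetics --traces inputs/traces --dlw inputs/dlw.csv \
                   --cohort inputs/participants.csv --out energetics/
gmadapt classify   --cohort energetics/cohort_energy.csv --out response/
gmadapt diversity  --table inputs/abundance.tsv --tree inputs/tree.nwk \
                   --meta inputs/sample_meta.csv --metric wuf \
                   --nperm 9999 --seed 1 --out diversity/
gmadapt screen     --table inputs/abundance.tsv --meta inputs/sample_meta.csv \
                   --labels response/labels.csv --seed 1 --out screen/
gmadapt associate  --alpha diversity/alpha_diversity.tsv \
                   --meta inputs/sample_meta.csv \
                   --energy energetics/cohort_energy.csv --out associations/
```

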