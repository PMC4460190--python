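# molo

Repopulation-weighted single-cell analysis for resolving functional
heterogeneity in sorted stem-cell populations.

Every hematopoietic stem-cell (HSC) sorting strategy isolates a mix of
genuine long-term HSCs and contaminating cells, and different strategies
barely share surface markers.  `molo` implements the computational route
around that problem: if the true HSCs inside each gate share one molecular
program, they should appear — in a 2D map of single-cell qPCR profiles —
as a single homogeneous region populated by the strategies *in proportion
to their published repopulation probabilities*.  The package finds that
molecularly overlapping (MolO) population, characterizes it, transfers a
per-cell MolO score to single-cell RNA-seq with a random-forest
classifier, derives score-correlated gene signatures, and links index-sort
surface phenotype to single-cell transplant outcomes through the SuMO
score.  It is aimed at groups combining index sorting, single-cell
expression and single-cell functional assays, in blood or in other stem
cell systems (a mammary colony variant is included).

## The core statistic

For cell *i* with k-nearest-neighborhood strategy composition
c<sub>i</sub> on the t-SNE map, and normalized repopulation weights
w<sub>s</sub> = p<sub>s</sub> / Σ<sub>s'</sub> p<sub>s'</sub>,

  d<sub>i</sub> = JSD(c<sub>i</sub>, w)   (Jensen–Shannon divergence, nats)

is ranked within a permutation null of the strategy labels; cells at or
below the alpha-quantile (default 0.95) are MolO, remaining weighted-
strategy cells are NoMO.  Downstream: Wilcoxon/BH differential genes and
index markers, ERCC-calibrated CV² = a1/μ + a0 technical-noise fit with
chi-square variable-gene calling, random-forest MolO scores in [0, 1],
total-least-squares SuMO axis, ≥1% donor-WBC repopulation calls with
alpha/beta/gamma/delta lineage-bias subtypes, and single-hit Poisson
limiting-dilution frequencies with likelihood-ratio CIs.

## Worked example

The package ships a synthetic-data generator that emulates all five input
kinds with a planted MolO state (see `docs/methods.md` for the generative
model).  The full chain, from a shell:

```
molo --seed 1 --out-dir run simulate
molo --seed 1 --out-dir run qpcr
molo --seed 1 --out-dir run embed
molo --seed 1 --out-dir run molo
molo --seed 1 --out-dir run classify
molo --seed 1 --out-dir run hvg
molo --seed 1 --out-dir run signature
molo --seed 1 --out-dir run sumo
molo --seed 1 --out-dir run transplant
molo --seed 1 --out-dir run mammary
```

prints, stage by stage:

```
simulated 1050 qPCR cells, 92 RNA-seq cells, 29 transplanted mice, 960 mammary wells
retained 43 analysis genes across 1050 cells
embedded 1050 cells
597 MolO / 453 NoMO cells; 36 differential genes
classifier on 19 shared variable genes; 10-fold CV accuracy 0.895 ± 0.097
26 variable genes (a1=1.025, a0=0.0001 on 32 spike-ins)
MolO signature: 20 positively / 4 negatively correlated genes at FDR 0.1
embedded 121 cells jointly; SuMO signature: 20+ / 1- genes
15/29 mice repopulated; frequency 1 in 1.4 (95% CI 1 in 1.0 .. 1 in 2.4)
colony-enriched cluster 1; mean CFE fold 2.15
```

Reading this: the 1,050 simulated panel cells (5 strategies × 210) yield
43 analysis genes after housekeeper/exclusion removal (48 − 3 − 2); the
weighted neighborhood search labels 597 cells MolO, of which 36 of 43
genes separate MolO from NoMO at FDR 0.05; the classifier trained on the
19 panel genes that are also variable above ERCC technical noise
(slope a1 ≈ 1 confirms near-Poisson spike-in behavior) generalizes with
~0.90 cross-validated accuracy and scores the 92 RNA-seq cells; the joint
marker map of 92 sequenced + 29 transplanted cells gives SuMO scores whose
gene signature largely overlaps the MolO one; 15 of the 29 single-cell
transplants repopulate (the simulated truth), giving a per-cell frequency
estimate near 1 in 2; and the mammary variant recovers its planted
EpCAM-high/SSC-low colony-forming cluster at a 2.15-fold colony-forming
efficiency.  Every output lands in `run/` as TSV/JSON next to a
`manifest.json`; re-running with the same seed reproduces every file byte
for byte.

The same steps are available as library calls (`simulate_qpcr`,
`delta_ct_normalize`, `embed_tsne`, `identify_molo`,
`train_molo_classifier`, `fit_technical_noise`, `fit_sumo_axis`,
`limiting_dilution`, `mammary_pipeline`, ...) — see the module docstrings
under `src/molo/`.

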