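# primmus

Quantitative analysis of FACS-sorted cell-cycle and intra-mitotic
proteomes: ergodic timing of sorted fractions, exponential
protein-accumulation modelling, SILAC/TMT quantitation, significance
screening for cell-cycle-regulated proteins, and phosphosite dynamics
(early risers, CDK motifs). The whole pipeline is exercisable end to end
through a built-in synthetic-data generator, so no external data download
is needed to run or test it.

## The problem

Sorting an asynchronous culture by flow cytometry into cell-cycle
fractions (G1, S, G2, M) — or, with H3S28ph/cyclin A immunostaining, into
intra-mitotic sub-stages (prophase Pro, prometaphase PM1/PM2, anaphase
Ana) — and quantifying each fraction by mass spectrometry against an
asynchronous internal standard yields relative protein abundances per
fraction. Turning those into *temporal* statements needs two pieces of
model:

**Ergodic timing.** In steady-state exponential growth, cell-cycle age
`t` (fraction of the division time; `t = 0` newborn, `t = 1` division)
follows the density

```
f(t) = 2 ln2 · 2^(−t),    F(t) = 2 (1 − 2^(−t)),
```

because newborn cells are twice as frequent as dividing ones. Inverting
the CDF converts a cumulative phase frequency `F` into a population-average
cell-cycle position `t(F) = −log2(1 − F/2)`. With per-cell content doubling
exponentially (`y = e^(m t)`, `m = ln 2`), the expected sorted-fraction /
asynchronous-standard ratio at position `t` is `2^t / (2 ln2)`.

**Selection and dynamics.** Cell-cycle-regulated candidates are screened
by the max/min fold change of the replicate-median profile, cut at
`median + 1.96·sd` of the log2 fold distribution (a ~95% band), with a
one-way ANOVA (interphase design) or a positive inter-replicate Pearson
correlation (mitotic design) as second criterion; profiles are k-means
clustered, degradation clusters are agglomerated by their trough sub-stage,
and phosphosites that rise already in the G2-enriched fraction and peak in
M are classified as "early risers" and tested for CDK-motif
([S/T]-P-x-[K/R]) enrichment with Fisher's exact test.

## Worked example

```sh
python analysis/01_ergodic_timeline.py
```

```
Cell-cycle positions (fraction of division time):
   phase     t  hours
 newborn 0.000  0.000
      G1 0.160  3.841
       S 0.567 13.609
      G2 0.889 21.335
       M 0.971 23.314
division 1.000 24.000
```

From measured NB4 cumulative phase frequencies (21/65/92/98% for
G1/S/G2/M) and a 24 h doubling time, the G1-sorted population sits on
average at 16% of the cycle (~3.8 h post-division), S at 57%, G2 at 89%,
M at 97%. The model ratio `2^t/(2 ln2)` at the G1 position is 0.81 — a
sorted G1 fraction mixed 1:1 by cell number with an asynchronous standard
is expected to show a median SILAC ratio just above 0.8, since G1 cells
are smaller than the population average.

```sh
python analysis/04_mitotic_degradation.py --seed 0
```

```
Merged matrix: 2060 proteins x 12 (fraction, replicate) columns
Fold cutoff 1.77 (z = 1.96); 62 significant (0 rescued from reproducible missingness)
Trough groups (earliest fraction with decreased abundance):
  PM1: 30 proteins (65%)
  PM2: 8 proteins (17%)
  Ana: 8 proteins (17%)
Agreement with planted trough labels: 1.00
```

On the synthetic mitotic design (2,000 unregulated proteins plus 60
planted degradation targets across two SILAC replicates and one 6-plex
TMT replicate), the data-derived fold cutoff lands near 1.8-fold, the
screen recovers the planted proteins, and k = 12 clustering followed by
trough agglomeration assigns them to the correct sub-stage — the
cyclin-A-like prometaphase group, the CycA-negative prometaphase group,
and the cyclin-B-like anaphase group (residual ~30% of prophase levels).

The other drivers: `analysis/02_interphase_accumulation.py` (per-fraction
ratio distributions and the exponential growth fit) and
`analysis/03_phospho_dynamics.py` (residue/motif frequencies, k = 6 site
clustering, early-riser classification and CDK-motif enrichment). A
`primmus` CLI exposes the same stages (`simulate`, `timeline`,
`normalize`, `select`, `cluster`, `profile`, `run-interphase`,
`run-mitotic`).

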