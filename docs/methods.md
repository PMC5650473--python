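# Methods

## Ergodic timing of sorted fractions

The timing model assumes steady-state exponential growth with negligible
cell death and symmetric division. Under those assumptions the cell-cycle
age density is `f(t) = 2 ln2 · 2^(−t)` on `t ∈ [0, 1]` (age as a fraction
of the division time), its CDF is `F(t) = 2(1 − 2^(−t))`, and the inverse
`t(F) = −log2(1 − F/2)` maps a cumulative flow-cytometry phase frequency
onto the cell-cycle position of that phase's *upper cumulative boundary*.
The boundary convention matters: it is what reproduces the published
positions 0.16/0.57/0.89 from the 21/65/92% inputs at printed precision,
and it is not the within-phase mean age. The M-phase input of 98%
transforms to 0.97; the conventionally quoted 0.98 is consistent with the
inputs being replicate means rounded at the percent level (a 1% shift in
`F` near 1 moves `t` by ~0.01). The implementation reports the computed
0.97 and does not adjust the formula.

With per-cell content doubling over the cycle, a cell of age `t` carries
`2^t` relative content units and the asynchronous population mean is
`∫ 2^t f(t) dt = 2 ln2 ≈ 1.386`. The expected sorted-fraction /
asynchronous-standard ratio is therefore `2^t / (2 ln2)`: 0.81 at the G1
position, 1.0 at `t = log2(2 ln2) ≈ 0.47`, 1.44 at division.

## The synthetic generator

The generator emulates the measurement chain of a sorted-fraction
proteomics experiment; it is the package's test bed and defines the
conditions under which every downstream claim is validated.

* **Population.** Ages are drawn by inverse-CDF sampling from `f(t)`;
  the intra-mitotic design samples ages conditional on the M window.
  Default 50,000 cells per sort (20,000 in the test-suite runs, where
  gate-mean Monte-Carlo error is already well below measurement noise).
* **Trajectories.** Six per-protein classes: bulk exponential
  (`2^t`, exact doubling), histone-like (doubles linearly across the S
  window, flat afterwards, tracking DNA), mitotic-peaking (logistic rise
  to 8-fold late in the cycle, AURKA-like), prometaphase- and
  anaphase-degraded (constant per cell — mitotic synthesis shut-off —
  with a linear drop to a residual of 0.4 / 0.3 completing at the PM1,
  PM2 or Ana boundary; cyclin-A/RRM2-like and cyclin-B-like), and
  constant-per-cell (stress-response-like). All parameters are
  overridable per trajectory.
* **Sorting.** Interphase gates sit at the ergodic boundary positions
  (the last gate extended to `t = 1`); the four mitotic sub-stages are
  ordered, equal-width sub-intervals of the M window, since no numeric
  within-M timings are published. Gate purity (default 0.96) is
  *composition* purity: each sorted gate contains that fraction of
  correct-phase cells, with contaminants drawn from adjacent phases and
  surplus cells left uncollected.
* **Readout.** A gate's SILAC ratio is the mean per-cell abundance over
  its cells divided by the mean over the asynchronous standard
  population — equal-cell-number 1:1 mixing. Note this gate *average*
  differs from the boundary-position value: for bulk proteins the full
  G1 gate averages to ~0.77 while the boundary value is 0.81. The
  `expected` simulation mode instead places each fraction exactly at its
  timeline position; growth-fit validation uses that mode because the
  quantity under test is the timeline itself.
* **Noise and missingness.** Measurement noise is multiplicative
  lognormal with CV 0.15 (chosen to match the scale of reported
  technical variability of the protocol, s.d. ≈ 0.15 on log2 ratios, not
  fitted). Dropout is missing-completely-at-random per protein and MS
  run (each fraction × replicate is one run) at rate 0.05 by default; an
  abundance-dependent mode (logistic in log-abundance) emulates
  data-dependent acquisition. Missing values are NaN, never zero.
* **TMT.** Reporter intensities are the true relative signals,
  ratio-compressed as `observed ratio = true ratio^c` anchored at the
  row geometric mean (`c = 1` by default, i.e. no compression, matching
  synchronous-precursor-selection acquisition), mixed through a
  column-wise isotope-impurity matrix (default ±1 channel spill of 3%;
  lot-specific matrices are a config input), and scaled by 10^6.
* **Phosphosites.** Planted classes early riser (G1 ≤ S ≤ G2 < M with
  G2 elevated ~3-fold; windows enriched 70% for the full CDK consensus;
  peak 10-fold), late riser (flat until M, peak 5-fold) and flat.
  Residue identities are drawn at the published frequencies
  (83.2/15.8/1.0% S/T/Y); background windows are proline-directed at
  35%. Early risers peak higher than late risers, mirroring the observed
  higher mitotic ratios of high-CDK-propensity sites.

What the generator does **not** emulate: peptide-level effects (missed
cleavages, modification artefacts, razor-peptide ambiguity), inter-protein
abundance correlation, batch effects between replicates, or cell-size
heterogeneity within a phase. Passing tests therefore demonstrate the
correctness and operating characteristics of the *procedures* under the
stated noise model, not performance on any real dataset; dataset-scale
published counts (numbers of proteins, sites, or candidates) are not
reproduced here and are not targets.

## Quantitation conventions

Ratios are stored in linear space; log2 transforms happen at analysis
time. Isotope-impurity correction solves the full linear system
`M · true = observed` per protein (exact inversion rather than one-pass
subtraction; the two differ negligibly at few-percent impurity but
inversion is exactly testable), clamping negative solutions to zero with
a flag. Reporter sum-normalisation makes rows sum to exactly 1;
referencing to prophase (TMT) or to G1 per replicate / prophase of
replicate 1 (SILAC) makes the reference exactly 1 and is idempotent.
Rows lacking their reference are marked missing and logged, never
silently dropped. The SILAC and TMT streams merge by outer join on the
protein identifier with source-tagged replicate columns.

## Selection procedure

Max/min fold changes are computed on the replicate-median profile,
complete cases only. The cutoff is `2^(median + z·sd)` of the log2 folds
with `z = 1.96`, applied one-sided upward (folds are bounded below by 1,
so the lower band never selects). On the default synthetic mitotic
design the realised cutoff is ~1.8-fold. No multiple-testing correction
is applied to the ANOVA p-values by default (the 0.05 cutoff is a
screening convention); BH-FDR is available via configuration. The
replicate-correlation criterion is Pearson on log2 profiles, passing on
at least one positive pair (a strict all-pairs mode is available). The
missing-value rescue rule is operationalised as: missing in exactly one
fraction, the same fraction in every replicate, quantified everywhere
else; rescued proteins join the candidate list but are excluded from
clustering.

A note on the null behaviour of the Z cutoff: the log2 max/min fold is a
*range* statistic and right-skewed, so the fraction of null proteins
beyond `median + 1.96·sd` is ~4.4% (by Monte-Carlo of the construction at
CV 0.15 with 3 replicates), not the 2.5% a normal distribution would
give. The acceptance tests check the measured null exceedance against
that Monte-Carlo value. Planted-recovery operating characteristics
(sensitivity ≥ 0.9, false-discovery proportion ≤ 0.1) are evaluated as
pooled counts across a fixed seed panel, since per-seed proportions on
~60 hits carry binomial noise of several percent.

## Clustering and phosphosite dynamics

Profiles are clustered complete-case on log2, per-row mean-centred
values with k-means (k-means++ seeding, 50 restarts, fixed seed; rows
sorted by identifier before fitting and clusters relabelled in
lexicographic centroid order, making the partition order-invariant and
deterministic). The elbow of the within-groups sum-of-squares curve is
taken as the k with maximum second difference; the published run
configurations (k = 12 for mitotic protein profiles, k = 6 for
phosphosite profiles) are defaults in the corresponding drivers.
Degradation clusters are agglomerated by trough: clusters whose centroid
maximum is not at Pro are removed as increasing, the rest are labelled
by the earliest fraction whose centroid falls below 0.75 of the Pro
value (the threshold is configurable; planted residuals of 0.3-0.4 sit
far below it).

Early risers: among significant, M-peaking sites, a site is early if its
mean log2 G2 ratio exceeds the G1/S baseline mean by 2 baseline standard
deviations (computed across baseline fractions and replicates). No
numeric rule is published for "significantly increased in G2"; this
operationalisation is validated against simulator ground truth (balanced
accuracy ≥ 0.9 at CV 0.15 with 2 replicates) and is configuration-exposed.
The pipeline's significance screen for sites is a simple 2-fold
max-change filter. Motif flags are exact string tests on the 15-mer
window (centre S/T with +1 P; full CDK additionally +3 K/R); enrichment
is the two-sided Fisher exact test with optional BH correction.

## Numerical choices and degenerate inputs

The exponential growth fit is least squares of ln(y) on t with the
intercept fixed at 0, because the model is `y = e^(mt)` with `y(0) = 1`
(a newborn cell defines one content unit); ratios to the asynchronous
standard are rescaled by `2 ln2` before fitting to restore that origin.
R² is reported on the ln scale against the centred total sum of squares,
with a perfect flat fit defined as R² = 1. Quartiles use linear
interpolation (type 7). Zero-variance fold distributions degenerate the
Z cutoff to the median and are flagged; all-zero reporter rows,
singular impurity matrices, overlapping gate boundaries, empty gates,
sub-15-mer windows and empty enrichment backgrounds raise errors rather
than propagating silently.

## Problem sizes

Default study conditions: 2,000 unregulated + 60 degraded proteins
(mitotic design), ~1,130 proteins across four classes (interphase
design), 1,000 phosphosites in three classes, 20,000-50,000 cells per
sort, 2-4 replicates as per design. These sizes put Monte-Carlo error
well below the CV-0.15 measurement noise while keeping any full run in
seconds on a single CPU.
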