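# Methods

## The screen and the PSI statistic

A GPS-peptidome screen expresses a control fluorophore and a GFP–peptide
fusion from one transcript; the GFP/control ratio reads out the degradation
conferred by the fused peptide. Cells are sorted into four gates of equal
cell number by that ratio and each gate is sequenced. The Protein
Stability Index of tile *i* is

PSI_i = Σ_g g·f_ig / Σ_g f_ig,  f_ig = count_ig / depth_g,  g ∈ {1,2,3,4}

The division by per-gate total reads matters: gates hold equal cell
numbers but are sequenced to unequal depth, and the statistic is defined
on frequencies. PSI is therefore invariant to rescaling any single gate's
counts, bounded in [1, 4], and monotone under moving read mass from a
lower to a higher gate (all three are property-tested).

Default thresholds, all configurable:

| quantity | default | role |
|---|---|---|
| coverage filter | total reads strictly > 50 | tiles entering training |
| unstable label | PSI < 2.2 | degron class for training |
| stable label | PSI > 2.8 | non-degron class for training |
| degron call | PSI < 1.7 (strict `<`) | screen-level degron fraction |
| high-confidence call | PSI ≤ 1.62 (inclusive) | conservative degron set |

The strict-vs-inclusive comparator at 1.7 is ambiguous in common usage;
the default is strict `<` with an `inclusive` switch, and the ΔPSI
analysis restricts to control degrons with PSI ≤ cutoff (inclusive) by
default. Tiles whose sequence maps to more than one library member are
dropped before scoring (`drop_ambiguous`); every drop is logged with its
reason so additional filters can be composed.

## The composition model

Degron probability of a 17-mer is σ(Σ_a w_a c_a): twenty weights, one per
amino acid, acting on composition fractions c_a = count_a / 17. Fractions
rather than raw counts are used so the same weights apply to any window
length (the regional average over windows of a longer peptide needs this).
There is **no intercept**: with Σ_a c_a = 1 an intercept is absorbable
into a uniform shift of all weights and is not identifiable; a flag
enables it for sensitivity analysis. Because the features are order-free,
prediction is exactly permutation-invariant — a peptide and any scramble
of it score identically, which matches the experimental observation that
scrambled degrons remain degrons.

Fitting is L2-penalized maximum likelihood (lbfgs, gradient tolerance
1e-8, no stochastic elements). The penalty uses the **per-sample
(mean-loss) convention**: the objective is mean log-loss +
‖w‖²/(2·C·n). This makes the estimator a functional of the empirical
distribution — duplicating the training set leaves the weights unchanged
— at the cost that C values are not comparable to total-loss
parametrizations; the default grid C ∈ {10⁰ … 10⁶} spans effectively-full
shrinkage to effectively-unpenalized at screen scale (n ≈ 10⁴–10⁵), and
5-fold stratified cross-validated log-loss with a fixed fold seed picks
one value, recorded in the model file. On realistic simulated screens the
CV picks the weakest penalty, as expected for 20 parameters and ≥10⁴
observations.

Learned weights are reported in log-odds units per unit composition
fraction. They are expected to correlate with the Kyte–Doolittle
hydropathy scale (hydrophobicity drives quality-control degron potency)
but their absolute magnitudes depend on the feature scaling and penalty,
so only probabilities, not raw weights, are comparable across
implementations.

## Proteome scanning and region calling

Every 17-mer window of a protein is scored and the score is assigned to
the window's **center residue** (start + 8). The first and last eight
residues of a protein carry no defined probability rather than an
extrapolated one; region extents in full-tile coordinates (center-run ± 8,
clipped) are reported alongside for users who need coverage to the
termini. Degron regions are maximal runs of defined center residues with
P ≥ 0.85 (comparator configurable); a region's center is
floor((start+end)/2), ties to the N-terminal side. All reported
coordinates are 1-based inclusive.

## TMD overlap

TM annotations come from TMHMM-style output (either `TMhelix` interval
lines or `%pred` posterior lines) or a plain interval TSV; the parser
normalizes both to 1-based inclusive segments and rejects overlapping or
inverted intervals. The residue-level Venn partition counts, over residues
with defined probability, those that are predicted degrons only, annotated
TM only, or both; segment- and region-level counts are reported as well
since either convention is defensible.

A TM segment is summarized by the **maximum** defined per-residue
probability it spans (a degron call anywhere in a segment makes it act as
a degron); the mean is available via `statistic="mean"`. Segments with no
defined residue (entirely within 8 residues of a terminus) are excluded
and logged. The high/low composition contrast uses a chi-square omnibus
test on the pooled 2×20 residue-count table (plain Pearson statistic, no
continuity correction) followed by per-amino-acid two-sided Mann–Whitney U
tests on per-segment fractions. Probability histograms over [0.85, 1.0]
default to 3 equal-width bins (edges configurable).

## E3 ΔPSI analysis

For each ligase-knockout strain, ΔPSI = PSI_knockout − PSI_control per
control degron present in both tables. The stabilization threshold is
mean(ΔPSI) + 2·SE with SE = sd/√n over that strain's ΔPSI values; "two
standard errors" could also mean 2·sd of the distribution, so `se_rule="sd"`
selects that reading. At screen scale (thousands of degrons) the SE rule
gives a threshold barely above the mean, so the stabilized percentage
approaches the fraction of the distribution above its mean — consistent
with the large stabilized percentages seen in real knockout screens.
Strains sharing fewer than 3 degrons with the control are an error. The
overlap analysis takes each strain's ⌈0.10·n⌉ largest-ΔPSI peptides (ties
at the boundary broken by peptide id for determinism) and reports all Venn
region cardinalities plus the fraction of peptides claimed by ≥2 ligases.

## The simulator

The generative model produces what the pipeline consumes with known truth:

* **Library**: random 17-mers drawn i.i.d. from a yeast-like residue
  background (approximate S. cerevisiae proteome frequencies; any
  20-vector accepted). True degron probability comes from a chosen weight
  vector through the same link function the predictor uses; the default
  truth is the Kyte–Doolittle scale, making hydrophobic tiles degrons.
* **Stability map**: true mean fluorescence ratio is a monotone decreasing
  map of degron probability, default linear from 1.0 at P = 0 to 0.2 at
  P = 1. The shape is arbitrary by design — only monotonicity matters for
  the rank-based recovery checks — and is configurable.
* **Sort**: each of a tile's cells (default 100) gets ratio = mean ×
  lognormal(0, σ), σ = 0.3 by default — lognormal is the standard model
  for flow-cytometry intensity spread and reproduces the overlapping gate
  occupancies of real screens. Gate boundaries sit at the pooled 25/50/75%
  quantiles, so gates hold equal cell numbers (the quantiles are
  configurable since real gating need not be exactly quartile).
* **Sequencing**: per-gate reads (default 25·n_tiles per gate, i.e. ~100
  reads/tile overall) are multinomial over tiles proportional to gate
  occupancy. Sequencing error is not modeled; counts are exact draws.
* Knockout biology is not modeled mechanistically: stabilization is
  injected as explicit PSI offsets (`inject_stabilization`).

What passing the simulation-based tests shows: the pipeline correctly
inverts its own generative assumptions (frequency normalization, gating,
composition-logistic truth) at realistic noise and depth. What it does not
show: robustness to features of real screens that the simulator omits —
PCR/sequencing bias, tile-specific expression artifacts, cell-cycle
heterogeneity, or degrons whose potency depends on residue order.

Default validation scale is 20,000 tiles × 100 cells at ~100 reads/tile;
the full simulate→sort→PSI→label→train chain runs in a few seconds, and
the whole test suite in well under a minute.

## Numerical and degenerate-input choices

* PSI for a tile with zero frequency in every gate is undefined; such
  tiles are dropped with a logged count. A gate with zero total reads
  contributes zero frequency for all tiles; all four gates empty is an
  error.
* Correlations in recovery reports are `None` (not NaN) when an input is
  constant (e.g. a truth with no degrons), and degron-call sensitivity is
  `None` when there are no true positives to recover.
* Proteins shorter than 17 residues cannot be scanned (error for a single
  protein, logged skip in proteome mode).
* FASTA entries containing residues outside the 20-letter alphabet are
  excluded under the default `drop` policy (the model has no parameter for
  them); `keep` turns the first such residue into an error naming it.
* The random scramble utility and every simulator stage take explicit
  seeds; generator algorithm (NumPy PCG64) and seed are fixed by the
  caller, so outputs are reproducible across platforms.

## Known limitations

* The predictor is composition-only by construction; it cannot represent
  order-dependent degron determinants (e.g. amphipathic patterning), which
  the scramble experiments show can modulate potency.
* Tiles shorter than 17 residues are unscorable; terminal degrons within
  8 residues of a protein end have no per-residue probability.
* The segment-level TMD statistic (max) is a design choice where the
  field's convention is unstated; conclusions sensitive to it should be
  re-run with the mean.
* Screen-scale reproduction numbers (degron fractions, knockout overlap
  counts) depend on the supplied screen table and proteome/annotation
  versions; the package asserts only scale-free properties and
  simulation-recovered quantities.
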