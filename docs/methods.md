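# Methods

## The variability statistic and its classification

For one gene in one sample, the per-base coverage vector *x*₁..*x*_L over
the gene body (1-based, contiguous, in the direction of transcription)
yields two statistics:

* **CV** — the sample standard deviation (n−1 denominator) divided by the
  mean. The n−1 convention is a deliberate, documented choice: at per-base
  n of several hundred the difference from the population form is
  negligible, but fixing it makes every worked value exactly reproducible.
  An all-zero profile has CV 0 (a zero mean with non-zero counts is
  impossible for non-negative coverage and is rejected).
* **range** — max − min, in reads.

A replicate *meets* the variability thresholds when CV ≥ `cv_min` (default
0.11) **or** range ≥ `range_min` (default 2,000 reads); both comparisons
are inclusive. Classification uses **unadjusted** coverage: CV is scale-free
but the range threshold is calibrated in raw reads, so passing
library-size-adjusted profiles to the classifier is an error (or a warning
with `strict=False`).

Default mode computes the statistics **per replicate** across positions —
one dot per replicate in the scatter export, six per gene. The alternative
`across-replicates` mode pools a strain's three replicate vectors into one
and yields one record per strain; its category collapses to the four
combinations of the two strain-level flags. The per-replicate reading is the
default because only it produces a replicate-resolved dot cloud and a
replicate-robust exclusivity call ("all three replicates meet in one strain
only"); the pooled mode is retained for comparison.

The five-way category is a pure function of the six meets flags
(fullWT = all 3 WT meet, fullMUT likewise): `common` = fullWT ∧ fullMUT;
`wt_only` = fullWT ∧ ¬fullMUT; `mutant_only` = fullMUT ∧ ¬fullWT;
`below_threshold` = no flag set in either strain; `partial` = anything else.
These five cases are exhaustive and disjoint; the test suite checks the
implementation against a literal restatement of the rules on all 2⁶ flag
combinations. The "below threshold" case is read as *no replicate in either
strain meets* — the reading under which the five categories partition any
input.

### Range-threshold derivation

`derive_range_threshold` defines the "median number of reads" as the median
over genes of the per-gene mean per-base coverage, pooled across all six
samples. Mean-then-median is one of several defensible readings (sums,
medians, per-strain pooling are others); the function therefore also reports
the **implied fraction** — any given range threshold expressed as a
percentage of the computed median — so the consequence of the choice is
always auditable: a 2,000-read threshold against a 5,147-read median is 39%
(0 d.p.).

## Adjusted reads and distribution summaries

"Adjustment" is linear library-size scaling, counts × scale/library_size
(scale defaults to 10⁶, i.e. per-million). No method beyond linear scaling
is offered: CV is invariant under it and range scales linearly, so the
classification stage is unaffected by the choice. Distribution summaries
(median, quartiles, min/max) are computed over the pooled per-base values of
an explicit replicate subset (default: all three; the subset is a parameter,
never silently two). Quartiles use linear interpolation between order
statistics — the mainstream numerical default — so the documented examples
are exact. Spread comparison reports WT/MUT IQR and range ratios only; no
variance-homogeneity test is offered, because the underlying comparison is
descriptive and adding a test statistic would overstate it.

## 2⁻ΔΔCt quantification

Technical replicates are averaged first. Per biological replicate,
ΔCt = Ct_target − Ct_rnpB using the *rnpB* measurement of the same
(strain, biological replicate) sample; ΔΔCt subtracts the mean ΔCt of the
reference strain (wild type) for the same target/region, so the reference
strain's mean ΔΔCt is 0 and its mean fold is 1 by construction. The whole
computation is invariant under a constant plate offset. Group comparisons
(one-way ANOVA, Tukey HSD, α = 0.05) run on the fold scale — the plotted
quantity — with a ΔΔCt-scale variant always exported as well, since fold
values are log-normal-ish and the ΔΔCt scale is statistically cleaner.
Primer efficiency is 10^(−1/slope) − 1 from the OLS slope of Ct on log₁₀
dilution (≥ 3 points; non-negative slopes flagged invalid); two primer
pairs are treated as comparable when their efficiencies differ by ≤ 0.10,
an operational tolerance chosen here. Amplicon coordinates are +bp from the
translation start (+1 = first base of the start codon), closed intervals.
Efficiency-corrected (Pfaffl-style) quantification is out of scope.

## Phenotype statistics

Sporulation efficiency is 100 × heat-resistant CFU / total CFU per
replicate; replicates where the heat count exceeds the total (plating noise
near 100% efficiency) are flagged but retained. Strains are compared by
one-way ANOVA + Tukey at α = 0.05. Germination curves are exported as
OD_t/OD₀ ratios only — no rate-constant fit, because the readout of
interest is curve overlap, not kinetics. Morphometry (radius, cortex,
radius/cortex ratio — the ratio always recomputed from the raw columns)
uses Welch's unequal-variance t-test by default (pooled-variance by flag)
with significance flagged at α = 0.01; the spore-count per strain is a
parameter, never hard-coded.

## The synthetic-data generator

`simulate.py` emulates exactly the features the analysis keys on:

* **Coverage**: counts per base are negative binomial with mean
  m(x) = baseline × strain multiplier × pause factor(x) × attenuation
  factor(x) and variance m + m²/k. Defaults: baseline 1,000 reads/base
  (wild type), mutant multiplier 0.6, dispersion k = 200, gene lengths
  800–2,000 bp. The negative binomial (rather than Poisson) is essential:
  Poisson CV is mechanically 1/√mean, which would make the 0.11 CV
  threshold trivially informative about expression level rather than about
  pausing; k = 200 puts the no-pause CV near 0.08 at the default baseline —
  comfortably below threshold but not degenerate. A Poisson limit
  (`dispersion=inf`) is available.
* **Pauses**: `n_pauses` rectangular bumps (default 2) of width 50 bp where
  the mean is multiplied by `amplitude` (default 8). Pause centers are
  drawn once per gene — the pause is a property of the sequence — and
  applied per strain/replicate according to the gene's intended category;
  `partial` genes fire the pause in exactly one replicate of one strain,
  modelling stochastic pausing. At the defaults a pause gene's range is
  ≈ 7 × baseline ≫ 2,000 and its CV far exceeds 0.11, so category recovery
  is essentially deterministic; the recovery tests hold the generator to
  ≥ 90–95% rather than 100% to leave room for boundary draws.
* **Attenuation**: a step retention factor (default 0.4 after 60% of the
  gene length; geometric decay by flag) models the mutant's reduced
  formation of 3′-complete transcripts. Attenuation is applied in the
  dedicated attenuation scenario (WT with pauses vs mutant attenuated,
  used by the read-distribution analyses), **not** to the truth-stratified
  category genes: a step drop is itself whole-gene variance and would
  mechanically lift the mutant's CV above threshold, changing the intended
  category.
* **Ct tables**: Ct = base − log₂(expression) + N(0, sd) per technical
  measurement (default sd 0.15 cycles), *rnpB* strain-independent. With
  sd = 0 the ΔΔCt pipeline returns the configured folds exactly — a closed
  loop used by the tests. Configured fold changes are powers of two in the
  defaults so the noise-free loop is exact in floating point.
* **Morphometry**: near-normal draws truncated to positive values and to
  cortex < 2 × radius. Default means are the observed strain medians
  (radius 310/301 nm, cortex 91/61 nm for WT/mutant). Spreads are
  per-metric: radius sd 40 nm, cortex sd 10 nm. The asymmetry is
  deliberate: overall spore size varies much more between individual spores
  than cortex thickness does, and it is what reproduces the reported
  pattern — a 9 nm radius difference at sd 40 and n = 30 has ≈ 4% power at
  α = 0.01 (non-significant in ≈ 96% of experiments), while the 30 nm
  cortex difference at sd 10 is detected essentially always. A common
  sd of 10 nm for both metrics would instead make the radius difference
  significant in ≈ 80% of experiments, contradicting the phenotype the
  generator is meant to emulate.
* **CFU**: heat-resistant counts are binomially thinned from Poisson
  totals, with optional log-normal between-replicate variability of the
  thinning probability (default 0.1) representing dilution/plating error —
  without it, counts of ~10⁸ make replicate scatter unrealistically tiny.
  Default efficiencies 45% (WT), 30% (mutant, a one-third reduction), 43%
  (restored).
* **Germination**: a shared drop-then-rise OD-ratio template for both
  strains (germination is Mfd-independent), multiplicative noise.

Every gene and every assay uses its own RNG substream seeded by
(seed, stream index) through NumPy's `SeedSequence` spawning, so outputs are
byte-identical for a fixed seed and adding genes never perturbs earlier
ones.

### What the generator does not emulate

Real coverage has positional autocorrelation (fragment-length smoothing),
3′/5′ bias, mappability gaps, and between-replicate library composition
effects; pauses in real data are asymmetric and of variable width; Ct noise
has replicate-level (not just measurement-level) components. Passing tests
therefore demonstrate that the pipeline's statistics and decision rules are
implemented correctly and are recoverable under the intended signal
structure — not that the thresholds are optimal for any particular real
data set.

## Numerical and design notes

* Thresholds and the MFE cutoff are inclusive (≥ 0.11, ≥ 2,000,
  MFE ≤ −5.0 kcal/mol). "Below −5 kcal/mol" for negative energies is read
  as *at least as stable as* −5, i.e. ≤.
* Gene identifiers match by exact case-insensitive equality after
  whitespace stripping; no synonym resolution (that belongs upstream).
* The analysis universe count is always computed, never assumed; published
  descriptions of comparable gene sets disagree by one gene between text
  and figure legend, which is exactly the kind of discrepancy a recomputed
  count surfaces.
* Spore-count per strain: descriptions of comparable experiments vary
  between 30 and 32 measured spores; `n` is a parameter everywhere.
* `run_all` reports are pure functions of (inputs, configuration): JSON is
  written with sorted keys, no timestamps, and the report hash (SHA-256 of
  the report body) plus a configuration hash are embedded for audit.
* Problem sizes used by the test suite and the acceptance script — 200
  genes for recovery, 100 seeded morphometry experiments, 25 ΔΔCt noise
  runs, 8–40 genes for end-to-end runs — were chosen so each check has
  enough replication to be stable at its stated bound while the whole
  suite stays fast to iterate on.

## Known limitations

* The bedGraph bridge assigns each base the value of the covering interval
  and zero elsewhere; overlapping bedGraph intervals are resolved
  last-writer-wins rather than summed.
* `across-replicates` mode cannot produce a `partial` category by
  construction; its counts are not comparable to per-replicate counts.
* The ANOVA on fold values inherits the skew of the 2^−ΔΔCt transform at
  large effect sizes; use the exported ΔΔCt-scale tests when that matters.
* The motif filter consumes precomputed MFE tables; it does not fold
  sequences or score G-quadruplex propensity.
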