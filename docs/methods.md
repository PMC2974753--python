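# Methods

## Problem and model

In an eQTL study on a haploid biparental cross, every expression trait
is tested for association against every genotyped marker, and the
multiple-testing burden is usually handled by permutation-based
genome-wide correction. That correction is family-wise over *all*
trait × marker tests, so moderate but real effects rarely survive it.
`hdqtl` implements a complementary, per-trait view: for each trait it
summarizes the *shape* of the trait's whole profile of genome-wide
corrected p-values in a single statistic, the Hellinger distance to a
fixed reference, and ranks traits by it. Traits whose profile is
dominated by one exceptional association are prioritized regardless of
whether that association clears the genome-wide threshold.

## Association mapping

For a 0/1-coded haploid panel the single-marker regression LOD has the
correlation closed form

    LOD = -(n/2) · log10(1 − r²),

with `r` the Pearson correlation between genotype codes and expression
over the `n` pairwise-complete strains. This is algebraically identical
to the residual-sum-of-squares form `(n/2)·log10(RSS0/RSS1)` of the
marker-vs-intercept regression (the test suite checks the identity to
1e-10 against explicit least-squares fits). Choices:

* **Missing data.** Each (trait, marker) cell uses its pairwise-complete
  strains. Cells with fewer than three complete strains, or a variable
  constant on the complete subset, are *undefined* and propagate as
  missing — never as LOD 0, which would be a real (null) value.
* **Cap.** Perfect separation gives r² = 1 and an infinite LOD; finite
  LODs are capped at 300 (configurable). The cap only matters in
  degenerate small-n cases and never affects ranks below it.
* **Numerical form.** Rows are centered and unit-scaled before the
  moment computation; correlation is affine-invariant per row, so this
  changes nothing mathematically but makes "constant on a subset"
  detectable with an absolute tolerance.

## Permutation null and corrected p-values

One iteration draws a single random permutation of strain labels,
applies it to the whole genotype matrix, recomputes all T × L LODs and
records the genome-wide maximum. The shared permutation preserves both
marker linkage and the correlation among traits, which the distribution
of the maximum depends on; an independent-per-trait mode exists behind a
flag. The corrected p-value of an observed LOD is its add-one rank,

    p = (1 + #{null maxima ≥ LOD}) / (N + 1),

so p ∈ [1/(N+1), 1], no association ever gets p = 0, and within a trait
p is a non-increasing step function of LOD with at most N + 1 levels.
Default N = 1000 for production runs; the simulation studies below use
200–500 to keep the default test suite fast, which coarsens the p-value
grid but changes none of the tested orderings.

Calibration: over 200 fully-null simulated datasets, the family-wise
rate of any corrected p ≤ 0.05 is measured at its nominal 5% (binomial
2 s.d. band); this follows from the exchangeability of the observed
genome maximum with the permutation maxima under the global null.

## The Hellinger statistic

A trait's corrected p-values are oriented with scores `s = 1 − p`
(alternative: `−log10 p`), so the unremarkable bulk (p ≈ 1) sits near
zero and the exceptional association near the top of the range. Scores
are histogrammed into 30 equal-width bins over their own range
(`binwidth = (max − min)/30`; half-open bins, last bin closed; a
constant profile degenerates to all mass in bin 1). The reference is
the histogram, under the same rules, of the multiset {x³ : x = 1..L}
over the L loci: most mass in the smallest bins, tapering to a single
value at the top — the idealized "one dominant locus" profile. Its
first-bin proportion tends to (1/30)^(1/3) ≈ 0.322 as L grows.

The distance between the two histograms' proportion vectors is

    HD(P, Q) = sqrt( Σ_a ( √(P_a/|P|) − √(Q_a/|Q|) )² )   ∈ [0, √2]

by default; a `printed` variant computes `Σ_a (P_a/|P| − Q_a/|Q|)²`
(range [0, 2]), since the formula circulates in both forms. Both are
symmetric, zero exactly when the proportions coincide, invariant to the
total count, and (for the default form) squared-HD lower-bounds the KL
divergence; these axioms are property-tested. Bin counts from 10 to 100
give rank-correlated statistics (Spearman ρ ≥ 0.9 measured on the
default design), so the choice of 30 is not load-bearing.

**What actually drives the ranking.** Because each profile is binned
over its own range, the statistic is scale-free and responds only to
profile *shape*. A fully flat profile (every corrected p equal, the
typical fully-null trait under genome-wide correction) degenerates to
the all-mass-in-bin-1 histogram, which is close to the farthest
achievable histogram from the tapering reference (HD ≈ 0.93 at 30
bins). Any structure — an exceptional association, linked neighbors at
intermediate p — moves mass out of bin 1 and strictly reduces the
distance. The operational consequence, which the recovery tests pin
down, is that traits with genuine single-locus signal rank *below*
flat null traits, and the small-HD tail enriches for them. One
consequence cuts the other way: a trait with *several* moderately
elevated loci has even more profile structure and can rank below a
single-locus trait; the statistic orders "structured vs flat" far more
reliably than "one locus vs several". The polygenic-vs-null separation
is therefore weak at this design size (see Limitations).

Per trait the result carries the statistic, the argmin-p marker (ties
broken to the lowest marker index, with the tie count recorded — with
step-function p-values ties are common and hotspot assignment depends
on the rule), and the minimal p.

## Tails, hotspots, cis/trans

* **Tails.** Small/large tails are inclusive quantile cuts (type-7
  interpolation) at `tail_fraction` (default 0.05) from each end; a
  count-matched mode takes exactly n smallest/largest (ties by trait
  id) for comparisons against "an equal number" of genome-wide eQTL
  traits. With heavy ties the inclusive cut can sweep in every tied
  trait; the overlap is warned about and logged.
* **Hotspot assignment.** Small-tail traits are assigned to their
  argmin-p marker. Traits with a *flat* profile are excluded from
  assignment (logged): they have no best locus, and the lowest-index
  tie-break would deposit all of them on the first marker of the map,
  fabricating a hotspot there on null data.
* **Hotspot null.** n assigned traits are thrown uniformly at the L
  markers, repeatedly. The default threshold is the 95th percentile of
  the per-iteration *maximum* per-marker count — a family-wise bound
  over markers, so fully-null data produces a hotspot in ≈5% of runs
  (measured 0/20–0/50 in the test suite) while a planted 25-trait
  hotspot is flagged in ≥95% of runs. The alternative `pooled` mode
  thresholds the pooled per-marker counts (Poisson(1) with as many
  traits as markers; pooled 95th percentile = 3); it is retained behind
  a flag but flags ~5% of *markers* under the null, which is rarely the
  wanted operating point. Both use a strict ">" at the threshold, so a
  count exactly at the threshold is not a hotspot. Adjacent flagged
  markers can be merged into chromosome-level regions.
* **Cis/trans.** A trait is cis when its best marker lies on the
  trait's annotated chromosome, trans otherwise, unknown when
  unannotated. This is the definitive-cutoff definition (no distance
  window).

## Synthetic data

The generator emulates a haploid biparental cross. Genotypes: per
strain and chromosome a two-state Markov chain (first marker
Bernoulli(0.5), flip probability = recombination fraction per
interval, default 0.1, chromosomes independent), giving adjacent-marker
allelic correlation 1 − 2r = 0.8. Expression: single-locus traits
(β/sd = 2 ⇒ expected r² = 0.5 with Var(g) = 1/4), k-locus polygenic
traits (default k = 5, per-locus β = β_single/√k so total genetic
variance — heritability 0.5 — matches the single-locus class), pure
noise traits, and optional hotspot traits (single-locus traits sharing
one designated marker). Gaussian noise throughout; effect sizes are
specified as β/sd. Missing genotypes are observation dropout applied
after expression is generated. Default design: 5 chromosomes × 20
markers, 50 strains, 50 single + 50 polygenic + 100 null traits.

What the generator does *not* emulate: correlated expression noise
across traits (co-expression), epistasis, heteroskedasticity, selection
or segregation distortion, and dense marker maps with gradual linkage
decay. Passing recovery tests therefore demonstrate the method's
behavior under clean additive architectures, not its performance on
real microarray data, where trait–trait correlation inflates the
permutation maxima and profiles are smoother.

## Numerical and procedural choices

* All randomness flows through `numpy.random.default_rng` seeds; fixed
  seed ⇒ bit-identical matrices, maxima, thresholds and output files.
* Histogram bin membership follows `numpy.histogram` (half-open, last
  closed); a zero-width range puts all mass in bin 1.
* Quantiles/percentiles use NumPy's default linear (type-7) rule.
* Simulation sizes in the test suite (200 null datasets of 20 × 20 × 30
  at 200 permutations; 50-replicate hotspot and overlap studies at 200
  permutations) were chosen to make binomial tolerance bands decisive
  at desk scale.
* TSV outputs print floats at six significant digits; every run writes
  its effective configuration and a key-value metadata sidecar.

## Known limitations

* Polygenic (multi-locus) traits are not reliably pushed into the
  large-HD tail: the large tail is dominated by flat-profile null
  traits, since the degenerate histogram is near-extremal for the
  distance (see "What actually drives the ranking"). On the default
  design only ~15–30% of five-locus traits land in the larger-HD half.
* With few permutations the corrected-p grid is coarse; ties multiply,
  and tail membership for tied traits is decided by the documented
  tie-breaks rather than by data.
* The x³ reference and the 1 − p orientation are modeling choices;
  both are configurable, and rankings — not absolute HD values — are
  the meaningful output.
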