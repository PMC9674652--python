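# Methods

This note documents the models and procedures implemented in `dim-atlas`,
the defaults and why they were chosen, and what the synthetic data can and
cannot establish about the real assay.

## Library enumeration and canonicalization

Coordinates are 1-based; deletion intervals are inclusive. An insertion at
gap *g* places the new residue between WT residues *g−1* and *g* and is
reported at the mutant-sequence position it occupies (an insertion between
positions 1 and 2 "is at position 2"). For the default Aβ42 WT
(`DAEFRHDSGYEVHHQKLVFFAEDVGSNKGAIIGLMVGGVVIA`, L = 42) the enumerations
are:

* substitutions: 19·L = 798, all unique;
* insertions: 20·(L+1) = 860 raw, 818 unique products with the full gap
  range. The gap range is a design parameter (`DesignParams.gap_range`), so
  a restricted vendor design can be reproduced; the full range is the
  default because no restriction is part of the design definition;
* deletions: 42 single-residue removals collapsing to 37 unique products
  (five adjacent identical pairs: HH, FF, II, GG, VV), plus 779 internal
  intervals of length 2–39 (neither endpoint touching a peptide end);
* truncations: all (a, b) end-removals with a+b in 2–39, i.e. products of
  3–40 residues: 817, all unique for Aβ42.

Distinct mutations with one product are collapsed into a single coding
variant carrying every contributing specification. Each unique product gets
exactly one class under the precedence

```
single_deletion  >  truncation  >  multi_deletion
```

Single-residue removals (including positions 1 and L) are always single
deletions; an internal interval whose product equals a truncation product
is classified as a truncation (exactly 4 such products exist for Aβ42,
e.g. Δ2–7 ≡ removal of 1–6 because residues 1 and 7 are both D); the
remaining contiguous internal removals are multi-residue deletions.
Substitutions and insertions cannot collide with other classes (their
products have different lengths or edit structure). This precedence
reproduces the per-class counts 37 / 817 / 731 for Aβ42. Degenerate
products are counted once in library-level statistics and expanded to all
contributing intervals only in position-indexed analyses (matrix,
marginals).

Every variant is assigned a coding sequence from a fixed one-codon-per-amino
acid table (E. coli-biased usage) from which the WT nucleotide sequence is
also derived; a caller may supply either. The only quantity that depends on
this choice is `nt_min_changes`, the minimum number of nucleotide
substitutions turning the WT coding sequence into the variant's product —
minimized over *all* sense codons of the target residue, and infinite for
indels. It exists to give the "single nucleotide change" read filter a
consistent definition; the true synthesized sequence of a physical library
can be substituted without touching anything else.

## Read processing

Paired 125-nt reads always overlap on the construct (25-nt 5′ flank +
variant region + 21-nt 3′ flank, at most 175 nt for the default design).
Merging scans every admissible construct length, scores overlap mismatches
and takes the best (ties to the longest overlap); conflicting bases take
the higher-quality call. Each flank must then match its reference within
floor(0.20·flank length) mismatches — 5 on the 5′ flank, 4 on the 3′ flank
— located ungapped at the construct ends; reads with indels in a flank are
discarded with the merge/trim failures.

"Phred quality below 30" is interpreted as a per-base minimum over the
variant region: a single low-quality base is exactly the failure mode of
downstream exact matching, so the read is discarded if any region base is
below Q30 (exactly Q30 passes). A mean-quality mode is available.

The variant region is matched exactly (string equality) against the
designed nucleotide sequences; non-matching reads are tallied and dropped.
A translated (amino-acid level) matching mode exists for count tables
simulated at protein level. There is deliberately no error-correcting or
fuzzy matching — the designed-set exact match replaces variant calling.

Count-table filters: a variant is removed if its input count (technical
replicates pooled) is below 10 in **any** biological replicate, or if it is
one nucleotide change from WT and its pooled input total is below 1000
(such counts are inflated by sequencing errors on the vastly more abundant
WT molecules). The 1000-read rule is applied to the pooled input total by
default (a per-replicate mode is available; the choice is not determined by
the assay definition). The WT reference is never removed. Both filters are
idempotent.

## Scoring model

Natural logarithms throughout ("log" without a base is a unit choice; NS is
only compared relatively). For variant *i* in biological replicate *r*:

```
ES_ir = ln(c_out,ir / T_out,r) − ln(c_in,ir / T_in,r)
NS_ir = ES_ir − ES_WT,r
```

Technical replicates are pooled by summation within their biological
replicate before scoring (they share the biological replicate's frequencies
and differ only by resampling, so summation is sufficient; a separate
layout can be scored by relabeling them as biological replicates).

Per-replicate variance is the Poisson delta-method counting term
`1/c_in + 1/c_out + 1/c_WT,in + 1/c_WT,out` plus a replicate-scatter
component. The default **additive** model estimates σ_add² as the mean over
fully-observed variants of (between-replicate sample variance of NS_ir −
mean counting variance), clipped at zero. The mean (not a median) is used
because the 2-df sample variance is skewed and a median systematically
underestimates the component; the additive (not multiplicative) form is the
default because biological replicate noise — including the noise of the
shared WT reference, which shifts every variant in a replicate coherently —
enters additively on the log scale, and a multiplicative factor on counting
variance would mis-scale high-count variants. A multiplicative model and a
pure counting model are selectable. This stands in for the full replicate
error model of dedicated DMS pipelines (shrinkage and per-replicate scaling
are not reimplemented); it has the same leading-order behaviour and is
validated by parametric bootstrap in the tests.

Merging is the inverse-variance weighted mean with SE = (Σ 1/σ²)^(−1/2);
the merged table is re-centered so NS(WT) = 0 to machine precision.
Classification: z = NS/SE, two-sided normal p, Benjamini–Hochberg across
all scored variants (Benjamini–Yekutieli selectable), q < FDR with the sign
of NS giving NS+ / NS−, otherwise WT-like. Variants with input reads in
every replicate but zero output reads everywhere are **non-nucleating**:
they receive no score and no pseudocount — a zero output after selection is
informative of essentially absent nucleation, and any pseudocount would
turn it into an arbitrary finite score. Variants with zero output in only
some replicates are scored from the remaining ones.

## Synthetic selection generator

The generator realizes exactly the process the scoring model assumes, so
recovery tests are well-posed: per biological replicate, input frequencies
are one Dirichlet draw (concentration α = 50 per variant — mild, realistic
unevenness of a synthesized library); output frequencies are proportional
to `f_in · exp(NS_true + ε)` with ε ~ N(0, σ_rep²) per (variant,
replicate); dead variants (probability 0.003, matching the ~0.3% of
non-nucleating variants observed in practice) are zeroed before
renormalization; every technical replicate is an independent multinomial of
size `depth` (default 10⁶, the per-sample scale of the real sequencing
run). Replicate noise σ_rep = 0.1 gives between-replicate score
correlations comparable to a reproducible selection assay.

True scores come from a three-component Gaussian mixture — decrease
N(−3.0, 1.2²), null N(0, 0.15²), increase N(+1.5, 0.5²) — whose weights
depend on mutation class and on region: variants touching only residues
1–28 draw from the N-terminal cell, anything touching 29–42 from the
C-terminal cell. The default weights match the published regional
frequencies of nucleation-increasing/-decreasing variants at FDR 0.1
(e.g. 18%/26% for N-terminal substitutions, 6%/76% C-terminal; 50%
increasing for N-terminal truncations with none decreasing; all C-terminal
single deletions decreasing). Internal deletions whose first and last
removed positions fall in the box (starts 17–23, ends 22–27) draw from a
dedicated hotspot mixture (95% increase), encoding the central deletion
hotspot; the N-terminal multi-deletion background weight is set to 15% so
that the overall N-terminal rate stays near the published ~28% once the
hotspot is included.

FASTQ emission: each counted molecule becomes one read pair covering the
construct from both ends (length min(125, construct length) — constructs
shorter than one read yield shorter reads rather than modelling adapter
read-through). With `err_rate = 0` reads are error-free at uniform Q37,
consistent with the round-trip property that no read is lost to filtering.
With `err_rate > 0`, base qualities are two-state (Q37/Q20, 5% low) and
per-base error probabilities are proportional to 10^(−Q/10), normalized so
the mean equals `err_rate` — low-quality bases carry most errors, so the
Q30 filter is genuinely exercised.

What the generator does **not** model: PCR amplification bias and
jackpotting, chimeric reads, position-dependent Illumina error profiles,
growth-rate/toxicity coupling, or colony-level branching during selection
(selection acts once as bulk exponential enrichment — any monotone
generative link suffices for a score defined purely from frequency ratios,
and this one makes the truth analytic). Passing recovery and calibration
tests therefore establishes that the estimator is correct *for its own
model*, and that the pipeline machinery (filters, merging, classification)
is sound; it does not establish robustness to the artefacts above, nor
validate the biological accuracy of any particular score.

## Atlas analyses

Regions: 1–11, 12–16, APR1 = 17–21, 22–28, APR2 = 29–42 (APR =
aggregation-prone region), with super-regions 1–28 (N-terminal) and 29–42
(C-terminal). The aliphatic set is {G, A, V, L, I, M} — glycine included
because the aggregation-prone stretches of the peptide consist of
aliphatics and glycines; it is configurable. Insertions at the gap between
the halves (inserted position 29) count as N-terminal. Interval variants
map to the set of regions their removed residues intersect plus an APR
category (APR1 only / APR2 only / APR1+APR2 / no APR).

The deletion matrix is indexed by (first, last) removed position;
degenerate variants populate every contributing interval with their one
shared score; single deletions occupy the diagonal and pure one-sided
truncations the end-touching intervals. Hotspot detection applies the rule
*frequency > ½·max(frequency)* to the per-position NS+ frequencies and
returns all maximal runs (the longest is the hotspot; ties report all).
For the packaged hotspot analysis the marginals are restricted to
N-terminal internal deletions (first ≥ 2, last ≤ 28) and positions backed
by fewer than 5 intervals are treated as missing: a half-maximum rule is
meaningless on one-variant cells, which otherwise produce spurious
frequency-1.0 spikes. The first-position axis is robust across simulation
seeds; the last-position axis is noisier (rows near the peptide ends carry
few intervals), so detected end boundaries fluctuate by a few residues
between runs.

Alternative aliphatic cores: internal deletions [s, e] removing residues
from both halves (s ≤ 28 < e) replace the e−28 lost core residues with the
residues immediately preceding the junction (WT positions s−(e−28) … s−1);
the variant is kept iff that replacement segment is exclusively aliphatic.
This is the most literal reading of "replacing part of the core with
aliphatic residues"; the resulting selection is reported, not asserted, as
a count, because alternative readings (e.g. judging the mutant's realized
core composition) select slightly different sets. The core length of any
peptide is the maximal contiguous aliphatic run ending at its C-terminus —
14 for the Aβ42 WT.

Truncation series: 38 pure N-terminal and 38 pure C-terminal truncations
(removing 2–39 residues from one end; the 27 N-terminal truncations
removing at most 28 residues leave the aliphatic core intact), ordered,
with normal-approximation confidence intervals.

ROC AUC is the Mann–Whitney probability that a random positive outranks a
random negative with ties at ½ (delegated to scikit-learn, verified against
O(n²) pair counting); disease labels are an input CSV and are not
redistributed. Weighted Pearson uses weighted means/covariances with
default weights 1/SE²; kinetic rate constants are compared on the log
scale. Growth rates are the maximum least-squares slope of ln(OD) over a
sliding window (default 10 points).

## Problem sizes and numerical choices

Library construction and all enumeration identities run in well under a
second. The recovery analysis uses the full Aβ42 library at depth 10⁶ with
3×5 replicates (one simulation + fit ≈ 1 s); the null-calibration analysis
averages 20 independent all-null simulations at the same scale; the
read-level round trip uses depth 800 over one biological replicate — the
round trip is exact at any depth, and this size keeps per-read Python
processing fast. All randomness flows through `numpy.random.default_rng`
seeds carried in the configuration objects; identical seeds give
byte-identical tables end to end (verified in the pipeline tests by output
hashing). Equality-style identities (WT centering, depth invariance,
degenerate-product equality) are asserted to machine precision; stochastic
checks use 3·SE bounds computed from their own samples.

## Known limitations

* The full internals of dedicated DMS error models (DiMSum-style shrinkage,
  per-replicate error fitting) are intentionally out of scope; the additive
  moment estimator is a transparent stand-in with the same leading-order
  behaviour.
* Insertion design counts depend on the (unknown) vendor gap convention;
  the package ships the complete 818-product design and exposes the gap
  range rather than guessing a restriction.
* Exact nucleotide-level matching means any synthesized library whose codon
  usage differs from the shipped table must supply its own coding sequences
  for read-level quantification (protein-level matching is the fallback).
* The hotspot end-axis and small marginal cells are noisy at realistic
  library sizes; the min-evidence threshold mitigates but does not remove
  this.
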