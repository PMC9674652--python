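# dim-atlas

Deep indel mutagenesis (DIM) of amyloid nucleation: a tested, reusable
pipeline for building complete substitution/insertion/deletion/truncation
variant libraries of a short peptide, simulating and processing the
selection assay that measures how each variant changes amyloid fibril
nucleation, and running the downstream atlas analyses.

The package is written for researchers doing multiplexed assays of variant
effect (MAVE/DMS) on aggregating peptides — by default the 42-residue
amyloid-beta peptide (Aβ42) central to Alzheimer's disease — who need

* the **complete indel library** for a wild-type (WT) peptide of length *L*:
  all 19·*L* substitutions, all single-residue insertions at every gap, all
  single and internal multi-residue deletions, and all truncations removing
  2–39 residues from one or both ends, **canonicalized**: distinct mutations
  that produce the same peptide (e.g. deleting either of two adjacent
  histidines) are collapsed into one coding variant with a single assigned
  mutation class;
* **nucleation scores** from selection sequencing counts, with per-replicate
  errors, inverse-variance merging, and FDR classification;
* the **atlas analyses**: region-resolved effect frequencies, the deletion
  start-by-end matrix with hotspot detection, alternative aliphatic cores,
  truncation series, ROC against disease labels, and weighted correlation
  against in-vitro kinetic rate constants.

## The model

For variant *i* in biological replicate *r*, with input/output read counts
*c* and sample totals *T*, the enrichment score and nucleation score are

```
ES_ir = ln(c_out/T_out) − ln(c_in/T_in)
NS_ir = ES_ir − ES_WT,r
```

Replicates are merged by inverse-variance weighting with per-replicate
variance

```
σ_ir² = 1/c_in + 1/c_out + 1/c_WT,in + 1/c_WT,out + σ_add²
```

where the additive component σ_add² is estimated from between-replicate
scatter (method of moments). Variants are classified **NS+** / **NS−** /
**WT-like** by a two-sided z-test with Benjamini–Hochberg control at
FDR = 0.1; variants with input reads but no output reads in any replicate
are flagged **non-nucleating** and carry no score.

A synthetic selection generator provides the full data-generating process
(Dirichlet input frequencies, exponential selection in the true NS,
replicate noise, multinomial sequencing depth, optional paired-end FASTQ
with Phred-consistent errors), so every downstream stage is testable
without any external download.

## Worked example

```python
import dim_atlas as da

lib = da.build_library(da.ABETA42)
print(sorted(lib.class_counts().items()))
# [('insertion', 818), ('multi_deletion', 731), ('single_deletion', 37),
#  ('substitution', 798), ('truncation', 817)]

cfg = da.SimulationConfig(seed=1)                      # study conditions:
effects, counts = da.simulate_dataset(lib, cfg)        # 3 bio x 5 tech, depth 1e6
res = da.NucleationModel(da.apply_read_filters(counts, lib)).fit(fdr=0.1)
print(res.summary())
```

```
Nucleation score fit
============================================
variants in table                  3202
variants scored                    3191
biological replicates                 3
error model                    additive
additive rep. SD                 0.1374
multiplicative inflation          1.000
FDR level (fdr_bh)              0.10
--------------------------------------------
NS-                                2177
WT-like                             607
NS+                                 407
non_nucleating                       11
============================================
```

The library has 3202 unique coding variants (798 substitutions, 818
insertions, 37 single deletions, 731 internal multi-residue deletions, 817
truncations, plus WT). On this simulated run most variants reduce
nucleation (NS−), a minority accelerate it (NS+), and 11 variants had input
but zero output reads (non-nucleating) — the qualitative structure of the
real assay. The deletion hotspot detector applied to the fitted scores

```python
from dim_atlas.atlas import hotspot_analysis
print(hotspot_analysis(res.scores, lib))
# {'first_del': [(17, 23)], 'last_del': [(22, 27)]}
```

returns the maximal runs of first/last deleted positions whose NS+
frequency exceeds half its maximum — here deletions starting at positions
17–23 and ending at 22–27, the central region where removing residues
accelerates nucleation.

The same stages are available as a CLI:

```
dim-atlas design   --out library.csv
dim-atlas simulate --library library.csv --out sim/ --seed 1
dim-atlas score    --counts sim/counts_true.csv --out scores.csv
dim-atlas analyze  --scores scores.csv --library library.csv --out analysis/
dim-atlas all      --out run/ --seed 1       # full pipeline with manifest
```

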