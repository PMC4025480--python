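# rilmap

Linkage mapping, recombination-rate estimation, inversion detection and QTL
scanning for recombinant inbred line (RIL) panels genotyped at low
sequencing coverage.

`rilmap` is aimed at plant and animal geneticists working with selfed RIL
panels (F2 … F8 by single-seed descent) typed with multiplexed shotgun /
genotyping-by-sequencing protocols: many SNPs, very few reads per SNP per
line. Individual SNP calls are unreliable at such depths, so the package
follows the windowed-genotyping strategy: filter SNPs hard, aggregate calls
in 50-kb scaffold windows into marker genotypes, and build everything else
— the genetic map, cM/Mb landscapes, recombination-suppressed blocks, QTL
scans — on those markers. A first-class synthetic-data module simulates the
whole data-generating process (pedigree, crossovers, inversions, reads,
phenotypes) with ground truth retained, so every estimator in the package
is validated against truth without any external data.

## The statistics at the core

* **Pairwise linkage.** For markers typed in n doubly homozygous lines
  with k discordant, the RIL recombination fraction is R̂ = k/n (≤ 0.5) and
  the LOD against free recombination is
  `k·log₁₀R̂ + (n−k)·log₁₀(1−R̂) + n·log₁₀2`.
* **Selfed-RIL map distances.** Repeated selfing inflates discordance:
  R = 2r/(1+2r) at fixation (Haldane–Waddington). Distances invert this and
  apply Haldane's map function d = −50·ln(1−2r) cM. An exact
  finite-generation correction (`selfing_generations=7` for F8) is
  available; the fixation formula under-lengths dense F8 maps by ≈ 5 %.
* **Marker ordering.** Within a linkage group (single-linkage components at
  R̂ ≤ 0.15), scaffold fragments are frozen in physical order and permuted /
  oriented to minimise the sum of adjacent recombination fractions
  (greedy + 2-opt with exact orientation DP; verified against exhaustive
  search).
* **Rates and intervals.** Scaffold rates are cM span / Mb span;
  chromosome and global CIs come from a circular block bootstrap of
  scaffolds with geometric block lengths (mean 3).
* **Inversions.** Maximal runs of ≥ 20 consecutive markers spanning ≤ 1 cM
  genetically but ≥ 2 Mb physically.
* **QTL.** log(x+1) phenotypes, nested ANOVA (RIL within grow-up; grow-up
  and method fixed) by method of moments, RIL mean residuals, then
  multiple-imputation interval mapping: 32 imputations from a two-state
  Markov chain along the map, per-imputation regression LOD
  (n/2)·log₁₀(RSS₀/RSS₁), combined as log₁₀-mean-10^LOD, with
  1000-permutation genome-wide thresholds, conditional (add-QTL) scans,
  1.8-LOD support intervals and effects in within-RIL SD units.

## Worked example

Simulate an F8 panel of 150 lines on three 100-cM / 25-Mb chromosomes
(4 cM/Mb), with a 3.5-Mb inversion on chromosome 3 and one QTL on
chromosome 1, sequence it at MSG-like sparse coverage, and run the
pipeline:

```python
import numpy as np, pandas as pd
from rilmap import simdata as sd, genotypes as gt, linkmap as lm
from rilmap import recombination as rc, inversions as invmod, qtl as q

layout = sd.make_layout(n_chromosomes=3, chrom_cM=100, chrom_bp=25_000_000,
                        scaffold_bp=2_500_000,
                        inversions=[(2, 9_000_000, 12_500_000)])
truth = sd.simulate_pedigree(layout, 150, 7, seed=42,
                             qtl_spec=[("chr1", 6_000_000, 0.4)],
                             variance_components=(0.1, 0.05, 0.3))
snps = sd.simulate_reads(truth, layout, snp_density_per_kb=0.1,
                         mean_depth=0.5, base_error=0.002, seed=43)

filtered, log = gt.filter_snps(snps, depth_min=10)
calls, _ = gt.call_snp_genotypes(filtered)
filtered, calls, _ = gt.consistency_filter(filtered, calls)
mat = gt.call_windows(filtered, calls, layout.scaffold_lengths(), window_bp=50_000)
mat = gt.select_mapping_set(mat, n_rils=100, completeness=0.5)

gmap = lm.build_map(mat, seed=44, selfing_generations=7)
print(len(gmap.groups), [round(g.length_cM, 1) for g in gmap.groups])
# 3 [99.4, 100.8, 116.1]

rates = rc.scaffold_rates(gmap)
print(rc.bootstrap_rate_table(rates, n_boot=2000, seed=45).round(2))
# chromosome  rate_cM_per_Mb  ci_lo  ci_hi  n_scaffolds
#          0            3.79   3.26   4.25           10
#          1            3.94   3.40   4.49           10
#          2            4.61   3.88   5.35           10
#     global            4.12   3.73   4.52           30
```

7,582 simulated SNPs pass all five filters; the windowed caller yields
1,444 markers, and the map recovers three linkage groups whose lengths
bracket the true 100 cM (the inversion chromosome runs long — single-SNP
windows in residual-heterozygous tracts add spurious discordance at this
depth; see `docs/methods.md`). The pooled rate, 4.12 cM/Mb with CI
(3.73–4.52), covers the simulated 4.0.

Phenotypes and the QTL scan:

```python
ph = sd.simulate_phenotypes(truth, 3, 3, True, seed=46, trait_name="conandroside")
means, dec = q.preprocess_phenotypes(ph, ["conandroside"])
imps = q.impute_genotypes(mat, gmap, n_imputations=32, seed=47)
model = q.find_qtl(imps, means["conandroside"], dec["conandroside"],
                   n_perm=1000, seed=48)
print(model.round(3))
# group  position_cM  marker_id     lod  p_value  interval_lo_cM  interval_hi_cM  pct_chromosome  effect_in_sd  pct_variance
#     2       32.604        111  10.306      0.0          30.521          34.456           3.388         1.363        37.787
```

One QTL exceeds the genome-wide 5 % permutation threshold (permutation
p < 0.001). Its linkage group is the one carrying the simulated chr1 QTL
(group numbering is by size, not chromosome name); the effect, 1.36
within-RIL SDs for the IM/IM − PR/PR class difference, recovers the
simulated 2 × 0.4 / √0.3 ≈ 1.46 up to marker attenuation.

Inversion detection reads the map directly. On this panel genotyped
error-free (calling noise removed via `sd.true_window_genotypes`), the
suppressed block is unambiguous:

```python
gmap_t = lm.build_map(sd.true_window_genotypes(truth, window_bp=50_000), seed=44)
print(invmod.detect_blocks(gmap_t))
# group  first_marker  last_marker  n_markers  physical_span_bp  map_span_cM                scaffolds
#     2          1169         1257         89           4450000        0.683  chr3_s3,chr3_s4,chr3_s5
```

89 markers spanning 4.45 Mb collapse to 0.68 cM — the inversion signature.

A command-line interface mirrors the same steps
(`rilmap simulate | genotypes | map | rates | inversions | qtl`); see
`rilmap --help`.

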