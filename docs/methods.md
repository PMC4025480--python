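# Methods

`rilmap` implements the computational path from low-coverage
genotyping-by-sequencing SNP calls in a selfed recombinant-inbred-line
(RIL) panel to a dense linkage map, recombination-rate estimates with
block-bootstrap confidence intervals, detection of recombination-suppressed
blocks (putative inversions), and QTL mapping of quantitative phenotypes.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## The synthetic panel

Real panels of this kind carry no deposited raw data, so every stage is
validated against a generator with retained ground truth.

**Pedigree.** Each line descends from a single F1 (IM × PR) by repeated
self-fertilisation with single-seed descent; `n_selfing_generations = 7`
(an F8 panel) is the default. Per meiosis, crossovers form a Poisson
process along the chromosome with expectation `genetic_length_cM / 100`,
uniform in physical position — no crossover interference, so the Haldane
map function used downstream is exact in expectation, and genetic and
physical scale are proportional within a chromosome. Residual
heterozygosity halves per selfing generation ((1/2)^7 ≈ 0.8 % at F8);
per-line heterozygous fractions are strongly right-skewed (a few lines
carry long unfixed tracts), which the tests account for by comparing means
at matched standard errors.

**Inversions.** An individual heterozygous across an inversion interval
transmits no crossovers inside it (suppression is absolute by default; an
escape-rate option exists). Because the F1 is heterozygous everywhere and
suppressed intervals therefore never break, each inversion segregates as a
single Mendelian unit — which is exactly why dozens of physically
dispersed markers collapse onto one map position in the real data.

**Reads.** SNPs are placed uniformly within scaffolds at a configurable
density; per (line, SNP) read depth is Poisson with a configurable mean
(the real depth distribution per SNP is not published beyond a cross-line
median; Poisson per-line depth is our modelling choice), and each read
reports the allele of a uniformly drawn haplotype, flipped with the base
error probability. FASTQ-level artefacts (alignment error, indels,
repeats) are deliberately out of scope, so passing recovery tests show the
statistical pipeline is sound, not that upstream read processing is.

**Phenotypes.** A replicate measurement is
`grand mean + Σ QTL effects + RIL deviate + grow-up offset + method offset
+ residual`, with QTL genotypes coded +a / 0 / −a for IM/IM, heterozygous,
PR/PR. Effects `a` are specified on the transformed (analysis) scale in
absolute units — the no-noise degenerate case must yield classes exactly
`2a` apart. With `skew_transform` the value is `expm1` of the linear value
so that `log(x+1)` recovers the linear model; rare negative concentrations
are censored at 0, mimicking below-detection measurements. Censoring makes
the skewed scale not exactly invertible in the extreme lower tail, so the
exact ANOVA-recovery tests run on the linear scale.

## Genotype calling

Per-SNP line calls use the IM-base sample frequency with strict thresholds
(IM/IM above 0.9, PR/PR below 0.1, heterozygous otherwise; no reads →
missing). Site filtering applies five criteria in order, with per-criterion
rejection counts: biallelic, unambiguous IM-parent base, total depth across
lines within [50, 1000] (bounds inclusive — "between" is read
inclusively), pooled alternative-base frequency within [0.2, 0.8]
(read-weighted by default; a per-line-weighted variant is exposed), and
heterozygous line fraction below 0.25. A neighbour-consistency screen then
drops SNPs whose calls disagree with other SNPs within 50 kb in more than
half of the valid (line, neighbour) comparisons; comparisons involving
missing or heterozygous calls are skipped, and the screen is a single pass
against the original calls.

Markers are 50-kb windows tiling each scaffold from coordinate 0 (the final
partial window is kept). Per window and line,
`p = (n_IM + 0.5·n_HET) / n_called` over called SNPs — a heterozygous SNP
call contributes half an IM allele, the symmetric reading of an
IM-allele frequency — and the marker call is IM (p > 0.9), PR (p < 0.1),
heterozygous (0.4 < p < 0.6) or missing (anything else, including empty
windows). The mapping subset keeps the 100 most completely genotyped lines
(ties by line id) and markers called in ≥ 75 % of them.

## Linkage map

Pairwise linkage between markers uses only doubly homozygous lines: the
RIL recombination fraction R̂ = k/n (discordant pairs over informative
lines, truncated at 0.5) and the binomial LOD
`k·log10 R̂ + (n−k)·log10(1−R̂) + n·log10 2` against free recombination.
Heterozygous calls are excluded rather than half-weighted: at < 1 %
residual heterozygosity the information loss is negligible and the
estimator stays binomial.

Groups are single-linkage components of the graph { R̂ ≤ 0.15 }. Scaffolds
whose windows land in different groups are broken into maximal runs of
consecutive windows per group ("chimeric" assembly scaffolds). Within a
group, markers of one scaffold fragment are frozen in physical order and
whole fragments are permuted and oriented to minimise the sum of adjacent
recombination fractions (SARF). The original analysis used ant-colony
optimisation for this objective; the objective, not the metaheuristic, is
what matters, so we use greedy nearest-neighbour construction (one tour
per distinct starting block, then random initial sequences up to
`n_restarts = 20`), refined by 2-opt reversals and single-block
relocations, with orientations chosen exactly per candidate sequence by a
two-state dynamic program. Tests verify the optimiser against exhaustive
permutation × orientation search for up to seven blocks and against the
true order on error-free data. Ties and direction are canonicalised so
results are deterministic given the seed.

**Distances.** Repeated selfing inflates observed discordance over the
meiotic recombination fraction; at fixation R = 2r/(1+2r)
(Haldane–Waddington), inverted as r = R/(2(1−R)), then the Haldane map
function d = −50·ln(1−2r) cM, with r capped at 0.49 to keep distances
finite. Positions are cumulative sums from 0; co-locating markers keep
input order.

**Finite-generation correction.** The fixation inverse is the field's
standard for selfed RILs and is the default. It is, however, measurably
biased for dense F8 maps: the exact two-locus selfing chain (implemented in
`selfing_discordance`) shows that F8 discordance at 1 cM is ≈ 5 % below the
fixation value, so dense F8 maps estimated with the fixation inverse are
≈ 5 % short. `estimate_positions(..., selfing_generations=7)` inverts the
exact finite-generation relation instead (monotone interpolation of the
chain); recovery studies use it so that map-length errors reflect sampling,
not estimator bias. Irreducible sampling error remains: a 100-cM
chromosome typed in 100 F8 lines carries ≈ 200 observable junctions, so
any length estimate has ≈ 7 % standard error per chromosome — genome
totals, with 14× the junctions, are stable to ≈ 2 %.

## Recombination rates

Per-scaffold rates divide the cM span of an unbroken scaffold's markers
(≥ 2 required) by its physical span (first window start to last window
end). Global summaries: mapped rate = Σ cM / Σ Mb over mapped scaffolds
(ratio of sums, i.e. length-weighted — whether the original per-chromosome
points were ratio-of-sums or mean-of-scaffolds is not documented; ratio of
sums matches the "total genetic and physical length" phrasing), unmapped
rate = residual map length over residual genome, genome-wide rate = total
map length over genome size.

Confidence intervals block-bootstrap whole scaffolds in genome order:
block lengths are geometric on {1, 2, …} with mean 3 (success probability
1/3; the zero-support variant would allow empty blocks), blocks wrap
circularly so every scaffold has equal inclusion probability, replicates
are truncated to the original scaffold count, and the interval is the
central 95 % percentile range of the replicate ratio-of-sums (a one-sided
option exists).

A known limitation, quantified during validation: scaffold-level
bootstraps presume exchangeable scaffold units. Junctions in selfed RILs
are clustered along a chromosome (the RIL genotype process is not Markov
across loci), which induces ≈ 0.26 correlation between adjacent scaffolds'
rate estimates on a shared chromosome; a mean-3 block bootstrap recovers
only part of it, leaving CIs ≈ 10 % too narrow (coverage ≈ 0.88 instead of
0.95) regardless of panel size or selfing depth. The coverage study in the
acceptance suite therefore simulates scaffolds as independent units (one
scaffold per chromosome) — isolating the interval machinery itself — and
uses 200 lines so that the ratio estimator's small-sample Jensen bias
(∝ 1/n, ≈ +2 % at 100 lines) stays below half a CI standard deviation.
Under those conditions measured coverage is ≈ 0.92.

## Inversion detection

The detector formalises the heatmap signature: maximal runs of consecutive
map markers whose total genetic span stays within `eps_cM = 1.0`, gated on
`min_markers = 20` and physical span ≥ `min_bp = 2 Mb` (gates chosen from
the smallest block reported in the motivating system, 54 markers over
2.95 Mb; the numeric `eps_cM` is our convention — the original calls were
made by inspection). Physical span across several scaffolds sums each
scaffold's marker extent, since inter-scaffold gaps are unknown ("at
least" semantics). A two-pointer sweep emits non-overlapping calls and is
invariant to reversing a group's marker order. The block report adds the
flanking map gaps — suppressed blocks sit next to unusually large
intermarker gaps, the other half of the signature.

## QTL mapping

**Preprocessing.** Trait values are log(x+1)-transformed. Grow-up batch
and quantification method are fixed effects estimated by least squares;
variance is partitioned into among-RIL (V_ril) and within-RIL (V_error)
components by method of moments on the nested layout, with the
unbalanced-design coefficient c = (N − Σnᵢ²/N)/(g−1); negative among-RIL
estimates truncate to zero and are flagged. RIL means are the average
fixed-effect residuals per line; with a single quantification method the
design matrix simply drops that column.

**Imputation.** Scans use the multiple-imputation flavour of interval
mapping, with `n_imputations = 32` and the observed markers as the scan
grid (at ≈ 0.6 cM marker spacing a pseudomarker grid adds nothing).
Missing calls — and heterozygous calls, treated as missing since a
three-genotype codominant model is out of scope at < 1 % residual
heterozygosity — are drawn from a two-state Markov chain along each
linkage group whose step probability between adjacent markers is the map
distance pushed through the inverse Haldane function and the fixation
formula R = 2r/(1+2r), conditioned on the nearest observed markers on both
sides (one side at ends; lines with no observed marker on a group get
unconditional chain draws and a flag). The conditional sampler is verified
against exact path enumeration.

**Scans.** Per imputation the LOD at a marker is the regression form
(n/2)·log10(RSS0/RSS1) with genotypes coded ±1 — with complete imputed
genotypes the normal-model interval-mapping LOD reduces exactly to this
ratio. Imputations combine as log10 of the arithmetic mean of 10^LOD
(evaluated by log-sum-exp; RSS1 is floored so a perfect fit caps at the
machine limit rather than overflowing). With no missing data every
imputation is identical and the combined LOD equals the single-fit LOD to
numerical precision — an invariant in the tests. Conditional (add-QTL)
scans put the model QTL genotypes in both null and alternative models via
an orthonormal covariate projector; collinear covariates are dropped with
a warning.

**Significance and summaries.** Genome-wide thresholds permute RIL means
against intact genotype rows (1000 permutations; 5 % and 10 % quantiles of
the per-permutation genome-wide maximum). A QTL's p-value is the fraction
of permutation maxima at or above its peak LOD. Support intervals expand
from the peak while LOD ≥ peak − 1.8, reported with the percentage of the
group's map length (flat profiles span the whole group and are flagged).
Effects are reported as the full IM/IM − PR/PR class difference of RIL
means in units of the within-RIL SD (√V_error) — the full difference, not
the half-difference a, explicitly labelled since the convention is
ambiguous in the field — averaged over imputations, alongside the percent
variance explained from sums of squares of the single-QTL regression.
Class differences measured at a marker attenuate by (1 − 2R) toward the
nearest window, which bounds accuracy at ≈ 15 % for 500-kb windows.

## Problem sizes in the validation suite

Recovery studies run at sizes where the checked property has adequate
power while the suite stays quick: map recovery on 14 chromosomes × 100 cM
at 100 lines (250-kb markers); single-chromosome length recovery at 300
lines; bootstrap coverage over 200 replications of 60 independent 1-Mb
scaffolds at 200 lines (1000 bootstrap replicates); inversion recovery
over 60 genomes with three 2.9–4.1 Mb inversions each at 20 markers/Mb;
null QTL calibration over 200 scans of 169 phenotyped lines with
1000-permutation thresholds and 16 imputations. The acceptance script
(`scripts/acceptance.py`) re-runs the same studies from a caller-supplied
seed.

## Window calling and map length: coverage-regime biases

Two opposing biases connect the window caller to adjacent-pair map
distances, both quantified on synthetic panels:

- **Censoring compression (dense windows).** A line whose crossover falls
  inside a window has a mixed window: with many called SNPs its p lands in
  the heterozygous or missing band, removing that line from exactly the
  adjacent pairs where it would count as a recombinant. Since adjacent
  midpoints are one window-width apart, essentially every recombinant is
  exposed; at ≳ 4 called SNPs per window most are censored and adjacent-pair
  maps compress severalfold. Multipoint estimators (the R/qtl route used in
  the field) bridge missing markers and largely avoid this; the
  strictly-adjacent-pair distance rule implemented here is validated on
  error-free window genotypes, where no censoring exists.
- **Heterozygosity inflation (sparse windows).** A window with a single
  called SNP in a residual-heterozygous tract is called homozygous to a
  random side, creating spurious discordance between adjacent windows and
  inflating the map (≈ +15 % at ~1–2 called SNPs per window and 0.8 %
  residual heterozygosity). The heterozygous p-band catches windows with
  ≥ 2 called SNPs; nothing can catch k = 1. The neighbour-consistency SNP
  filter does not help here — it aggregates over lines and targets
  systematically misplaced SNPs, not per-line miscalls.

Real low-coverage panels sit between the regimes, so window-caller map
lengths should be read with these biases in mind.

## Known limitations

- No crossover interference; sex-averaged rates only.
- The generator emulates GATK-style allele-depth output, not reads;
  alignment and repeat artefacts are unmodelled.
- Window calls at the midpoint of a crossover-containing window can
  legitimately disagree with either flank; at 50-kb windows this affects
  < 0.5 % of cells and is treated as calling noise.
- Scaffold-level bootstrap CIs are anti-conservative on long chromosomes
  with junction clustering (quantified above).
- The permutation scheme assumes exchangeable RIL means under the null;
  family or batch structure beyond grow-up is not modelled.
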