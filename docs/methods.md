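# Methods

`yakpop` implements the two computational arms of a wild/domestic yak
(*Bos grunniens*) domestication-genomics analysis — a sliding-window
selective-sweep scan and SFS-based coalescent demographic inference — as a
reusable, tested pipeline that runs end-to-end on synthetic data with known
truth.  This note records the models, the defaults and why they were
chosen, the numerical conventions, and what the synthetic experiments do
and do not demonstrate.

## Input model and filtering

The pipeline operates on called diploid biallelic SNP genotypes (VCF) with
a sample→population map: wild ("W") and two domestic herds ("D1", "D2";
the study design is 13 wild, 11 + 48 domestic diploids).  Internally all
coordinates are 0-based half-open; VCF positions convert at the boundary.
Missing genotypes are a distinct sentinel and are dropped site-wise from
allele-frequency denominators, so the called allele number n varies per
site.

Site filters follow the source protocol for called genotypes: a site is
removed when its call rate is below 90% in the wild samples or in the
pooled domestic samples, or when an exact Hardy–Weinberg test on the pooled
sample gives p < 10⁻³.  The HWE test is the standard exact test —
conditioning on allele counts and summing probabilities of heterozygote
configurations no more probable than the observed one — rather than a χ²
approximation, which misbehaves at low counts.  The protocol does not say
whether HWE was tested per population; the pooled choice is configurable.
Read-depth filters (the 2×–18× bounds of the original pipeline) cannot be
recomputed from genotypes, so they are honoured through an optional
user-supplied exclusion mask.

## Window statistics

Statistics are computed in 50-kb windows sliding by 10 kb; windows with
less than 80% callable sequence are dropped.  Per window and population:

* π — sum over sites of the unbiased per-site heterozygosity
  (n/(n−1))·2p̂(1−p̂), divided by the callable length.  Reporting per
  callable bp (rather than per window) keeps windows of unequal callable
  length comparable; Tajima's D consumes the unnormalised sum.
* Watterson θ_w — S/(a₁·L) with a₁ the (n−1)-th harmonic number.
* Tajima's D — the textbook normalisation; undefined (NaN) when S = 0,
  and NaN windows are excluded from summaries rather than imputed as zero.
* FST — the protocol does not name its estimator; we use Hudson's, with
  ratio-of-averages aggregation across sites, because it is robust to
  unequal sample sizes and rare variants.
* π log-ratio — ln(π_W) − ln(π_D); defined only when both diversities are
  positive.

LD is summarised as unphased genotype r² (squared Pearson correlation of
dosage vectors), since the analysis operates on unphased diploid calls.
Identity-by-state, the per-SNP identity score against a haploid reference
(equal to the sample REF frequency), and the great-circle distance formula
(sphere radius 6378.135 km) are provided for the relatedness and geography
side-analyses.

## Sweep scan

Domestication sweeps are called as *joint* upper-tail outliers: each of
(π log-ratio, FST) is z-scored against its empirical genome-wide
distribution and a window is flagged when both one-sided normal p-values
fall below the tail probability p (default 0.005), i.e. the Z test is
interpreted as one-sided with a joint AND — the two published cutoffs are
simultaneous lower bounds.  Because absolute cutoffs are dataset-specific,
the scan is parameterised by p and reports the realised cutoffs on the
statistic scale; fixed cutoffs can be supplied instead.  Flagged windows
that overlap or are bookended merge into regions carrying peak statistics;
genes overlap a region if the half-open intervals intersect by ≥ 1 bp.

Called regions are validated by one-sided Wilcoxon rank-sum contrasts:
domestic Tajima's D lower in sweep windows than background, and mean
within-window r² higher.  The rank-sum test uses mid-ranks; groups smaller
than 10 are tested by exact enumeration of group assignments, larger ones
by the normal approximation with tie and continuity corrections.  The
population-structure robustness check repeats the scan with D1 and D2
separately against W on the identical window grid and reports the fraction
of pooled-scan genes significant (overlapping a flagged window) in both
subscans.  Category enrichment is a per-category 2×2 χ² test without Yates
correction with Benjamini–Hochberg control at q < 0.05.

Note on region sizes: merged regions are unions of 50-kb windows, so their
minimum span is one window; published region sizes extend below that,
implying an untrimmed-boundary convention that is not described and is not
reproduced here.

## Coalescent engine

The demographic model is a structured coalescent for two populations (W,
D) that merge into an ancestor of size N_anc at t_div generations before
present, with piecewise-constant sizes (instantaneous changes only — no
continuous growth, matching the inference family used), and optional
backwards-in-time migration expressed as per-lineage, per-generation
movement probabilities.  Calendar times convert at g = 3 yr/generation.
Loci are unlinked and non-recombining, matching the independence
assumptions of SFS-based inference.

Two simulation paths share one event-driven core:

* a Python path that returns full genealogies and infinite-sites
  haplotypes (used to emit VCFs), and
* a compiled (numba) kernel that accumulates, for each branch, its length
  into the joint-SFS cell indexed by the branch's descendant counts in
  (W, D).

The kernel's branch-length matrix yields both the expected joint SFS
(expected counts are μ·L·E[length]; a Rao-Blackwellised, low-variance
estimator) and exact SFS sampling: conditional on the genealogies the cell
counts are Poisson, and because loci are independent the Poisson rates sum
— a draw on the summed matrix is distributionally identical to
site-by-site simulation.  A guard on the per-tree event count aborts
parameterisations that cannot coalesce.  Seeded runs are bit-reproducible.
The two paths are cross-checked against each other, against single-
population closed forms (E[π] = 4Nμ, E[S] = θa₁, ξ_i ∝ 1/i), and against
an independent established coalescent simulator under the identical
demography.

The folded joint SFS pools each cell (i, j) with its complement
(n_W−i, n_D−j); a pair at exactly half the pooled total maps to its
lexicographically smaller member, kept once.  Monomorphic cells are
excluded from all likelihoods.

## Demographic inference

The composite log-likelihood of an observed joint SFS is multinomial over
polymorphic cells, Σ m·ln p, with cell probabilities estimated by
simulation.  Zero cells of the estimated spectrum are floor-bounded at one
tenth of a site out of the expected polymorphic total before
renormalisation, so the likelihood stays finite — standard practice in
simulation-based SFS likelihoods.

Fitting maximises this likelihood by multi-start Nelder–Mead over
log-parameters (default 50 starts, log-uniform initial points within
bounds).  Within one start every evaluation reuses the same simulation
seed (common random numbers), making the surface deterministic and smooth
per start; starts use fresh streams.  The ECM cycling of the original
inference tool is an internal optimiser detail; the contract — maximise a
simulated composite likelihood — is unchanged.  Models are ranked by
AIC = 2k − 2lnL, and uncertainty comes from a parametric bootstrap:
simulate datasets at the fitted parameters, refit, take percentile 2.5/97.5
intervals (an error is raised if fewer than 80% of replicates converge).

The published analysis searched thirty two-population model topologies;
the full list lives in supplementary material and is not reproducible from
the main text, so the package ships ten representative archetypes (strict
isolation, isolation-with-migration, each with instantaneous size changes
in the wild daughter, the domestic daughter, or both, plus the full
domestication scenario with and without migration) as configurable
`ModelSpec`s; users can define further topologies the same way.

### The reference scenario

`domestication_scenario()` encodes the best-supported history with its
published point estimates as defaults: divergence (domestication) 7,300 yr
BP; domestic Ne 1,100 from domestication until a six-fold expansion to
6,500 at 3,600 yr BP; wild Ne 21,200 until a recent collapse to 1,700
about 500 yr BP.  The ancestral size is not printed in the main text; the
package defaults it to the pre-decline wild size, and recovery experiments
use zero migration (absolute per-epoch migration rates are likewise not
printed and must be user-set when wanted).

Parameter-recovery experiments simulate a folded joint SFS for the study's
sample sizes (13 + 59 diploids) from ≥ 30,000 unlinked 1-kb loci at
μ = 10⁻⁸/bp/generation and profile the composite likelihood over each
parameter on a 17-point log-grid spanning 0.25×–4× truth (19% steps), with
150,000 genealogies per likelihood evaluation so that Monte-Carlo noise
cannot move the maximiser by more than one grid step.  The two recent
wild-side quantities (post-decline size, decline timing) are the most
weakly identified, as expected for a short terminal epoch; the acceptance
script therefore simulates 100,000 observed loci.

## Synthetic study generator

`generate_study` emits a complete truth-annotated stand-in for the real
dataset: VCF, sample map, gene BED, truth table and folded joint SFS.  The
neutral background uses the reference scenario plus symmetric migration
m = 5×10⁻⁴ per lineage per generation (≈ 6.5 migrants/generation into the
domestic pool), chosen so the background reproduces the study's stated
structure — weak differentiation (FST ≈ 0.05) and near-equal wild and
domestic diversity.  The default genome is 2 chromosomes × 3 Mb tiled from
1-kb loci: large enough for ~590 sliding windows and stable empirical null
distributions, small enough for desk-scale runtimes.

Sweeps are injected phenomenologically, without a selection simulator.  A
naive local reduction of domestic Ne lasting to the present acts like a
pure bottleneck and *raises* domestic Tajima's D (loss of rare variants) —
the opposite of a sweep's signature.  Each sweep is therefore modelled as
a transient local bottleneck: domestic Ne is multiplied by s (default 0.1)
from the onset (default: domestication) until a recovery time (default:
a quarter of the way back to the present), after which the genome-wide
size applies and rare variants regrow; effective gene flow is suppressed
at the swept locus, as expected under divergent selection (otherwise
migrant wild lineages coalesce through the domestic bottleneck and the
wild population's local diversity collapses too, erasing the log-ratio
contrast).  This reproduces all four scanned signatures simultaneously:
reduced π_D, elevated FST, negative domestic Tajima's D, elevated LD.
With the default strength and 100-kb spans, the scan at p = 0.005 attains
recall 1.0 and region-level FDR 0 over ten seeds, and the Tajima's D
validation contrast is significant in all ten.

What the generator does *not* emulate: within-chromosome linkage between
loci (windows therefore mix independent genealogies; fine for windowed
scan statistics, but genome-wide LD decay is not realistic beyond the 1-kb
locus scale), sequencing error and depth variation (genotypes are exact,
so depth-based filters are exercised only via exclusion masks), genotype
imputation artefacts, and reference bias.  Passing the end-to-end tests
shows the pipeline's statistics and calling logic behave correctly under
the modelled signal structure, not that the thresholds would attain the
same power on real resequencing data.

## Numerical conventions

* Undefined statistics (π log-ratio with zero diversity, D with S = 0,
  r² at monomorphic sites, FST in doubly monomorphic windows) are NaN and
  excluded, never imputed.
* The scan requires non-degenerate empirical distributions and raises on
  zero variance; NaN windows cannot be flagged.
* acos arguments in the great-circle formula are clamped to [−1, 1];
  coincident points return exactly 0.
* All randomness flows from explicit seeds; kernel runs are
  bit-reproducible given (seed, parameters).
* Nelder–Mead tolerances: xatol 10⁻³ on log-parameters, fatol 10⁻² in lnL
  units; out-of-bounds proposals are clipped with a linear penalty.

## Known limitations

* No recombination and no haplotype-based statistics (iHS, XP-EHH are out
  of scope); r² validation uses within-locus structure only.
* Multiallelic sites and indels are skipped on read.
* The archetype family approximates, not reproduces, the original
  thirty-model search space.
* Windowed Watterson θ and Tajima's D use the full population sample size
  per window; with missing data the effective n varies per site, which
  slightly biases these two statistics in low-call-rate windows (π and
  FST handle per-site n exactly).
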