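# yakpop

Population-genomics pipeline for yak domestication analysis: a
sliding-window selective-sweep scan contrasting wild and domestic gene
pools, and coalescent demographic inference from the folded joint site
frequency spectrum (SFS).  Written for analyses of wild vs. domestic yak
(*Bos grunniens*) resequencing panels, but any two-population diploid SNP
dataset with a wild/domestic-style contrast fits.

## What it computes

**Sweep scan.**  From a VCF of diploid biallelic SNPs and a
sample→population map (wild `W`, domestic `D1`/`D2`), the pipeline filters
sites (call rate ≥ 90% per gene pool, exact Hardy–Weinberg test p ≥ 10⁻³),
slides 50-kb windows in 10-kb steps (≥ 80% callable), and computes per
window: nucleotide diversity π per population, Watterson θ_w, Tajima's D,
Hudson's F_ST (ratio of averages), and the diversity log-ratio

    ln(π_W) − ln(π_D)

Windows jointly in the upper tail of both the log-ratio and F_ST
(one-sided Z test against the empirical genome-wide distributions, both
p < 0.005 by default) are flagged, merged into candidate sweep regions,
annotated with overlapping genes, and validated by rank-sum contrasts of
domestic Tajima's D (lower in sweeps) and LD (r², higher in sweeps), plus
a D1/D2 robustness check and χ²/FDR category enrichment.

**Demographic inference.**  A two-population structured coalescent
(piecewise-constant sizes, divergence into a common ancestor, optional
migration) powers simulation-based composite-likelihood inference from the
folded joint SFS: multinomial likelihood over SFS cells, multi-start
simplex optimisation with common random numbers, AIC model ranking, and
parametric-bootstrap confidence intervals.  The built-in reference
scenario encodes the published best-fit yak history (domestication
7,300 yr BP; domestic Ne 1,100 → 6,500 at 3,600 yr BP; wild Ne
21,200 → 1,700 at ~500 yr BP; generation time 3 yr).

**Synthetic studies.**  `yakpop.synthetic_data` generates complete
truth-annotated stand-ins (VCF + sample map + genes + truth table + SFS)
with injected sweeps of known location and strength, so the whole pipeline
is testable without any external data.  See `docs/methods.md` for the
models and design choices.

## Worked example

Simulate a default study (13 wild + 59 domestic diploids, 2 × 3 Mb genome,
four 100-kb sweeps of strength s = 0.1), scan it, and fit demographic
models to its SFS:

```
yakpop simulate --outdir run --seed 1
yakpop scan --vcf run/study.vcf --sample-map run/samples.tsv \
            --genes run/genes.bed --outdir run
yakpop fit --sfs run/joint_sfs.tsv --models si,im --n-starts 3 --outdir run
yakpop report run
```

`yakpop report run` prints (seed 1):

```
sweep regions: 4
  mean size: 100.0 kb (range 100-100 kb)
  genes overlapped: 5
realized cutoffs: log-ratio > 2.085, FST > 0.198 (p=0.005)
sweep vs background domestic Tajima's D: one-sided p = 4.22e-20
demographic fits (AIC-ranked):
  si: lnL=-129116.5 k=3 AIC=258238.9 dAIC=0.0
  im: lnL=-129141.0 k=4 AIC=258290.0 dAIC=51.1
simulated study: seed=1 hash=a4bbadc1c78966d2
```

Reading this: the scan recovered all four injected 100-kb sweeps (and
nothing else); the realised statistic cutoffs are the analogues of fixed
published thresholds, reported so runs are comparable across datasets; and
the strongly significant Tajima's D contrast confirms the sweep signature.
The quick two-model fit ranks the three-parameter strict-isolation
archetype first: both single-epoch archetypes are deliberately simpler
than the generating history (size changes plus gene flow), and at this
simulation budget (5,000 genealogies per likelihood evaluation, 3 starts)
AIC differences of this order also carry Monte-Carlo noise — the full
`scenario_si`/`scenario_im` archetypes with more starts and loci are the
serious inference route (see `docs/methods.md`).

The same functionality is importable as a library
(`yakpop.genotype_io`, `popgen_stats`, `sweep_scan`, `coalescent`,
`demography_fit`, `synthetic_data`); every CLI artifact is a standard
format (VCF, BED, TSV, JSON) readable without the CLI.

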