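# Methods

## The screen model

A pooled CRISPRi screen measures, for every sgRNA *g*, the change in its
relative abundance between a *before* and an *after* sample of the same
biological replicate. Writing `n(g, s)` for the read count of guide *g*
in sample *s*, the package models counts as negative-binomially
distributed around expectations proportional to guide abundance, and the
per-guide signal as

    log2FC(g) = mean over replicates r of
                log2[(n_after(g, r) + ε) / (n_before(g, r) + ε)]

after normalization (below). In a growth screen the expected log2FC of a
guide with per-generation fitness cost *w* over *G* generations is
`w·G`; in a phage screen it is the log2 ratio of survival
probabilities; in a transduction screen it combines growth, lysis and
packaging effects.

## Normalization

Read counts are normalized by the counts of a single non-targeting
control guide: the control's per-sample counts define the size factors,
exactly as one would override the size factors of a count-based
differential test with a spike-in. Two refinements keep this usable:

1. **Scale.** The raw ratio `n(g,s)/n(control,s)` (exposed as
   `normalize_by_control`; the control row becomes 1) has arbitrary
   units. For quantities that need a count scale — `baseMean` and the
   `baseMean < 10` phage-screen read floor — the control size factors
   are geometric-mean-centred (`sf_s = ctl_s / geomean(ctl)`), which is
   what a DESeq2-style `controlGenes` size-factor estimate produces.
   The centring constant cancels in every before/after ratio, so
   log2FC is identical on either scale.
2. **Residual shared noise.** A single control guide is itself a noisy
   count: its sampling error shifts *every* guide of that sample by the
   same factor and would both bias log2FC by a shared offset and break
   the calibration of the per-guide test. After control normalization,
   the estimator therefore removes the residual per-sample factor as
   the median across guides of the ratio to a per-guide geometric-mean
   reference (median-of-ratios against a pseudo-reference). The control
   still anchors the overall scale; the refinement only absorbs its
   sampling noise. This step assumes a majority of guides are null,
   which holds for every screen in scope: in growth screens most guides
   are intergenic, template-strand or target non-essential genes, and
   in phage screens the control and the bulk of the library share the
   same lysis floor, so the refinement cannot absorb the resistance
   signal.

The pseudocount ε defaults to 0.5 raw reads and is propagated through
the normalization (`ε_s = 0.5 / sf_s`). Because half a read is a
depth-dependent quantity, log2FC is invariant to per-sample depth
rescaling only up to ~ε/min-count; the tests check this invariance on
adequately covered guides.

## The guide-level test

Per-guide dispersion is estimated by the method of moments on the
across-replicate variance of normalized counts within each condition,
`α = (s² − m)/m²`. With three replicates the raw estimate is noisy, so
it is shrunk toward a parametric mean–dispersion trend
`α_trend(m) = a₀/m + a₁` (fitted by least squares across guides, both
coefficients clipped at zero) with weight `(R−1)/(R−1+4)`, and floored
at 0.01. Because the across-replicate variance of normalized counts
already contains every noise source of a sample — counting, library
multinomial sampling, and residual normalization error — no additional
terms are added. The Wald statistic is
`z = log2FC / sqrt(Σ_r var_r / R²)` with the delta-method replicate
variance `var_r = [1/(n_b+ε) + 1/(n_a+ε) + 2α] / ln²2`, two-sided
normal p-values, and Benjamini–Hochberg adjustment over tested guides.
Guides with all-zero counts get p = 1, as does every guide when fewer
than two replicates are available (with a warning).

This is a deliberately documented stand-in for DESeq2, not a port: the
scientifically load-bearing choices are the control-guide size factors,
the unshrunk ratio log2FC, and the downstream medians; exact DESeq2
internals (Cox–Reid dispersion, LFC shrinkage) are out of scope. Under
the null simulation the test's type-I error at α = 0.05 is 0.058–0.062
and the p-value distribution is uniform to a KS statistic < 0.03
(n = 10,000).

## Gene scoring and strand semantics

"Targets the coding strand" means the sgRNA hybridizes to the gene's
sense (coding, non-template) strand — the orientation that blocks the
elongating RNA polymerase — i.e. the protospacer lies on the template
strand, so `targets_coding = (protospacer strand ≠ gene strand)`. The
gene score is the median log2FC of coding-strand guides, with the
unscaled median absolute deviation (no 1.4826 consistency factor) as
the error summary. Candidate essential genes satisfy
`median_coding < −2` strictly; ties at the threshold are not called.
ROC curves score `−median_coding` with midrank tie handling (AUC by the
Mann–Whitney identity), over genes with at least one coding-strand
guide. Phage resistance scores are the same aggregation over
post-infection log2FC; the selection rule keeps genes with > 1 coding
guide scoring above 20% of the screen's maximum.

## Operon (polar-effect) classification

dCas9 silencing propagates to all downstream genes of a transcription
unit. Within a TU read in transcription order, a depleted gene whose
next *observed* gene is also depleted stays *potentially essential*
(its signal may be entirely polar); the most downstream gene of each
maximal depleted run is *confidently essential* — an intervening clean
gene proves that any further-downstream depletion is independently
driven. A non-depleted gene upstream of a depleted one is an
*internal-promoter candidate*. Genes with no coding-strand guides are
"unobserved": skipped when scanning downstream and never called.
Monocistronic depleted genes are confidently essential. Genes present
in several TUs are classified under each, flagged, and counted once in
summaries (potential beats confident).

## The transduction model

For each gene, ordinary least squares of `y = β₀ + β₁x + β₂z` over all
retained coding-strand guides, where z marks the focal gene's guides —
the only reading under which a per-gene Boolean factor is meaningful —
against the reduced model `y = β₀ + β₁x`, giving a 1-df nested F-test.
β₂ ("estimate") ranks genes; a hit has BH-FDR < 0.05, and negative
estimates mean silencing decreases functional-capsid output. Guides
lacking a growth log2FC are dropped and counted. Degenerate designs are
handled explicitly: a collinear (x, z) pair returns p = 1 with a
warning; a perfect full fit returns F = ∞ (p = 0) unless the reduced
model is equally perfect, in which case F = 0, p = 1.

## The synthetic-data generator

The generator emulates, with everything derived from one mandatory
seed:

- a circular chromosome of i.i.d. uniform ACGT (default 200 kb) packed
  with non-overlapping genes (300–1,200 nt) in operons of geometric
  size (mean 2) sharing a strand;
- essential labels planted at the operon level — essential genes
  cluster in operons in real bacterial genomes, and that clustering is
  what keeps gene-by-gene calling accurate despite polarity — with a
  35% chance that only an operon's downstream tail is essential, which
  leaves upstream genes as polar false-positive generators;
  near-essential genes (default 10%) cost 30% of an essential gene's
  fitness; a 15% subset of essentials is dosage-"sensitive";
- a guide library sampled uniformly from all NGG-adjacent 20-mers
  (default 8,000 guides) plus the non-targeting control;
- per-guide fitness `w = efficiency × Σ strand-scaled costs of silenced
  genes`: the target gene plus, under polarity, all downstream TU
  genes; template-strand targeting scales costs by 0.1 except for
  sensitive genes (full effect); repression efficiency is uniform on
  (0.75, 1); bad-seed guides pay an extra −0.08 per generation. Full
  silencing of an essential gene costs N(−0.4, 0.1) doublings per
  generation, so over the default 17 generations a fully effective
  coding-strand guide reaches log2FC ≈ −6, matching the depleted tail
  of a real growth screen qualitatively;
- counts: initial abundances are log-normal (σ = 0.7); samples are
  multinomial at depth 10⁶ and then gamma-Poisson overdispersed
  (dispersion 0.05), three independent before/after replicate pairs;
- phage screen: the before sample follows 8 generations of induced
  growth (the pre-infection outgrowth); survival is 0.8 for guides that
  effectively silence a host factor (coding strand, directly or polar)
  and 0.02 otherwise;
- transduction screen: compared against the initial pool, packaged
  output reflects growth over the full 17 generations, the lysed
  fraction (lysis-protected cells package less), and a −3 log2
  packaging penalty when a capsid-competence gene is silenced — so the
  regression of transduction on growth log2FC has slope ≈ 1 by
  construction when no capsid genes are planted.

What the generator does **not** emulate: sequence-dependent guide
activity, mismatch-tolerant off-target binding (only exact PAM-proximal
suffix matches exist, planted by chance), PCR jackpots or
GC-dependent depth bias, phage kinetics (MOI, adsorption time courses)
— survival is a per-guide multiplier — and read-level artefacts
(counts, not FASTQ, are generated). Passing recovery tests therefore
demonstrates that the statistics recover the model's own structure at
realistic noise levels, not that they are robust to every artefact of
real sequencing data.

## Problem sizes and numerical choices

Tests and the acceptance script run the generator's default conditions
(200 genes, 8,000 guides, 3 replicates, depth 10⁶) and two null
configurations (10,000 guides with no planted effects; 300 genes with
no phage/capsid labels), sizes at which the full pipeline completes in
seconds while estimates are stable. Dispersion floor 0.01; Fisher's
two-sided p by the minimum-likelihood rule (hypergeometric tails
accumulated in log space, exact at p ≈ 10⁻⁴¹); Mann–Whitney with
normal approximation and tie correction, p = 1 when all values tie;
gene-overlap ties in guide annotation resolved by smallest left
coordinate then name order; genomic coordinates 0-based half-open
internally and 1-based inclusive in files.

## Known limitations

- Single-control normalization leaves a residual scale tied to the
  majority-null assumption; screens where most guides shift in one
  direction (e.g. near-total library collapse) would bias log2FC.
- The Wald test is mildly anti-conservative (~0.06 at nominal 0.05)
  with three replicates; users needing strict control should treat the
  BH threshold accordingly.
- The per-gene transduction F-test inherits OLS homoscedasticity
  assumptions; strongly depleted genes with near-zero transduction
  counts have inflated residuals and can appear as spurious hits, a
  property shared with the modelling approach it implements.
- Off-target QC is exact-suffix only by design; mismatch-weighted
  models are out of scope.
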