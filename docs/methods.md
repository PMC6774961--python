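# Methods

## The estimand

The analysis asks whether the relative probabilities of the 96
strand-collapsed triplet mutation classes depend on local heterozygosity.
The unit of observation is a *focal rare variant*: a biallelic SNP carried
on 1–5 chromosomes, all of whose carrier samples belong to one major
geographical region. Such variants are young (copy number is an inverse age
proxy; doubletons in 1000 Genomes-scale panels are mostly < 500 generations
old), so present-day heterozygosity around them approximates the
heterozygosity in which the mutation arose, and region confinement further
filters out older, dispersed alleles.

### Classification

The ancestral triplet is the panel-wide **major** allele at the focal site
flanked by its immediate reference bases; the derived base is the minor
allele. Flanking bases are always taken from the reference even when a
flanking site is itself polymorphic — unphased data give no better option,
and any misassignment only adds classification noise. Triplets are
strand-collapsed so the central ancestral base is A or C: 64 triplets → 32,
each with 3 derived bases, giving 96 classes from 192 raw strand-specific
pairs (an exact 2-to-1 partition, tested exhaustively). Exact 50/50 allele
ties (possible only in tiny panels) leave the direction undefined and are
skipped with a counter, as are sites whose triplet context contains an
ambiguity code or touches a contig edge.

### Window heterozygosity

For each focal variant, the score is the **sum** of per-site expected
heterozygosities `2p(1−p)` over all SNPs within ±1 kb (a 2 kb window),
where `p` is the allele frequency in the focal variant's own region with
missing genotypes dropped from the denominator. A sum rather than a mean is
what makes the published binning ("bin 30 holds scores above 30")
attainable in 2 kb of human data. Expected rather than observed
heterozygosity is used because low-coverage panels estimate frequencies far
better than individual genotypes; linkage disequilibrium between window
SNPs inflates only the error variance, which biases slopes toward zero —
i.e. conservatively. The focal site is excluded from its own window so the
response cannot leak into the predictor (its own contribution would be
≤ 2·(5/N)(1−5/N) anyway). Scores are binned by `bin = min(⌊score⌋+1, 30)`:
unit-width bins with the top bin absorbing overflow, deterministic and
monotone. Window half-width and bin count are parameters
(`window_half_width`, default 1000 bp; `n_bins`, default 30); a 10 kb
half-width rerun reproduces the 20 kb-window robustness comparison.

### Regression

Within each (class, region, copy-number) stratum, class counts per bin are
binomial out of the bin margin (all focal variants in the bin), with the
bin index as a single numeric covariate on the logit scale. Fits use a
standard IRLS binomial GLM; the test suite checks agreement with an
independent hand-written Newton–Raphson implementation to 1e-6 and against
the closed-form two-bin solution (slope = difference of logits). A bin
enters a fit only if its margin is non-zero; at least two such bins are
required. Degenerate strata — class never observed, class being every
observation, or separated fits (|slope| > 100 or non-finite standard
errors) — are reported as missing values with a reason code, never as
zeros, so the downstream GC trend is not biased by pseudo-zeros. Because
each class is fitted against all others, the 96 fits per stratum sum to
a closed system and are not independent; no multiplicity correction is
applied and p-values are raw. A weighted-least-squares fit on raw
proportions (`family="gaussian"`) is available for comparison only.

### Summaries

*Cross-region concordance*: per class, the across-region standard deviation
of slopes; per region pair, the Pearson correlation of the two 96-class
slope vectors (pairwise-complete). Concordance across the five regions is
the key internal-replication argument: each region is an independent sample
of recent mutations.

*GC trend*: per central base-change type (6 types × 16 classes), class
slopes are averaged **unweighted** across regions and correlated with the
triplet's G/C count (0–3); two-sided p from the t-distribution with
n − 2 df (14 when all 16 classes fit). Singletons and doubletons are
analysed separately.

*Indel proximity*: the fraction of SNP records within 5 bp of an indel on
the same contig — the transparency diagnostic justifying the deliberate
absence of any quality/accessibility filtering. No other filtering is
applied anywhere; every exclusion is counted and logged so that
input = retained + Σ skips is checkable from the manifest.

## The synthetic generator

`hetspec.simulate` emulates exactly the statistical structure the estimator
assumes, so parameter recovery is an identity test of the estimator, not a
model-realism test:

* **Reference**: i.i.d. uniform A/C/G/T contig.
* **Background common SNPs**: Poisson-placed with piecewise-constant
  per-bp densities over equal contig segments; alt frequency uniform on
  (0.05, 0.5) (mean per-site expected heterozygosity 0.365); genotypes HWE
  per sample. The density profile is what creates the spatially varying
  heterozygosity landscape; a density *d* yields window scores ≈
  2000·d·0.365, and the presets choose densities so realised scores span
  bins 1–30.
* **Focal variants**: positions drawn uniformly (≥ 3 bp apart and away
  from background SNPs so triplet contexts never overlap), region uniform,
  copy number from (0.45, 0.25, 0.15, 0.10, 0.05) over 1–5 — singletons
  commonest, as in real panels. The class is drawn from
  `P(t | bin b) ∝ w_t · exp(β_t · b)`, conditioning on the **bin** with a
  logit-linear link — the regression's estimand. The reference is rewritten
  so the ancestral triplet at the site equals the drawn class's triplet, on
  a random strand (so strand collapse is exercised); carriers are sampled
  without replacement from the region's chromosomes (homozygous rare
  carriers arise naturally).
* **Default slopes** `β_t`: deterministic recipe mirroring the qualitative
  human pattern — C→T transitions mostly negative, A→G mostly positive, a
  positive GC gradient (+0.015 per G/C) in every type, plus a small fixed
  per-class jitter (σ = 0.008) so all 96 values are distinct. Class base
  weights default to uniform.
* **Planted violations**: cross-region doubletons and >5-copy variants as
  negative controls for the selection rule; sparse 1 bp indels to exercise
  the proximity diagnostic.

Identical config + seed reproduces the on-disk bundle byte-for-byte (the
VCF writer emits a minimal deterministic VCF 4.2 for exactly this reason).

### Truth vs estimate

The generator's true window score uses the background landscape only,
whereas the estimator's landscape also contains the rare focal variants
themselves (the "all SNPs" rule). At recovery-preset densities this
contaminates scores by ≲ 1 score unit of roughly position-independent
noise, an errors-in-variables effect that attenuates recovered slopes by
under ~2% — well inside the acceptance band, and absent from real-scale
panels where a rare variant contributes only ~2/N to the score.

### What passing does and does not show

The generator has no linkage disequilibrium, recombination, demography,
mutation clustering, CpG hypermutability or sequencing error; regions are
exchangeable with equal sample sizes. Passing recovery therefore
demonstrates that the selection, classification, windowing and regression
machinery estimate the generative slopes correctly — it does not validate
the HI interpretation on real data, where LD and shared history make
regions non-independent in ways the concordance statistic cannot see.

## Problem sizes and presets

* `smoke` (default CLI preset): 150 kb contig, 5 regions × 6 samples,
  400 focal variants, a second or so end-to-end — plumbing checks only.
* `recovery`: 20 Mb contig, 5 regions × 60 samples, 10⁶ focal variants,
  8-step density ladder; analysed in-memory in ~1–2 minutes. At this scale
  the recovered slopes regress on the generating slopes with slope
  1.00 ± 0.01, R² ≈ 0.997, and mean pairwise cross-region concordance
  r ≈ 0.98 (computed fresh by the tests and `scripts/acceptance.py`).
* `discordant`: 5 Mb / 2.5·10⁵ variants with one region's slope vector
  replaced by independent noise of matched scale; its concordance with the
  other regions collapses to ≈ 0 while the others stay > 0.9.

## Numerical choices

* All coordinates 1-based (VCF convention); reference slices use 0-based
  half-open arithmetic only at the format boundary.
* Bases uppercased on read; soft-masking ignored.
* Window scores clamped at 0 to absorb −1e−16 cumulative-sum residue.
* Canonical class order (triplet, then derived base, lexicographic) fixes
  every output table's row order; reruns are byte-identical.
* Copies counted as minor-allele chromosomes; a single homozygous carrier
  satisfies region confinement trivially.
* Sites where the reference allele is the minor allele are retained, with
  the alt allele as the ancestral state.
* Autosome-style single-contig analysis by default; a contig allowlist
  restricts multi-contig inputs (sex chromosomes and MT are a user
  decision, not a default).

## Known limitations

* Phased haplotypes, BCF/CRAM and liftover are out of scope.
* The per-class GLM ignores overdispersion; standard errors on real data
  will be optimistic where mutations cluster.
* `hetscore`'s landscape construction materialises the site list; for
  whole-genome VCFs run per chromosome via the contig allowlist.
* Extended contexts (5-/7-mers) and outgroup-based ancestral inference are
  not implemented; the major-allele rule misassigns the ancestral state
  only for high-frequency derived alleles, which the 1–5 copy rule
  excludes.
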