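# hetspec

Does local heterozygosity change *which* mutations happen?

`hetspec` implements an analysis of the relationship between flanking
sequence diversity and the human triplet mutation spectrum. Point mutations
are classified by their ancestral 3-mer context into 96 strand-collapsed
triplet classes (e.g. `TCC(T)` for TCC → TTC). Young mutations are proxied
by rare variants (1–5 allele copies) from a multi-sample VCF whose carriers
are all confined to one major geographical region. For each such variant the
local diversity is summarised as windowed expected heterozygosity, and a
per-class binomial regression asks whether the class's share of all
mutations rises or falls with that diversity. The motivating idea is the
heterozygote-instability (HI) hypothesis: heterozygous sites become
mismatches in meiotic heteroduplex DNA and are "repaired" by gene-conversion
events whose extra DNA synthesis carries its own error spectrum, so regions
of high diversity should sample a measurably different palette of mutations.

The package is aimed at population geneticists who want to run this analysis
on 1000 Genomes-style data (indexed FASTA reference + multi-sample VCF +
sample/population/region panel), and at method developers who want a fully
synthetic, ground-truthed harness for context-dependent mutation-spectrum
estimators.

## The model

For focal variant *v* in region *r*, flanking diversity is scored over a
window of half-width *w* (default 1 kb, i.e. a 2 kb window):

```
H(v) = Σ_{s : |pos_s − pos_v| ≤ w, s ≠ v}  2 p_s (1 − p_s)
```

where `p_s` is the allele frequency of SNP *s* computed from region *r*'s
samples (expected heterozygosity under Hardy–Weinberg; robust to
low-coverage genotypes). Scores are discretised into 30 unit-width bins,
bin 30 absorbing all larger scores. For each mutation class *t*, region and
copy-number stratum, the count of class-*t* variants out of all variants in
bin *b* is modelled as binomial with

```
logit P(class = t | bin b) = α_t + β_t · b
```

β_t — the *heterozygosity slope* of class *t* — is the quantity of
interest. A meta-analysis then correlates the 96 slopes (averaged across
regions) with the triplet's G/C content (0–3) within each of the six central
base-change types, using Pearson's r with a two-sided t-test on n − 2 df.

Because each class is regressed against "everything else", the 96 fits per
stratum are not independent and no multiplicity correction is applied;
p-values are reported raw.

## Worked example

Fit the per-class regressions on a hand-written two-bin count table (10% of
mutations are `ACA(T)` in bin 1, 20% in bin 2):

```bash
cat > counts.csv <<'EOF'
region,copy_number,het_bin,class,count
Africa,1,1,ACA(T),10
Africa,1,1,TCC(T),90
Africa,1,2,ACA(T),20
Africa,1,2,TCC(T),80
EOF
hetspec regress --counts counts.csv --out slopes.csv
```

`slopes.csv` contains one row per class; the two observed classes fit as

```
 class region  copy_number    slope  std_err  intercept  n_trials
ACA(T) Africa            1  0.81093 0.416667  -3.008155       200
TCC(T) Africa            1 -0.81093 0.416667   3.008155       200
```

`0.81093 = logit(0.2) − logit(0.1)` is the exact saturated-model slope: the
log-odds of being an `ACA(T)` mutation increase by 0.81 per heterozygosity
bin. The 94 unobserved classes are flagged `no_successes` with missing
slopes, never silent zeros.

A full synthetic end-to-end run (generate fixture, then analyse):

```bash
hetspec simulate --preset smoke --seed 11 --outdir fix
hetspec run --fasta fix/reference.fa --vcf fix/sites.vcf \
            --panel fix/panel.tsv --outdir out
```

which prints a fit summary ("strata fitted: 2400 ok: 370 ...") and writes
`focal_variants.csv`, `binned_proportions.csv` (class proportions × 1000 per
region/copy/bin), `slopes.csv`, `concordance.csv`, `gc_trend.csv`,
`indel_proximity.txt` and a `manifest.json` recording the configuration and
all skip counters. On real data the same command is pointed at the reference
FASTA, the release VCFs and the sample panel; `--window-half-width 10000
--label w20kb` reruns everything with a 20 kb window under a separate label.

The smoke preset is deliberately tiny (≈400 focal variants), so its
per-class slopes are noisy; the `recovery` preset (10⁶ focal variants,
known per-class slopes) is the scale at which the estimator's accuracy is
demonstrated — see `docs/methods.md`.

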