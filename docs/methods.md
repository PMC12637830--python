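# Methods

This note documents the models, estimators and numerical choices behind
`agpopgen`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Data model and conventions

All coordinates are 1-based inclusive, matching VCF; BED input is converted
on read. Genotypes are alternate-allele counts in {0, 1, 2} with −1 as the
missing sentinel. Missing calls are excluded from every allele-frequency
denominator — they are never treated as reference. Phased haplotypes, when
present, are stored as a (2·samples) × variants binary matrix whose row
pairs sum to the genotype matrix; loading a VCF populates haplotypes only
when every retained record is phased for every sample. Only biallelic SNPs
are modelled; multi-allelic records and indels are excluded on load.

Sample QC keeps samples with median coverage ≥ 10×, genome fraction
strictly > 0.5 and cross-contamination strictly < 4.5% (a sample at exactly
4.5% is excluded). Cohorts are (location, year) groups; groups below 10
members remain listed but are skipped by all cohort statistics. Analysis
SNPs require minor allele frequency strictly > 0.002 and (by default) no
missing data; when more than the target count (default 100 000) survive,
thinning is deterministic index striding — variant *i* of the output is
passing variant ⌊i·m/target⌋ — so "evenly spread" selection is reproducible
without a seed.

## Estimators

**Hudson's F<sub>ST</sub>.** Per variant, with sample frequencies p̂₁, p̂₂
and allele-copy totals n₁, n₂ (two per called diploid genotype):
N = (p̂₁−p̂₂)² − p̂₁(1−p̂₁)/(n₁−1) − p̂₂(1−p̂₂)/(n₂−1) and
D = p̂₁(1−p̂₂) + p̂₂(1−p̂₁). Variants need ≥ 2 called copies per cohort.
Across variants the estimate is the ratio of sums ΣN/ΣD, the standard
recommendation for combining the estimator over many sites: ratios of
per-site averages are far less biased than averages of per-site ratios.
The finite-sample terms make N unbiased for the squared frequency
difference, which is why a cohort compared against itself has a *negative*
numerator sum on polymorphic data — a property the tests assert.

**Diversity.** θ̂<sub>π</sub> sums a(n_v−a)/C(n_v,2) over variants (a alt
copies among n_v called copies) and θ̂<sub>W</sub> is S/a₁ with a₁ the
harmonic number over the cohort's full copy count; both are scaled by
`accessible_sites`, defaulting to the spanned region length — per-site
values are only as meaningful as that denominator, which on real data
should be the accessibility-masked length. Tajima's *D* uses the 1989
constants (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂) derived from the cohort copy
count; *D* is null when S = 0. With per-variant missingness the constants
use the full copy count while π uses per-variant totals — exact for
complete data, a mild approximation otherwise.

**PCA** mean-centres alt counts per variant (mean-imputing any missing
values) and takes a full SVD; variants are deliberately not variance
scaled — with no normalisation named for the analysis this package mirrors,
unscaled centring is the simplest defensible choice, and rare variants are
consequently down-weighted relative to a Patterson-style scaling.

**Neighbour joining** delegates to scikit-bio's Saitou–Nei implementation;
negative branch lengths are clamped to zero with the deficit moved to the
sister branch. On additive distances the reconstruction is exact (verified
by round-tripping random 8-leaf trees, Robinson–Foulds distance 0).

## Taxon assignment

Two AIM panels are scored per sample: a large panel (default 2612 markers)
whose diagnostic fraction separates the gambiae/coluzzii pair from
arabiensis, and a 700-marker panel separating gambiae from coluzzii. The
fraction is diagnostic allele copies over called copies at panel sites
(per-allele counting, so a heterozygous site contributes ½); markers whose
alleles do not match the dataset's ref/alt pair are ignored, and a sample
with no usable site is "unassigned". Thresholds (0.6 / 0.12 / 0.9) are
strict inequalities, so boundary values resolve to "intermediate" — the
conservative side for surveillance.

## Inversion karyotyping

A sample's karyotype score is the mean inverted-allele count over usable
tag SNPs, rounded half-up (0.5 → 1, 1.5 → 2; the tie rule is a package
convention). Missing tags reduce the usable-tag count rather than being
imputed; a configurable minimum (default 1) gates calling. With tag-SNP
concordance r per chromosome copy, the score of a karyotype-k sample is
the mean of 2·tags Bernoulli draws centred on k, so 20 tags at r = 0.95
give > 95% class recovery — the tests verify both this and exactness at
r = 1. Karyotype-frequency tables report percentages over karyotyped
members only.

## CNV calling

Coverage is normalised per sample by its median window depth, placing the
baseline copy number (2, or 1 on the male X) at 1.0. Copy states 0..12 have
Gaussian emissions with means c/baseline and a shared per-sample standard
deviation estimated robustly (1.4826·MAD about the median, floored at
0.02), or supplied explicitly. The transition matrix is symmetric with
self-transition probability 0.96 and the remainder uniform; Viterbi
decoding gives the copy-number path.

A call is a maximal decoded run of ≥ 5 windows above baseline. Its
likelihood score is the ratio of the decoded path's joint probability to
the forced all-baseline path's over the call span, computed in log space;
calls are retained when that ratio exceeds 1000 (≈ 6.9 nats) and the
normalised-depth variance inside the call is below 0.35. The ratio scale is
the only one on which a threshold of 1000 is attainable: an 8–12-window
CN=3 segment at coverage noise σ = 0.25 carries roughly 16–24 nats of
evidence in total.

The self-transition default was set from the operating curve measured on
independent random-seed experiments: the Viterbi switch cost
2·log(st·12/(1−st)) acts as the evidence threshold, and 0.96 (≈ 11.9 nats)
gave ≈ 1 false call per 100 null cohorts of 20 samples × 300 windows at
σ = 0.25 while keeping detection of 12-window CN=3 segments at ≈ 0.95.
A residual false-call probability of order 1% per cohort at that noise
level is irreducible for any likelihood-based caller — a five-window noise
excursion averaging 4–5 σ above baseline is statistically indistinguishable
from a genuine amplification. Very high persistence values (e.g. 0.9995)
would push the switch cost above the total evidence of the segments this
caller targets and silently disable detection. Gene-level amplification
frequency is the fraction of cohort members with ≥ 1 retained call
overlapping the gene by any base; genes must strictly exceed 5% in some
eligible cohort to be reported.

## Selection scans

H12 operates on phased haplotypes only (diplotype clustering covers the
unphased representation). Windows are non-overlapping blocks of consecutive
SNPs — 1500 by default — with the trailing partial window dropped.
Window-size calibration scans candidate sizes in ascending order and
returns the smallest whose genome-wide 95th-percentile H12 is below 0.1,
along with the full percentile table. "1500" is interpreted as SNPs per
window: the calibration procedure is only coherent as a function of window
size. Peak calling thresholds at the contig-wide 99th percentile and merges
adjacent windows; both the percentile and the 80%/20% inside/outside
frequencies used to report a cluster's distinguishing variants are package
conventions, configurable.

Diplotype clustering uses city-block distance on alt-count vectors with
complete linkage (monotone merge heights). Per-sample heterozygosity is the
fraction of heterozygous calls in the region; clusters reported as sweep
candidates need ≥ 2 members and mean heterozygosity below the cut.

## Synthetic data

The generator's role is to produce data with the statistical structure each
stage assumes, with recorded truth — not to be demographically realistic.

* **Two demes** follow the Balding–Nichols model: ancestral frequency
  p ~ U(0.05, 0.95), deme frequency ~ Beta(p(1−F)/F, (1−p)(1−F)/F), allele
  draws Bernoulli at the deme frequency. The Hudson estimator's expectation
  under this model equals F, so parameter recovery (±0.002 at F = 0.01 with
  200 diploids/deme and 50 000 variants) is a genuine end-to-end check.
  Sites are independent — no LD, no drift history.
* **Haplotype backgrounds** for sweep scans use a founder-mosaic copying
  model: 8 founder haplotypes, switch probability 2×10⁻³ per SNP, flip
  noise 2×10⁻³. This produces decaying haplotype identity, so H12 is
  elevated in short windows and falls below the 0.1 calibration threshold
  by a few hundred SNPs — making window calibration non-trivial, as on real
  data. Sweeps are planted by replacing a fraction of rows in the window
  with 1 (hard) or k (soft) core haplotypes; recombination during the sweep
  is not modelled.
* **Neutral-SFS haplotypes** (derived counts ∝ 1/c, independent sites) give
  E[θ̂π] = E[θ̂W], centring Tajima's D near zero for the neutrality check;
  they carry no linkage, so they validate the estimator, not demographic
  inference.
* **Coverage** is Normal(copy/baseline, σ)·sample-scale with σ = 0.25 by
  default — a hard noise regime chosen so the caller's filters are
  genuinely exercised. Planted amplifications default to CN 3 over 12
  windows (3.6 kb at 300 bp), the small end of the multi-kilobase gene
  amplifications the caller targets. The minimum-length rule is checked at
  low noise (σ = 0.05), where a 4-window plant decodes to exactly 4 windows
  and is rejected by length; at σ = 0.25 any length-based caller will
  occasionally annex one noisy flanking window, so that check isolates the
  rule itself while the precision/recall experiment covers noise
  robustness.
* **Tag SNPs** flip independently per chromosome copy with probability
  1 − tag_ld, which makes karyotype-recovery rates analytically
  predictable. **AIM panels** draw each allele copy as diagnostic with
  probability `purity`. **Resistance sites** are binomial at per-deme
  frequencies, independent of karyotype and of each other — linkage between
  substitutions and inversions is constructed explicitly in the tests that
  need it.

Passing tests on these generators demonstrates estimator correctness,
planted-signal recovery and rule semantics. They do not demonstrate
robustness to alignment artefacts, batch effects, accessibility masks,
admixture, or realistic recombination/demography — none of which the
generators emulate.

## Problem sizes

The default test and acceptance runs use cohorts of 20–400 diploids,
5 000–50 000 variants, 300-window coverage matrices and 20-seed replicate
experiments; the end-to-end fixture is 60 samples × ~4 000 SNPs across five
contigs. These sizes were chosen so the full statistical checks (parameter
recovery to ±0.002, 20-seed detection rates) run comfortably on a single
CPU while keeping every comparison at its stated tolerance.

## Known limitations

* Multi-allelic sites, indels and structural variants other than
  amplifications are out of scope; deletions are not called.
* Effect annotation is consumed, never predicted; the annotation TSV is
  trusted for amino-acid labels.
* H12 requires phased input; no statistical phasing is performed.
* The coverage HMM assumes homoscedastic Gaussian noise per sample; real
  coverage is overdispersed and GC-biased, which the normalisation only
  partly absorbs.
* Per-site diversity values depend on the accessible-sites denominator
  supplied by the caller.
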