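# Methods

This note records the statistical models the package implements, the
defaults and why they were chosen, what the simulators do and do not
emulate, and the numerical conventions a maintainer needs.

## Pairwise mismatch rate (PMR)

Model: each individual contributes one uniformly sampled allele per
covered site (pseudo-haploid calling). For sites with alternate-allele
frequency *p*, two unrelated outbred individuals mismatch with
probability 2p(1−p); averaging over the panel gives the baseline
*b* = Σ 2pᵢ(1−pᵢ)/L. A pair sharing a fraction *r* of the genome
identical-by-descent mismatches only at non-IBD-sampled alleles, giving
E[PMR] = b(1 − r/2). This holds exactly under independent sites, no
inbreeding and frequency-representative cohorts; it degrades with
strong inbreeding, contamination, or reference bias, none of which are
modeled.

Decision rule: the expected ratios define four hypotheses
(r = 1, 0.5, 0.25, 0); a pair is assigned the degree whose expected PMR
is nearest the observed rate, with ties broken toward the more distant
relationship. No decision rule is canonical in the literature for this
statistic; nearest-expected-value is transparent and symmetric, and the
conservative tie-break avoids over-claiming kinship. Pairs with fewer
than 10,000 overlapping SNPs (configurable) are reported but left
`undetermined`: at smaller overlaps the binomial noise of the rate
(≈ √(b(1−b)/n) ≈ 0.005 at n = 10,000, b = 0.3) approaches the 1/16·b
half-gap between adjacent degrees.

Baseline: cohort median by default when a cohort is supplied (robust to
a minority of truly related pairs), otherwise the analytic
frequency-expected value. All sites of the supplied matrix are used; a
transversions-only analysis can be had by subsetting the panel before
calling.

## Rx sexing

ratioₐ = (n_X/w_X)/(nₐ/wₐ) over the 22 autosomes; Rx is their mean.
Weights default to GRCh37 chromosome lengths (Mb integers); for capture
data, per-chromosome target counts are the right weights and can be
passed instead. Thresholds (CI < 0.6 → XY, CI > 0.8 → XX) follow the
method's originating convention; they are parameters, not constants.

CI: the 22 ratios share the single X count, so their spread alone
understates the sampling variance — under a multinomial model the
spread-only CI covers the true Rx only ~30% of the time. The reported
SE is therefore √(SE_spread² + Rx²/n_X), a delta-method combination of
the across-autosome spread and the binomial noise of the X count;
simulation shows it unbiased with near-nominal coverage. With 22
ratios the normal approximation is still approximate, which the
function logs.

## Damage profile and trimming

Counting is in molecule orientation (reverse-strand alignments are
reverse-complemented first) and conditional on the reconstructed
reference base: ct5[i] = #(ref C, read T at 5' position i) / #(ref C at
position i), and symmetrically ga3 from the 3' end. Reference bases come
from CIGAR + MD only; soft-clipped bases never enter; positions with
zero opportunities report NaN, not 0. K = 25 terminal positions are
profiled (the mapDamage convention) and the interior baseline pools all
columns more than K from both ends.

Filters: reads are retained iff length ≥ 30 and MAPQ ≥ 30. The ≥ 30
MAPQ boundary (rather than > 30) follows common EAGER-era pipeline
defaults; `mapq_strict=True` switches to a strict inequality.

Trim recommendation: the smallest t per end such that every position
beyond t has frequency ≤ baseline + 2·SE, with SE the binomial error of
the baseline at that position's opportunity count; the reported trim is
the max over ends so a single symmetric mask suffices. Trimming is
masking (N-substitution), not hard clipping, so coordinates survive;
reads with length ≤ 2t are dropped.

## f-statistics

f3(O; A, B) = mean over usable sites of (o−a)(o−b) − h_O/n_O, with
h_O = o(1−o)·n_O/(n_O−1) the unbiased outgroup heterozygosity term,
applied where the outgroup has ≥ 2 observed alleles (below that the raw
product is used and a warning logged). f4 uses the uncorrected product
(a−b)(c−d). Sites are equally weighted. Pseudo-haploid individuals
contribute one allele to frequencies.

Standard errors: weighted delete-one-block jackknife (unequal block
sizes handled by the h_j = n/m_j weighting). Blocks are contiguous 5 Mb
windows by panel position; if that yields fewer than two usable blocks
(tiny or synthetic panels), 20 equal-count blocks are used instead.
Only exact identities are asserted in tests (antisymmetry, A=B
nullity); cross-f4 additivity identities depend on corrections and are
deliberately not promised.

## PCA projection

Reference dosages (alternate-allele fraction per individual, in [0,1])
are mean-imputed at missing entries, centered, and scaled by
√(p̄(1−p̄)) of the site mean (the smartpca normalization); monomorphic
sites are dropped. Components come from SVD; loadings are orthonormal.
A sample is placed by solving min‖L_obsᵀc − x_obs‖² over its non-missing
model sites, which reduces exactly to the fitted scores for
complete-data reference individuals. Projection is refused below 50
usable sites by default — far fewer and the coordinates are mostly
noise.

## Isotopes and osteometrics

Atomic C/N = (C%/12.011)/(N%/14.007); QC passes in [2.9, 3.6], the
standard collagen-integrity window (the ratio is stored at full
precision; 1-dp rounding is for display only — note that recomputing
from percentages already rounded to 1 dp can shift the displayed ratio
by one unit in the last place). Diet summaries group by skeletal
turnover class (rib vs limb), use the n−1 SD, and report SD as missing
for singleton groups. The δ13C mixing window (≤ −18‰ C3-dominant,
≥ −10‰ C4-dominant, mixed between) and δ15N bands (< 9‰ low, 9–12‰
moderate, ≥ 12‰ high animal protein) are conventional collagen readings
and are configurable constants. Cranial-index bins follow the Martin
convention, closed on the left (75.0 is mesocrany, 80.0 brachycrany).
Facial prognathism indices are not classified: the standard facial
index categories do not include an "orthognathous" bin, and no
defensible threshold set exists for one.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical* structure the analyses rely
on: HWE founders on a stated frequency law, Mendelian transmission
(pair mechanisms: duplicate, parent–offspring, full-sib, half-sib,
grandparent, unrelated; second degree defaults to half-siblings, the
simplest two-founder construction), uniform allele sampling with i.i.d.
missingness, multinomial read allocation with the X weight halved for
XY, exponential terminal deamination d₀·λ^(i−1) with mirrored G→A, an
optional uniform error floor, and tree-structured drift whose branch
variances add (noise is scaled by the *root* heterozygosity precisely
so that expected f2 equals summed path drift; the (0,1) clamp makes
this exact only for small drifts and interior base frequencies, the
regime the tests use).

Not emulated: linkage (sites are independent — fine for PMR and
f-statistic expectations, but block-jackknife SEs on simulated data are
honest only because blocks are still contiguous), reference bias,
contamination, sequencing-quality structure, GC-content and fragment-end
composition biases, and realistic read placement. Passing tests
therefore demonstrate correctness of the estimators under their stated
model, not robustness to every artifact of real ancient-DNA data.

Determinism: every generator takes a seed (or Generator); `split_seed`
derives independent substreams from one master seed so a whole pipeline
run reproduces from a single integer.

## Problem sizes used in the checks

The statistical checks run at: 200k sites × 20 pairs per relatedness
class for the ratio law; 50k sites × 200 pairs for classification
accuracy; 10⁵ reads per damage profile and 100 + 100 simulated
individuals at 10⁵ reads for sexing; 50k sites for the null-f4 test and
30 replicates × 20k sites for f3 ranking recovery. These sizes put
Monte-Carlo error well inside the asserted tolerances while keeping the
whole suite around a minute of compute.
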