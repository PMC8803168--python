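# Methods

## Transcript classification and splice-site variants

A transcript's class follows from its strand-aware 5' terminus: a lncRNA
starting within 500 bp (default, inclusive of overlap) of an intergenic
enhancer is an elncRNA; transcripts starting within the same window of a
promoter are plncRNAs or protein-coding genes by biotype; enhancers with no
assigned transcript form the eRNA background class. Distances are measured
to the nearest *contained base* of an interval, which keeps the rule
symmetric on both sides. Two deliberate dialect choices, since the
definitions leave them open: the window boundary itself (distance exactly
500) is included, and when a lncRNA 5' end is within range of both an
enhancer and a promoter the enhancer wins, because the elncRNA set is
defined first.

Splice-site variants are SNPs overlapping the donor GT (first two intronic
bases in transcript orientation) or acceptor AG (last two) of any intron of
a multi-exonic elncRNA. On the minus strand the donor dinucleotide sits at
the genomic *end* of the intron; the implementation works in transcript
orientation so both strands reduce to the same rule.

## Splicing quantification

PSI is intron-centric: within a cluster of introns sharing at least one
splice-site coordinate (connected components under the shared-coordinate
relation), PSI_i = n_i / Σ n over the cluster's junction reads, per sample.
A cluster/sample cell with fewer than `min_cluster_reads` (default 10,
matching common junction-caller practice) total reads is missing rather
than noisy. Defined PSI sums to 1 per cluster and is exactly invariant to
uniform count scaling.

coSI per intron is j / (j + (b5 + b3)/2): junction-spanning reads over
junction plus boundary reads, with the two exon–intron boundary counts
averaged so one incompletely spliced molecule is not counted at both ends.
The gene-level coSI is the mean over introns weighted by each intron's
total supporting reads.

Genotype-group contrasts use the sign-preserving log10-modulus transform of
the relative difference against the reference-genotype median:
L(v) = sign(fd)·log10(1 + |fd|) with fd = (v − median_ref)/median_ref.
Whether "fold difference" means the relative difference or the plain ratio
v/median is ambiguous; the two differ only by a unit offset before the
transform. The relative-difference reading is the default because it
centres the reference group at zero; the ratio variant is available behind
`ratio=True`. A zero reference median leaves the statistic undefined
(flagged, not silently dropped). Panels with fewer than two usable samples
per genotype group are skipped; group differences are tested with
two-tailed Mann–Whitney U.

Junction position within a transcript (the 5'/3' split of mediation calls)
is decided by whether the intron midpoint falls in the strand-aware first
half of the transcript span; an exact tie goes to the 5' end.

## Motif scanning and GC profiles

ESE scans use the 50 exonic nt flanking each splice site of internal exons
longer than 100 nt, masking the 5 nt nearest the splice site against
splice-site-driven composition bias; the scan counts perfect hexamer
matches at every offset (overlaps allowed, no match may touch a masked
base, N never matches) and reports matches per *unmasked* nt — the
alternative denominator (full window length) only rescales densities by a
constant. U1 scans use one 9-nt window per 5' splice site (3 exonic + 6
intronic nt); any of the three canonical U1 hexamers at any of the four
possible offsets counts. The U1 set {GGTAAG, GGTGAG, GTGAGT} ships exactly;
the two bundled ESE hexamer files are deterministic purine-rich *synthetic
stand-ins* for the published 238- and 54-motif collections (external
supplementary data), preserving set sizes and nesting but not the published
sequences — analyses of real data should drop in the published lists.

GC profiles report the GC fraction of the first exon, remaining exons,
introns, and two intergenic flanks that mirror the transcript span length
and start 500 nt away from the annotation.

## Substitution rates and the matched-AR permutation test

Pairwise distances drop gapped/N columns first. JC69 uses the closed form
d = −¾ ln(1 − 4p̂/3) on the mismatch fraction, returning +inf at saturation
(p̂ ≥ ¾). The GTR distance is a two-sequence maximum-likelihood branch
length: with two taxa a reversible-model tree degenerates to a single
branch, so base frequencies are taken from the pooled empirical counts,
exchangeabilities from the symmetrised substitution-count matrix (half-count
pseudocounts keep the rate matrix irreducible), the rate matrix is
normalised to one expected substitution per unit time, and the branch
length is optimised by bounded scalar search (tolerance 1e-8). On
JC-generated data the GTR estimate collapses onto JC69 within 0.005 at
10 kb.

Constraint is tested against 1,000 replicate subsamples of neutrally
evolving ancestral repeats (ARs): for each motif segment and replicate, one
AR window of identical length, |ΔGC| ≤ 0.02 (widening in 0.02 steps when no
window qualifies, then doubling the 1 Mb locality once, then dropping the
segment — each step logged), drawn uniformly with replacement from ARs on
the same chromosome. Replicate rates are computed from pooled mismatch
counts, so the 1,000-replicate null costs one pass over cumulative sums.
The one-tailed (lower-rate) empirical p uses the add-one estimator
p = (1 + #{d_AR ≤ d_obs}) / (1 + N), whose floor 1/1001 matches the
smallest p reportable from 1,000 replicates and which is conservative under
ties. Calibration at desk scale (10 motifs of 60 nt, 5 local ARs of 600 nt
each, divergence 0.5): neutral simulations reject at 5–7% at α = 0.05 over
200 runs; at constraint ratio 0.2 every run rejects.

## Derived allele frequencies

DAF polarises each SNP by its ancestral allele (frequency of the
non-ancestral allele); SNPs whose ancestral call matches neither observed
allele are dropped with a logged count. Class contrasts use the 2×2 table
of DAF < 0.1 vs ≥ 0.1 with a two-tailed Fisher exact test; the reported
odds ratio is the sample cross-product ratio with the Haldane 0.5
correction when a cell is empty. The synthetic null spectrum is the
standard neutral 1/x site-frequency spectrum discretised on 100 bins;
constrained classes mix in an extra mass fraction uniform below 0.1 — only
the low-DAF contrast matters downstream, so the exact null shape is not
load-bearing.

## cis-QTL mapping

Traits are rank-inverse-normal transformed (ties averaged, mean-centred);
no expression covariates are used. Variants must have MAF strictly above
5% and share a TAD with the trait (traits without a containing TAD are
skipped with a warning — the cis-window is defined only through TADs).
Associations are ordinary least squares of the transformed trait on dosage,
with two-tailed p from the t statistic (df = n − 2). Gene-level
significance permutes the trait 1,000 times, records the maximum |r| over
cis variants per permutation, and passes the gene iff its observed maximum
exceeds 95% of the permuted maxima — applied per gene, which makes the null
pass rate 5% by exchangeability (measured 3–6% over 500 null genes at 50
cis variants, n = 300). Within each TAD, nominal p-values are
Benjamini–Hochberg corrected and records need q < 0.05 *and* the
permutation pass. A planted logit-PSI effect of 1.0 per allele at n = 300
and read depth 50 is recovered in 50/50 seeds. `best_per_trait()` keeps the
most significant variant per trait for the conservative LD-robust
reanalysis; the generator's `add_ld_copy` (copy a variant with a flip
probability) supports that sensitivity check.

Putative targets are genes sharing a TAD and a significant eQTL variant
with an elncRNA. Joint triplets pair a variant that is both an elncRNA
sQTL and an outcome eQTL/cQTL; variants that are also eQTLs for the
elncRNA's own expression, or sQTLs for the target, are excluded and the
exclusions recorded as audit flags. Replication uses
slope = z / √(2f(1−f)(n + z²)) to convert Z-scores and requires
BH-adjusted replication p < 0.05 with matching effect sign.

## Mediation classification

Statistics per triplet (E dosage, A mediator, B outcome; A and B
rank-normalised upstream) are Fisher-z transformed Pearson and first-order
partial correlations, z = atanh(r)·√(n − k − 3). Composite scores:

    causal      = min(|z(E,B)|, |z(A,B|E)|) − |z(E,B|A)|
    reactive    = min(|z(E,A)|, |z(A,B|E)|) − |z(E,A|B)|
    independent = min(|z(E,A)|, |z(E,B)|)   − |z(A,B|E)|

The independent score includes the E→A term even though triplet
construction already guarantees that association, because this makes all
three scores *exactly* symmetric under A↔B exchange (causal and reactive
swap, independent is fixed) — a property the test suite asserts bitwise.
Collinear triplets get partial correlations of 0 and a degenerate flag.

Each score ensemble is calibrated against a permutation null: B permuted
across samples for the causal direction (preserving the E–A edge that
construction guarantees), A permuted for the reactive mirror, and both
halves pooled for the independent score, all with identical permutation
indices so the exchange symmetry carries through the null. Local FDR is
lfdr(s) = π₀·f₀(s)/f(s) with Gaussian-kernel densities (Silverman
bandwidth), clipped to [0, 1] and made monotone non-increasing by isotonic
regression. π₀ doubles the fraction of observed scores at or below the
null median — that fraction estimates π₀/2, and doubling is what makes the
estimator ≈ 1 (not ½) under a pure null, as the calibration tests require —
capped at 1. A triplet takes the lowest-lfdr model among those below the
0.1 threshold; exact ties and empty candidate sets are "undecided"
(conservative). The classifier is a transparent partial-correlation /
empirical-null construction with the same four-way output and decision rule
as Bayesian mediation-posterior tools; it does not reproduce any specific
tool's posterior values, and one label is assigned per triplet while all
per-model lfdrs are exported.

At n = 300 with standardised effects 0.7 and unit noise, sensitivity for
the causal model is ~0.90 over 500 triplets, the false-causal rate under
the independent model is ~0, and under a pure noise null (no E→B edge) the
causal-call rate stays below the 10% threshold.

## Nested-model gain

Target expression is regressed on elncRNA expression alone (model 1) and
with elncRNA splicing added (model 2), on identical complete cases
(n ≥ 30); the gain is the adjusted-R² difference,
adj R² = 1 − (1 − R²)(n−1)/(n−p−1). Because of the adjustment penalty a
pure-noise splicing predictor yields negative gain about half the time —
asserted, not assumed. When an elncRNA has several intron PSIs the
predictor is the most variable intron (the summary entering the original
models is unstated; this is the documented choice). Collinear predictors
(|r| > 0.999) flag the record unstable. Target vs non-target gain
distributions are compared with two-tailed Mann–Whitney U.

## Synthetic cohorts: what they emulate, and what they do not

Defaults mirror the study conditions the pipeline is meant for: 373-sample
cohorts (`CohortConfig.n_samples`), MAF uniform in (0.05, 0.5) under
Hardy–Weinberg, mean junction depth 50 per cluster, mediation effects of
0.7 trait-SD per allele with unit Gaussian noise, pairwise human–mouse-like
divergence 0.5 substitutions/site for neutral sequence. The full-cohort
generator (`simulate_cohort`) plants one elncRNA locus per 1-Mb TAD — an
intergenic enhancer, a two-intron alternative-acceptor elncRNA starting
within 500 bp of it, a protein-coding target, one true sQTL (effect 1.0 on
logit PSI, a strong molecular effect typical of splice-site variants; depth
100 and latent logit noise 0.5) and two null variants — and draws target
expression as log-normal RPKM monotone in either the splicing mediator
(causal loci) or the genotype directly (independent loci). elncRNA
expression is genotype-independent by construction so the exclusion rules
keep the planted triplets.

Not emulated: linkage maps beyond single LD copies, population structure,
imputation uncertainty, sequencing error, overdispersed counts,
context-dependent substitution. Passing tests therefore demonstrate the
*statistical machinery* — calibration, recovery, exclusion logic — not
robustness to those real-data complications.

## Problem sizes and determinism

Every stochastic step takes an explicit seed and is byte-reproducible. The
test-suite and acceptance-script problem sizes — 1,000 PSI clusters, 10 kb
alignments, 200 neutral + 40 constrained evolution simulations with 1,000
AR replicates each, 500 null genes × 1,000 permutations × 50 cis variants,
500 triplets per mediation scenario at n = 300, and a 200-sample/50-locus
end-to-end cohort — were chosen as the smallest scales at which the
binomial error of each calibration estimate is well inside the asserted
bands; all run in seconds on one CPU thanks to vectorised permutation and
replicate arithmetic.

## Known limitations

- The ESE motif files are synthetic stand-ins (see above).
- The permutation-null local FDR needs ensembles (≥ 50 triplets, ≥ 500
  null scores); single-locus analyses must pool triplets.
- The GTR distance assumes stationarity and reversibility on a single
  branch; for deeply saturated pairs it inherits JC's +inf behaviour.
- Gene-level BH correction is per trait within its TAD, the reading most
  consistent with a per-gene permutation threshold; a pooled-across-genes
  variant would be stricter.
- `compute_cosi` consumes pre-computed junction/boundary read counts;
  extracting those counts from alignments is out of scope.
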