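# Methods

This note documents the models, numerical choices and the synthetic-data
design behind `dairycnv`.  It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Phenotype editing and 305-day standardisation

A DHI test-day record holds one cow's daily milk yield (kg), fat and protein
percentage, fat and protein yield (kg/d), somatic cell score, parity, age at
first calving (months) and days in milk (DIM).  Edit rules are applied in a
fixed order with first-triggering-rule attribution in the audit: (1) parity
1–3; (2) age at first calving in [22, 36] months (read as inclusive bounds
on age, the standard interpretation of a "first calving month" window);
(3) DIM in [5, 305]; (4) daily milk in [5, 80] kg and SCS in [0, 9];
(5) per trait × parity, values outside mean ± 3 SD, where mean/SD are
computed once on the records surviving rules 1–4 (a single pass, not
iterated); finally lactations with fewer than 7 surviving tests are dropped.
A record failing rule 5 for any one trait is removed entirely.  The audit
stores the reference means/SDs so that re-filtering retained output with the
frozen statistics is a no-op (idempotence).

305-day yields use the test-interval method: the first interval contributes
y₁·d₁, interior intervals the neighbour mean times the gap, and the tail
yₙ·(305−dₙ).  This is the standard ICAR-style calculation for monthly
recording; the 305-day fat and protein percentages are ratio traits,
100·fat305/milk305 and 100·protein305/milk305, which makes them invariant
under proportional scaling of the daily records.  Lactations with duplicate
DIM values are rejected with a diagnostic rather than silently deduplicated.

Descriptive statistics follow the SPSS conventions because those are what
herd reports in this field print: sample SD (n−1), adjusted Fisher–Pearson
skewness g1·√(n(n−1))/(n−2), and bias-corrected excess kurtosis.  Statistics
below their minimum n (3 for skewness, 4 for kurtosis) or undefined on a
constant vector are reported as NaN, never as 0.

## Pedigree relationship matrix and REML

The additive relationship matrix A comes from the tabular method after an
internal topological sort (so input order is free; cycles are reported with
the offending path).  The diagonal is 1+F.

Variance components maximise the restricted likelihood of the intercept-only
animal model.  For two traits (typically one milk trait in two parities)
with records y₁, y₂ mapped to animals by index vectors, the phenotypic
covariance is

    V = [ g11·K + r11·I   g12·K12 + r12·J ]
        [      ...        g22·K + r22·I   ]

with K the A-submatrix of recorded animals and J the same-animal indicator.
The engine is AI-REML: scores −½(tr(P Vₖ) − y'P Vₖ P y), average-information
matrix ½·y'P Vₖ P Vₗ P y, Newton steps with step-halving on the restricted
log-likelihood, and eigenvalue bending (floor 1e-8 on the standardised
scale) whenever an update would leave the PSD cone.  When both traits share
one record set the first iterations are exact EM-REML updates,

    G_new = G − G (Tr_K − W_K) G / q,    R_new = R − R (Tr_I − W_I) R / n,

which are monotone in the restricted likelihood and give a robust start;
EM is also the fallback when an AI step cannot ascend (typically at a
correlation boundary).  Convergence uses the update-vector norm < 1e-7 or
gradient norm < 1e-6, applied to internally standardised (unit-variance)
data so the thresholds are scale-free; components are rescaled to data units
afterwards.  Three consecutive accepted steps that improve the restricted
log-likelihood by less than 1e-9 terminate the fit as a boundary solution.
Standard errors come from the inverse AI matrix at the solution.

Genetic and phenotypic correlations are Cov/√(var·var) on G and P = G + R,
clamped to [−1, 1] with a warning when numerics overshoot.  Estimates of rA
at ±1 are genuine boundary maxima, not failures: with a few hundred cows the
likelihood along the G-vs-R covariance tradeoff is flat enough that single
fits scatter widely, which is why recovery is assessed on seed means.

## Genotype QC, HWE and IBS

The QC order matters and is fixed: SNP call rate (> 0.90, strict), sample
call rate (> 0.95), then MAF (≥ 0.05) and the exact Hardy–Weinberg test
(p ≥ 1e-6) computed on the reduced sample set.  The HWE p-value is the exact
conditional test: conditioning on the observed allele counts, all
heterozygote counts with the feasible parity are enumerated, and the
p-value sums the probabilities of tables no more probable than the observed
one (the plain exact test; the mid-p variant is deliberately not used).
The 1e-6 threshold is the PLINK convention.  IBS is the allele-sharing mean
(2−|gᵢ−gⱼ|)/2 over jointly called SNPs, and population structure is screened
with average-linkage hierarchical clustering on 1−IBS.

## The CNV hidden Markov model

States are copy numbers 0–4; state 2 (diploid) is the background.

*Emissions.*  LRR is Normal(μₛ, σₛ) with defaults
μ = (−3.5, −0.66, 0, 0.40, 0.68) and σ = (1.3, 0.28, 0.16, 0.21, 0.24) —
the standard intensity-HMM parameterisation for Illumina-style arrays; all
values sit in `HmmParams` and are configurable.  BAF for state s ≥ 1 is a
mixture over the B-copy count k = 0..s with binomial weights
Binom(s, PFB) and Gaussian bands at k/s (σ_b = 0.04); observations pinned
at exactly 0 or 1 carry the band's tail mass beyond the boundary, so each
state's BAF law (continuous part plus two point masses) integrates to 1 —
a property the tests verify numerically.  State 0 has no genotype and emits
uniform BAF.  Missing LRR or BAF contributes log 1 = 0.  The PFB itself is
the across-sample median BAF per SNP clipped to [0.01, 0.99].

*Transitions.*  For an inter-SNP gap d, the probability of moving to state
t ≠ u is (1 − e^(−d/D))·π_t with D = 100 kb and a diploid-dominant prior
π = (1e-4, 1e-3, 0.9965, 2e-3, 4e-4); the self-transition is the remainder.
This is the stationary-mixing kernel: as d grows the chain forgets its state
and relaxes toward π, so the off-state probability increases strictly with
gap length.  An alternative that renormalises the off-state mass to
1 − e^(−d/D) regardless of π was considered and rejected: it makes the exit
probability from the diploid state ≈ 22% per 25 kb step, which floods the
decoder with spurious segments; under the chosen kernel the diploid exit
mass is (1 − e^(−d/D))(1 − π₂) ≈ 10⁻³ per step, and π controls the
false-segment rate directly.

*Decoding and confidence.*  Exact Viterbi in log space per chromosome
(chromosomes with < 2 SNPs are skipped with a log entry); maximal
non-diploid runs become calls.  The confidence score is the emission-only
log-likelihood ratio of the called state against diploid summed over the
run, matching the "> 10" scale of the call-level QC.  The decoder is tested
against brute-force enumeration of all 5ⁿ paths on small instances.

*GC correction and signal metrics.*  Each SNP is assigned the
length-weighted mean GC of the 1 Mb window centred on it (500 kb each side,
truncated at chromosome ends); per sample, LRR is regressed on window GC and
replaced by residual + sample mean.  Sample QC metrics: the SD of corrected
LRR; BAF drift, the fraction of BAF in (0.2, 0.25) ∪ (0.75, 0.8) — a literal
genome-wide BAF SD is ≈ 0.4 for any sample because BAF clusters at 0/½/1,
so the "< 0.01" criterion is implemented as this inter-band drift fraction,
the companion metric used by the established caller family; and GCWF, the
SD of per-1 Mb-window median LRR signed by its correlation with window GC.
Note GCWF has a sampling floor of about 1.25·σ_LRR/√(SNPs per window)
(≈ 0.03 at 40 SNPs per window), so clean samples sit near 0.03, not at 0,
and a small fraction of genuinely clean samples can exceed the 0.05
threshold — behaviour consistent with how this QC acts on real cohorts.

## CNVR construction and association

Call-level QC applies the six criteria in order: the three sample-signal
criteria drop every call of a failing sample; confidence > 10 (strict) and
n_SNPs ≥ 10 (inclusive) drop individual calls; last, a call must share at
least one SNP with another sample's retained call.  Same-sample adjacent
calls of the same direction merge when the overlap is at least 20% of the
union span ("total length" is read as the union, the stricter and
self-consistent reading); the merged call takes the longer member's copy
number, spans the union and sums the confidences; merging repeats to a fixed
point and is order-invariant.  The 20% rule applies within samples only —
across samples the SNP-sharing rule below governs.

CNVRs are the connected components, per chromosome, of the
"shares ≥ 1 SNP" relation across all samples' calls, spanning the outermost
member coordinates; single-sample regions are removed, survivors are
numbered in genome order and typed Gain (all member states > 2), Loss
(all < 2) or Mixed.  Coordinates are 1-based inclusive with
size = end − start + 1; this convention is validated in the acceptance suite
against independently published region sizes.  Post-construction, regions on
a chromosome are disjoint in SNP space, so per-chromosome coverage is the
sum of region sizes over the chromosome length.

Association uses first-parity 305-day phenotypes only.  Samples are coded
loss/normal/gain per CNVR (a sample with both directions takes the longer
aggregate span; exact ties are excluded with a flag).  Each CNVR × trait
pair is a one-way ANOVA with classes under 3 observations dropped; with
fewer than two usable classes the test is skipped (p = NaN, not 1).  The
FDR family is per trait across CNVRs, adjusted by Benjamini–Hochberg
step-up ("q-value" here means the BH-adjusted p; a Benjamini–Yekutieli
switch is provided); significance is q < 0.05.  Null calibration and the
F = t² identity are covered by tests.

## The synthetic herd

*What it emulates.*  Multi-parity Holstein test-day data at the published
descriptive scale (parity means such as 30.4/36.3/36.9 kg/d milk,
between-cow SDs about 65% of the printed total SDs), heritabilities
(0.30, 0.30, 0.25, 0.35, 0.25) across the five traits, genetic correlation
0.86 between parities of a trait and 0.50 between traits (the Kronecker
product of two correlation matrices, hence PSD by construction), and
phenotypic correlation targets 0.47 / 0.35; the lactation-environment
covariance is derived as Cov_P − Cov_A and bent to the nearest PSD
correlation if needed.  Breeding values are matrix-normal with the pedigree
A as row covariance; the pedigree is two generations with ~n/10 sires and
~n/3 dams — paternal half-sib families of about ten, the structure of an
AI-bred herd and enough family replication to keep the additive
(co)variances identifiable at a few hundred cows.  A test-day record is a
Wood curve a·t^b·e^(−ct) (shape per trait, scale solved so the DIM-grid mean
hits the parity mean) plus breeding value, lactation-environment effect and
test-day noise.

*Deliberate contamination.*  At rate c, rows receive one violation each
(DIM out of range, milk out of range, SCS > 9, parity > 3, or a ±3 SD
outlier) and a matching fraction of cows get an out-of-range age at first
calving (a cow-level attribute, so such cows lose all records to rule 2).
Clean values are truncated at ±2.5 total SD around the trait × parity pooled
mean; without truncation the Gaussian tails alone would lose ~0.3% of clean
records to the ±3 SD rule, breaking the contract that zero contamination
passes the filter untouched.  The truncation trims ~1% of mass and slightly
shrinks realized variances — irrelevant to ratio quantities like h².

*Intensity signals.*  Exponentially spaced SNPs (mean 25 kb, the 100K-chip
scale) on 5 chromosomes, 5,000 SNPs and 200 samples by default; a GC track
of 500 kb windows following an AR(1) process (mean 0.45, SD 0.05); an LRR
wave equal to amplitude (default 0.10) times the standardised per-SNP 1 Mb
window GC; per-SNP B-allele frequencies uniform on [0.05, 0.95].  Planted
CNVs follow a 20-locus plan dominated by copy number 3 with lengths 15–40
SNPs (~0.4–1 Mb) and carrier fractions 3–8%, mirroring the published state
mix in array surveys of dairy cattle; loci never overlap and carriers are
drawn independently per locus (copy-number inheritance is not modelled —
the association model ignores pedigree, so nothing downstream needs it).
Inside a planted CNV both signals are drawn from the caller's own emission
table (`SimConfig.hmm_params()`), so the caller is exactly well-specified on
its generator; misspecification experiments pass a different table to the
caller than to the generator.

*What it does not emulate.*  No linkage disequilibrium or haplotype
structure; no X chromosome; no herd/season fixed effects; the five traits
are generated as separate correlated traits, so fat yield is not literally
milk × fat%/100 (305-day ratio traits therefore have slightly inflated
means, by roughly 1 + CV² of milk yield — no downstream method uses the
product identity); genotype calls inside CNVs keep their diploid labels;
signal artefacts beyond the GC wave (batch effects, waves uncorrelated with
GC, mosaicism) are absent.  Passing recovery tests therefore demonstrates
correctness of the inference machinery under its stated model, not
performance on real chip data.

## Problem sizes and determinism

Everything is a deterministic function of the configuration seed
(`numpy.random.default_rng` with derived streams).  The test suite runs
CNV recovery at 200 samples × 5,000 SNPs over seeds 1–5 and REML recovery at
500 cows over seeds 1–10 (assessed on seed means, since single-seed rA
estimates at this herd size scatter widely and can pin at ±1); the
acceptance script repeats both from the caller-supplied seed (CNV recovery
over 5 seeds, REML over 10).  Brute-force Viterbi verification enumerates
all paths for up to 8 SNPs, 200 random instances.

## Known limitations

- The bivariate REML engine requires at most one record per animal per
  trait (305-day data; no repeated-records or permanent-environment model)
  and fits intercept-only fixed effects.
- EM warm-up is available only when both traits share one record set; for
  disjoint record patterns the engine is AI-only with step-halving.
- The HWE exact test enumerates heterozygote counts, which is exact but
  O(n) per SNP; for n ≫ 10⁴ samples a normal approximation would be cheaper.
- CNVR classification uses call states only; no probabilistic genotype for
  regions (carrier classes are hard loss/normal/gain).
- The GCWF noise floor (above) means sample QC at |GCWF| < 0.05 rejects a
  few percent of clean samples at chip-like SNP densities.
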