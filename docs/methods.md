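# Methods

This note documents the statistical models behind `trimark`, the
defaults and why they were chosen, the numerical conventions, and what
the synthetic-data tests do and do not establish about real data.

## Phenotype statistics

Per-trait summaries use the sample standard deviation (divisor n − 1)
throughout; the printed reference summaries are consistent with either
convention at n = 93, and the sample form is the package's choice. The
coefficient of variation is CV = 100·δ/x̄ (percent) and is undefined
for zero-mean traits (an error, since the reference traits are all
positive).

**Shannon–Weiner diversity.** Each trait is binned into 10 grades from
its own mean and SD: grade 1 holds values strictly below x̄ − 2δ, grade
10 values strictly above x̄ + 2δ, and grades 2–9 partition [x̄ − 2δ,
x̄ + 2δ] into eight half-open [lo, hi) intervals of width 0.5δ. A value
exactly at x̄ − 2δ therefore falls in grade 2 and one exactly at x̄ + 2δ
in grade 9; only the outer cut-offs are fixed by the definition, so the
interior convention (left-closed) is a documented choice, and
reproduced reference indices are asserted to ±0.05 to absorb it. H′ =
−Σ Pᵢ ln Pᵢ (nats) over occupied grades with 0·ln 0 := 0; a zero-SD
trait occupies one grade and returns H′ = 0 rather than an error.
Because the grading is built from the trait's own moments, H′ is
invariant to affine rescaling of the measurements — this is a property
test.

**Correlations.** Pairwise Pearson r with two-sided p-values from
t = r·√((n−2)/(1−r²)) on n − 2 df, starred at 0.05/0.01. **PCA** is an
eigendecomposition of the trait correlation matrix, so eigenvalues sum
to the trait count and contributions to 100 % (asserted to 1e-9).
Eigenvector sign is fixed by making each component's largest-magnitude
loading positive; loading signs are otherwise arbitrary and are not
treated as reproducible. **Distances** are Euclidean on z-scored traits
(each column mean 0, sample SD 1); **clustering** uses between-groups
linkage, i.e. the size-weighted average-linkage (UPGMA) criterion,
which cannot produce inversions, so merge heights are monotone.

The packaged 93 × 15 trait table preserves the printed source values
verbatim, including two identical rows (W1/W298). The minimum pairwise
distance is therefore exactly 0; the published minimum (0.90) is
inconsistent with the published table and is deliberately not
reconciled. The printed correlation table used as the generator default
contains one sign misprint (traits 2 vs 14: +0.353 printed, −0.353
recomputed); the printed value is kept and the PSD repair step absorbs
it.

## SSR statistics

Dominant bands are scored 1 (present), 0 (absent) and 9 (the sample is
missing for the *whole primer* — "complete absence of band" is
primer-level missingness). Each band of a primer is treated as one
allele; band frequencies are presence counts over scored samples,
normalized to sum to 1 within the primer. No Hardy–Weinberg
back-transformation from band frequency to allele frequency is
attempted — this matches the common PIC-calculator workflow for
dominant data and is a documented simplification. PIC follows Botstein:
1 − Σpᵢ² − Σᵢ<ⱼ 2pᵢ²pⱼ², classified low/moderate/high at 0.25/0.5. A
band is polymorphic iff present in ≥1 and absent in ≥1 scored sample.
Band distances offer simple matching (default; mismatches over
comparable bands) and Dice, both with pairwise deletion of code-9
bands; the choice is exposed because the source workflow's coefficient
is unstated.

## SNP population genetics

Genotypes are unphased diploid alternate-allele counts (0/1/2, missing
explicit; never imputed except site-mean imputation inside PCA).
Positions are 1-based with opaque chromosome labels; unplaced markers
(reserved label `Un`) are excluded from windowed LD/blocks but kept for
diversity and AMOVA.

**Filtering** masks calls below the depth threshold (default 2, skipped
without depth data), then drops sites with missing fraction > 0.3 or
folded MAF < 0.05 — the reference pipeline's thresholds.

**LD.** r² is the squared Pearson correlation of allele-count vectors
over jointly scored samples (composite LD): deterministic,
missing-tolerant, and equal to haplotype r² when phase is known. D′
comes from 2-locus EM haplotype frequencies (tolerance 1e-8, ≤200
iterations; only double heterozygotes are phase-ambiguous, so EM equals
direct counting without them). The window default is 200 kb.

**Haplotype blocks** use a deterministic Gabriel-style rule: a run of
consecutive sites (span ≤ window) is a block when ≥95 % of its
informative pairs have point-estimate D′ ≥ 0.7; candidates are accepted
greedily, longest span first, without overlap. A pair is informative
only when both sites have MAF ≥ 0.1: D′ point estimates at rare minor
alleles are strongly upward-biased, which is what the original rule's
bootstrap confidence bounds absorb; the MAF guard is the deterministic
stand-in. The threshold triple (0.7, 0.95, 0.1) is configurable.

**Tajima's D** treats the 2N chromosomes as the sample without phasing:
π per segregating site is 2p(1−p)·n/(n−1) from folded frequencies,
Watterson's estimate is S/a₁, and D uses the standard a/b/c/e constants
(cross-checked against an independent evaluation for n ∈ {4, 10,
100}).

**AMOVA** is the two-level variance decomposition on squared
inter-individual distances: SS from the Σd²/(group size) identity,
σ²_within = SS_w/(N−G), σ²_among = (MS_a − σ²_w)/n₀ with the standard
unequal-size n₀, Φ_ST = σ²_a/(σ²_a+σ²_w), and a label-permutation p
with the (hits+1)/(n_perm+1) estimator (default 9999 permutations,
seeded). The SNP pipeline feeds **IBS distances as the squared-distance
term** (`already_squared=True`). Rationale: the IBS distance is already
a per-allele mismatch *mean* — the analogue of a mean squared
difference for 0/1 allele indicators — and for a two-population
Balding–Nichols panel with inbreeding coefficient f the expected
components give Φ_ST ≈ 2F / (2F + (1−F)(1+f)), which equals F for
fully selfed material and ≈ F for this package's defaults. Squaring
the IBS mean again would instead give Φ_ST ≈ 1 − (μ_w/μ_b)², a
systematic inflation (≈0.5 when F = 0.3). Distance-based AMOVA on
individuals is only an F_ST analogue; with outbred material at low f it
overestimates F (the classical haplotype-level AMOVA does not), which
is why the recovery tests run under the selfing defaults that match the
target crop.

**Gene flow** is Wright's island model N_m = (1−F_ST)/(4F_ST), with the
conventional bands (>4 ample exchange, >1 high gene flow, <1
drift-dominated; the boundary N_m = 1 is placed in the drift band).

## Bayesian admixture clustering

The sampler implements the admixture model: cluster allele frequencies
p_kl with a Beta(λ, λ) prior (λ = 1), per-sample ancestry q_i with a
symmetric Dirichlet(α) prior (α fixed at 1.0 by default, not sampled —
the reference protocol gives no α-inference detail, so fixed-α is the
documented, configurable choice), and latent per-allele-copy origins.
One Gibbs sweep updates origins (multinomial), frequencies (Beta
conditional) and ancestries (Dirichlet conditional). Missing genotypes
are skipped in all conditionals and in the likelihood.

Model evidence per chain is Pritchard's estimator mean(lnL) −
var(lnL)/2 over retained sweeps, with the likelihood evaluated on a
thinned schedule (every 5th retained sweep) since adjacent sweeps are
highly autocorrelated. Label switching is resolved within a chain by
greedily matching each retained sweep's Q columns to the first retained
sweep, and across replicates by exhaustively matching to replicate 0
(K ≤ 6; greedy beyond). RNG design: each chain owns two deterministic
streams seeded from the run seed — numpy's generator for the Beta and
Dirichlet conditionals and an inline xorshift64* stream for the
~2·n·m origin draws per sweep (the hot path). One consequence is that
results are exchangeable over sample order only in distribution, not
bitwise.

Reference-scale settings (K = 1..5, 5 chains, 10,000 burn-in, 100,000
post-burn-in sweeps; the ambiguous printed "10,0000" iteration count is
read as 100,000) are preserved as pipeline defaults; tests and the
bundled demo use desk-scale settings (2,000 / 5,000, 2 chains,
K ≤ 4) on an evenly thinned ≤300-marker subset — marker thinning is
standard practice for STRUCTURE-type runs and the subset is a config
knob, not a hard-coded limit.

**Evanno ΔK** uses replicate means: ΔK = |L(K+1) − 2L(K) + L(K−1)| /
sd(L(K)), defined for interior K with ≥2 replicates; zero replicate SD
is an error, and a flat second difference yields "no preferred K"
rather than an arbitrary winner. Group assignment takes argmax q when
it reaches the 0.60 membership threshold, else "admixed"; the pipeline
excludes admixed samples from the downstream AMOVA (the reference
protocol is silent on their handling; the exclusion is logged).

Dominant SSR bands enter the sampler as pseudo-biallelic loci (presence
→ homozygous alternate), reflecting that dominant scoring cannot see
heterozygotes; this overstates homozygosity at SSR loci and is
documented as an approximation.

## Mantel comparison

r is the Pearson correlation of the off-diagonal upper triangles; the
null permutes rows/columns of the second matrix simultaneously;
p is one-tailed upper with the (hits+1)/(n_perm+1) estimator
(9999 permutations default), counting permutations within 1e-12 of the
observed r as ties so exact enumeration is matched on small inputs.
Both r and R² are reported, and r is classified with the four-band
rubric (≥0.9 significant, 0.8–0.9 moderate, 0.7–0.8 weak, <0.7 none)
applied to r itself, not |r|, per the rubric's literal definition.

## Synthetic-data generator

The generator emulates the study panel, and its defaults are the
panel's documented conditions:

| parameter | default | rationale |
| --- | --- | --- |
| n_samples | 93 | panel size |
| K | 2 | subgroups found by every marker system |
| F | 0.61 | the panel's reported between-group F_ST |
| α (admixture) | 0.05 | mostly unadmixed breeding lines |
| maf_bounds | (0.05, 0.5) | post-filter ancestral spectrum; yields mean folded MAF ≈ 0.20 (panel: 0.21) |
| selfing f | 0.65 | expected het rate (1−f)·E[2pq]·(1−F) ≈ 0.365·0.35·0.39 ≈ 5 % (panel: 5.198 %) |
| block_r | 0.9 | within-block haplotype association of a selfer (panel mean r² 0.73 among linked pairs) |
| block_length_bp | 30 kb | panel mean haplotype length 33.71 kb |
| site_spacing_bp / chromosomes | 5 kb / 12 | ~67k markers over ~370 Mb |
| missing_rate | 0.02 | below the 0.3 filter threshold |

Mechanics: ancestral frequency per site ~ U(maf_bounds); population
frequencies ~ Beta(p(1−F)/F, (1−p)(1−F)/F) (Balding–Nichols, so F is
the expected fixation index); ancestry ~ Dirichlet(α·1_K); the two
allele copies of each 30 kb block draw origins from the individual's
ancestry (shared across the block), are identical by descent with
probability f, and draw alleles through a Gaussian copula with a
per-copy-per-block latent factor (loading √block_r). The copula leaves
every per-site marginal exactly Binomial(2, p_origin) — so frequency-
based estimators (F_ST, MAF, heterozygosity, Tajima's D) are
unaffected — while giving within-block haplotypes the strong
association real selfing panels show. Shared origins alone do *not*
create a within-block LD contrast when individuals are nearly pure:
admixture LD then affects all pairs equally, which is why the copula
term exists.

SSR panels draw 1–14 alleles per primer (Dirichlet frequencies,
independently per group when labels are supplied), give every sample
two allele copies and score a band present when either copy carries it;
code 9 marks whole-primer missingness. Phenotypes are multivariate
normal with the published per-trait means/SDs and correlation matrix
(repaired to the nearest PSD correlation by eigenvalue clipping when
needed), with integer traits rounded and percentage traits clipped to
[0, 100].

**What the synthetic tests do not show.** The generator has no
mutation/recombination genealogy, no allele-frequency clines, no
genotyping-error model, uniform marker spacing, and block boundaries on
a fixed grid; clipping makes percentage traits slightly non-normal.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated generative model at desk scale, not
robustness to real GBS artifacts. The published marker-level results
(378 bands, PIC 0.77, Tajima's D 1.66, F_ST 0.61, AMOVA 98 %/2 %, LD
r² 0.73, Mantel R² values) are not desk-reproducible because the raw
band and call matrices are unpublished; they are contextual targets
only.

## Numerical conventions and degenerate inputs

* Missing codes: genotype −1, band 9; pairwise deletion everywhere a
  pair statistic is computed; an all-missing site or primer is an
  error.
* Modes report the smallest value on ties; UPGMA ties break on the
  smallest cluster indices by creation order, making trees
  deterministic.
* Permutation p-values always use (hits+1)/(n_perm+1); all permutation
  tests and samplers take explicit seeds, and the pipeline derives
  stage seeds from one root seed (no wall-clock seeding).
* Distance matrices are validated (symmetry, zero diagonal,
  finiteness, non-negativity) on construction; Q rows are validated to
  sum to 1.
* Problem sizes used by the test suite: recovery cohorts of n = 100,
  m = 2000 (10 replicates), MCMC on 300-marker thinned subsets at
  2,000/5,000 sweeps, 999 permutations for AMOVA and 199–4,999 for
  Mantel — chosen as the smallest sizes at which the recovery bands
  (±0.05 on F_ST, ARI ≥ 0.9, 9/10 Evanno hits) are stable across
  seeds.

## Known limitations

* The admixture sampler implements the original no-admixture-prior-
  update, uncorrelated-frequencies model; later linkage/correlated-
  frequency variants are out of scope, as are CLUMPP-style multi-run
  consensus methods beyond greedy alignment.
* Distance-based AMOVA on individuals estimates an F_ST analogue whose
  expectation depends on the within-individual correlation (see
  above); compare across panels only at similar mating systems.
* The 2-locus EM assumes random union of the *observed* genotypes;
  under extreme inbreeding D′ estimates remain consistent but converge
  more slowly than in outbred panels.
* `ld_scan`/`haplotype_blocks` are O(sites²) within windows and are
  meant for desk-scale or thinned marker sets; the pipeline caps the
  scan at a configurable number of sites.
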