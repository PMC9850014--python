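# Methods

This note records the models behind each stage, the defaults and why,
what the synthetic generators do and do not emulate, and the numerical
choices made where the design was open.  Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Coalescent SNP simulator

Unlinked biallelic loci are simulated under a serial-sampling
n-coalescent with piecewise-constant diploid size N(t): among k active
lineages the coalescence rate is k(k−1)/(4N(t)); lineages sampled at a
later epoch (the historical sample, t_b generations back) enter the
process only at their sampling time.  Each locus carries exactly one
segregating site, placed on a branch chosen with probability
proportional to branch length (Hudson's fixed-S with S = 1).  This
mimics SNP-panel ascertainment and avoids a mutation-rate prior; the
cost is a conditioning effect worth knowing about:

* the spectrum of the single site is E[ℓ_i/ℓ_total], not
  E[ℓ_i]/E[ℓ_total] ∝ 1/i — a few percent singleton-enriched relative
  to the textbook neutral SFS (the test suite checks against a
  tree-level Monte-Carlo oracle rather than 1/i);
* a bottleneck *raises* the mean per-SNP gene diversity of the
  ascertained loci (surviving variants sit on the few deep branches
  and so segregate at intermediate frequencies) while the diversity
  loss expresses itself in the number of segregating sites, which the
  conditioning hides.  The scenario classifier works off this shifted
  spectrum; tests assert the direction actually derived by simulation.

The per-locus kernel is numba-compiled (~15 ms for a 203 × 300
dataset), with a pure-numpy lockstep engine kept as a fallback and as
an agreement cross-check.  Times are in generations; the study species
matures at ~3 years, so 50 generations ≈ 150 years — conversion happens
only in reporting, never in the model.

## Wright–Fisher engine

LD-based Ne estimation measures associations among *unlinked* loci that
exist only because loci share one pedigree.  Independently simulated
coalescent loci have no such associations (an LD-Ne run on them
correctly returns Ne ≈ ∞), so the generator for Ne work is an
individual-based forward Wright–Fisher simulation: random mating
(selfing allowed) within demes, each gamete drawn from an adjacent deme
with probability m/2 per side on a 1-D river lattice, all demes founded
from a common pool.  Twenty generations suffice for inter-locus LD to
equilibrate (unlinked-locus LD halves each generation).  Founder allele
frequencies are uniform on [0.05, 0.95] by default, or Beta(0.4, 0.4)
("SFS-like", rare-heavy) where a rare-allele tail matters (the
P_crit-sweep contrasts).  Loci are ascertained polymorphic in the
sample from a single realization — never re-simulated piecemeal, which
would break the shared pedigree.

What these generators do not emulate: genotyping error and allelic
dropout, linked loci, overlapping generations (the study species'
overlapping generations are a known downward bias on Ne_LD — documented,
not corrected), selection, and two-dimensional or dendritic habitat
geometry.  A green simulation test therefore validates estimator logic
and calibration, not robustness to those artifacts.

## Filtering cascade

Missingness filtering alternates locus and individual passes while
tightening the cut-off along a configurable schedule (default 0.9 →
0.7 → 0.5 → 0.3), then iterates at the final 30% thresholds to a fixed
point, so the published end-state rule ("sites in >70% of individuals,
individuals at >70% of loci") holds jointly on exit.  MAC filtering
keeps loci with minor-allele count ≥ 2 (the tool semantics of
`min-mac 2`).  HDplot computes per-locus H (heterozygote share) and
D = (A−B)/√(A+B), the z-score of summed ref/alt read counts over
heterozygotes against binomial(0.5); loci with H > 0.55 or |D| > 7 are
flagged as probable collapsed paralogs.  D's sign is ref-positive by
convention; only |D| is thresholded.  One SNP per RAD locus is kept —
highest MAF, ties to the lowest position.  All filters are pure and
append every removal with its reason to a provenance log.

Relatedness screening uses the method-of-moments correlation estimator
r̂ = mean over loci of (x_i−2p̂)(x_j−2p̂)/(2p̂(1−p̂)) (E[r̂] = 0.5 for
parent–offspring), not maximum likelihood: adequate for a screen whose
outcome in the source study was "no exclusions", and self-contained.
Accuracy improves with the panel used to estimate p̂; with ~30
background individuals the estimator reads ~0.44 for true 0.5, with ~80
it reads ~0.48.

## Diversity and temporal tests

Per locus with sample size n, Ho is the heterozygote share and Nei's
unbiased gene diversity is Hs = n/(n−1)·(1 − Σp̂² − Ho/(2n));
Fis = 1 − Ho/Hs.  Population means are unweighted over loci (matching
hierfstat's basic.stats); with no missing data, mean MLH over
individuals equals mean Ho over loci exactly, and the suite asserts the
identity.  IR follows the Rhh convention: at each homozygous locus both
allele copies contribute 2·f(allele) to Σf_i, frequencies taken from
the full sample.  Temporal comparisons: a two-sided Wilcoxon
signed-rank over per-locus differences (zeros dropped) for Ho/Hs, and a
5000-draw label-permutation test with p = (1 + #{|Δ̄|_perm ≥ |Δ̄|_obs})
/(n_perm + 1) for the individual metrics, robust to the 8-vs-195 era
imbalance.  Weir–Cockerham θ uses the standard biallelic a/b/c variance
components summed over loci; the 95% CI is a percentile bootstrap over
loci (1000 resamples — the resample count is not stated by the source
analysis, 1000 is the community default).

## LD effective population size

Loci failing MAF ≥ P_crit are excluded (for biallelic SNPs, allele
exclusion degenerates to locus exclusion; P_crit = 0 keeps everything
polymorphic).  For each locus pair over shared-complete individuals,
the Burrows composite disequilibrium is Δ̂ = (S/(S−1))·(Σx_iy_i/(2S) −
2p̂_Ap̂_B) and r² is the squared genotype correlation scaled by
(S/(S−1))², capped at 1.  The S/(S−1) factor is NeEstimator's
convention and is load-bearing: without it, mean r̄² undershoots
Waples' E[r²|S] regression constants and Ne is overestimated (~70% at
true Ne = 500, S = 100).  r̄²_drift = r̄² − E[r²|S] is inverted through
the published quadratic (S ≥ 30: Ne = (1/3 + √(1/9 − 2.76·r̄²_drift))
/(2·r̄²_drift)); non-positive drift signal → Ne = ∞, the correct report
for data without LD information (small samples from large populations,
or independently simulated loci).  CIs are a delete-one-locus jackknife
on r̄² mapped through the monotone inversion; harmonic-mean S
summarizes per-pair sample sizes.  The simulation recovery oracle (true
Ne ∈ {50, 100, 500}, 1000 SNPs) is the correctness reference for the
whole chain, not the constants themselves.

## ABC-RF

Priors are independent uniforms — N_ancestral, N_establishment,
N_contemporary ∈ [2, 10000], N_bottleneck ∈ [2, 100], t0 ∈ [0, 5],
ta, tb ∈ [2, 15], tc ∈ [2, 50], td ∈ [1, 100] — rejection-resampled
until t0 < ta < tb < tc < td (the exhaustive-enumeration conditional of
each time marginal is chi-square-checked in the suite).  Scenario
structures are data: group 2 inserts the N_bottleneck epoch ending at
td (ancestral beyond), group 1 does not, and the four within-group
variants toggle size changes at ta and tc; scenario 5 is the bottleneck
with neither change — no recovery.  The published figure shows the
within-group variants only schematically, so this 2×2 reading is a
declared interpretation and users can supply their own `ScenarioSpec`s.

Each reference-table row is draw → simulate at the observed design
(8 + 195 individuals; desk scale 300 loci and 500 rows/scenario,
study scale 1898 and 5000) → a 36-value summary vector: per-era and
pooled {proportion monomorphic, mean/var MAF, mean/var Ho, mean/var Hs,
mean Fis}, between-era {Weir–Cockerham Fst, Nei's standard distance,
mean |Δp̂|}, and the pooled MAF deciles.  The exact summary set used by
the original DIYABC analysis is unprinted; this set spans the same
moment families and is recorded in output metadata.

Scenario choice trains a 1000-tree random forest (features per split =
√36, unlimited depth); votes are per-tree predictions at the observed
summary, the prior error rate is the out-of-bag misclassification, and
the posterior probability of the selected class is a second regression
forest trained on out-of-bag correctness, evaluated at the observed
point.  A linear-discriminant projection of the table plus the observed
summary is returned for overlap inspection.  Parameter estimation is a
Meinshausen quantile regression forest (leaf-co-occurrence weights over
training rows) reporting the weighted median and [0.025, 0.975]
quantiles, with NMAE = mean(|OOB prediction − truth|/truth).

## Spatial analyses

River distances come in as a TSV matrix (haversine from lon/lat is a
logged fallback).  nMDS (nonmetric, initialized from classical scaling,
seeded restarts) re-projects them to Cartesian coordinates for the
sPCA connection network.  The *minimum-distance neighbour graph*
connects every pair within the smallest distance that keeps the graph
connected — the longest MST edge — a reproducible reading of an
underspecified phrase.  sPCA diagonalizes (1/2n)·Xᵀ(W+Wᵀ)X with X the
centred genotype matrix and W row-normalized adjacency: positive
eigenvalues are global (neighbours alike), negative local.  The global
(local) permutation test statistic is the largest positive eigenvalue
(largest negative magnitude) under row shuffling; the published
variant of the "max(t)" statistic is not recoverable from the text, so
this choice is validated by a type-I-error calibration test instead.
Permutations run through the Gram-matrix identity
eig(X_pᵀSX_p) = eig(G^{1/2}P S PᵀG^{1/2}), avoiding per-permutation
matrix rebuilds.

MEM analysis builds Moran eigenvectors from the doubly-centred
truncated weight matrix (weights 1 − (d/4t)², truncation t = longest
MST edge), takes principal coordinates of the 1 − proportion-of-shared-
alleles genetic distance as the response, and forward-selects
eigenvectors while the permutation p stays under 0.05 and adjusted R²
increases.  An empty selection with R²adj = 0 is the designed
no-structure outcome.

Mantel correlograms correlate genetic distance with the membership
indicator of each 10-km distance class (sign flipped so positive r =
within-class similarity), with 999 seeded permutations and progressive
Holm correction across ordered classes (raw p is also reported — the
source analysis is silent on multiplicity).  The genetic neighbourhood
is the largest class bound of the initial unbroken run of significant
positive classes; the alternative reading ("first class no longer
significant") coincides when significance is an unbroken prefix and is
reported alongside, as is half the neighbourhood (the eradication-
radius scale).  Empty classes are flagged and skipped by the rule.
The Holm correction makes the estimate mildly conservative (typically
one class short of the frequency-level oracle range in the calibration
fixtures).

Neighbourhood diversity: members are all individuals within the radius
(default 220 km — exposed as configuration, since the source's "~112 km
radius" phrasing suggests it may have been a diameter); neighbourhoods
under min_n = 20 are reported as not-computed with a reason (the Lake
Ontario case).  Ho/He/Fis are the same per-locus estimators as the
diversity module — at infinite radius the values equal the global ones
exactly, asserted as a cross-module identity.  Allelic richness is
Hurlbert-rarefied to 2× the smallest qualifying neighbourhood size;
for biallelic SNPs Ar ∈ [1, 2].

Decay regressions fit OLS metric ~ distance × direction and eliminate
backward by likelihood-ratio χ² at α = 0.05, interaction first; slopes
are reported per 100 km.  A single direction level drops the direction
terms with a note.  The high-leverage rule (exclude distance > 4× mean)
is off by default and logs every exclusion.  Under a null metric the
interaction survives at the nominal 5%, and the full backward path
reaches intercept-only in ≈ 86% of replicates (three sequential 5%
tests) — the calibration test asserts both.

## Pipeline

One TOML config drives filter → diversity → Ne → structure → ABC →
spatial.  Every stage records its config hash, seed and in/out counts
in `manifest.json`; re-running resumes past completed stages with
unchanged config.  A missing distance matrix skips the spatial stages
with a notice; a P_crit value that leaves fewer than two loci (e.g.
0.5 on data without MAF-0.5 loci) is recorded as an error row rather
than failing the stage.  Defaults mirror the published settings: HDplot
0.55/7, MAC 2, 5000 randomizations, 999 spatial permutations, 1000
trees, classes 10–300 × 10 km, radius 220 km, min_n 20.

## Known limitations

* Scenario topologies within groups are an interpretation (above);
  only the group contrast is anchored by the source figure.
* The ABC desk scale (500 rows/scenario, 300 loci) trades prior-error
  precision for minutes-scale runtime; `paper_scale = true` restores
  the full 5000 × 1898 design.
* Ne_LD inherits the overlapping-generations downward bias of the
  method; no correction is applied.
* The relatedness screen is method-of-moments, not ML; it is a screen,
  not an estimator of record.
* Spatial analyses assume a 1-D river geometry in the fixtures; the
  estimators take arbitrary distance matrices but are calibrated here
  on the lattice.
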