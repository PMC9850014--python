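# invadepop

Population-genomic analysis of a recently introduced, range-expanding
population — built around the eastern North American Tench (*Tinca
tinca*) invasion: a single documented introduction of a few dozen fish,
three decades of expansion along ~500 km of river, and a RAD-seq SNP
dataset sampled at two time points (a small historical sample and a
large contemporary one).

The package is aimed at invasion geneticists and fisheries managers who
want to answer three questions from a SNP matrix, sample metadata, and
along-river distances:

1. **Did the population pass through a genetic bottleneck, and how
   severe?**  Approximate Bayesian computation with random forests
   (ABC-RF): serial-sampling coalescent simulation of eight competing
   demographic scenarios (with/without a bottleneck epoch
   N<sub>bottleneck</sub> between the ancestral and established
   population), random-forest scenario choice with out-of-bag prior
   error rate and posterior probability, and quantile-regression-forest
   estimation of N<sub>ancestral</sub>, N<sub>bottleneck</sub> and the
   bottleneck time t<sub>d</sub> (with NMAE accuracy).
2. **How many effective breeders are there now?**  Linkage-
   disequilibrium N̂e from the Burrows composite r̄² over all pairs of
   unlinked SNPs, with Waples' sample-size correction
   (E[r²|S] = 1/S + 3.19/S² for S ≥ 30), allele-exclusion screening
   across P<sub>crit</sub> ∈ {0, 0.1, 0.2, 0.5}, and a delete-one-locus
   jackknife CI.
3. **How connected is the invaded range?**  Mantel correlograms over
   10–300 km distance classes sizing the *genetic neighbourhood*
   (largest class with significant positive autocorrelation), sGD-style
   per-individual neighbourhood diversity (Ho, He, Fis, rarefied
   allelic richness) at a 220 km radius, sPCA and Moran-eigenvector
   (MEM) decompositions of spatial genetic structure, and
   distance-by-direction decay regressions with backward
   likelihood-ratio selection.

Upstream of the analyses sits the standard RAD-seq filtering cascade
(iterative missingness, minor-allele count ≥ 2, HDplot paralog removal
at H > 0.55 or |D| > 7, one SNP per locus by highest MAF) and a
method-of-moments relatedness screen.  A synthetic-data module — a
serial-sampling coalescent with piecewise-constant population size
(numba-compiled; it doubles as the ABC training simulator) and an
individual-based Wright–Fisher stepping-stone — generates every test
input, so the whole pipeline is exercisable without the original reads.

## Worked example

```python
import invadepop as ip

# founder bottleneck: ~75 effective founders 50 generations ago,
# ancestral source of 5000; sampled 8 historical + 195 contemporary fish
dem = ip.Demography(((0, 75), (50, 5000)), "founder-bottleneck")
ds = ip.simulate_snp_dataset(dem, ip.two_era_scheme(8, 195), 1000, seed=1)

for era, t in ip.diversity_by_group(ds.genotypes, ds.metadata["era"]).items():
    print(f"{era:12s} Ho={t.mean_ho:.3f}  Hs={t.mean_hs:.3f}  Fis={t.mean_fis:+.3f}")

# LD-Ne needs pedigree LD: a closed Wright-Fisher population of 75
wf = ip.simulate_isolated_population(75, 1000, 75, seed=2)
r = ip.ne_ld_estimate(wf.genotypes, (0.1,))[0]
print(f"Ne_LD (Pcrit={r.pcrit}) = {r.ne_point:.1f} [{r.ci_low:.1f}-{r.ci_high:.1f}]")

ref = ip.build_reference_table(n_per_scenario=125, n_loci=150, seed=3)
res = ip.scenario_choice(ref, ip.summarize(ds), level="group", n_trees=500, seed=4)
print(f"bottleneck votes: {res.votes}  posterior={res.posterior_probability:.3f}  "
      f"prior error={res.prior_error_rate:.3f}")
```

prints

```
contemporary Ho=0.294  Hs=0.293  Fis=-0.003
historical   Ho=0.304  Hs=0.305  Fis=-0.002
Ne_LD (Pcrit=0.1) = 75.7 [71.0-81.2]
bottleneck votes: {1: 0, 2: 500}  posterior=1.000  prior error=0.045
```

Read top to bottom: per-era diversity is moderate and in
Hardy–Weinberg balance (Fis ≈ 0); the LD method recovers the true
effective size of the closed population (75) with a tight jackknife
interval; and the random forest assigns the simulated bottleneck
dataset to the bottleneck scenario group with every one of its 500
trees, on a training set whose out-of-bag prior error is 4.5%.

The same analyses run from the shell on VCF + TSV inputs:

```bash
invadepop simulate --kind bottleneck --n-loci 300 --paralogs 20 --seed 1 --out fixture/
invadepop filter fixture/genotypes.vcf --out filtered.vcf --h-max 0.55 --d-max 7
invadepop run --config run.toml --out results/
```

`invadepop run` executes the full pipeline (filter → diversity → Ne →
structure → ABC → spatial) from one TOML config, caches completed
stages in a manifest, and resumes cleanly.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates a synthetic bottlenecked two-era fixture from scratch
(VCF with read depths and injected paralogs, metadata, river
distances), runs the complete pipeline on it — filtering cascade,
diversity and temporal tests, the P<sub>crit</sub> sweep, PCA/K-means,
a reduced ABC-RF scenario choice, correlogram/neighbourhood/decay
analyses — and writes the result JSON.  Quantitative acceptance
checks (estimator oracles, coalescent validity, Ne and bottleneck
recovery, spatial calibration) live in `tests/test_acceptance.py`.
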