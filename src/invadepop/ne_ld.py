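"""Linkage-disequilibrium effective population size (NeEstimator-style).

In a small closed population, drift generates nonrandom associations
(r²) between unlinked loci.  The method: (1) screen loci by minor allele
frequency against a Pcrit threshold; (2) estimate the Burrows composite
disequilibrium for every locus pair from unphased diploid genotypes and
square-standardize it to r²; (3) subtract the expected sample-size
contribution E[r²|S] (Waples 2006 regression constants, random mating);
(4) invert the drift relation to Ne (Waples & Do 2008).  Confidence
intervals come from a delete-one-locus jackknife on mean r² mapped
through the same inversion.

The r² used is Weir's composite correlation
r² = Δ̂²/[(pA qA + D̂A)(pB qB + D̂B)] — the squared Pearson correlation
of genotype columns, with NeEstimator's S/(S-1) small-sample correction
on Δ̂ (and hence (S/(S-1))² on r², capped at 1).  Under Hardy-Weinberg
proportions this reduces to the classic Δ²/(pA qA pB qB), stays within
[0, 1] for every pair, and is the estimator for which the Waples
regression constants were calibrated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix, InvadepopError


@dataclass
class NeResult:
    pcrit: float
    mean_r2: float
    n_comparisons: int
    harmonic_mean_S: float
    ne_point: float
    ci_low: float
    ci_high: float
    ci_method: str = "jackknife_loci"


def _pcrit_screen(g: GenotypeMatrix, pcrit: float) -> GenotypeMatrix:
    """Allele exclusion for biallelic SNPs: drop loci with MAF < pcrit.

    pcrit = 0 keeps every polymorphic locus."""
    maf = g.maf()
    if pcrit <= 0:
        keep = maf > 0
    else:
        keep = maf >= pcrit
    return g.take_loci(np.flatnonzero(keep))


def burrows_r2(g: GenotypeMatrix, pcrit: float = 0.0):
    """Mean composite r² over all locus pairs after the Pcrit screen.

    Returns ``(mean_r2, harmonic_mean_S, n_comparisons, per_pair)``
    where ``per_pair`` holds (i, j, r2, S, Delta) rows.  Pairs are
    evaluated over the individuals non-missing at both loci.
    """
    gs = _pcrit_screen(g, pcrit)
    if gs.n_loci < 2:
        raise InvadepopError("fewer than 2 loci pass the Pcrit screen")
    x = gs.codes.astype(float)
    miss = gs.missing
    ok = (~miss).astype(float)
    x0 = np.where(miss, 0.0, x)
    # pairwise-complete first/second moments via masked matrix products
    S = ok.T @ ok
    sx = x0.T @ ok      # sum of x over rows where partner locus present
    sxy = x0.T @ x0
    sx2 = (x0**2).T @ ok
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_x = sx / S
        mean_y = mean_x.T
        cov = sxy / S - mean_x * mean_y
        var_x = sx2 / S - mean_x**2
        var_y = var_x.T
        r2 = cov**2 / (var_x * var_y)
    iu = np.triu_indices(gs.n_loci, k=1)
    sv = S[iu]
    # NeEstimator's small-sample convention: Burrows Delta carries an
    # S/(S-1) correction; its square enters r².  Waples' E[r²|S]
    # constants are calibrated for this corrected estimator.  Capped at
    # 1 so pathological pairs keep r² in [0, 1].
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = sv / (sv - 1.0)
    r2v = np.minimum(r2[iu] * factor**2, 1.0)
    deltav = (cov / 2.0)[iu] * factor  # Burrows composite disequilibrium
    good = np.isfinite(r2v) & (sv >= 2)
    r2v, sv, deltav = r2v[good], sv[good], deltav[good]
    if r2v.size == 0:
        raise InvadepopError("no usable locus pairs")
    mean_r2 = float(r2v.mean())
    harm_s = float(1.0 / np.mean(1.0 / sv))
    per_pair = np.column_stack([iu[0][good], iu[1][good], r2v, sv, deltav])
    return mean_r2, harm_s, int(r2v.size), per_pair


def expected_r2_sample(s: float) -> float:
    """E[r²|S]: the sample-size contribution under random mating
    (Waples 2006 regression constants)."""
    if s >= 30:
        return 1.0 / s + 3.19 / s**2
    return 0.0018 + 0.907 / s + 4.44 / s**2


def ne_from_r2(mean_r2: float, harmonic_mean_S: float, mating: str = "random") -> float:
    """Invert the drift relation: r²_drift -> Ne (Waples & Do 2008).

    Returns ``inf`` when mean r² does not exceed the sample-size
    expectation (no drift signal).
    """
    if mating != "random":
        raise InvadepopError("only random mating is implemented")
    s = harmonic_mean_S
    if s < 10:
        raise InvadepopError(
            "harmonic mean sample size < 10: LD-Ne is unreliable; "
            "collect more individuals or pool samples"
        )
    r2_drift = mean_r2 - expected_r2_sample(s)
    if r2_drift <= 0:
        return float("inf")
    if s >= 30:
        disc = max(1.0 / 9.0 - 2.76 * r2_drift, 0.0)
        ne = (1.0 / 3.0 + np.sqrt(disc)) / (2.0 * r2_drift)
    else:
        disc = max(0.308**2 - 2.08 * r2_drift, 0.0)
        ne = (0.308 + np.sqrt(disc)) / (2.0 * r2_drift)
    return float(max(ne, 0.0))


def _jackknife_ci(per_pair: np.ndarray, harm_s: float):
    """Delete-one-locus jackknife on mean r², mapped through the Ne
    inversion (monotone decreasing) to a 95% CI."""
    r2v = per_pair[:, 2]
    total = r2v.sum()
    n_pairs = len(r2v)
    loci = per_pair[:, :2].astype(int)
    # accumulate per-locus sums and counts in one pass
    n_idx = loci.max() + 1
    sums = np.zeros(n_idx)
    counts = np.zeros(n_idx, dtype=int)
    for col in (0, 1):
        np.add.at(sums, loci[:, col], r2v)
        np.add.at(counts, loci[:, col], 1)
    present = counts > 0
    means = []
    for s_l, m in zip(sums[present], counts[present]):
        if n_pairs - m >= 1:
            means.append((total - s_l) / (n_pairs - m))
    means = np.asarray(means)
    if len(means) < 3:
        return float("nan"), float("nan")
    nl = len(means)
    theta_dot = means.mean()
    se = np.sqrt((nl - 1) / nl * ((means - theta_dot) ** 2).sum())
    mean_r2 = total / n_pairs
    lo_r2 = mean_r2 - 1.96 * se
    hi_r2 = mean_r2 + 1.96 * se
    # Ne is decreasing in r²: upper r² -> lower Ne bound
    ne_low = ne_from_r2(hi_r2, harm_s) if hi_r2 > 0 else float("inf")
    ne_high = ne_from_r2(lo_r2, harm_s) if lo_r2 > 0 else float("inf")
    return float(ne_low), float(ne_high)


def ne_ld_estimate(
    g: GenotypeMatrix,
    pcrit_list: tuple[float, ...] = (0.0, 0.1, 0.2, 0.5),
    seed=None,
) -> list[NeResult]:
    """One LD-Ne estimate per Pcrit value, with jackknife CIs.

    A stable Ne across Pcrit suggests a stable isolated population;
    large spread flags processes generating excess rare alleles
    (immigration, expansion).  Use :func:`pcrit_spread` on the result.
    """
    results = []
    for pcrit in pcrit_list:
        mean_r2, harm_s, n_cmp, per_pair = burrows_r2(g, pcrit)
        ne = ne_from_r2(mean_r2, harm_s)
        ci_low, ci_high = _jackknife_ci(per_pair, harm_s)
        results.append(
            NeResult(
                pcrit=float(pcrit),
                mean_r2=mean_r2,
                n_comparisons=n_cmp,
                harmonic_mean_S=harm_s,
                ne_point=ne,
                ci_low=ci_low,
                ci_high=ci_high,
            )
        )
    return results


def pcrit_spread(results: list[NeResult]) -> float:
    """Max relative spread of finite point estimates across Pcrit values:
    (max - min)/min; inf when any estimate is infinite and another is
    finite, NaN when none is finite."""
    pts = np.array([r.ne_point for r in results])
    finite = pts[np.isfinite(pts)]
    if len(finite) == 0:
        return float("nan")
    if len(finite) < len(pts):
        return float("inf")
    return float((finite.max() - finite.min()) / finite.min())
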