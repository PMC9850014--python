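"""Genetic-diversity metrics and temporal comparison tests.

Population level: per-locus observed heterozygosity Ho, Nei's unbiased
within-population gene diversity Hs, and the inbreeding coefficient
Fis = 1 - Ho/Hs.  Individual level: multilocus heterozygosity (MLH) and
internal relatedness (IR).  Comparisons between the historical and
contemporary samples use a locus-paired Wilcoxon signed-rank test for
the per-locus metrics and label-permutation tests for the per-individual
metrics.  Weir-Cockerham Fst with a bootstrap CI quantifies
differentiation between groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix, InvadepopError


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str


@dataclass
class DiversityTable:
    """Per-locus Ho/Hs/Fis with unweighted means across loci."""

    per_locus: pd.DataFrame
    mean_ho: float
    mean_hs: float
    mean_fis: float
    group: str = ""


def _locus_counts(g: GenotypeMatrix):
    ok = ~g.missing
    n = ok.sum(axis=0).astype(float)
    het = ((g.codes == 1) & ok).sum(axis=0).astype(float)
    alt = np.where(ok, g.codes, 0).sum(axis=0).astype(float)
    return n, het, alt


def ho_hs_fis(g: GenotypeMatrix, group: str = "") -> DiversityTable:
    """Per-locus Ho, Nei's unbiased Hs and Fis for one population.

    Hs = n/(n-1) * (1 - sum p^2 - Ho/(2n)) with n the locus sample size;
    Fis = 1 - Ho/Hs (NaN where Hs = 0).  Loci with fewer than two
    non-missing genotypes are skipped.
    """
    n, het, alt = _locus_counts(g)
    usable = n >= 2
    if not usable.any():
        raise InvadepopError("no locus has >= 2 non-missing genotypes")
    n, het, alt = n[usable], het[usable], alt[usable]
    ids = [g.locus_ids[i] for i in np.flatnonzero(usable)]
    ho = het / n
    p = alt / (2 * n)
    sum_p2 = p**2 + (1 - p) ** 2
    hs = n / (n - 1) * (1 - sum_p2 - ho / (2 * n))
    with np.errstate(invalid="ignore", divide="ignore"):
        fis = np.where(hs != 0, 1 - ho / hs, np.nan)
    per_locus = pd.DataFrame(
        {"locus_id": ids, "n": n.astype(int), "Ho": ho, "Hs": hs, "Fis": fis}
    )
    fis_def = fis[np.isfinite(fis)]
    return DiversityTable(
        per_locus,
        float(np.mean(ho)),
        float(np.mean(hs)),
        float(fis_def.mean()) if fis_def.size else float("nan"),
        group,
    )


def mlh(g: GenotypeMatrix) -> np.ndarray:
    """Multilocus heterozygosity: het loci / typed loci per individual.

    Individuals with zero typed loci get NaN.
    """
    ok = ~g.missing
    typed = ok.sum(axis=1).astype(float)
    het = ((g.codes == 1) & ok).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(typed > 0, het / typed, np.nan)


def ir(g: GenotypeMatrix) -> np.ndarray:
    """Internal relatedness (Amos): IR = (2H - sum f_i)/(2N - sum f_i).

    H = number of homozygous loci, N = typed loci; at each homozygous
    locus both allele copies contribute, i.e. sum f_i adds 2*f(allele),
    with allele frequencies taken from the full sample.  Positive values
    indicate inbreeding, negative outbreeding.
    """
    ok = ~g.missing
    p_alt = g.alt_freq()  # full-sample frequencies
    hom_ref = (g.codes == 0) & ok
    hom_alt = (g.codes == 2) & ok
    n_hom = (hom_ref | hom_alt).sum(axis=1).astype(float)
    n_typed = ok.sum(axis=1).astype(float)
    sum_f = 2 * (hom_ref @ np.nan_to_num(1 - p_alt) + hom_alt @ np.nan_to_num(p_alt))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (2 * n_hom - sum_f) / (2 * n_typed - sum_f)
    out[n_typed == 0] = np.nan
    return out


def paired_wilcoxon_by_locus(a: np.ndarray, b: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on per-locus paired differences.

    Zero differences are dropped (Wilcoxon's original treatment); all
    ties is a degenerate test and raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InvadepopError("paired metrics must share the locus set")
    d = b - a
    d = d[np.isfinite(d)]
    nz = d[d != 0]
    if nz.size == 0:
        raise InvadepopError("all per-locus differences are zero (degenerate test)")
    if nz.size < 10:
        raise InvadepopError("fewer than 10 non-tied pairs")
    res = stats.wilcoxon(nz, alternative="two-sided", mode="auto")
    return TestResult(float(res.statistic), float(res.pvalue), 0, "wilcoxon_signed_rank")


def permutation_mean_diff(
    values: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 5000,
    seed=None,
) -> TestResult:
    """Two-sided randomization test for a difference in group means.

    p = (1 + #{permuted |dmean| >= observed}) / (n_perm + 1); group
    labels are shuffled.  Robust to the study's extreme 8-vs-195 group
    imbalance.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = np.isfinite(values)
    values, groups = values[keep], groups[keep]
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise InvadepopError("permutation test needs exactly two groups")
    m1 = groups == labels[0]
    n1 = int(m1.sum())
    if n1 < 2 or (len(values) - n1) < 2:
        raise InvadepopError("each group needs >= 2 members")
    obs = abs(values[m1].mean() - values[~m1].mean())
    total = values.sum()
    n = len(values)
    n2 = n - n1
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)[:n1]
        s1 = values[idx].sum()
        d = abs(s1 / n1 - (total - s1) / n2)
        if d >= obs - 1e-15:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return TestResult(float(obs), float(p), n_perm, "permutation_mean_diff")


# ---------------------------------------------------------------------------
# Weir & Cockerham Fst
# ---------------------------------------------------------------------------

def _wc_components(g: GenotypeMatrix, pops: np.ndarray):
    """Per-locus Weir-Cockerham variance components (a, b, c) for
    biallelic loci across r populations."""
    pops = np.asarray(pops)
    labels = pd.unique(pops)
    r = len(labels)
    if r < 2:
        raise InvadepopError("Fst needs at least two populations")
    ok = ~g.missing
    ni = np.zeros((r, g.n_loci))
    pi = np.zeros((r, g.n_loci))
    hi = np.zeros((r, g.n_loci))
    for s, lab in enumerate(labels):
        rows = pops == lab
        ok_s = ok[rows]
        n_s = ok_s.sum(axis=0).astype(float)
        alt_s = np.where(ok_s, g.codes[rows], 0).sum(axis=0)
        het_s = ((g.codes[rows] == 1) & ok_s).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            pi[s] = np.where(n_s > 0, alt_s / (2 * n_s), np.nan)
            hi[s] = np.where(n_s > 0, het_s / n_s, np.nan)
        ni[s] = n_s
    usable = (ni > 0).all(axis=0)
    ni, pi, hi = ni[:, usable], pi[:, usable], hi[:, usable]
    nbar = ni.mean(axis=0)
    rr = float(r)
    nc = (rr * nbar - (ni**2).sum(axis=0) / (rr * nbar)) / (rr - 1)
    pbar = (ni * pi).sum(axis=0) / (rr * nbar)
    s2 = (ni * (pi - pbar) ** 2).sum(axis=0) / ((rr - 1) * nbar)
    hbar = (ni * hi).sum(axis=0) / (rr * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2
            - 1.0 / (nbar - 1) * (pbar * (1 - pbar) - (rr - 1) / rr * s2 - hbar / 4)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (rr - 1) / rr * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
    c = hbar / 2
    good = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    return a[good], b[good], c[good]


def weir_cockerham_fst(
    g: GenotypeMatrix,
    pops: np.ndarray,
    n_bootstrap: int = 1000,
    seed=None,
) -> dict:
    """Multi-locus Weir-Cockerham theta with a percentile bootstrap CI.

    theta = sum_l a_l / sum_l (a_l + b_l + c_l); the CI resamples loci.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a, b, c = _wc_components(g, pops)
    denom = a + b + c
    if denom.sum() == 0:
        raise InvadepopError("no variation: Fst undefined")
    theta = float(a.sum() / denom.sum())
    nl = len(a)
    if n_bootstrap < 1:
        return {"theta": theta, "ci_low": float("nan"), "ci_high": float("nan"),
                "n_loci": nl, "n_bootstrap": 0}
    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        idx = rng.integers(0, nl, nl)
        den = denom[idx].sum()
        boots[i] = a[idx].sum() / den if den != 0 else np.nan
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return {
        "theta": theta,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n_loci": nl,
        "n_bootstrap": n_bootstrap,
    }


def diversity_by_group(g: GenotypeMatrix, groups: np.ndarray) -> dict[str, DiversityTable]:
    """Ho/Hs/Fis tables per group label (e.g. era)."""
    groups = np.asarray(groups)
    out = {}
    for lab in pd.unique(groups):
        sub = g.take_samples(np.flatnonzero(groups == lab))
        out[str(lab)] = ho_hs_fis(sub, group=str(lab))
    return out
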