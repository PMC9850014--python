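"""Non-spatial population structure: PCA, K-means BIC scan, DAPC.

The K scan follows adegenet's find.clusters logic: K-means on all
retained principal components for K = 1..Kmax, scored by
BIC = n*ln(WSS/n) + K*ln(n), with two selection rules — "min" (smallest
BIC) and "diffNgroup" (the K where successive BIC decreases collapse).
DAPC runs linear discriminant analysis on a PC subspace whose dimension
is chosen by repeated stratified 90/10 cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import GenotypeMatrix, InvadepopError


@dataclass
class PcaResult:
    scores: np.ndarray
    eigenvalues: np.ndarray
    proportion_variance: np.ndarray


@dataclass
class ClusterScan:
    bic: np.ndarray                # index K-1
    assignments: dict              # K -> labels
    best_k_min: int
    best_k_diffngroup: int


@dataclass
class DapcResult:
    n_pcs: int
    axes: np.ndarray               # discriminant scores per individual
    posterior: np.ndarray          # per-individual group membership probs
    groups: np.ndarray
    classes: np.ndarray
    cv_trace: dict | None          # n_pcs -> mean assignment error


def _imputed_centred(g: GenotypeMatrix) -> np.ndarray:
    """Centred genotype matrix with missing values replaced by the locus
    mean (PCA-only; never written back)."""
    x = g.codes.astype(float)
    miss = g.missing
    x[miss] = np.nan
    mean = np.nanmean(x, axis=0)
    keep = np.isfinite(mean)
    x = x[:, keep]
    mean = mean[keep]
    idx = np.where(np.isnan(x))
    x[idx] = np.take(mean, idx[1])
    return x - mean


def pca(g: GenotypeMatrix, n_components: int | None = None) -> PcaResult:
    """PCA of centred, mean-imputed genotypes (deterministic full SVD)."""
    if g.n_samples < 2:
        raise InvadepopError("PCA needs at least 2 individuals")
    x = _imputed_centred(g)
    n = x.shape[0]
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    eig = s**2 / n
    scores = u * s
    total_var = (x**2).sum() / n
    prop = eig / total_var if total_var > 0 else np.zeros_like(eig)
    if n_components is not None:
        scores = scores[:, :n_components]
        eig = eig[:n_components]
        prop = prop[:n_components]
    return PcaResult(scores, eig, prop)


def kmeans_bic_scan(scores: np.ndarray, k_max: int = 10, seed=None) -> ClusterScan:
    """K-means for K=1..k_max on the retained PCs, scored by BIC.

    best_k_min minimizes BIC; best_k_diffngroup picks the smallest K
    whose BIC decrease towards K+1 falls below one-third of the largest
    successive decrease (a sharp-elbow reading of adegenet's
    'diffNgroup' criterion).
    """
    from sklearn.cluster import KMeans

    if k_max < 2:
        raise InvadepopError("k_max must be >= 2")
    rs = int(np.random.default_rng(seed).integers(2**31 - 1))
    n = scores.shape[0]
    k_max_eff = min(k_max, n)
    bic = np.full(k_max_eff, np.nan)
    assignments = {}
    for k in range(1, k_max_eff + 1):
        if k == 1:
            labels = np.zeros(n, dtype=int)
            wss = ((scores - scores.mean(axis=0)) ** 2).sum()
        else:
            km = KMeans(n_clusters=k, n_init=10, random_state=rs + k)
            labels = km.fit_predict(scores)
            wss = km.inertia_
        wss = max(wss, 1e-12)
        bic[k - 1] = n * np.log(wss / n) + k * np.log(n)
        assignments[k] = labels
    best_min = int(np.nanargmin(bic) + 1)
    # diffNgroup: successive decreases d_K = BIC(K) - BIC(K+1)
    d = bic[:-1] - bic[1:]
    best_diff = 1
    if len(d) and np.nanmax(d) > 0:
        thresh = np.nanmax(d) / 3.0
        best_diff = len(d) + 1
        for k in range(1, len(d) + 1):
            if d[k - 1] < thresh:
                best_diff = k
                break
    return ClusterScan(bic, assignments, best_min, best_diff)


def dapc(
    scores: np.ndarray,
    groups: np.ndarray,
    n_pcs: int | str = "cv",
    seed=None,
    n_cv_reps: int = 30,
) -> DapcResult:
    """Discriminant analysis of principal components.

    With ``n_pcs="cv"``, candidate PC counts are compared by repeated
    stratified 90/10 splits; the count with the lowest mean assignment
    error is retained.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.model_selection import StratifiedShuffleSplit

    groups = np.asarray(groups)
    classes, counts = np.unique(groups, return_counts=True)
    if len(classes) < 2:
        raise InvadepopError("DAPC needs >= 2 groups")
    if counts.min() < 3:
        raise InvadepopError("every group needs >= 3 members")
    if n_pcs == 0:
        raise InvadepopError("n_pcs must be positive")
    rng = np.random.default_rng(seed)
    n, p = scores.shape
    max_pcs = min(p, n - len(classes) - 1)
    cv_trace = None
    if n_pcs == "cv":
        candidates = sorted(
            {max(1, int(round(f * max_pcs))) for f in (0.1, 0.2, 0.3, 0.5, 0.7, 0.9)}
        )
        cv_trace = {}
        for cand in candidates:
            sss = StratifiedShuffleSplit(
                n_splits=n_cv_reps, test_size=0.1,
                random_state=int(rng.integers(2**31 - 1)),
            )
            errs = []
            for tr, te in sss.split(scores, groups):
                lda_cv = LinearDiscriminantAnalysis()
                lda_cv.fit(scores[tr][:, :cand], groups[tr])
                pred = lda_cv.predict(scores[te][:, :cand])
                errs.append(np.mean(pred != groups[te]))
            cv_trace[cand] = float(np.mean(errs))
        n_pcs = min(cv_trace, key=cv_trace.get)
    n_pcs = int(n_pcs)
    if n_pcs < 1:
        raise InvadepopError("n_pcs must be positive")
    n_pcs = min(n_pcs, p)
    lda = LinearDiscriminantAnalysis()
    axes = lda.fit_transform(scores[:, :n_pcs], groups)
    post = lda.predict_proba(scores[:, :n_pcs])
    return DapcResult(n_pcs, axes, post, groups, classes, cv_trace)


def cluster_location_association(labels: np.ndarray, locations: np.ndarray) -> dict:
    """Contingency chi-square test between cluster labels and sampling
    locations (the paper reports 'no associations'; the exact test it
    used is unstated, so a standard chi-square is provided)."""
    from scipy.stats import chi2_contingency
    import pandas as pd

    tab = pd.crosstab(pd.Series(labels), pd.Series(locations))
    chi2, p, dof, _ = chi2_contingency(tab.to_numpy())
    return {"chi2": float(chi2), "p_value": float(p), "dof": int(dof)}
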