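"""Spatially explicit analyses of within-population structure.

Covers: river-distance handling and nMDS re-projection to Cartesian
coordinates; spatial PCA (eigenanalysis of genetic variance times
Moran's autocorrelation over a connection network) with permutation
tests for global and local structure; Moran's-eigenvector-map (MEM)
forward selection against a proportion-of-shared-alleles genetic
distance; Mantel correlograms over distance classes with the genetic
neighbourhood rule; sGD-style neighbourhood diversity within a fixed
radius; and directional distance-decay regressions with backward
likelihood-ratio selection.

Sign convention for the correlogram: positive Mantel r means
individuals within the class are genetically more similar than average
(positive spatial autocorrelation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.special import gammaln

from .diversity import TestResult, ho_hs_fis
from .genotype_io import GenotypeMatrix, InvadepopError


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

def load_distances(
    path: str | None = None,
    metadata: pd.DataFrame | None = None,
    sample_ids: list[str] | None = None,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Load (or derive) the pairwise distance matrix keyed by sample id.

    A TSV square matrix (ids as header row and first column) is the
    primary route — the study metric is along-river network distance.
    Without a file, a haversine great-circle fallback is computed from
    metadata lon/lat with a logged warning (river distance is the
    intended metric).
    """
    import logging

    if path is not None:
        d = pd.read_csv(path, sep="\t", index_col=0)
        d.index = d.index.astype(str)
        d.columns = d.columns.astype(str)
    elif metadata is not None and {"lon", "lat"} <= set(metadata.columns):
        logging.getLogger("invadepop").warning(
            "no distance matrix supplied; falling back to haversine "
            "distances (the study metric is river network distance)"
        )
        lon = np.radians(metadata["lon"].to_numpy(float))
        lat = np.radians(metadata["lat"].to_numpy(float))
        dlon = lon[None, :] - lon[:, None]
        dlat = lat[None, :] - lat[:, None]
        a = (
            np.sin(dlat / 2) ** 2
            + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
        )
        km = 2 * 6371.0 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
        ids = [str(s) for s in metadata["sample_id"]]
        d = pd.DataFrame(km, index=ids, columns=ids)
    else:
        raise InvadepopError("supply a distance TSV or metadata with lon/lat")
    m = d.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or list(d.index) != list(d.columns):
        raise InvadepopError("distance matrix must be square with matching ids")
    if np.nanmax(np.abs(m - m.T)) > tol:
        raise InvadepopError("distance matrix asymmetric beyond tolerance")
    if np.nanmax(np.abs(np.diag(m))) > tol:
        raise InvadepopError("distance matrix diagonal must be zero")
    if sample_ids is not None:
        missing = [s for s in sample_ids if str(s) not in set(d.index)]
        if missing:
            raise InvadepopError(f"ids missing from distance matrix: {missing[:10]}")
        d = d.loc[[str(s) for s in sample_ids], [str(s) for s in sample_ids]]
    return d


def proportion_shared_allele_distance(g: GenotypeMatrix) -> np.ndarray:
    """1 - mean proportion of shared alleles (Dps) between individuals.

    At one locus two diploid genotypes share (2 - |xi - xj|)/2 of their
    alleles; the mean runs over loci typed in both individuals.
    """
    x = g.codes.astype(float)
    miss = g.missing
    x[miss] = np.nan
    n = g.n_samples
    out = np.zeros((n, n))
    # |xi-xj| via expansion: loop rows (n is modest) keeping memory flat
    for i in range(n):
        diff = np.abs(x - x[i])
        shared = 1.0 - np.nanmean(diff, axis=1) / 2.0
        out[i] = 1.0 - shared
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# nMDS projection
# ---------------------------------------------------------------------------

def nmds_project(d: np.ndarray | pd.DataFrame, dims: int = 2, seed=None,
                 n_restarts: int = 4):
    """Nonmetric MDS embedding of a distance matrix; returns
    (coordinates, stress-1).  Initialized from classical scaling, with
    seeded random restarts keeping the best solution."""
    from sklearn.manifold import MDS

    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    n = dm.shape[0]
    if n < 3:
        raise InvadepopError("nMDS needs at least 3 samples")
    if dims >= n:
        raise InvadepopError("dims must be < number of samples")
    rng = np.random.default_rng(seed)
    # classical scaling start
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dims]
    init = v[:, order] * np.sqrt(np.maximum(w[order], 0))
    best = None
    import warnings

    for r in range(n_restarts):
        mds = MDS(
            n_components=dims,
            metric=False,
            dissimilarity="precomputed",
            n_init=1,
            max_iter=500,
            random_state=int(rng.integers(2**31 - 1)),
            normalized_stress=True,
        )
        start = init if r == 0 else init + rng.normal(scale=init.std() + 1e-9, size=init.shape)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            coords = mds.fit_transform(dm, init=start)
        if best is None or mds.stress_ < best[1]:
            best = (coords, float(mds.stress_))
    return best


# ---------------------------------------------------------------------------
# Connection networks and Moran eigenvector maps
# ---------------------------------------------------------------------------

def min_distance_neighbour_graph(dm: np.ndarray) -> np.ndarray:
    """Binary adjacency connecting all pairs within the smallest
    distance that keeps the graph connected (the longest edge of the
    minimum spanning tree).  Raises on degenerate geometry (duplicated
    single sampling point: threshold 0)."""
    dm = np.asarray(dm, dtype=float)
    n = dm.shape[0]
    if n < 3:
        raise InvadepopError("connection network needs >= 3 samples")
    mst = minimum_spanning_tree(dm).toarray()
    thresh = mst.max()
    if thresh <= 0:
        raise InvadepopError("degenerate graph: all sampling points coincide")
    adj = (dm <= thresh) & ~np.eye(n, dtype=bool)
    if (adj.sum(axis=1) == 0).any():
        raise InvadepopError("disconnected connection network")  # pragma: no cover
    return adj


def _row_normalize(adj: np.ndarray) -> np.ndarray:
    w = adj.astype(float)
    return w / w.sum(axis=1, keepdims=True)


@dataclass
class SpcaResult:
    eigenvalues: np.ndarray
    scores: np.ndarray
    global_test: TestResult
    local_test: TestResult
    n_positive_retained: int = 2
    n_negative_retained: int = 3


def spca(
    g: GenotypeMatrix,
    coords: np.ndarray,
    n_perm: int = 999,
    seed=None,
) -> SpcaResult:
    """Spatial PCA (Jombart): eigenanalysis of (1/2n) X'(W+W')X with X
    the centred genotype matrix and W the row-normalized
    minimum-distance neighbour graph built on ``coords``.

    Positive eigenvalues capture global structure (neighbours alike),
    negative ones local structure (neighbours contrasting).  Both are
    tested by permuting genotype rows across locations; the statistics
    are the largest positive eigenvalue and the largest negative
    magnitude.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    dm = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    adj = min_distance_neighbour_graph(dm)
    w = _row_normalize(adj)
    n = g.n_samples
    x = g.codes.astype(float)
    x = np.where(g.missing, np.nan, x)
    mean = np.nanmean(x, axis=0)
    x = np.where(np.isnan(x), mean, x) - mean
    s = (w + w.T) / (2.0 * n)
    c = x.T @ s @ x
    eigval, eigvec = np.linalg.eigh(c)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    scores = x @ eigvec[:, order]

    rng = np.random.default_rng(seed)
    # fast permutations through G = X X': eig(Xp' S Xp) = eig(G^1/2 Pt S P G^1/2)
    gmat = x @ x.T
    gw, gv = np.linalg.eigh(gmat)
    gh = (gv * np.sqrt(np.maximum(gw, 0))) @ gv.T
    obs_max = eigval.max()
    obs_min = abs(min(eigval.min(), 0.0))
    cnt_g = cnt_l = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        sp = s[np.ix_(p, p)]
        ev = np.linalg.eigvalsh(gh @ sp @ gh)
        if ev.max() >= obs_max:
            cnt_g += 1
        if abs(min(ev.min(), 0.0)) >= obs_min:
            cnt_l += 1
    p_g = (1 + cnt_g) / (n_perm + 1)
    p_l = (1 + cnt_l) / (n_perm + 1)
    return SpcaResult(
        eigenvalues=eigval,
        scores=scores,
        global_test=TestResult(float(obs_max), float(p_g), n_perm, "spca_global_max_eig"),
        local_test=TestResult(float(obs_min), float(p_l), n_perm, "spca_local_max_eig"),
    )


def _mem_basis(dm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Moran eigenvector map basis from a truncated connectivity matrix.

    Weights 1 - (d/(4t))^2 within the truncation distance t (longest
    MST edge), 0 beyond; the doubly-centred weight matrix is
    eigendecomposed and near-zero eigenvalues dropped.  Returns
    (eigenvalues, eigenvectors) sorted by descending eigenvalue
    (positive = broad-scale / positive autocorrelation patterns).
    """
    dm = np.asarray(dm, dtype=float)
    n = dm.shape[0]
    mst = minimum_spanning_tree(dm).toarray()
    t = mst.max()
    if t <= 0:
        raise InvadepopError("degenerate geometry for MEM basis")
    a = np.where((dm <= t) & (dm > 0), 1.0 - (dm / (4.0 * t)) ** 2, 0.0)
    np.fill_diagonal(a, 0.0)
    j = np.eye(n) - np.ones((n, n)) / n
    omega = j @ a @ j
    w, v = np.linalg.eigh(omega)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    keep = np.abs(w) > 1e-9 * max(np.abs(w).max(), 1.0)
    return w[keep], v[:, keep]


def _rda_r2(y: np.ndarray, x: np.ndarray) -> float:
    """Redundancy R²: share of total variance of Y explained by the
    column space of X (with intercept)."""
    x1 = np.column_stack([np.ones(len(y)), x]) if x.size else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(x1, y, rcond=None)
    fit = x1 @ beta
    yc = y - y.mean(axis=0)
    sst = (yc**2).sum()
    ssr = ((fit - fit.mean(axis=0)) ** 2).sum()
    return float(ssr / sst) if sst > 0 else 0.0


def _adj_r2(r2: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return float("nan")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


@dataclass
class MemResult:
    selected: list[int]
    r2_adj: float
    trace: list[dict] = field(default_factory=list)
    eigenvalues: np.ndarray | None = None


def mem_forward_selection(
    g: GenotypeMatrix,
    d: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    seed=None,
    alpha: float = 0.05,
) -> MemResult:
    """MEM analysis of genetic distance (MEMgene-style).

    The response is the principal-coordinate representation of the
    1 - proportion-of-shared-alleles genetic distance; candidate
    predictors are the MEM eigenvectors of the river-distance
    connectivity.  Forward selection adds the best eigenvector while its
    permutation p-value stays below alpha and the adjusted R² of the
    selected set keeps increasing; an empty selection (R²adj = 0) is a
    valid no-structure outcome.
    """
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    n = g.n_samples
    if n < 10:
        raise InvadepopError("MEM analysis needs >= 10 samples")
    rng = np.random.default_rng(seed)
    gd = proportion_shared_allele_distance(g)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (gd**2) @ j
    w, v = np.linalg.eigh(b)
    pos = w > 1e-9 * max(w.max(), 1.0)
    y = v[:, pos] * np.sqrt(w[pos])
    mem_w, mem_v = _mem_basis(dm)

    selected: list[int] = []
    trace: list[dict] = []
    r2_prev = 0.0
    adj_prev = 0.0
    candidates = list(range(mem_v.shape[1]))
    while candidates:
        best_c, best_r2 = None, -np.inf
        for cnd in candidates:
            r2 = _rda_r2(y, mem_v[:, selected + [cnd]])
            if r2 > best_r2:
                best_c, best_r2 = cnd, r2
        delta_obs = best_r2 - r2_prev
        # permutation of residual rows under the current model
        x_sel = mem_v[:, selected]
        x1 = np.column_stack([np.ones(n), x_sel]) if selected else np.ones((n, 1))
        beta, *_ = np.linalg.lstsq(x1, y, rcond=None)
        resid = y - x1 @ beta
        cnt = 0
        for _ in range(n_perm):
            yp = (x1 @ beta) + resid[rng.permutation(n)]
            r2p = _rda_r2(yp, mem_v[:, selected + [best_c]])
            if r2p - _rda_r2(yp, x_sel) >= delta_obs:
                cnt += 1
        pval = (1 + cnt) / (n_perm + 1)
        adj_new = _adj_r2(best_r2, n, len(selected) + 1)
        trace.append(
            {"mem": int(best_c), "r2": best_r2, "r2_adj": adj_new, "p": pval}
        )
        if pval > alpha or adj_new <= adj_prev:
            break
        selected.append(best_c)
        candidates.remove(best_c)
        r2_prev, adj_prev = best_r2, adj_new
    r2_adj = _adj_r2(r2_prev, n, len(selected)) if selected else 0.0
    return MemResult(selected, max(r2_adj, 0.0) if selected else 0.0, trace, mem_w)


# ---------------------------------------------------------------------------
# Mantel correlogram and genetic neighbourhood
# ---------------------------------------------------------------------------

@dataclass
class CorrelogramRow:
    class_upper_km: float
    mantel_r: float
    p_value: float
    p_corrected: float
    n_pairs: int
    significant: bool


@dataclass
class CorrelogramResult:
    rows: list[CorrelogramRow]
    neighbourhood_size_km: float          # largest class of the initial significant run
    first_nonsignificant_km: float        # alternative reading of the rule
    eradication_radius_km: float          # half the neighbourhood size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])


def mantel_correlogram(
    gdist: np.ndarray,
    d: np.ndarray | pd.DataFrame,
    class_start: float = 10.0,
    class_end: float = 300.0,
    class_step: float = 10.0,
    n_perm: int = 999,
    seed=None,
    alpha: float = 0.05,
) -> CorrelogramResult:
    """Mantel correlogram over distance classes with the genetic
    neighbourhood rule.

    Per class, Mantel r correlates the genetic distance with the
    class-membership indicator (sign flipped so that positive r =
    within-class similarity).  p-values come from 999 seeded
    permutations of sample order, with progressive Holm correction
    across ordered classes.  The genetic neighbourhood is the largest
    class bound of the initial unbroken run of significant positive
    classes; the alternative reading (first class no longer
    significant) is also reported, as is half the neighbourhood (the
    eradication-radius scale discussed for management).
    """
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    gdist = np.asarray(gdist, dtype=float)
    n = dm.shape[0]
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    gvec = gdist[iu]
    gc = gvec - gvec.mean()
    gnorm = np.sqrt((gc**2).sum())
    uppers = np.arange(class_start, class_end + 1e-9, class_step)
    lowers = uppers - class_step
    ind_cols = []
    n_pairs = []
    for lo, up in zip(lowers, uppers):
        mvec = ((dm[iu] > lo) & (dm[iu] <= up)).astype(float)
        n_pairs.append(int(mvec.sum()))
        mc = mvec - mvec.mean()
        norm = np.sqrt((mc**2).sum())
        ind_cols.append(mc / norm if norm > 0 else np.zeros_like(mc))
    m = np.column_stack(ind_cols)  # pairs x classes, centred+normalized

    def all_r(gmat_perm_vec):
        gcp = gmat_perm_vec - gmat_perm_vec.mean()
        nrm = np.sqrt((gcp**2).sum())
        if nrm == 0:
            return np.zeros(m.shape[1])
        return -(gcp @ m) / nrm  # sign: positive = similarity within class

    r_obs = all_r(gvec)
    counts = np.zeros(len(uppers))
    for _ in range(n_perm):
        p = rng.permutation(n)
        gp = gdist[np.ix_(p, p)][iu]
        counts += np.abs(all_r(gp)) >= np.abs(r_obs) - 1e-15
    p_raw = (1 + counts) / (n_perm + 1)
    # progressive Holm: class i tested after classes 1..i-1 -> factor i
    p_corr = np.minimum(p_raw * (np.arange(len(uppers)) + 1), 1.0)
    rows = []
    for i, up in enumerate(uppers):
        sig = bool(n_pairs[i] > 0 and r_obs[i] > 0 and p_corr[i] <= alpha)
        rows.append(
            CorrelogramRow(float(up), float(r_obs[i]), float(p_raw[i]),
                           float(p_corr[i]), n_pairs[i], sig)
        )
    nb = float("nan")
    first_nonsig = float("nan")
    for row in rows:
        if row.n_pairs == 0:
            continue  # empty class: skipped by the rule
        if row.significant:
            nb = row.class_upper_km
        else:
            first_nonsig = row.class_upper_km
            break
    er = nb / 2.0 if np.isfinite(nb) else float("nan")
    return CorrelogramResult(rows, nb, first_nonsig, er)


# ---------------------------------------------------------------------------
# Neighbourhood diversity (sGD-style)
# ---------------------------------------------------------------------------

def _rarefied_ar(g: GenotypeMatrix, rows: np.ndarray, g_copies: int) -> float:
    """Mean rarefied allelic richness over loci for the given
    individuals, at a rarefaction depth of ``g_copies`` gene copies.
    For biallelic SNPs Ar lies in [1, 2]."""
    sub = g.codes[rows]
    ok = sub >= 0
    n_copies = 2 * ok.sum(axis=0)
    alt = np.where(ok, sub, 0).sum(axis=0)
    ref = n_copies - alt
    usable = n_copies >= g_copies
    if not usable.any():
        return float("nan")
    alt, ref, n_copies = alt[usable], ref[usable], n_copies[usable]

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    denom = log_comb(n_copies, g_copies)
    ar = np.zeros(len(alt))
    for counts in (ref, alt):
        with np.errstate(invalid="ignore"):
            miss_all = np.where(
                n_copies - counts >= g_copies,
                np.exp(log_comb(n_copies - counts, g_copies) - denom),
                0.0,
            )
        ar += 1.0 - miss_all
    return float(ar.mean())


def neighborhood_diversity(
    g: GenotypeMatrix,
    d: np.ndarray | pd.DataFrame,
    radius_km: float = 220.0,
    min_n: int = 20,
) -> pd.DataFrame:
    """Per-individual genetic-neighbourhood diversity within a radius.

    Members are all individuals within ``radius_km`` of the focal
    (inclusive, along the supplied distance).  Neighbourhoods smaller
    than ``min_n`` are reported but not computed (the study's Lake
    Ontario case).  Ho, He (Nei unbiased) and Fis are neighbourhood
    means over loci; Ar is rarefied to 2x the smallest qualifying
    neighbourhood size.
    """
    if radius_km <= 0:
        raise InvadepopError("radius must be positive")
    dm = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    n = g.n_samples
    members = [np.flatnonzero(dm[i] <= radius_km) for i in range(n)]
    sizes = np.array([len(m) for m in members])
    qualifying = sizes[sizes >= min_n]
    g_copies = 2 * int(qualifying.min()) if len(qualifying) else 0
    recs = []
    for i in range(n):
        rec = {
            "sample_id": g.sample_ids[i],
            "n_members": int(sizes[i]),
            "computed": False,
            "reason": "",
            "Ho": np.nan, "He": np.nan, "Fis": np.nan, "Ar": np.nan,
        }
        if sizes[i] < min_n:
            rec["reason"] = "insufficient n"
        else:
            sub = g.take_samples(members[i])
            t = ho_hs_fis(sub)
            rec.update(
                computed=True,
                Ho=t.mean_ho,
                He=t.mean_hs,
                Fis=t.mean_fis,
                Ar=_rarefied_ar(g, members[i], g_copies),
            )
        recs.append(rec)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Distance-decay regressions
# ---------------------------------------------------------------------------

@dataclass
class DecayModel:
    response: str
    formula: str
    coefficients: dict
    adj_r2: float
    slope_per_100km: float | None
    lrt_trace: list[dict]
    n_used: int
    excluded: list[str] = field(default_factory=list)


def decay_regression(
    metric: np.ndarray | pd.Series,
    metadata: pd.DataFrame,
    response_name: str = "metric",
    alpha: float = 0.05,
    exclude_outliers: bool = False,
    outlier_fold: float = 4.0,
) -> DecayModel:
    """OLS of a diversity metric on distance x direction with backward
    likelihood-ratio elimination.

    Starts from ``metric ~ distance * direction`` and drops the
    interaction, then nonsignificant main effects, by LRT chi-square at
    ``alpha``.  With a single direction level the direction terms are
    dropped up front (warning in the trace).  ``exclude_outliers``
    optionally removes high-leverage points whose distance exceeds
    ``outlier_fold`` times the mean (off by default; every exclusion is
    reported).
    """
    import statsmodels.formula.api as smf
    from scipy.stats import chi2

    df = pd.DataFrame(
        {
            "y": np.asarray(metric, dtype=float),
            "distance": metadata["distance_from_origin"].to_numpy(float),
            "direction": metadata["direction"].astype(str).to_numpy(),
        }
    ).dropna()
    excluded: list[str] = []
    if exclude_outliers:
        lim = outlier_fold * df["distance"].mean()
        out_rows = df.index[df["distance"] > lim]
        excluded = [str(metadata["sample_id"].iloc[i]) for i in out_rows]
        df = df.drop(out_rows)
    if len(df) < 10:
        raise InvadepopError("decay regression needs >= 10 observations")
    trace: list[dict] = []
    single_direction = df["direction"].nunique() < 2
    if single_direction:
        trace.append({"term": "direction", "note": "single level; dropped", "kept": False})
        terms = ["distance"]
    else:
        terms = ["distance", "direction", "distance:direction"]

    def fit(ts):
        rhs = " + ".join(ts) if ts else "1"
        return smf.ols(f"y ~ {rhs}", data=df).fit()

    def lrt(full_terms, drop_term):
        m_full = fit(full_terms)
        reduced = [t for t in full_terms if t != drop_term]
        m_red = fit(reduced)
        stat = 2 * (m_full.llf - m_red.llf)
        dof = int(m_full.df_model - m_red.df_model)
        p = float(chi2.sf(stat, max(dof, 1)))
        return stat, dof, p, reduced

    # interaction first, then main effects (largest p first)
    if "distance:direction" in terms:
        stat, dof, p, reduced = lrt(terms, "distance:direction")
        keep = p < alpha
        trace.append({"term": "distance:direction", "chi2": stat, "df": dof,
                      "p": p, "kept": keep})
        if not keep:
            terms = reduced
    if "distance:direction" not in terms:
        improved = True
        while improved and terms:
            improved = False
            results = []
            for t in terms:
                stat, dof, p, reduced = lrt(terms, t)
                results.append((p, t, stat, dof, reduced))
            results.sort(reverse=True)
            p, t, stat, dof, reduced = results[0]
            keep = p < alpha
            trace.append({"term": t, "chi2": stat, "df": dof, "p": p, "kept": keep})
            if not keep:
                terms = reduced
                improved = True
    model = fit(terms)
    coefs = dict(model.params)
    slope = None
    if "distance" in coefs:
        slope = float(coefs["distance"] * 100.0)
    return DecayModel(
        response=response_name,
        formula="y ~ " + (" + ".join(terms) if terms else "1"),
        coefficients={k: float(v) for k, v in coefs.items()},
        adj_r2=float(model.rsquared_adj) if model.df_model > 0 else 0.0,
        slope_per_100km=slope,
        lrt_trace=trace,
        n_used=len(df),
        excluded=excluded,
    )
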