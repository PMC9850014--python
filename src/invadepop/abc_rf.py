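"""ABC random-forest inference of invasion history.

Eight competing coalescent scenarios describe the introduction of a
founder population, in two groups: group 1 (scenarios 1-4) has no recent
bottleneck; group 2 (scenarios 5-8) passes through a small bottleneck
population (Nbottleneck) between the ancestral population and
establishment.  Within each group the four variants are the 2x2
combinations of {population-size change at ta: yes/no} x {change at tc:
yes/no}; scenario 5 is a contemporary bottleneck with no subsequent
recovery.  Scenario structures are data (:class:`ScenarioSpec`), so
alternative topologies can be supplied without code changes.

Inference follows the ABC-RF recipe: draw parameters from uniform priors
constrained to t0 < ta < tb < tc < td, simulate SNP datasets matching
the observed design, reduce each to a fixed summary vector, train a
1000-tree random forest for scenario choice (prior error rate =
out-of-bag misclassification; posterior probability from a second
regression forest trained on out-of-bag correctness), and a quantile
regression forest for parameter estimation (median, 95% interval, and
out-of-bag NMAE).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import ho_hs_fis, weir_cockerham_fst
from .genotype_io import GenotypeMatrix, InvadepopError
from .simulate import (
    Demography,
    SamplingScheme,
    SimulatedDataset,
    simulate_snp_dataset,
    two_era_scheme,
)

PRIOR_BOUNDS = {
    "Nancestral": (2, 10_000),
    "Nestablishment": (2, 10_000),
    "Ncontemporary": (2, 10_000),
    "Nbottleneck": (2, 100),
    "t0": (0, 5),
    "ta": (2, 15),
    "tb": (2, 15),
    "tc": (2, 50),
    "td": (1, 100),
}
TIME_ORDER = ("t0", "ta", "tb", "tc", "td")


@dataclass(frozen=True)
class ScenarioSpec:
    """One demographic scenario: bottleneck or not, and which of the
    ta / tc size changes are active."""

    id: int
    group: int  # 1 = no bottleneck, 2 = recent bottleneck
    change_at_ta: bool
    change_at_tc: bool
    description: str = ""

    def demography(self, draw: dict) -> Demography:
        """Map a prior draw to a piecewise-constant demography.

        Backwards in time: the contemporary epoch runs to ta, the
        establishment epoch to tc; group 2 inserts the bottleneck epoch
        [tc, td) at Nbottleneck; the ancestral size applies beyond
        (beyond tc for group 1, beyond td for group 2).  Inactive
        changes merge an epoch with the one behind it.
        """
        if self.group == 2:
            pre = int(draw["Nbottleneck"])
        else:
            pre = int(draw["Nancestral"])
        n_estab = int(draw["Nestablishment"]) if self.change_at_tc else pre
        n_cont = int(draw["Ncontemporary"]) if self.change_at_ta else n_estab
        epochs = [(0, n_cont)]
        if self.change_at_ta:
            epochs.append((int(draw["ta"]), n_estab))
        if self.change_at_tc:
            epochs.append((int(draw["tc"]), pre))
        if self.group == 2:
            epochs.append((int(draw["td"]), int(draw["Nancestral"])))
        # merge epochs with equal start (inactive changes) keeping the last
        dedup: dict[int, int] = {}
        for start, n in epochs:
            dedup[start] = n
        merged = sorted(dedup.items())
        # drop no-op size repeats
        final = [merged[0]]
        for start, n in merged[1:]:
            if n != final[-1][1]:
                final.append((start, n))
        return Demography(tuple(final), label=f"scenario{self.id}")


def default_scenarios() -> list[ScenarioSpec]:
    """The eight-scenario set: 1-4 without and 5-8 with a bottleneck."""
    combos = [(False, False), (True, False), (False, True), (True, True)]
    out = []
    for g, base in ((1, 0), (2, 4)):
        for i, (ta, tc) in enumerate(combos):
            out.append(
                ScenarioSpec(
                    id=base + i + 1,
                    group=g,
                    change_at_ta=ta,
                    change_at_tc=tc,
                    description=(
                        ("bottleneck" if g == 2 else "no bottleneck")
                        + f", change@ta={ta}, change@tc={tc}"
                    ),
                )
            )
    return out


def draw_prior(scenario: ScenarioSpec, seed=None, max_tries: int = 100_000) -> dict:
    """Uniform prior draw, rejection-sampled until t0 < ta < tb < tc < td.

    All bounds are inclusive; sizes and times are integers.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_tries):
        draw = {
            k: int(rng.integers(lo, hi + 1)) for k, (lo, hi) in PRIOR_BOUNDS.items()
        }
        ts = [draw[k] for k in TIME_ORDER]
        if all(a < b for a, b in zip(ts, ts[1:])):
            return draw
    raise InvadepopError("prior rejection sampling did not terminate")  # pragma: no cover


def scheme_from_draw(
    draw: dict, n_historical: int = 8, n_contemporary: int = 195
) -> SamplingScheme:
    return two_era_scheme(n_historical, n_contemporary, draw["t0"], draw["tb"])


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _era_summaries(g: GenotypeMatrix) -> list[float]:
    if g.n_loci == 0:
        return [0.0] * 8
    maf = g.maf()
    mono = float(np.mean(maf == 0))
    t = ho_hs_fis(g)
    ho = t.per_locus["Ho"].to_numpy()
    hs = t.per_locus["Hs"].to_numpy()
    out = [
        mono,
        float(np.mean(maf)),
        float(np.var(maf)),
        float(np.mean(ho)),
        float(np.var(ho)),
        float(np.mean(hs)),
        float(np.var(hs)),
        t.mean_fis,
    ]
    # Fis can be undefined on degenerate draws (every locus Hs = 0);
    # summaries must stay complete for the forests
    return [v if np.isfinite(v) else 0.0 for v in out]


_ERA_NAMES = ["prop_mono", "maf_mean", "maf_var", "ho_mean", "ho_var",
              "hs_mean", "hs_var", "fis_mean"]


def summary_names() -> list[str]:
    names = []
    for scope in ("pooled", "contemporary", "historical"):
        names += [f"{scope}_{n}" for n in _ERA_NAMES]
    names += ["fst_wc", "nei_d", "mean_abs_dp"]
    names += [f"maf_decile_q{10 * i}" for i in range(1, 10)]
    return names


def summarize(dataset: SimulatedDataset) -> np.ndarray:
    """Reduce a two-era SNP dataset to the fixed 36-value summary vector.

    Per era and pooled: proportion monomorphic, mean/var MAF, mean/var
    Ho, mean/var Hs, mean Fis.  Between eras: Weir-Cockerham Fst, Nei's
    standard distance, mean absolute allele-frequency difference.
    Plus the pooled MAF deciles.  Order fixed by :func:`summary_names`.
    """
    g = dataset.genotypes
    era = dataset.metadata["era"].to_numpy()
    labels = set(era)
    if not {"contemporary", "historical"} <= labels:
        raise InvadepopError("summaries need both a contemporary and a historical era")
    idx_c = np.flatnonzero(era == "contemporary")
    idx_h = np.flatnonzero(era == "historical")
    g_c = g.take_samples(idx_c)
    g_h = g.take_samples(idx_h)
    out = _era_summaries(g) + _era_summaries(g_c) + _era_summaries(g_h)

    # between-era differentiation
    try:
        fst = weir_cockerham_fst(g, era, n_bootstrap=0)["theta"]
    except InvadepopError:
        fst = 0.0
    p_c = g_c.alt_freq()
    p_h = g_h.alt_freq()
    ok = np.isfinite(p_c) & np.isfinite(p_h)
    p_c, p_h = p_c[ok], p_h[ok]
    num = np.sum(p_c * p_h + (1 - p_c) * (1 - p_h))
    den = np.sqrt(
        np.sum(p_c**2 + (1 - p_c) ** 2) * np.sum(p_h**2 + (1 - p_h) ** 2)
    )
    nei_d = float(-np.log(num / den)) if den > 0 and num > 0 else 0.0
    out += [float(fst), nei_d, float(np.mean(np.abs(p_c - p_h)))]
    out += list(np.quantile(g.maf(), np.arange(1, 10) / 10.0))
    vec = np.asarray(out, dtype=float)
    return np.where(np.isfinite(vec), vec, 0.0)


# ---------------------------------------------------------------------------
# Reference table
# ---------------------------------------------------------------------------

@dataclass
class ReferenceTable:
    """Simulated summaries labelled by scenario and parameters."""

    summaries: np.ndarray          # n_rows x n_summaries
    scenario_ids: np.ndarray       # n_rows
    groups: np.ndarray             # n_rows
    params: pd.DataFrame           # n_rows x prior parameters
    names: list[str] = field(default_factory=summary_names)
    design: dict = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return len(self.scenario_ids)

    def restrict(self, scenario_id: int) -> "ReferenceTable":
        keep = self.scenario_ids == scenario_id
        return ReferenceTable(
            self.summaries[keep],
            self.scenario_ids[keep],
            self.groups[keep],
            self.params.loc[keep].reset_index(drop=True),
            list(self.names),
            dict(self.design),
        )


def simulate_draw(
    scenario: ScenarioSpec,
    draw: dict,
    n_loci: int,
    rng,
    n_historical: int = 8,
    n_contemporary: int = 195,
) -> SimulatedDataset:
    dem = scenario.demography(draw)
    scheme = scheme_from_draw(draw, n_historical, n_contemporary)
    ds = simulate_snp_dataset(dem, scheme, n_loci, rng)
    ds.true_params = dict(draw, scenario=scenario.id, group=scenario.group)
    return ds


def build_reference_table(
    scenarios: list[ScenarioSpec] | None = None,
    n_per_scenario: int = 500,
    n_loci: int = 300,
    n_historical: int = 8,
    n_contemporary: int = 195,
    seed=None,
) -> ReferenceTable:
    """Simulate the training set: per scenario, ``n_per_scenario``
    (draw -> simulate -> summarize) rows.

    The desk-scale default (500/scenario, 300 loci) keeps a laptop run
    in minutes; the study-scale design is 5000/scenario at 1898 loci.
    Seeded per (scenario, replicate), so tables are reproducible.
    """
    scenarios = scenarios if scenarios is not None else default_scenarios()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows, sids, grps, draws = [], [], [], []
    for sc in scenarios:
        for _ in range(n_per_scenario):
            draw = draw_prior(sc, rng)
            ds = simulate_draw(sc, draw, n_loci, rng, n_historical, n_contemporary)
            rows.append(summarize(ds))
            sids.append(sc.id)
            grps.append(sc.group)
            draws.append(draw)
    return ReferenceTable(
        np.asarray(rows),
        np.asarray(sids),
        np.asarray(grps),
        pd.DataFrame(draws),
        summary_names(),
        {
            "n_per_scenario": n_per_scenario,
            "n_loci": n_loci,
            "n_historical": n_historical,
            "n_contemporary": n_contemporary,
        },
    )


# ---------------------------------------------------------------------------
# Scenario choice and parameter estimation
# ---------------------------------------------------------------------------

@dataclass
class ScenarioChoiceResult:
    votes: dict
    selected: int | str
    posterior_probability: float
    prior_error_rate: float
    lda_projection: np.ndarray
    lda_labels: np.ndarray
    lda_observed: np.ndarray
    n_trees: int


def scenario_choice(
    ref: ReferenceTable,
    observed_summary: np.ndarray,
    level: str = "group",
    n_trees: int = 1000,
    seed=None,
) -> ScenarioChoiceResult:
    """Random-forest scenario choice with prior error rate and
    posterior probability.

    ``level`` chooses the target: "group" (bottleneck vs not) or
    "scenario" (the eight ids).  The prior error rate is the forest's
    out-of-bag misclassification over the prior; the posterior
    probability of the selected class is a regression forest trained on
    out-of-bag correctness (Pudlo et al. style) evaluated at the
    observed summary.  A linear-discriminant projection of the reference
    rows and the observed point is returned for overlap inspection.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

    if ref.n_rows == 0:
        raise InvadepopError("empty reference table")
    y = ref.groups if level == "group" else ref.scenario_ids
    if len(np.unique(y)) < 2:
        raise InvadepopError("reference table holds a single class")
    rs = int(np.random.default_rng(seed).integers(2**31 - 1)) if not isinstance(seed, int) else seed
    x = ref.summaries
    obs = np.asarray(observed_summary, dtype=float).reshape(1, -1)
    if obs.shape[1] != x.shape[1]:
        raise InvadepopError("observed summary length mismatch")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=rs,
        n_jobs=1,
    )
    clf.fit(x, y)
    # per-tree votes: sub-estimators predict encoded class indices
    votes_arr = np.zeros(len(clf.classes_), dtype=int)
    for tree in clf.estimators_:
        votes_arr[int(tree.predict(obs)[0])] += 1
    selected = clf.classes_[votes_arr.argmax()]
    prior_error = 1.0 - clf.oob_score_
    # posterior probability: regression forest on OOB correctness
    oob_pred = clf.classes_[np.argmax(clf.oob_decision_function_, axis=1)]
    ok_rows = ~np.isnan(clf.oob_decision_function_).any(axis=1)
    correct = (oob_pred == y).astype(float)
    reg = RandomForestRegressor(
        n_estimators=max(n_trees // 2, 100), random_state=rs + 1, n_jobs=1
    )
    reg.fit(x[ok_rows], correct[ok_rows])
    posterior = float(np.clip(reg.predict(obs)[0], 0.0, 1.0))
    lda = LinearDiscriminantAnalysis()
    proj = lda.fit_transform(x, y)
    proj_obs = lda.transform(obs)
    return ScenarioChoiceResult(
        votes={int(c): int(v) for c, v in zip(clf.classes_, votes_arr)},
        selected=int(selected),
        posterior_probability=posterior,
        prior_error_rate=float(prior_error),
        lda_projection=proj,
        lda_labels=np.asarray(y),
        lda_observed=proj_obs,
        n_trees=n_trees,
    )


@dataclass
class ParamEstimate:
    parameter: str
    median: float
    q025: float
    q975: float
    nmae: float


def _qrf_weights(forest, x_train: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Meinshausen quantile-regression-forest weights of training rows
    for one query point."""
    w = np.zeros(len(x_train))
    leaves_train = forest.apply(x_train)          # n x n_trees
    leaves_obs = forest.apply(obs)[0]             # n_trees
    for t in range(leaves_train.shape[1]):
        same = leaves_train[:, t] == leaves_obs[t]
        n_same = same.sum()
        if n_same:
            w[same] += 1.0 / n_same
    return w / leaves_train.shape[1]


def _weighted_quantiles(y: np.ndarray, w: np.ndarray, qs) -> np.ndarray:
    order = np.argsort(y)
    y, w = y[order], w[order]
    cw = np.cumsum(w)
    cw /= cw[-1]
    return np.interp(qs, cw, y)


def estimate_parameters(
    ref: ReferenceTable,
    observed_summary: np.ndarray,
    params: list[str] = ("Nancestral", "Nbottleneck", "td"),
    n_trees: int = 1000,
    seed=None,
    min_rows: int = 500,
) -> list[ParamEstimate]:
    """Quantile-regression-forest parameter estimation on a one-scenario
    reference table: posterior median, [0.025, 0.975] interval, and the
    out-of-bag normalized mean absolute error per parameter."""
    from sklearn.ensemble import RandomForestRegressor

    if ref.n_rows < min_rows:
        raise InvadepopError(f"need >= {min_rows} rows for parameter estimation")
    rs = int(np.random.default_rng(seed).integers(2**31 - 1)) if not isinstance(seed, int) else seed
    x = ref.summaries
    obs = np.asarray(observed_summary, dtype=float).reshape(1, -1)
    out = []
    for k, name in enumerate(params):
        if name not in ref.params.columns:
            raise InvadepopError(f"parameter {name!r} absent from the prior draws")
        y = ref.params[name].to_numpy(dtype=float)
        reg = RandomForestRegressor(
            n_estimators=n_trees,
            max_features="sqrt",
            oob_score=True,
            random_state=rs + k,
            n_jobs=1,
        )
        reg.fit(x, y)
        if np.ptp(y) == 0:
            q025 = med = q975 = float(y[0])
        else:
            w = _qrf_weights(reg, x, obs)
            q025, med, q975 = _weighted_quantiles(y, w, [0.025, 0.5, 0.975])
        oob = reg.oob_prediction_
        ok = y != 0
        nmae = float(np.mean(np.abs(oob[ok] - y[ok]) / y[ok]))
        out.append(ParamEstimate(name, float(med), float(q025), float(q975), nmae))
    return out
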