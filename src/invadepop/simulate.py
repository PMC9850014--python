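"""Synthetic SNP data generators.

Two engines:

* a backwards-in-time serial-sampling coalescent with piecewise-constant
  diploid population size, producing unlinked single-SNP loci (one
  segregating site placed uniformly on the genealogy's total branch
  length — Hudson fixed-S with S=1, mimicking SNP ascertainment).  This
  is the training simulator for the demographic-inference module.
* a forward-in-time individual-based Wright-Fisher simulator (optionally
  a 1-D stepping-stone of demes) whose shared pedigree generates the
  drift LD among unlinked loci that linkage-disequilibrium Ne estimation
  measures, and isolation-by-distance for the spatial analyses.

Time is measured in generations throughout; conversion to years
(generation time 3 for the study species) is left to reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, InvadepopError, write_vcf

CONTEMPORARY_YEAR = 2018  # nominal sampling year for t=0
GENERATION_TIME_YEARS = 3


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Demography:
    """Piecewise-constant diploid population sizes, backwards in time.

    ``epochs`` is an ordered list of ``(start_generation, N)``: the first
    epoch must start at generation 0 and starts must strictly increase.
    """

    epochs: tuple[tuple[int, int], ...]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.epochs:
            raise InvadepopError("demography needs at least one epoch")
        prev = None
        for start, n in self.epochs:
            if int(start) != start or start < 0:
                raise InvadepopError("epoch start times must be integers >= 0")
            if int(n) != n or n < 2:
                raise InvadepopError(f"population size must be an integer >= 2, got {n}")
            if prev is None and start != 0:
                raise InvadepopError("first epoch must start at generation 0")
            if prev is not None and start <= prev:
                raise InvadepopError("epoch start times must strictly increase")
            prev = start

    def size_at(self, t: float) -> int:
        n = self.epochs[0][1]
        for start, size in self.epochs:
            if t >= start:
                n = size
            else:
                break
        return n

    def boundaries(self) -> list[float]:
        return [float(s) for s, _ in self.epochs if s > 0]


@dataclass(frozen=True)
class SamplingScheme:
    """Sampling events ``(time_backwards, n_diploids, era_label)``."""

    events: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        times = [t for t, _, _ in self.events]
        if len(set(times)) != len(times):
            raise InvadepopError("sampling times must be distinct")
        for t, n, _ in self.events:
            if t < 0 or n < 1:
                raise InvadepopError("invalid sampling event")
        if self.total_diploids < 2:
            raise InvadepopError("need at least 2 sampled diploids in total")

    @property
    def total_diploids(self) -> int:
        return sum(n for _, n, _ in self.events)

    def sorted_events(self) -> list[tuple[int, int, str]]:
        return sorted(self.events, key=lambda e: e[0])


def two_era_scheme(n_historical: int = 8, n_contemporary: int = 195,
                   t0: int = 0, tb: int = 5) -> SamplingScheme:
    """The study design: a large contemporary and a small historical sample."""
    return SamplingScheme(
        ((t0, n_contemporary, "contemporary"), (tb, n_historical, "historical"))
    )


@dataclass
class SimulatedDataset:
    """A simulated genotype matrix with its metadata and true parameters."""

    genotypes: GenotypeMatrix
    metadata: pd.DataFrame
    true_params: dict = field(default_factory=dict)
    paralog_mask: np.ndarray | None = None  # loci flagged as injected paralogs


@dataclass
class Genealogy:
    """A coalescent tree: node times and parent pointers.

    Nodes ``0 .. n_leaves-1`` are sampled lineages (two consecutive
    leaves per diploid, in sampling-event time order); internal nodes
    follow in coalescence order.  The root has parent -1.
    """

    times: np.ndarray
    parents: np.ndarray
    n_leaves: int

    def branch_lengths(self) -> np.ndarray:
        bl = np.zeros(len(self.times))
        has_parent = self.parents >= 0
        bl[has_parent] = self.times[self.parents[has_parent]] - self.times[has_parent]
        return bl

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tmrca(self) -> float:
        return float(self.times[-1])

    def leaves_under(self, node: int) -> np.ndarray:
        """Leaf ids in the subtree rooted at ``node`` (iterative DFS)."""
        children: list[list[int]] = [[] for _ in range(len(self.parents))]
        for i, p in enumerate(self.parents):
            if p >= 0:
                children[p].append(i)
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                out.append(v)
            else:
                stack.extend(children[v])
        return np.asarray(out, dtype=np.int64)


# ---------------------------------------------------------------------------
# Serial-sampling coalescent
# ---------------------------------------------------------------------------

def simulate_locus_genealogy(
    demography: Demography, scheme: SamplingScheme, seed=None
) -> Genealogy:
    """Simulate one n-coalescent genealogy under the demography.

    Among k active lineages the coalescence rate is k(k-1)/(4N(t));
    lineages sampled at time t enter the process only at t.  Rates are
    piecewise constant between epoch boundaries and sampling events.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    events = scheme.sorted_events()
    n_leaves = 2 * scheme.total_diploids
    max_nodes = 2 * n_leaves - 1
    times = np.zeros(max_nodes)
    parents = np.full(max_nodes, -1, dtype=np.int64)

    # assign leaf ids in event order
    leaf_start = 0
    pending: list[tuple[float, list[int]]] = []
    for t_s, n_dip, _era in events:
        ids = list(range(leaf_start, leaf_start + 2 * n_dip))
        times[ids] = t_s
        pending.append((float(t_s), ids))
        leaf_start += 2 * n_dip

    boundaries = demography.boundaries()
    active: list[int] = []
    next_node = n_leaves
    t = 0.0
    pi = 0  # pending sampling event index
    # start at the first sampling time
    if pending:
        t = pending[0][0]
    while True:
        while pi < len(pending) and pending[pi][0] <= t:
            active.extend(pending[pi][1])
            pi += 1
        k = len(active)
        next_sample = pending[pi][0] if pi < len(pending) else np.inf
        next_epoch = np.inf
        for b in boundaries:
            if b > t:
                next_epoch = b
                break
        horizon = min(next_sample, next_epoch)
        if k < 2:
            if np.isinf(horizon):
                break
            t = horizon
            continue
        n_now = demography.size_at(t)
        rate = k * (k - 1) / (4.0 * n_now)
        dt = rng.exponential(1.0 / rate)
        if t + dt >= horizon:
            t = horizon
            continue
        t += dt
        i = int(rng.integers(k))
        j = int(rng.integers(k - 1))
        if j >= i:
            j += 1
        a, b_ = active[i], active[j]
        times[next_node] = t
        parents[a] = next_node
        parents[b_] = next_node
        # swap-remove the two coalesced lineages, append the parent
        for victim in sorted((i, j), reverse=True):
            active[victim] = active[-1]
            active.pop()
        active.append(next_node)
        next_node += 1
        if next_node == max_nodes:
            break
    return Genealogy(times[:next_node], parents[:next_node], n_leaves)


def _simulate_codes_vectorized(
    demography: Demography,
    scheme: SamplingScheme,
    n_loci: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate genotype codes for ``n_loci`` independent loci in lockstep.

    Identical model to :func:`simulate_locus_genealogy` +
    single-mutation placement, but all loci advance together through
    vectorized coalescence steps — the fast path behind
    :func:`simulate_snp_dataset`.
    """
    events = scheme.sorted_events()
    n_dip = scheme.total_diploids
    n_leaves = 2 * n_dip
    n_nodes = 2 * n_leaves - 1
    L = n_loci
    rows = np.arange(L)

    parents = np.full((L, n_nodes), -1, dtype=np.int32)
    times = np.zeros((L, n_nodes))
    active = np.zeros((L, n_leaves), dtype=np.int32)
    k = np.zeros(L, dtype=np.int64)
    nxt = np.full(L, n_leaves, dtype=np.int64)

    # leaf ids in event order; leaf sampling times
    leaf_blocks = []
    start = 0
    for t_s, nd, _ in events:
        ids = np.arange(start, start + 2 * nd, dtype=np.int32)
        leaf_blocks.append((float(t_s), ids))
        times[:, ids] = t_s
        start += 2 * nd

    checkpoints = sorted(
        {t for t, _ in leaf_blocks[1:]} | set(demography.boundaries())
    )
    t0 = leaf_blocks[0][0]
    t = np.full(L, t0)
    ids0 = leaf_blocks[0][1]
    active[:, : len(ids0)] = ids0
    k[:] = len(ids0)
    entered = 1

    windows = [t0] + [c for c in checkpoints if c > t0] + [np.inf]
    for wi in range(len(windows) - 1):
        w_start, w_end = windows[wi], windows[wi + 1]
        # lineages entering at this window start
        while entered < len(leaf_blocks) and leaf_blocks[entered][0] <= w_start:
            ids = leaf_blocks[entered][1]
            m = len(ids)
            pos = k[:, None] + np.arange(m)[None, :]
            active[rows[:, None], pos] = ids[None, :]
            k += m
            entered += 1
        t = np.maximum(t, w_start)
        n_now = demography.size_at(w_start)
        while True:
            alive = (k >= 2) & (t < w_end)
            if not alive.any():
                break
            rate = k * (k - 1) / (4.0 * n_now)
            dt = np.full(L, np.inf)
            a_idx = np.flatnonzero(alive)
            dt[a_idx] = rng.exponential(1.0, a_idx.size) / rate[a_idx]
            t_new = t + dt
            acc = alive & (t_new < w_end)
            # clamp the rest to the window end (memoryless restart there)
            t = np.where(alive & ~acc, w_end, t)
            r = np.flatnonzero(acc)
            if r.size == 0:
                continue
            t[r] = t_new[r]
            kk = k[r]
            i = (rng.random(r.size) * kk).astype(np.int64)
            j = (rng.random(r.size) * (kk - 1)).astype(np.int64)
            j = j + (j >= i)
            lo = np.minimum(i, j)
            hi = np.maximum(i, j)
            a = active[r, lo]
            b = active[r, hi]
            node = nxt[r]
            times[r, node] = t[r]
            parents[r, a] = node
            parents[r, b] = node
            active[r, lo] = node.astype(np.int32)
            active[r, hi] = active[r, kk - 1]
            k[r] = kk - 1
            nxt[r] += 1

    # place one mutation per locus, uniformly on total branch length
    par_safe = np.maximum(parents, 0)
    parent_times = np.take_along_axis(times, par_safe, axis=1)
    bl = np.where(parents >= 0, parent_times - times, 0.0)
    cum = np.cumsum(bl, axis=1)
    tot = cum[:, -1]
    if np.any(tot <= 0):
        raise InvadepopError("degenerate genealogy with zero branch length")
    u = rng.random(L) * tot
    chosen = (cum < u[:, None]).sum(axis=1)

    # propagate the derived state down to the leaves (parents always have
    # a higher node index than their children)
    mark = np.zeros((L, n_nodes), dtype=bool)
    mark[rows, chosen] = True
    for col in range(n_nodes - 2, -1, -1):
        pcol = parents[:, col]
        valid = pcol >= 0
        mark[:, col] |= valid & mark[rows, np.maximum(pcol, 0)]
    derived = mark[:, :n_leaves]
    geno = derived[:, 0::2].astype(np.int16) + derived[:, 1::2].astype(np.int16)
    return geno.T  # individuals x loci


def _numba_kernel():
    """Build (once) the compiled per-locus coalescent kernel, or None."""
    global _KERNEL
    if _KERNEL is not None:
        return _KERNEL
    try:
        from numba import njit
    except Exception:  # pragma: no cover - numba is expected to be present
        _KERNEL = False
        return False

    @njit(cache=True)
    def kernel(epoch_starts, epoch_sizes, leaf_times_sorted, n_loci, seed):
        np.random.seed(seed)
        n_leaves = leaf_times_sorted.shape[0]
        n_nodes = 2 * n_leaves - 1
        n_dip = n_leaves // 2
        out = np.zeros((n_loci, n_dip), np.int16)
        times = np.zeros(n_nodes)
        parents = np.empty(n_nodes, np.int64)
        active = np.empty(n_leaves, np.int64)
        mark = np.zeros(n_nodes, np.bool_)
        bl = np.zeros(n_nodes)
        n_epochs = epoch_starts.shape[0]
        for l in range(n_loci):
            for v in range(n_nodes):
                parents[v] = -1
                mark[v] = False
            for v in range(n_leaves):
                times[v] = leaf_times_sorted[v]
            t = leaf_times_sorted[0]
            k = 0
            pi = 0  # next leaf to enter
            while pi < n_leaves and leaf_times_sorted[pi] <= t:
                active[k] = pi
                k += 1
                pi += 1
            ei = 0  # current epoch
            while ei + 1 < n_epochs and epoch_starts[ei + 1] <= t:
                ei += 1
            nxt = n_leaves
            while nxt < n_nodes:
                horizon = np.inf
                if pi < n_leaves:
                    horizon = leaf_times_sorted[pi]
                if ei + 1 < n_epochs and epoch_starts[ei + 1] < horizon:
                    horizon = epoch_starts[ei + 1]
                if k < 2:
                    t = horizon
                else:
                    rate = k * (k - 1) / (4.0 * epoch_sizes[ei])
                    dt = np.random.exponential(1.0 / rate)
                    if t + dt >= horizon:
                        t = horizon
                    else:
                        t = t + dt
                        i = int(np.random.random() * k)
                        j = int(np.random.random() * (k - 1))
                        if j >= i:
                            j += 1
                        a = active[i]
                        b = active[j]
                        times[nxt] = t
                        parents[a] = nxt
                        parents[b] = nxt
                        lo = i if i < j else j
                        hi = j if i < j else i
                        active[lo] = nxt
                        active[hi] = active[k - 1]
                        k -= 1
                        nxt += 1
                        continue
                # advance past the horizon: admit leaves / epochs
                while pi < n_leaves and leaf_times_sorted[pi] <= t:
                    active[k] = pi
                    k += 1
                    pi += 1
                while ei + 1 < n_epochs and epoch_starts[ei + 1] <= t:
                    ei += 1
            # mutation placement proportional to branch length
            tot = 0.0
            for v in range(n_nodes - 1):
                bl[v] = times[parents[v]] - times[v] if parents[v] >= 0 else 0.0
                tot += bl[v]
            bl[n_nodes - 1] = 0.0
            u = np.random.random() * tot
            acc = 0.0
            chosen = 0
            for v in range(n_nodes - 1):
                acc += bl[v]
                if u < acc:
                    chosen = v
                    break
            mark[chosen] = True
            for v in range(n_nodes - 2, -1, -1):
                p = parents[v]
                if p >= 0 and mark[p]:
                    mark[v] = True
            for d in range(n_dip):
                out[l, d] = np.int16(mark[2 * d]) + np.int16(mark[2 * d + 1])
        return out

    _KERNEL = kernel
    return kernel


_KERNEL = None


def _simulate_codes(
    demography: Demography,
    scheme: SamplingScheme,
    n_loci: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Genotype codes (individuals x loci), compiled kernel when available."""
    kernel = _numba_kernel()
    if kernel is False:
        return _simulate_codes_vectorized(demography, scheme, n_loci, rng)
    events = scheme.sorted_events()
    leaf_times = np.concatenate(
        [np.full(2 * nd, float(ts)) for ts, nd, _ in events]
    )
    epoch_starts = np.array([float(s) for s, _ in demography.epochs])
    epoch_sizes = np.array([float(n) for _, n in demography.epochs])
    seed = int(rng.integers(2**31 - 1))
    codes = kernel(epoch_starts, epoch_sizes, leaf_times, n_loci, seed)
    return codes.T


def _metadata_for_scheme(scheme: SamplingScheme) -> pd.DataFrame:
    rows = []
    i = 0
    for t_s, n_dip, era in scheme.sorted_events():
        for _ in range(n_dip):
            rows.append(
                {
                    "sample_id": f"ind{i:04d}",
                    "era": era,
                    "year": CONTEMPORARY_YEAR - GENERATION_TIME_YEARS * int(t_s),
                    "river_km": 0.0,
                    "direction": "north",
                    "distance_from_origin": 0.0,
                }
            )
            i += 1
    return pd.DataFrame(rows)


def simulate_snp_dataset(
    demography: Demography,
    scheme: SamplingScheme,
    n_loci: int,
    seed=None,
    max_redraws: int = 100,
) -> SimulatedDataset:
    """Simulate unlinked single-SNP loci under the demography.

    One mutation per locus is placed on a branch chosen with probability
    proportional to branch length; lineages below it carry the derived
    allele.  Diploid genotypes pair consecutive lineages of one
    individual.  Loci monomorphic after genotyping are redrawn (at most
    ``max_redraws`` attempts each).
    """
    if n_loci < 0:
        raise InvadepopError("n_loci must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_dip = scheme.total_diploids
    if n_loci == 0:
        codes = np.zeros((n_dip, 0), dtype=np.int16)
    else:
        codes = _simulate_codes(demography, scheme, n_loci, rng)
        # a mutation subtends a proper, non-empty subset of lineages, so
        # loci are allele-polymorphic by construction; redraw only the
        # pathological all-identical-genotype columns (e.g. all-het)
        for _ in range(max_redraws):
            bad = np.flatnonzero(codes.min(axis=0) == codes.max(axis=0))
            if bad.size == 0:
                break
            codes[:, bad] = _simulate_codes(demography, scheme, bad.size, rng)
        else:
            raise InvadepopError(
                f"ascertainment failure: monomorphic loci persist after "
                f"{max_redraws} redraws"
            )
    meta = _metadata_for_scheme(scheme)
    g = GenotypeMatrix(
        codes, list(meta["sample_id"]), [f"loc{j}:1" for j in range(n_loci)]
    )
    return SimulatedDataset(
        g, meta, {"demography": demography.label or "custom", "scheme": scheme}
    )


# ---------------------------------------------------------------------------
# Forward Wright-Fisher (single population and 1-D stepping-stone)
# ---------------------------------------------------------------------------

def _founder_freqs(n_loci: int, rng: np.random.Generator, sfs_like: bool) -> np.ndarray:
    if sfs_like:
        # heavy at the rare end, roughly neutral-SFS shaped
        p = rng.beta(0.4, 0.4, n_loci)
        return np.clip(p, 0.01, 0.99)
    return rng.uniform(0.05, 0.95, n_loci)


def _wf_forward(
    deme_sizes: np.ndarray,
    n_loci: int,
    generations,
    migration_rate: float,
    rng: np.random.Generator,
    sfs_like_founders: bool = False,
):
    """Individual-based diploid WF forward simulation on a line of demes.

    ``generations`` may be an int or, for a single deme, a sequence of
    per-generation diploid sizes (most recent last) enabling size-change
    scenarios.  Random mating (selfing allowed) within demes; each
    gamete's parent is drawn from an adjacent deme with probability
    migration_rate/2 per side (reflecting at the ends).  Returns the two
    allele matrices (individuals x loci) and the deme index per row.
    """
    n_demes = len(deme_sizes)
    size_schedule = None
    if not np.isscalar(generations):
        if n_demes != 1:
            raise InvadepopError("size schedules supported for a single deme only")
        size_schedule = [int(s) for s in generations]
        n_gen = len(size_schedule)
    else:
        n_gen = int(generations)

    deme_of = np.repeat(np.arange(n_demes), deme_sizes)
    starts = np.concatenate([[0], np.cumsum(deme_sizes)])
    p0 = _founder_freqs(n_loci, rng, sfs_like_founders)
    n_total = int(deme_sizes.sum())
    a1 = (rng.random((n_total, n_loci)) < p0).astype(np.uint8)
    a2 = (rng.random((n_total, n_loci)) < p0).astype(np.uint8)

    for gen in range(n_gen):
        if size_schedule is not None:
            new_sizes = np.array([size_schedule[gen]])
        else:
            new_sizes = np.asarray(deme_sizes)
        new_total = int(new_sizes.sum())
        new_deme = np.repeat(np.arange(n_demes), new_sizes)
        gam = []
        for _ in range(2):
            src = new_deme.copy()
            if n_demes > 1 and migration_rate > 0:
                u = rng.random(new_total)
                left = u < migration_rate / 2
                right = (u >= migration_rate / 2) & (u < migration_rate)
                src = src - left.astype(int) + right.astype(int)
                np.clip(src, 0, n_demes - 1, out=src)
            counts = deme_sizes[src]
            parent = starts[src] + rng.integers(0, counts)
            mask = rng.integers(0, 2, (new_total, n_loci), dtype=np.uint8).astype(bool)
            gam.append(np.where(mask, a1[parent], a2[parent]))
        a1, a2 = gam
        deme_sizes = new_sizes
        deme_of = new_deme
        starts = np.concatenate([[0], np.cumsum(deme_sizes)])
    return a1, a2, deme_of


def simulate_isolated_population(
    n_diploids: int,
    n_loci: int,
    sample_size: int,
    generations=20,
    seed=None,
    min_maf: float = 0.0,
    sfs_like_founders: bool = False,
) -> SimulatedDataset:
    """A single random-mating WF population sampled in the last generation.

    The shared pedigree of the final generations generates drift LD
    among the unlinked loci, so LD-based Ne estimates target
    ``n_diploids`` (or the recent sizes of a ``generations`` schedule).
    Monomorphic loci (and loci below ``min_maf`` in the sample) are
    replaced by resimulation so the dataset is fully ascertained.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    final_size = n_diploids if np.isscalar(generations) else int(list(generations)[-1])
    if sample_size > final_size:
        raise InvadepopError("sample_size exceeds population size")
    # all loci must come from ONE population realization: the shared
    # pedigree is what generates the drift LD among unlinked loci
    codes = None
    factor = 1.5
    for _ in range(6):
        a1, a2, _ = _wf_forward(
            np.array([n_diploids]), int(n_loci * factor) + 16, generations,
            0.0, rng, sfs_like_founders,
        )
        geno = (a1 + a2).astype(np.int16)
        pick = rng.permutation(geno.shape[0])[:sample_size]
        geno = geno[pick]
        p = geno.mean(axis=0) / 2.0
        maf = np.minimum(p, 1 - p)
        keep = (p > 0) & (p < 1) if min_maf == 0.0 else maf > min_maf
        if keep.sum() >= n_loci:
            codes = geno[:, keep][:, :n_loci]
            break
        factor *= 2
    if codes is None:
        raise InvadepopError("could not ascertain the requested number of loci")
    meta = pd.DataFrame(
        {
            "sample_id": [f"ind{i:04d}" for i in range(sample_size)],
            "era": "contemporary",
            "year": CONTEMPORARY_YEAR,
            "river_km": 0.0,
            "direction": "north",
            "distance_from_origin": 0.0,
        }
    )
    g = GenotypeMatrix(
        codes, list(meta["sample_id"]), [f"loc{j}:1" for j in range(n_loci)]
    )
    return SimulatedDataset(g, meta, {"n_diploids": n_diploids, "generations": generations})


def simulate_river_population(
    n_demes: int,
    deme_size: int,
    migration_rate: float,
    generations: int,
    n_loci: int,
    samples_per_deme: int,
    deme_spacing_km: float = 20.0,
    seed=None,
    origin_km: float | None = None,
) -> SimulatedDataset:
    """1-D stepping-stone WF population along a river.

    All demes descend from a common founder pool; with small
    ``migration_rate`` the deme structure produces positive spatial
    autocorrelation of genotypes that decays with river distance
    (isolation by distance).  River coordinate = deme index x spacing.
    """
    if not 0.0 <= migration_rate <= 0.5:
        raise InvadepopError("migration_rate must be in [0, 0.5]")
    if min(n_demes, deme_size, generations, n_loci, samples_per_deme) < 1:
        raise InvadepopError("all stepping-stone parameters must be positive")
    if samples_per_deme > deme_size:
        raise InvadepopError("samples_per_deme exceeds deme_size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    deme_sizes = np.full(n_demes, deme_size, dtype=int)
    # one forward realization for all loci (consistent spatial history)
    codes = None
    deme_of_sample = None
    factor = 1.4
    for _ in range(6):
        a1, a2, deme_of = _wf_forward(
            deme_sizes, int(n_loci * factor) + 8, generations, migration_rate, rng
        )
        geno = (a1 + a2).astype(np.int16)
        rows = []
        for d in range(n_demes):
            members = np.flatnonzero(deme_of == d)
            rows.extend(members[:samples_per_deme])
        rows = np.asarray(rows)
        geno = geno[rows]
        p = geno.mean(axis=0) / 2.0
        keep = (p > 0) & (p < 1)
        if keep.sum() >= n_loci:
            deme_of_sample = deme_of[rows]
            codes = geno[:, keep][:, :n_loci]
            break
        factor *= 2
    if codes is None:
        raise InvadepopError("could not ascertain the requested number of loci")
    n_samples = codes.shape[0]
    river_km = deme_of_sample * deme_spacing_km
    if origin_km is None:
        origin_km = (n_demes - 1) / 2.0 * deme_spacing_km
    meta = pd.DataFrame(
        {
            "sample_id": [f"ind{i:04d}" for i in range(n_samples)],
            "era": "contemporary",
            "year": CONTEMPORARY_YEAR,
            "river_km": river_km.astype(float),
            "direction": np.where(river_km >= origin_km, "north", "south"),
            "distance_from_origin": np.abs(river_km - origin_km).astype(float),
        }
    )
    g = GenotypeMatrix(
        codes, list(meta["sample_id"]), [f"loc{j}:1" for j in range(n_loci)]
    )
    return SimulatedDataset(
        g,
        meta,
        {
            "n_demes": n_demes,
            "deme_size": deme_size,
            "migration_rate": migration_rate,
            "generations": generations,
            "deme_spacing_km": deme_spacing_km,
        },
    )


# ---------------------------------------------------------------------------
# Paralog injection and fixture writing
# ---------------------------------------------------------------------------

def inject_paralogs(
    dataset: SimulatedDataset, n_paralogs: int, seed=None
) -> SimulatedDataset:
    """Append loci imitating collapsed paralogs (RAD over-merged duplicates).

    Paralog loci show excess apparent heterozygosity, and
    :func:`write_fixture` biases their heterozygote read balance to 0.65
    so HDplot's H and D both separate them from true SNPs.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g = dataset.genotypes
    n = g.n_samples
    cols = np.zeros((n, n_paralogs), dtype=np.int16)
    for j in range(n_paralogs):
        h = rng.uniform(0.55, 0.80)
        p_hom_alt = rng.uniform(0.1, 0.4)
        u = rng.random(n)
        cols[:, j] = np.where(u < h, 1, np.where(u < h + p_hom_alt, 2, 0))
    codes = np.concatenate([g.codes, cols], axis=1)
    locus_ids = list(g.locus_ids) + [f"par{j}:1" for j in range(n_paralogs)]
    mask = np.zeros(codes.shape[1], dtype=bool)
    mask[g.n_loci:] = True
    new_g = GenotypeMatrix(codes, list(g.sample_ids), locus_ids)
    return SimulatedDataset(new_g, dataset.metadata.copy(), dict(dataset.true_params), mask)


def synthesize_depths(
    g: GenotypeMatrix,
    seed=None,
    mean_depth: float = 100.0,
    paralog_mask: np.ndarray | None = None,
    paralog_ref_share: float = 0.65,
) -> GenotypeMatrix:
    """Attach synthetic read depths (total ~ negative binomial around
    ``mean_depth``; heterozygote ref share binomial 0.5, or 0.65 for
    flagged paralog loci)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = g.codes.shape
    size_param = 1000.0  # near-Poisson: SD ~ 10 at mean 100, as in RAD data
    total = rng.negative_binomial(size_param, size_param / (size_param + mean_depth), shape)
    total = np.maximum(total, 1)
    ref = np.zeros(shape, dtype=np.int32)
    alt = np.zeros(shape, dtype=np.int32)
    hom_ref = g.codes == 0
    hom_alt = g.codes == 2
    het = g.codes == 1
    ref[hom_ref] = total[hom_ref]
    alt[hom_alt] = total[hom_alt]
    share = np.full(shape[1], 0.5)
    if paralog_mask is not None:
        share[paralog_mask] = paralog_ref_share
    share2 = np.broadcast_to(share, shape)
    ref_het = rng.binomial(total[het], share2[het])
    ref[het] = ref_het
    alt[het] = total[het] - ref_het
    miss = g.missing
    ref[miss] = 0
    alt[miss] = 0
    out = g.copy()
    out.ref_depth = ref
    out.alt_depth = alt
    return out


def distance_matrix_from_metadata(meta: pd.DataFrame) -> pd.DataFrame:
    x = meta["river_km"].to_numpy(dtype=float)
    d = np.abs(x[:, None] - x[None, :])
    ids = list(meta["sample_id"])
    return pd.DataFrame(d, index=ids, columns=ids)


def write_fixture(
    dataset: SimulatedDataset,
    directory,
    seed=None,
    mean_depth: float = 100.0,
) -> dict:
    """Write VCF (+synthetic AD), metadata TSV and distance-matrix TSV.

    Genotype codes round-trip exactly through ``genotype_io.read_vcf``.
    Returns the paths written.
    """
    from pathlib import Path

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    g = synthesize_depths(
        dataset.genotypes, rng, mean_depth, dataset.paralog_mask
    )
    vcf_path = directory / "genotypes.vcf"
    write_vcf(g, str(vcf_path))
    meta_path = directory / "metadata.tsv"
    dataset.metadata.to_csv(meta_path, sep="\t", index=False)
    dist_path = directory / "distances.tsv"
    distance_matrix_from_metadata(dataset.metadata).to_csv(dist_path, sep="\t")
    return {"vcf": str(vcf_path), "metadata": str(meta_path), "distances": str(dist_path)}
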