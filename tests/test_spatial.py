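"""Spatial analyses: distances, nMDS, sPCA, MEM, correlogram,
neighbourhood diversity and decay regressions."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import invadepop as ip
from invadepop.genotype_io import InvadepopError
from invadepop.simulate import distance_matrix_from_metadata
from invadepop.spatial import min_distance_neighbour_graph
from conftest import hwe_matrix


@pytest.fixture(scope="module")
def river(river_dataset):
    ds = river_dataset
    d = distance_matrix_from_metadata(ds.metadata)
    gd = ip.proportion_shared_allele_distance(ds.genotypes)
    return ds, d, gd


class TestDistances:
    def test_collinear_points(self, tmp_path):
        ids = ["a", "b", "c"]
        m = np.array([[0, 10, 20], [10, 0, 10], [20, 10, 0]], dtype=float)
        pd.DataFrame(m, index=ids, columns=ids).to_csv(
            tmp_path / "d.tsv", sep="\t"
        )
        d = ip.load_distances(str(tmp_path / "d.tsv"))
        assert d.loc["a", "c"] == 20

    def test_mismatched_ids_rejected(self, tmp_path):
        ids = ["a", "b", "c"]
        m = np.zeros((3, 3))
        pd.DataFrame(m, index=ids, columns=ids).to_csv(tmp_path / "d.tsv", sep="\t")
        with pytest.raises(InvadepopError, match="missing"):
            ip.load_distances(str(tmp_path / "d.tsv"), sample_ids=["a", "zzz"])

    def test_asymmetry_rejected(self, tmp_path):
        ids = ["a", "b"]
        m = np.array([[0.0, 5.0], [9.0, 0.0]])
        pd.DataFrame(m, index=ids, columns=ids).to_csv(tmp_path / "d.tsv", sep="\t")
        with pytest.raises(InvadepopError, match="asymmetric"):
            ip.load_distances(str(tmp_path / "d.tsv"))

    def test_roundtrip_exact(self, river, tmp_path):
        _, d, _ = river
        d.to_csv(tmp_path / "d.tsv", sep="\t")
        back = ip.load_distances(str(tmp_path / "d.tsv"))
        assert np.allclose(back.to_numpy(), d.to_numpy())


class TestNmds:
    def test_euclidean_embeddable_low_stress(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(0, 100, (20, 2))
        dm = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        coords, stress = ip.nmds_project(dm, dims=2, seed=2)
        assert stress < 0.05

    def test_river_line_preserves_rank_order(self, river):
        _, d, _ = river
        coords, _ = ip.nmds_project(d, dims=2, seed=3)
        emb = np.sqrt(((coords[:, None] - coords[None, :]) ** 2).sum(-1))
        iu = np.triu_indices(len(coords), 1)
        rho = spearmanr(emb[iu], d.to_numpy()[iu]).statistic
        assert rho > 0.95

    def test_dims_ge_n_rejected(self):
        dm = np.zeros((3, 3))
        with pytest.raises(InvadepopError):
            ip.nmds_project(dm, dims=3)


class TestSpca:
    def test_null_type_one_error_calibrated(self):
        """Spatially shuffled genotypes: the global test rejects at
        about the nominal 5% rate."""
        rng = np.random.default_rng(4)
        coords = np.column_stack([np.arange(40) * 10.0, np.zeros(40)])
        hits = 0
        n_rep = 100
        for rep in range(n_rep):
            g = hwe_matrix(40, 80, seed=1000 + rep)
            res = ip.spca(g, coords, n_perm=99, seed=rep)
            hits += res.global_test.p_value <= 0.05
        # binomial(100, 0.05): 3 SE band
        assert hits <= 5 + 3 * np.sqrt(100 * 0.05 * 0.95)

    def test_ibd_fixture_recovered(self):
        """Stepping-stone fixture: significant global structure and a
        clinal first axis in >= 90% of replicates."""
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            ds = ip.simulate_river_population(
                8, 100, 0.01, 150, 120, 5, deme_spacing_km=20, seed=2000 + rep
            )
            coords = np.column_stack(
                [ds.metadata["river_km"].to_numpy(),
                 np.zeros(len(ds.metadata))]
            )
            # jitter to avoid coincident points in the graph
            rng = np.random.default_rng(rep)
            coords[:, 1] = rng.uniform(0, 1, len(coords))
            res = ip.spca(ds.genotypes, coords, n_perm=99, seed=rep)
            rho = abs(spearmanr(res.scores[:, 0],
                                ds.metadata["river_km"]).statistic)
            hits += (res.global_test.p_value <= 0.05) and (rho > 0.5)
        assert hits >= 0.9 * n_rep

    def test_duplicated_single_point_degenerate(self):
        g = hwe_matrix(10, 20, seed=5)
        coords = np.zeros((10, 2))
        with pytest.raises(InvadepopError):
            ip.spca(g, coords, n_perm=9, seed=6)

    def test_min_distance_graph_connected(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 100, (25, 2))
        dm = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        adj = min_distance_neighbour_graph(dm)
        import scipy.sparse.csgraph as csg

        n_comp, _ = csg.connected_components(adj)
        assert n_comp == 1


class TestMem:
    def test_shuffled_genotypes_near_zero_r2(self, river):
        ds, d, _ = river
        rng = np.random.default_rng(8)
        g = ds.genotypes.take_samples(rng.permutation(ds.genotypes.n_samples))
        res = ip.mem_forward_selection(g, d, n_perm=99, seed=9)
        assert res.r2_adj < 0.05

    def test_stepping_stone_recovers_broad_structure(self):
        """IBD fixture: positive adjusted R² with at least one
        broad-scale (positive-eigenvalue) MEM selected in >= 80%."""
        hits = 0
        n_rep = 10
        for rep in range(n_rep):
            ds = ip.simulate_river_population(
                12, 50, 0.01, 50, 120, 5, deme_spacing_km=20, seed=3000 + rep
            )
            d = distance_matrix_from_metadata(ds.metadata)
            res = ip.mem_forward_selection(ds.genotypes, d, n_perm=99, seed=rep)
            broad = any(res.eigenvalues[m] > 0 for m in res.selected)
            hits += (res.r2_adj > 0) and broad
        assert hits >= 0.8 * n_rep

    def test_weak_r2_representable(self, river):
        """Adjusted R² values of the order reported for weak structure
        (~0.02) are representable and non-negative."""
        ds, d, _ = river
        res = ip.mem_forward_selection(ds.genotypes, d, n_perm=99, seed=10)
        assert np.isfinite(res.r2_adj) and res.r2_adj >= 0.0


class TestCorrelogram:
    def test_thirty_classes_on_standard_grid(self, river):
        _, d, gd = river
        cg = ip.mantel_correlogram(gd, d, 10, 300, 10, n_perm=49, seed=11)
        assert len(cg.rows) == 30

    def test_shuffled_coordinates_null(self, river):
        ds, d, gd = river
        rng = np.random.default_rng(12)
        perm = rng.permutation(len(d))
        d_sh = d.to_numpy()[np.ix_(perm, perm)]
        cg = ip.mantel_correlogram(gd, d_sh, 20, 280, 20, n_perm=199, seed=13)
        n_sig = sum(r.significant for r in cg.rows)
        assert n_sig <= 1
        if n_sig == 0:
            assert np.isnan(cg.neighbourhood_size_km)

    def test_mantel_r_bounded_and_p_floor(self, river):
        _, d, gd = river
        cg = ip.mantel_correlogram(gd, d, 20, 280, 20, n_perm=99, seed=14)
        for row in cg.rows:
            assert -1 <= row.mantel_r <= 1
            assert row.p_value >= 1 / 100


class TestNeighborhoodDiversity:
    def test_infinite_radius_equals_global(self, river):
        ds, d, _ = river
        nd = ip.neighborhood_diversity(ds.genotypes, d, radius_km=1e12, min_n=2)
        t = ip.ho_hs_fis(ds.genotypes)
        assert nd["Ho"].iloc[0] == pytest.approx(t.mean_ho, abs=1e-12)
        assert nd["He"].iloc[0] == pytest.approx(t.mean_hs, abs=1e-12)
        assert nd["Fis"].iloc[0] == pytest.approx(t.mean_fis, abs=1e-12)
        assert nd["computed"].all()

    def test_isolated_sample_not_computed(self, river):
        """An individual with no neighbours inside the radius is
        reported with reason, not an error (the Lake Ontario case)."""
        ds, d, _ = river
        dm = d.to_numpy().copy()
        dm[0, 1:] = 5000.0
        dm[1:, 0] = 5000.0
        nd = ip.neighborhood_diversity(ds.genotypes, dm, radius_km=100, min_n=10)
        assert not nd["computed"].iloc[0]
        assert nd["reason"].iloc[0] == "insufficient n"

    def test_ar_bounds_for_biallelic(self, river):
        ds, d, _ = river
        nd = ip.neighborhood_diversity(ds.genotypes, d, radius_km=100, min_n=10)
        ar = nd.loc[nd["computed"], "Ar"]
        assert ((ar >= 1) & (ar <= 2)).all()

    def test_fixed_locus_contributes_ar_one(self):
        """A locus fixed in the neighbourhood has rarefied Ar exactly 1."""
        from invadepop.spatial import _rarefied_ar

        g = ip.GenotypeMatrix(np.zeros((25, 1), dtype=np.int16),
                              [f"s{i}" for i in range(25)], ["l:1"])
        assert _rarefied_ar(g, np.arange(25), 10) == pytest.approx(1.0)


class TestDecayRegression:
    def _meta(self, n, rng, two_dirs=True):
        dist = rng.uniform(0, 300, n)
        if two_dirs:
            direction = np.where(rng.random(n) < 0.5, "north", "south")
        else:
            direction = np.array(["north"] * n)
        return pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "distance_from_origin": dist,
            "direction": direction,
        })

    def test_pure_noise_reduces_to_intercept(self):
        """Type-I control: noise metrics drop every term in ~95% of
        replicates (quick check; the 200-replicate calibration runs in
        the acceptance suite)."""
        rng = np.random.default_rng(15)
        n_intercept = 0
        for _ in range(40):
            meta = self._meta(80, rng)
            m = ip.decay_regression(rng.normal(size=80), meta)
            n_intercept += m.formula == "y ~ 1"
        assert n_intercept >= 40 * 0.85

    def test_opposite_slopes_keep_interaction(self):
        """North/south slopes of opposite sign at 2x residual SD:
        interaction retained with p < 0.05 in >= 90% of replicates."""
        rng = np.random.default_rng(16)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            meta = self._meta(80, rng)
            sd = 1.0
            slope = 2 * sd / 300.0
            sign = np.where(meta["direction"] == "north", 1.0, -1.0)
            y = slope * meta["distance_from_origin"] * sign + rng.normal(0, sd, 80)
            m = ip.decay_regression(y, meta)
            kept = [t for t in m.lrt_trace if t["term"] == "distance:direction"]
            hits += bool(kept and kept[0]["kept"] and kept[0]["p"] < 0.05)
        assert hits >= 0.9 * n_rep

    def test_slope_reported_per_100km(self):
        rng = np.random.default_rng(17)
        meta = self._meta(120, rng, two_dirs=False)
        y = -0.00007 * meta["distance_from_origin"] + rng.normal(0, 0.0004, 120)
        m = ip.decay_regression(y, meta)
        if m.slope_per_100km is not None:
            assert m.slope_per_100km == pytest.approx(-0.007, rel=0.5)

    def test_single_direction_drops_direction_terms(self):
        rng = np.random.default_rng(18)
        meta = self._meta(50, rng, two_dirs=False)
        m = ip.decay_regression(rng.normal(size=50), meta)
        assert "direction" not in m.formula

    def test_outlier_rule_reports_exclusions(self):
        rng = np.random.default_rng(19)
        meta = self._meta(40, rng)
        meta.loc[0, "distance_from_origin"] = 100000.0
        m = ip.decay_regression(rng.normal(size=40), meta, exclude_outliers=True)
        assert m.excluded == ["s0"]


def test_spca_and_mem_agree_on_null(river):
    """Agreement of negatives: a spatially shuffled fixture shows no
    structure under either method."""
    ds, d, _ = river
    rng = np.random.default_rng(20)
    perm = rng.permutation(ds.genotypes.n_samples)
    g = ds.genotypes.take_samples(perm)
    res_mem = ip.mem_forward_selection(g, d, n_perm=99, seed=21)
    coords = np.column_stack(
        [ds.metadata["river_km"].to_numpy(), rng.uniform(0, 1, len(d))]
    )
    res_spca = ip.spca(g, coords, n_perm=199, seed=22)
    assert res_mem.r2_adj < 0.05
    assert res_spca.global_test.p_value > 0.01
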