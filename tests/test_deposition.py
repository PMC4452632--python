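import numpy as np
import pytest
from scipy import stats

from sirtsim.deposition import (
    ClusterSizeDistribution,
    chaotic_deposit,
    default_cluster_distribution,
    deposit,
    sample_cluster_sizes,
)


class TestClusterSizeDistribution:
    def test_calibrated_moments_over_seeds(self):
        """Defaults reproduce the two calibration targets: mean location
        size ~3.3 spheres and ~64% of locations being singles."""
        dist = default_cluster_distribution()
        all_sizes = np.concatenate(
            [sample_cluster_sizes(793 * 5, dist, rng_seed=s) for s in range(40)]
        )
        assert all_sizes.mean() == pytest.approx(3.3, abs=0.1)
        assert (all_sizes == 1).mean() == pytest.approx(0.64, abs=0.02)
        assert all_sizes.max() <= dist.max_cluster

    def test_theoretical_mean_matches_target(self):
        for law in ("power_law", "geometric"):
            dist = ClusterSizeDistribution(tail_law=law).resolved()
            assert dist.theoretical_mean == pytest.approx(3.3, rel=1e-6)

    def test_degenerate_all_singles(self):
        sizes = sample_cluster_sizes(57, ClusterSizeDistribution(p_single=1.0))
        assert np.array_equal(sizes, np.ones(57, dtype=int))

    def test_impossible_distribution_rejected(self):
        with pytest.raises(ValueError):
            ClusterSizeDistribution(p_single=0.5, max_cluster=1)
        with pytest.raises(ValueError):
            # tail mean needed to hit mean_size exceeds max_cluster
            ClusterSizeDistribution(p_single=0.9, mean_size=9.0, max_cluster=5)


class TestSampleClusterSizes:
    def test_single_sphere(self):
        assert sample_cluster_sizes(1, rng_seed=0).tolist() == [1]

    @pytest.mark.parametrize("n", [1, 7, 793, 10_000])
    def test_exact_sphere_count_conservation(self, n):
        sizes = sample_cluster_sizes(n, rng_seed=5)
        assert sizes.sum() == n
        assert sizes.min() >= 1

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            sample_cluster_sizes(0)


class TestDeposit:
    def test_uniform_weights_match_multinomial(self, small_model):
        """With no field, gradient or enrichment, cluster→tract counts are
        multinomial-uniform (chi-square goodness of fit)."""
        sizes = np.ones(40_000, dtype=int)
        dep = deposit(small_model, sizes, rng_seed=7, exclusive_tracts=False)
        counts = np.bincount(
            dep.spheres["tract_id"].to_numpy(), minlength=small_model.n_tracts
        )
        chi2, p = stats.chisquare(counts)
        assert p > 1e-3

    def test_cluster_of_27_shares_one_tract(self, small_model):
        dep = deposit(small_model, np.array([27]), rng_seed=3)
        sp = dep.spheres
        assert len(sp) == 27
        assert sp["cluster_id"].nunique() == 1
        assert sp["tract_id"].nunique() == 1
        # jittered within 100 um of the shared trapping site
        tract = small_model.tract_points[sp["tract_id"].iloc[0]]
        d = np.linalg.norm(sp[["x_mm", "y_mm", "z_mm"]].to_numpy() - tract, axis=1)
        assert d.max() <= 0.1 + 1e-9

    def test_realised_tnc_near_target(self):
        """Equal-mass compartments, enrichment 3.2 → realised ratio ≈ 3.2."""
        from sirtsim import build_lattice

        model = build_lattice(4000.0, tumour_fraction=0.5)
        ratios = []
        for s in range(10):
            sizes = sample_cluster_sizes(40_000, rng_seed=100 + s)
            dep = deposit(
                model, sizes, tnc_target=3.2, rng_seed=200 + s, exclusive_tracts=False
            )
            ratios.append(
                dep.compartment_concentration_bq_per_mg("tumour")
                / dep.compartment_concentration_bq_per_mg("normal")
            )
        assert np.mean(ratios) == pytest.approx(3.2, rel=0.05)

    def test_extreme_gradient_rejected(self, small_model):
        with pytest.raises(ValueError, match="gradient"):
            deposit(small_model, np.array([5, 5]), gradient_per_mm=1.0)

    def test_activity_and_diameter_ranges(self, small_deposition):
        act = small_deposition.spheres["activity_bq"]
        assert act.min() >= 40.0 and act.max() <= 70.0
        assert act.mean() == pytest.approx(50.0, rel=0.02)
        diam = small_deposition.spheres["diameter_um"]
        assert diam.min() >= 20.0 and diam.max() <= 60.0
        assert diam.mean() == pytest.approx(30.0, rel=0.05)

    def test_activity_conservation(self, small_deposition):
        assert small_deposition.total_activity_bq == pytest.approx(
            small_deposition.spheres["activity_bq"].sum()
        )
        assert small_deposition.total_activity_bq == pytest.approx(
            small_deposition.n_spheres * 50.0, rel=0.02
        )

    def test_deterministic_under_seed(self, small_model):
        sizes = sample_cluster_sizes(500, rng_seed=4)
        a = deposit(small_model, sizes, rng_seed=9)
        b = deposit(small_model, sizes, rng_seed=9)
        assert a.spheres.equals(b.spheres)

    def test_exclusive_tracts_no_sharing(self, small_model):
        sizes = sample_cluster_sizes(900, rng_seed=6)
        dep = deposit(small_model, sizes, rng_seed=8, exclusive_tracts=True)
        per_tract = dep.spheres.groupby("tract_id")["cluster_id"].nunique()
        assert per_tract.max() == 1

    def test_singles_isolation_when_exclusive(self, small_model):
        """With one cluster per tract, isolated singles sit >200 um from
        any other sphere (tracts are 600 um apart, jitter <=100 um)."""
        from scipy.spatial import cKDTree

        sizes = sample_cluster_sizes(600, rng_seed=16)
        dep = deposit(small_model, sizes, rng_seed=17, exclusive_tracts=True)
        sp = dep.spheres
        singles = sp.groupby("cluster_id").filter(lambda g: len(g) == 1)
        pts = sp[["x_mm", "y_mm", "z_mm"]].to_numpy()
        tree = cKDTree(pts)
        d, _ = tree.query(singles[["x_mm", "y_mm", "z_mm"]].to_numpy(), k=2)
        assert d[:, 1].min() > 0.2


class TestChaoticDeposit:
    def test_zero_patchiness_is_csr(self, small_model):
        """patchiness 0, no drift → cluster centres uniform in the volume."""
        sizes = np.ones(4000, dtype=int)
        dep = chaotic_deposit(small_model, sizes, patchiness=0.0, rng_seed=13)
        pos = dep.positions
        lo, hi = small_model.bbox_lo, small_model.bbox_hi
        for axis in range(3):
            u = (pos[:, axis] - lo[axis]) / (hi[axis] - lo[axis])
            # jitter can push slightly past the box; clip for the marginal test
            _, p = stats.kstest(np.clip(u, 0, 1), "uniform")
            assert p > 1e-3

    def test_single_patch_contains_all_clusters(self, small_model):
        sizes = np.ones(300, dtype=int)
        dep = chaotic_deposit(
            small_model,
            sizes,
            patchiness=1e9,
            n_patches=1,
            patch_radius_median_mm=2.0,
            patch_radius_sigma=0.0,
            rng_seed=14,
        )
        pos = dep.positions
        centre = pos.mean(axis=0)
        assert np.linalg.norm(pos - centre, axis=1).max() <= 2.0 + 0.1 + 0.5

    def test_parameter_validation(self, small_model):
        with pytest.raises(ValueError):
            chaotic_deposit(small_model, np.array([1]), patchiness=-1.0)
        with pytest.raises(ValueError):
            chaotic_deposit(
                small_model, np.array([1]), patchiness=0.0, systematic_gradient=1.5
            )

    def test_sphere_count_conservation(self, small_model):
        sizes = sample_cluster_sizes(2000, rng_seed=15)
        dep = chaotic_deposit(small_model, sizes, patchiness=0.5, rng_seed=15)
        assert dep.n_spheres == sizes.sum() == 2000
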