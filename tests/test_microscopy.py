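import numpy as np
import pytest

from sirtsim.biopsy import punch
from sirtsim.microscopy import (
    concentration_from_counts,
    find_locations,
    location_stats,
    section_biopsy,
)
from tests_support_oracles import brute_force_locations, make_stack


class TestSectionBiopsy:
    def test_empty_biopsy_gives_empty_stack(self, small_deposition):
        m = small_deposition.model
        b = punch(
            small_deposition,
            (m.bbox_hi[0] + 40, m.bbox_hi[1] + 40, 0.75),
            4.0, 1.0, require_inside=False,
        )
        stack = section_biopsy(b, small_deposition)
        assert stack.n_spheres == 0

    def test_stack_thicker_than_biopsy_rejected(self, small_deposition):
        m = small_deposition.model
        b = punch(small_deposition, tuple((m.bbox_lo + m.bbox_hi) / 2), 4.0, 0.1,
                  require_inside=False)
        with pytest.raises(ValueError, match="exceeds biopsy thickness"):
            section_biopsy(b, small_deposition, n_sections=10)

    def test_sectioned_fraction_bookkeeping(self, mid_model):
        """Six 2.5 mm-thick punches sectioned 10x20 um: ~8% investigated,
        ~34 mm3 of sectioned volume."""
        from sirtsim import deposit, sample_cluster_sizes
        from sirtsim.biopsy import punch_plan

        dep = deposit(mid_model, sample_cluster_sizes(3000, rng_seed=41), rng_seed=41)
        biopsies, _ = punch_plan(dep, [(6.0, 6, 2.5)], rng_seed=42)
        stacks = [section_biopsy(b, dep) for b in biopsies]
        assert all(s.sectioned_fraction == pytest.approx(0.08) for s in stacks)
        assert sum(s.sectioned_volume_mm3 for s in stacks) == pytest.approx(
            6 * np.pi * 9.0 * 0.2
        )

    def test_slab_assignment_matches_direct_binning(self, small_deposition, rng):
        m = small_deposition.model
        b = punch(small_deposition, tuple((m.bbox_lo + m.bbox_hi) / 2), 8.0, 1.4,
                  require_inside=False)
        stack = section_biopsy(b, small_deposition, n_sections=10)
        z_top = b.centre[2] + b.thickness_mm / 2
        sp = small_deposition.spheres.loc[b.sphere_ids]
        for _, row in stack.records.iterrows():
            expected = int(np.floor((z_top - row["z_mm"]) / 0.02))
            assert row["section_index"] == expected
        # every sphere within the stack depth appears exactly once
        depth = 10 * 0.02
        n_in_depth = int(((z_top - sp["z_mm"]) < depth).sum())
        assert abs(stack.n_spheres - n_in_depth) <= 1  # boundary convention


class TestFindLocations:
    def test_pair_within_linkage_radius_is_one_location(self):
        stack = make_stack([[0, 0, 0.01], [0.15, 0, 0.01]])
        locs = find_locations(stack)
        assert len(locs) == 1
        assert locs["n_spheres"].iloc[0] == 2
        assert not locs["is_isolated_single"].iloc[0]

    def test_pair_beyond_radius_is_two_singles(self):
        stack = make_stack([[0, 0, 0.01], [0.25, 0, 0.01]])
        locs = find_locations(stack)
        assert len(locs) == 2
        assert locs["is_isolated_single"].all()

    def test_cluster_spanning_sections_is_one_location(self, rng):
        # 36 spheres spread through adjacent sections within 100 um steps
        base = np.array([2.0, 2.0, 0.0])
        pts = base + rng.uniform(-0.05, 0.05, size=(36, 3)) + [0, 0, 0.1]
        stack = make_stack(pts)
        locs = find_locations(stack)
        assert len(locs) == 1
        assert locs["n_spheres"].iloc[0] == 36
        assert locs["last_section"].iloc[0] >= locs["first_section"].iloc[0]

    def test_matches_brute_force_union_find(self, rng):
        """Single-linkage grouping equals the all-pairs union-find oracle."""
        for trial in range(5):
            n = int(rng.integers(20, 400))
            # clumpy point set: a few centres with satellites
            centres = rng.uniform(0, 3, size=(max(2, n // 10), 2))
            pick = rng.integers(0, len(centres), n)
            xy = centres[pick] + rng.normal(scale=0.08, size=(n, 2))
            z = rng.uniform(0, 0.2, n)
            stack = make_stack(np.column_stack([xy, z]))
            locs = find_locations(stack)
            dz = 0.02
            pts = np.column_stack(
                [
                    stack.records["x_mm"],
                    stack.records["y_mm"],
                    (stack.records["section_index"] + 0.5) * dz,
                ]
            )
            oracle = brute_force_locations(pts, 0.2)
            assert sorted(locs["n_spheres"]) == sorted(len(g) for g in oracle)
            assert len(locs) == len(oracle)
            # partition conserves the sphere count
            assert locs["n_spheres"].sum() == stack.n_spheres

    def test_invalid_isolation_distance(self):
        stack = make_stack([[0, 0, 0.01]])
        with pytest.raises(ValueError):
            find_locations(stack, isolation_distance_um=0.0)


class TestLocationStats:
    def test_published_counts(self):
        """240 locations, 793 spheres, 154 singles: mean 3.3, 64% of
        locations, 19% of spheres."""
        sizes = [1] * 154 + [8] * 37 + [7] * 49
        assert sum(sizes) == 793 and len(sizes) == 240
        stats = location_stats(sizes)
        assert round(stats.mean_size, 1) == 3.3
        assert round(100 * stats.fraction_singles_of_locations) == 64
        assert round(100 * stats.fraction_singles_of_spheres) == 19
        assert stats.histogram.sum() == 240
        assert stats.histogram.loc[1] == 154

    def test_accepts_location_frame(self):
        stack = make_stack([[0, 0, 0.01], [0.25, 0, 0.01], [0.27, 0, 0.01]])
        stats = location_stats(find_locations(stack))
        assert stats.n_locations == 2
        assert stats.n_spheres == 3

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            location_stats([])


class TestConcentrationFromCounts:
    def test_worked_value_and_scaling(self):
        c = concentration_from_counts(793, 36.0)
        assert c == pytest.approx(39650.0 / 36.0)
        assert concentration_from_counts(793, 72.0) == pytest.approx(c / 2)
        assert concentration_from_counts(0, 36.0) == 0.0

    def test_invalid_volume(self):
        with pytest.raises(ValueError):
            concentration_from_counts(10, 0.0)

    def test_count_estimate_unbiased_for_biopsy_concentration(self, mid_model):
        """Over seeds, the sectioned-count estimate scatters around the
        biopsy-level detector concentration (subsampling consistency)."""
        from sirtsim import chaotic_deposit, sample_cluster_sizes
        from sirtsim.biopsy import punch_plan

        estimates = []
        biopsy_conc = []
        for s in range(20):
            sizes = sample_cluster_sizes(60_000, rng_seed=400 + s)
            dep = chaotic_deposit(mid_model, sizes, patchiness=0.0, rng_seed=500 + s)
            biopsies, _ = punch_plan(
                dep, [(8.0, 3, 1.4)], rng_seed=600 + s, compartment=None
            )
            for b in biopsies:
                stack = section_biopsy(b, dep)
                estimates.append(
                    concentration_from_counts(stack.n_spheres, stack.sectioned_volume_mm3)
                )
                biopsy_conc.append(b.concentration_bq_per_mg)
        assert np.mean(estimates) == pytest.approx(np.mean(biopsy_conc), rel=0.10)
        # individual stack estimates scatter around the detector value
        rel = np.array(estimates) / np.array(biopsy_conc)
        assert rel.std() > 0.05
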