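"""Stopping-rule contracts, percentile CIs, determinism, first-passage oracle."""
import numpy as np
import pytest
from scipy.stats import ks_2samp

from noduleco.bootstrap import (ResamplingError, SpecimenIndex,
                                bootstrap_by_area, bootstrap_by_count,
                                class_rng, summarize_bootstrap)

from conftest import make_image, make_specimen


SPECIES_CYCLE = ("actiniaria-msp1", "porifera-msp5", "isidid-msp1")


def build_index(counts, areas=None):
    areas = areas or [1.71] * len(counts)
    images = [make_image(i, float(i % 90), area=areas[i])
              for i in range(len(counts))]
    specimens = []
    n = 0
    for i, c in enumerate(counts):
        for _ in range(c):
            specimens.append(make_specimen(
                n, f"img{i:04d}", species=SPECIES_CYCLE[n % 3]))
            n += 1
    return SpecimenIndex.build(images, specimens, focal_group="metazoan")


class TestCountRule:
    def test_single_image_holding_exact_target(self):
        index = build_index([500])
        bset = bootstrap_by_count(index, 1, min_count=500, reps=20, seed=1)
        assert (bset.focal_counts == 500).all()
        assert all(len(idx) == 1 for idx in bset.draw_indices)

    def test_unit_count_images_force_exact_draws(self):
        index = build_index([1] * 30)
        bset = bootstrap_by_count(index, 1, min_count=500, reps=50, seed=2)
        assert (bset.focal_counts == 500).all()
        assert all(len(idx) == 500 for idx in bset.draw_indices)

    def test_minimality_of_every_sample(self, rng):
        counts = rng.poisson(0.7, size=120)
        counts[0] = max(counts[0], 1)
        index = build_index(list(counts))
        bset = bootstrap_by_count(index, 1, min_count=500, reps=300, seed=3)
        focal = index.focal_counts
        for idx, total in zip(bset.draw_indices, bset.focal_counts):
            assert total >= 500
            assert total - focal[idx[-1]] < 500   # last draw was necessary
            assert total == focal[idx].sum()

    def test_overshoot_band_bounded_by_max_image_count(self, rng):
        counts = rng.poisson(0.7, size=150)
        counts[0] = max(counts[0], 1)
        index = build_index(list(counts))
        bset = bootstrap_by_count(index, 1, min_count=500, reps=1000, seed=4)
        assert bset.focal_counts.min() >= 500
        assert bset.focal_counts.max() < 500 + counts.max() + 1

    def test_zero_focal_class_is_infeasible(self):
        index = build_index([0, 0, 0])
        with pytest.raises(ResamplingError):
            bootstrap_by_count(index, 1, min_count=10, reps=5, seed=5)

    def test_fixed_seed_reproduces_bit_identically(self):
        index = build_index([2, 1, 0, 3, 1])
        a = bootstrap_by_count(index, 1, min_count=50, reps=40, seed=6)
        b = bootstrap_by_count(index, 1, min_count=50, reps=40, seed=6)
        assert all((x == y).all()
                   for x, y in zip(a.draw_indices, b.draw_indices))
        assert (a.focal_counts == b.focal_counts).all()

    def test_first_passage_matches_sequential_oracle(self):
        """Stopping counts agree in distribution with a naive one-draw-at-a-
        time simulation (two-sample KS on independent streams)."""
        counts = np.array([0, 1, 2, 0, 3, 1, 1, 0, 2, 4])
        index = build_index(list(counts))
        bset = bootstrap_by_count(index, 1, min_count=40, reps=800, seed=7)
        rng = np.random.default_rng(987)
        naive = []
        for _ in range(800):
            total = 0
            while total < 40:
                total += counts[rng.integers(0, len(counts))]
            naive.append(total)
        assert ks_2samp(bset.focal_counts, naive).pvalue > 0.01


class TestAreaRule:
    def test_uniform_area_images_forced_composition(self):
        index = build_index([1] * 40)
        bset = bootstrap_by_area(index, 1, area_low=650.0, area_high=670.0,
                                 reps=100, seed=8)
        assert all(len(idx) == 381 for idx in bset.draw_indices)
        assert np.allclose(bset.total_areas, 381 * 1.71)

    def test_degenerate_window_single_image(self):
        index = build_index([1], areas=[660.0])
        bset = bootstrap_by_area(index, 1, area_low=660.0, area_high=660.0,
                                 reps=10, seed=9)
        assert all(len(idx) == 1 for idx in bset.draw_indices)

    def test_all_samples_inside_window(self, rng):
        areas = list(rng.uniform(1.2, 2.4, size=60))
        index = build_index([1] * 60, areas=areas)
        bset = bootstrap_by_area(index, 1, area_low=650.0, area_high=670.0,
                                 reps=1000, seed=10)
        assert (bset.total_areas >= 650.0).all()
        assert (bset.total_areas <= 670.0).all()

    def test_impossible_window_raises_configuration_error(self):
        index = build_index([1, 1], areas=[100.0, 100.0])
        with pytest.raises(ResamplingError, match="widen"):
            bootstrap_by_area(index, 1, area_low=650.0, area_high=651.0,
                              reps=5, seed=11, max_rejections=200)

    def test_oversized_images_rejected_up_front(self):
        index = build_index([1], areas=[900.0])
        with pytest.raises(ResamplingError, match="exceeds"):
            bootstrap_by_area(index, 1, area_low=650.0, area_high=670.0,
                              reps=5, seed=12)


class TestPercentileSummary:
    def test_constant_vector(self):
        assert summarize_bootstrap([3.5] * 1000) == (3.5, 3.5, 3.5)

    def test_rank_convention_on_1_to_1000(self):
        values = np.arange(1, 1001, dtype=float)
        center, lo, hi = summarize_bootstrap(values, center="mean", level=0.95)
        assert (lo, hi) == (25.0, 976.0)

    def test_median_center_contained(self):
        values = np.arange(1, 1001, dtype=float)
        center, lo, hi = summarize_bootstrap(values, center="median")
        assert center == 500.5 and lo < center < hi

    def test_wider_level_widens_interval(self, rng):
        values = rng.normal(size=500)
        _, lo90, hi90 = summarize_bootstrap(values, level=0.90)
        _, lo99, hi99 = summarize_bootstrap(values, level=0.99)
        assert lo99 <= lo90 and hi99 >= hi90

    def test_shuffle_invariance(self, rng):
        values = rng.normal(size=400)
        shuffled = rng.permutation(values)
        assert summarize_bootstrap(values) == summarize_bootstrap(shuffled)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            summarize_bootstrap([1.0])


def test_child_streams_independent_of_other_classes():
    """Recomputing one class alone reproduces its stream from the root seed."""
    index = build_index([2, 1, 3, 1, 2])
    full = [bootstrap_by_count(index, c, min_count=30, reps=10, seed=42)
            for c in (1, 2, 3)]
    alone = bootstrap_by_count(index, 2, min_count=30, reps=10, seed=42)
    assert (full[1].focal_counts == alone.focal_counts).all()
    rng_a = class_rng(42, 2, "count", "metazoan")
    rng_b = class_rng(42, 2, "count", "xenophyophore")
    assert rng_a.integers(0, 1 << 30) != rng_b.integers(0, 1 << 30)
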