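import numpy as np
import pytest

from engramkit import (
    EventRaster, compare_group_to_null, materialize_replicate,
    null_correlations, pairwise_correlations,
)


def bern_raster(rng, n_cells=10, n_bins=500, p=0.1):
    return EventRaster((rng.random((n_cells, n_bins)) < p).astype(int),
                       list(range(n_cells)))


class TestObserved:
    def test_identical_rows_r_one(self):
        row = np.tile([1, 0, 1, 1, 0, 0, 1, 0], 10)
        table = pairwise_correlations(EventRaster(np.vstack([row, row]), [0, 1]))
        assert table.pairs.r.iloc[0] == pytest.approx(1.0)

    def test_complementary_rows_r_minus_one(self):
        row = np.tile([1, 0, 1, 1, 0, 0, 1, 0], 10)
        table = pairwise_correlations(EventRaster(np.vstack([row, 1 - row]), [0, 1]))
        assert table.pairs.r.iloc[0] == pytest.approx(-1.0)

    def test_closed_form_zero_correlation(self):
        a = np.tile([1, 0, 1, 0], 20)
        b = np.tile([1, 1, 0, 0], 20)
        table = pairwise_correlations(EventRaster(np.vstack([a, b]), [0, 1]))
        assert table.pairs.r.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_cells_excluded_with_reason(self, rng):
        ev = (rng.random((4, 100)) < 0.2).astype(int)
        ev[2] = 0
        table = pairwise_correlations(EventRaster(ev, [0, 1, 2, 3]))
        assert (2, "zero variance") in table.excluded
        assert 2 not in set(table.pairs.cell_i) | set(table.pairs.cell_j)

    def test_all_flat_rejected(self):
        with pytest.raises(ValueError):
            pairwise_correlations(EventRaster(np.zeros((3, 100), int), [0, 1, 2]))


class TestNull:
    def test_event_counts_conserved_exactly(self, rng):
        raster = bern_raster(rng)
        table = pairwise_correlations(raster)
        null = null_correlations(raster, table, n_replicates=8, seed=3)
        for rep in range(8):
            shifted = materialize_replicate(raster, null, rep)
            assert np.array_equal(shifted.events.sum(1), raster.events.sum(1))

    def test_fast_path_matches_direct_correlation_of_shifted_arrays(self, rng):
        """Dual route: the FFT cross-correlation lookup must reproduce
        np.corrcoef on the explicitly shifted rasters."""
        raster = bern_raster(rng, n_cells=6, n_bins=200)
        table = pairwise_correlations(raster)
        null = null_correlations(raster, table, n_replicates=5, seed=9)
        for rep in range(5):
            shifted = materialize_replicate(raster, null, rep).events.astype(float)
            direct = np.corrcoef(shifted)
            iu, ju = np.triu_indices(6, k=1)
            assert np.allclose(null.r[rep], direct[iu, ju], atol=1e-10)

    def test_null_mean_near_zero_for_independent_cells(self, rng):
        raster = bern_raster(rng, n_cells=10, n_bins=1000)
        table = pairwise_correlations(raster)
        null = null_correlations(raster, table, n_replicates=500, seed=1)
        assert abs(null.r.mean()) < 0.01

    def test_seeded_determinism(self, rng):
        raster = bern_raster(rng)
        table = pairwise_correlations(raster)
        a = null_correlations(raster, table, n_replicates=50, seed=21)
        b = null_correlations(raster, table, n_replicates=50, seed=21)
        assert np.array_equal(a.r, b.r) and np.array_equal(a.offsets, b.offsets)


class TestGroupComparison:
    def test_coactive_ensemble_significant(self):
        """Cells sharing event times are declared significant every seed."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            shared = (rng.random(600) < 0.1).astype(int)
            ev = np.array([shared] * 5 + [(rng.random(600) < 0.1).astype(int)
                                          for _ in range(5)])
            raster = EventRaster(ev, list(range(10)))
            mem = {"planted": set(range(5)), "bg": set(range(5, 10))}
            table = pairwise_correlations(raster, mem)
            null = null_correlations(raster, table, n_replicates=200, seed=seed)
            cmp_ = compare_group_to_null(table, null, ("planted", "planted"))
            assert cmp_.significant

    def test_single_replicate_flagged_underpowered(self, rng):
        raster = bern_raster(rng)
        mem = {"g": set(range(5))}
        table = pairwise_correlations(raster, mem)
        null = null_correlations(raster, table, n_replicates=1, seed=0)
        cmp_ = compare_group_to_null(table, null, ("g", "g"))
        assert cmp_.underpowered

    def test_empty_slice_rejected(self, rng):
        raster = bern_raster(rng)
        table = pairwise_correlations(raster, {"g": set()})
        null = null_correlations(raster, table, n_replicates=10, seed=0)
        with pytest.raises(ValueError):
            compare_group_to_null(table, null, ("g", "g"))

    def test_inter_group_slice_unordered(self, rng):
        raster = bern_raster(rng, n_cells=6)
        mem = {"a": {0, 1}, "b": {4, 5}}
        table = pairwise_correlations(raster, mem)
        m1 = table.pair_mask("a", "b")
        m2 = table.pair_mask("b", "a")
        assert np.array_equal(m1, m2) and m1.sum() == 4

    def test_significance_persists_under_tracking_subset(self):
        """A planted co-active ensemble stays significant when restricted to
        a tracked subset of cells (>= 50% tracking)."""
        rng = np.random.default_rng(4)
        shared = (rng.random(800) < 0.12).astype(int)
        jittered = [np.clip(shared + (rng.random(800) < 0.02), 0, 1).astype(int)
                    for _ in range(8)]
        bg = [(rng.random(800) < 0.1).astype(int) for _ in range(12)]
        full = EventRaster(np.array(jittered + bg), list(range(20)))
        tracked_ids = sorted(rng.choice(20, 12, replace=False).tolist())
        planted_tracked = {i for i in tracked_ids if i < 8}
        sub = EventRaster(full.events[tracked_ids], tracked_ids)
        mem = {"planted": planted_tracked}
        table = pairwise_correlations(sub, mem)
        null = null_correlations(sub, table, n_replicates=300, seed=6)
        assert compare_group_to_null(table, null, ("planted", "planted")).significant
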