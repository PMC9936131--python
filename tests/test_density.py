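"""Density integration, correlation matrices and release curves."""

import numpy as np
import pytest

from flashmap.core import AtomSelection, DensityMap, UnitCell
from flashmap.density import (
    DifferenceSeries,
    correlation_matrix,
    equalize_multiplicity,
    greedy_block_segmentation,
    integrate_density,
    occupancy_snr_scale,
    per_atom_density_vector,
    release_curve,
)


def selection(cell, cart_positions, tag="sel"):
    cart = np.atleast_2d(np.asarray(cart_positions, dtype=float))
    frac = np.linalg.solve(cell.orthogonalization, cart.T).T
    return AtomSelection(ids=list(range(1, len(cart) + 1)), cart=cart, frac=frac, cell=cell, tag=tag)


def blob_map(cell, grid, centers, heights, width=0.8):
    """Periodic Gaussian blobs; returned flagged as sigma-scaled."""
    nx, ny, nz = grid
    fx, fy, fz = np.meshgrid(
        np.arange(nx) / nx, np.arange(ny) / ny, np.arange(nz) / nz, indexing="ij"
    )
    gf = np.stack([fx, fy, fz], axis=-1)
    vals = np.zeros(grid)
    m = cell.orthogonalization
    for c, h in zip(centers, heights):
        cf = np.linalg.solve(m, np.asarray(c, dtype=float))
        d = gf - cf
        d -= np.round(d)
        cart = d @ m.T
        r2 = np.sum(cart**2, axis=-1)
        vals += h * np.exp(-r2 / (2 * width**2))
    return DensityMap(cell, vals, sigma_scaled=True)


@pytest.fixture
def grid():
    return (20, 24, 28)


class TestIntegrateDensity:
    def test_subthreshold_map_integrates_to_zero(self, cell, grid):
        rng = np.random.default_rng(0)
        m = DensityMap(cell, rng.uniform(-1.4, 1.4, grid), sigma_scaled=True)
        sel = selection(cell, [[10, 12, 14]])
        assert integrate_density(m, sel, radius=3.0, sigma_threshold=1.5) == 0.0

    def test_distant_selection_sees_nothing(self, cell, grid):
        m = blob_map(cell, grid, [[2, 2, 2]], [-8.0])
        sel = selection(cell, [[12, 14, 16]])
        assert integrate_density(m, sel, radius=2.0, sigma_threshold=3.0, sign="negative") == 0.0

    def test_matches_brute_force_masked_sum(self, cell, grid):
        m = blob_map(cell, grid, [[10, 12, 14]], [-6.0])
        sel = selection(cell, [[10, 12, 14]])
        radius, thr = 2.0, 1.5
        got = integrate_density(m, sel, radius, thr, sign="negative")
        # explicit distance-mask loop
        total = 0.0
        mo = cell.orthogonalization
        for ix in range(grid[0]):
            for iy in range(grid[1]):
                for iz in range(grid[2]):
                    d = np.array([ix / grid[0], iy / grid[1], iz / grid[2]]) - sel.frac[0]
                    d -= np.round(d)
                    if np.linalg.norm(mo @ d) <= radius:
                        v = m.values[ix, iy, iz]
                        if v < 0 and abs(v) >= thr:
                            total += abs(v)
        assert got == pytest.approx(total)

    def test_sign_split_additivity(self, cell, grid):
        m = blob_map(cell, grid, [[8, 10, 12], [11, 10, 12]], [-5.0, 4.0])
        sel = selection(cell, [[9.5, 10, 12]])
        both = integrate_density(m, sel, 3.0, 1.5, "both")
        neg = integrate_density(m, sel, 3.0, 1.5, "negative")
        pos = integrate_density(m, sel, 3.0, 1.5, "positive")
        assert both == pytest.approx(neg + pos)
        assert neg > 0 and pos > 0

    def test_unscaled_map_rejected(self, cell, grid):
        m = DensityMap(cell, np.zeros(grid))
        with pytest.raises(ValueError, match="sigma"):
            integrate_density(m, selection(cell, [[1, 1, 1]]), 2.0, 1.5)

    def test_empty_selection_rejected(self, cell, grid):
        m = DensityMap(cell, np.zeros(grid), sigma_scaled=True)
        sel = AtomSelection([], np.empty((0, 3)), np.empty((0, 3)), cell)
        with pytest.raises(ValueError, match="empty"):
            integrate_density(m, sel, 2.0, 1.5)


class TestPerAtomVector:
    def test_null_map_zero_vector(self, cell, grid):
        m = DensityMap(cell, np.zeros(grid), sigma_scaled=True)
        sel = selection(cell, [[5, 5, 5], [15, 15, 15]])
        assert np.array_equal(per_atom_density_vector(m, sel), np.zeros(2))

    def test_linearity_in_map_scale(self, cell, grid):
        m = blob_map(cell, grid, [[10, 12, 14]], [-6.0])
        m3 = DensityMap(cell, 3.0 * m.values, sigma_scaled=True)
        sel = selection(cell, [[10, 12, 14]])
        v1 = per_atom_density_vector(m, sel, sigma_threshold=1.5)
        v3 = per_atom_density_vector(m3, sel, sigma_threshold=4.5)
        assert np.allclose(v3, 3.0 * v1)

    def test_disjoint_blobs_match_single_atom_integrals(self, cell, grid):
        c1, c2 = [5, 6, 7], [15, 18, 21]
        m = blob_map(cell, grid, [c1, c2], [-5.0, 7.0])
        pair = per_atom_density_vector(m, selection(cell, [c1, c2]), radius=2.0)
        solo1 = per_atom_density_vector(m, selection(cell, [c1]), radius=2.0)
        solo2 = per_atom_density_vector(m, selection(cell, [c2]), radius=2.0)
        assert pair[0] == pytest.approx(solo1[0])
        assert pair[1] == pytest.approx(solo2[0])


class TestCorrelationMatrix:
    def make_series(self, cell, grid, maps):
        return DifferenceSeries(
            labels=[f"t{i}" for i in range(len(maps))],
            times=np.geomspace(1e-9, 1e-1, len(maps)),
            maps=maps,
        )

    def test_identical_maps_correlate_perfectly(self, cell, grid):
        m = blob_map(cell, grid, [[10, 12, 14]], [-6.0])
        series = self.make_series(cell, grid, [m, m])
        sel = selection(cell, [[10, 12, 14], [5, 5, 5]])
        cm = correlation_matrix(series, sel)
        assert cm.values[0, 1] == pytest.approx(1.0)
        assert cm.normalized[0, 1] == pytest.approx(1.0)

    def test_negated_map_anticorrelates(self, cell, grid):
        m = blob_map(cell, grid, [[10, 12, 14], [5, 5, 5]], [-6.0, 4.0])
        neg = DensityMap(cell, -m.values, sigma_scaled=True)
        series = self.make_series(cell, grid, [m, neg])
        sel = selection(cell, [[10, 12, 14], [5, 5, 5]])
        cm = correlation_matrix(series, sel)
        assert cm.values[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_vector_marked_missing(self, cell, grid):
        m = blob_map(cell, grid, [[10, 12, 14], [5, 5, 5]], [-6.0, 4.0])
        flat = DensityMap(cell, np.zeros(grid), sigma_scaled=True)
        series = self.make_series(cell, grid, [m, m, flat])
        sel = selection(cell, [[10, 12, 14], [5, 5, 5]])
        cm = correlation_matrix(series, sel)
        assert np.isnan(cm.values[2, 0]) and np.isnan(cm.values[2, 2])
        assert not cm.display_mask[2, 0]

    def test_invariant_to_common_rescaling(self, cell, grid):
        rng = np.random.default_rng(1)
        maps = [
            blob_map(cell, grid, [[10, 12, 14], [6, 7, 8]], list(rng.normal(0, 5, 2)))
            for _ in range(3)
        ]
        series = self.make_series(cell, grid, maps)
        sel = selection(cell, [[10, 12, 14], [6, 7, 8], [15, 18, 21]])
        cm1 = correlation_matrix(series, sel, sigma_threshold=0.5)
        scaled_maps = [DensityMap(cell, 2.5 * m.values, sigma_scaled=True) for m in maps]
        cm2 = correlation_matrix(
            self.make_series(cell, grid, scaled_maps), sel, sigma_threshold=1.25
        )
        assert np.allclose(cm1.values, cm2.values, equal_nan=True)

    def test_greedy_segmentation_reads_block_pattern(self):
        cm_norm = np.array(
            [
                [1.0, 0.9, 0.1, 0.1],
                [0.9, 1.0, 0.1, 0.1],
                [0.1, 0.1, 1.0, 0.8],
                [0.1, 0.1, 0.8, 1.0],
            ]
        )
        from flashmap.density import CorrelationMatrix

        cm = CorrelationMatrix(
            labels=list("abcd"), values=cm_norm, normalized=cm_norm,
            display_mask=cm_norm >= 0.3, threshold=0.3,
        )
        assert greedy_block_segmentation(cm) == [[0, 1], [2, 3]]


class TestMultiplicityAndRelease:
    def test_target_is_min_count(self):
        target, fac = equalize_multiplicity([100000, 55065, 70000])
        assert target == 55065
        assert fac[1] == 1.0

    def test_equal_counts_no_rescale(self):
        _, fac = equalize_multiplicity([5, 5, 5])
        assert np.allclose(fac, 1.0)

    def test_quadruple_count_doubles_sigma(self):
        _, fac = equalize_multiplicity([4000, 1000])
        assert fac[0] == pytest.approx(2.0)

    @pytest.mark.parametrize("ratio,expected", [(4.0, 0.5), (1.0, 1.0), (2.0, 2 ** -0.5)])
    def test_occupancy_snr_scale(self, ratio, expected):
        assert occupancy_snr_scale(ratio) == pytest.approx(expected)

    def test_release_normalization_arithmetic(self, cell, grid):
        # single-voxel spikes with known integrals 0.2, 0.2, 0.8; apo 2.0
        lig = [10.0, 12.0, 14.0]
        sel = selection(cell, [lig])

        def spike(v):
            vals = np.zeros(grid)
            idx = tuple(
                int(round(f * n)) % n
                for f, n in zip(np.linalg.solve(cell.orthogonalization, np.array(lig)), grid)
            )
            vals[idx] = -v
            return DensityMap(cell, vals, sigma_scaled=True)

        series = DifferenceSeries(
            labels=["a", "b", "c"], times=np.array([1e-9, 1e-6, 1e-3]),
            maps=[spike(0.2), spike(0.2), spike(0.8)],
        )
        rc = release_curve(series, sel, spike(2.0), occupancy_ratio=4.0, radius=1.0, sigma_threshold=0.1)
        assert rc.apo_scale == pytest.approx(0.5)
        assert np.allclose(rc.normalized, [0.0, 0.0, 0.75])
        assert rc.apo_normalized == pytest.approx(1.0)
        assert not rc.degenerate

    def test_degenerate_normalization_flagged(self, cell, grid):
        lig = [10.0, 12.0, 14.0]
        sel = selection(cell, [lig])
        m = blob_map(cell, grid, [lig], [-8.0])
        series = DifferenceSeries(labels=["a", "b"], times=np.array([1e-9, 1e-3]), maps=[m, m])
        rc = release_curve(series, sel, m, occupancy_ratio=4.0)
        assert rc.degenerate
        assert np.all(rc.raw >= 0)
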