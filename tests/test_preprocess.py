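"""ROI selection, neighborhood averaging, transmittance and subsampling."""

import numpy as np
import pandas as pd
import pytest

from honeyspec import (
    Hypercube,
    NoiseModel,
    RoiSpec,
    SpectralCurveSet,
    WavelengthGrid,
    average_neighborhoods,
    compute_transmittance,
    mixture_spectrum,
    select_roi,
    simulate_cube_pair,
    subsample_curves,
)
from honeyspec.exceptions import (
    ConfigurationError,
    DimensionError,
    DivisionDomainError,
    SamplingError,
)


def _cube(data, grid, kind="sample"):
    return Hypercube(data=data, grid=grid, kind=kind)


@pytest.fixture()
def small_grid():
    return WavelengthGrid(np.linspace(420.0, 430.0, 3))


class TestSelectRoi:
    def test_centered_window_arithmetic(self, small_grid, rng):
        cube = _cube(rng.random((3, 64, 64)), small_grid)
        out = select_roi(cube, "center", size=16)
        assert out.shape == (3, 16, 16)
        assert np.array_equal(out.data, cube.data[:, 24:40, 24:40])
        assert out.metadata["roi"] == [24, 40, 24, 40]

    def test_full_extent_is_identity(self, small_grid, rng):
        cube = _cube(rng.random((3, 8, 12)), small_grid)
        out = select_roi(cube, RoiSpec(0, 8, 0, 12))
        assert np.array_equal(out.data, cube.data)

    def test_non_multiple_of_four_rejected(self, small_grid, rng):
        cube = _cube(rng.random((3, 64, 64)), small_grid)
        with pytest.raises(DimensionError):
            select_roi(cube, "center", size=17)
        with pytest.raises(DimensionError):
            select_roi(cube, RoiSpec(0, 64, 0, 70))


class TestAverageNeighborhoods:
    def test_constant_cube_gives_constant_curves(self, small_grid):
        cube = _cube(np.full((3, 8, 8), 0.7), small_grid)
        out = average_neighborhoods(cube)
        assert out.n_curves == 4
        assert np.allclose(out.curves, 0.7)

    def test_matches_bruteforce_tile_means(self, small_grid, rng):
        """Vectorised tiling equals the nested-loop definition."""
        data = rng.random((3, 8, 8))
        out = average_neighborhoods(_cube(data, small_grid), k=4)
        expected = np.empty((4, 3))
        row = 0
        for tr in range(2):
            for tc in range(2):
                for b in range(3):
                    expected[row, b] = data[b, 4 * tr : 4 * tr + 4, 4 * tc : 4 * tc + 4].mean()
                row += 1
        assert np.max(np.abs(out.curves - expected)) < 1e-12
        assert list(out.provenance["tile_row"]) == [0, 0, 1, 1]
        assert list(out.provenance["tile_col"]) == [0, 1, 0, 1]

    def test_non_divisible_extent_rejected(self, small_grid, rng):
        with pytest.raises(DimensionError):
            average_neighborhoods(_cube(rng.random((3, 10, 8)), small_grid))


class TestComputeTransmittance:
    def _pair(self, sample_data, white_data, grid):
        s = average_neighborhoods(_cube(sample_data, grid))
        w = average_neighborhoods(_cube(white_data, grid, kind="white_reference"))
        return s, w

    def test_equal_power_gives_unity(self, small_grid, rng):
        w = rng.random((3, 8, 8)) + 0.5
        s, wref = self._pair(w, w, small_grid)
        tau = compute_transmittance(s, wref)
        assert np.allclose(tau.curves, 1.0)
        assert not tau.flagged.any()

    def test_zero_power_gives_zero(self, small_grid, rng):
        w = rng.random((3, 8, 8)) + 0.5
        s, wref = self._pair(np.zeros((3, 8, 8)), w, small_grid)
        assert np.allclose(compute_transmittance(s, wref).curves, 0.0)

    def test_half_power_gives_half(self, small_grid, rng):
        w = rng.random((3, 8, 8)) + 0.5
        s, wref = self._pair(0.5 * w, w, small_grid)
        assert np.max(np.abs(compute_transmittance(s, wref).curves - 0.5)) < 1e-12

    def test_nonpositive_white_names_band_and_tile(self, small_grid):
        w = np.ones((3, 8, 8))
        w[1, 5, 2] = 0.0  # tile (1, 0), band 425 nm
        s, wref = self._pair(np.ones((3, 8, 8)), np.zeros((3, 8, 8)), small_grid)
        wref = type(wref)(
            curves=np.zeros_like(wref.curves), grid=small_grid,
            labels=wref.labels, provenance=wref.provenance,
        )
        with pytest.raises(DivisionDomainError, match=r"tile \(0, 0\).*420"):
            compute_transmittance(s, wref)

    def test_super_unity_flagged_not_clipped(self, small_grid, rng):
        w = np.ones((3, 8, 8))
        s_data = np.ones((3, 8, 8))
        s_data[:, :4, :4] = 1.2  # first tile exceeds the white level
        s, wref = self._pair(s_data, w, small_grid)
        tau = compute_transmittance(s, wref)
        assert tau.flagged[0]
        assert not tau.flagged[1:].any()
        assert tau.curves[0, 0] == pytest.approx(1.2)

    def test_misaligned_sets_rejected(self, small_grid, rng):
        s, wref = self._pair(rng.random((3, 8, 8)), np.ones((3, 8, 8)), small_grid)
        with pytest.raises(ConfigurationError):
            compute_transmittance(s, wref.subset([0, 1, 3, 2]))


class TestPipelineOrderAndRecovery:
    def test_average_then_divide_is_the_fixed_order(self, grid, library):
        """Under non-flat illumination the two orders differ; ours is average-then-divide."""
        tau_true = mixture_spectrum(library, "Q", "F", 80.0)
        sample, white = simulate_cube_pair(
            tau_true, grid, dims=(8, 8), noise=NoiseModel(sigma_read=0.0), seed=3
        )
        s = average_neighborhoods(sample)
        w = average_neighborhoods(white)
        ours = compute_transmittance(s, w).curves

        # reference: explicit average-then-divide
        avg_then_div = s.curves / w.curves
        assert np.max(np.abs(ours - avg_then_div)) == 0.0

        # divide-then-average differs once the illumination varies in a tile
        ratio_cube = Hypercube(
            data=sample.data / white.data, grid=grid, kind="sample"
        )
        div_then_avg = average_neighborhoods(ratio_cube).curves
        assert np.max(np.abs(ours - div_then_avg)) > 0.0

    def test_noiseless_end_to_end_recovery(self, grid, library):
        """sigma_read = 0: the full path reproduces the generating mixture."""
        tau_true = mixture_spectrum(library, "GS", "M", 70.0)
        sample, white = simulate_cube_pair(
            tau_true, grid, dims=(16, 16), noise=NoiseModel(sigma_read=0.0), seed=0
        )
        tau = compute_transmittance(
            average_neighborhoods(sample), average_neighborhoods(white)
        )
        assert np.max(np.abs(tau.curves - tau_true[None, :])) < 1e-10


class TestSubsample:
    def _curves(self, grid, n_per_class, classes):
        n = n_per_class * len(classes)
        rng = np.random.default_rng(0)
        labels = np.repeat(classes, n_per_class)
        prov = pd.DataFrame(
            {"cube_id": labels, "tile_row": np.arange(n), "tile_col": np.zeros(n, int)}
        )
        return SpectralCurveSet(
            curves=rng.random((n, grid.n_bands)), grid=grid,
            labels=labels.astype(object), provenance=prov,
        )

    def test_exact_population_is_identity_up_to_order(self, small_grid):
        cs = self._curves(small_grid, 10, ["a", "b"])
        out = subsample_curves(cs, n_per_class=10, seed=0)
        assert sorted(out.provenance["tile_row"]) == list(range(20))

    def test_deterministic_and_distinct(self, small_grid):
        cs = self._curves(small_grid, 100, ["a", "b", "c", "d"])
        out1 = subsample_curves(cs, n_per_class=10, seed=42)
        out2 = subsample_curves(cs, n_per_class=10, seed=42)
        assert np.array_equal(
            out1.provenance["tile_row"].to_numpy(), out2.provenance["tile_row"].to_numpy()
        )
        assert out1.n_curves == 40
        assert out1.provenance["tile_row"].nunique() == 40
        counts = pd.Series(out1.labels).value_counts()
        assert set(counts) == {10}

    def test_small_class_names_the_class(self, small_grid):
        cs = self._curves(small_grid, 5, ["a", "b"])
        with pytest.raises(SamplingError, match="'a'"):
            subsample_curves(cs, n_per_class=6, seed=0)


class TestPersistence:
    def test_csv_and_hdf5_mirror(self, small_grid, rng, tmp_path):
        cs = average_neighborhoods(
            _cube(rng.random((3, 8, 8)), small_grid), label="x", cube_id="c0"
        )
        csv_path = tmp_path / "curves.csv"
        h5_path = tmp_path / "curves.h5"
        cs.to_csv(csv_path)
        cs.to_hdf5(h5_path)
        from_csv = SpectralCurveSet.from_csv(csv_path)
        from_h5 = SpectralCurveSet.from_hdf5(h5_path)
        assert np.max(np.abs(from_csv.curves - from_h5.curves)) < 1e-9
        assert np.array_equal(from_csv.labels, from_h5.labels)
        assert from_csv.grid == cs.grid
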