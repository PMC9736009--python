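"""Sum-of-sines fitting: initialization, canonical form, fits, feature matrix."""

import numpy as np
import pandas as pd
import pytest

from honeyspec import (
    FeatureMatrix,
    NoiseModel,
    SpectralCurveSet,
    SumOfSinesFit,
    SumOfSinesModel,
    WavelengthGrid,
    average_neighborhoods,
    build_feature_matrix,
    canonicalize,
    compute_transmittance,
    fit_sum_of_sines,
    initialize_sine_parameters,
    mixture_spectrum,
    reconstruct_spectrum,
    simulate_cube_pair,
)


def _eval_terms(terms, lam):
    return sum(a * np.sin(b * lam + c) for a, b, c in np.asarray(terms).reshape(-1, 3))


def _well_separated_terms(grid, n_terms, seed):
    """Random canonical terms whose frequencies sit >= 2 FFT bins apart."""
    rng = np.random.default_rng(seed)
    bin_width = 2.0 * np.pi / (grid.span + grid.step)
    ks = np.sort(rng.choice(np.arange(2, 40, 3), n_terms, replace=False))
    bs = ks * bin_width * 1.013  # deliberately off-bin
    return np.column_stack(
        [rng.uniform(0.1, 0.6, n_terms), bs, rng.uniform(-3.0, 3.0, n_terms)]
    )


class TestInitialization:
    def test_single_sinusoid_frequency_within_one_bin(self, grid):
        lam = grid.values
        curve = 0.5 * np.sin(0.03 * lam)
        init = initialize_sine_parameters(curve, grid, n_terms=3)
        top = init[np.argmax(init[:, 0])]
        bin_width = 2.0 * np.pi / (grid.n_bands * grid.step)
        assert abs(top[1] - 0.03) <= bin_width

    def test_constant_curve_all_amplitudes_zero(self, grid):
        init = initialize_sine_parameters(np.full(grid.n_bands, 0.4), grid, n_terms=4)
        assert np.allclose(init[:, 0], 0.0)

    def test_two_separated_sinusoids_both_recovered(self, grid):
        lam = grid.values
        curve = 0.4 * np.sin(0.05 * lam + 0.3) + 0.2 * np.sin(0.2 * lam - 1.0)
        init = initialize_sine_parameters(curve, grid, n_terms=2)
        bin_width = 2.0 * np.pi / (grid.n_bands * grid.step)
        found = np.sort(init[:, 1])
        assert abs(found[0] - 0.05) <= bin_width
        assert abs(found[1] - 0.2) <= bin_width

    def test_too_short_curve_rejected(self):
        grid = WavelengthGrid(np.linspace(420, 440, 21))
        from honeyspec.exceptions import ConfigurationError

        with pytest.raises(ConfigurationError):
            initialize_sine_parameters(np.zeros(21), grid, n_terms=8)


class TestCanonicalization:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_idempotent_and_reconstruction_invariant(self, grid, seed):
        rng = np.random.default_rng(seed)
        terms = np.column_stack(
            [rng.normal(0, 1, 6), rng.normal(0, 0.2, 6), rng.uniform(-9, 9, 6)]
        )
        canon = canonicalize(terms)
        assert np.array_equal(canonicalize(canon), canon)
        assert np.all(canon[:, 0] >= 0)
        assert np.all(canon[:, 1] >= 0)
        assert np.all((canon[:, 2] > -np.pi) & (canon[:, 2] <= np.pi))
        assert np.all(np.diff(canon[:, 1]) >= 0)
        lam = grid.values
        assert np.max(np.abs(_eval_terms(terms, lam) - _eval_terms(canon, lam))) < 1e-9


class TestFitting:
    def test_exact_single_sinusoid_identity(self, grid):
        lam = grid.values
        curve = 0.7 * np.sin(0.02 * lam + 1.0)
        fit = fit_sum_of_sines(curve, grid, n_terms=1)
        assert fit.rmse < 1e-8
        assert np.max(np.abs(fit.predict() - curve)) < 1e-6
        assert fit.converged

    def test_eight_seeded_terms_reconstructed(self, grid):
        """Generator-as-oracle: reconstruction quality, not raw coefficients."""
        terms = _well_separated_terms(grid, 8, seed=7)
        curve = _eval_terms(terms, grid.values)
        fit = fit_sum_of_sines(curve, grid, n_terms=8)
        assert fit.rmse < 1e-3

    def test_synthetic_mixture_curves_under_one_percent(self, grid, library):
        """Smooth honey/syrup blends compress to < 1% RMSE of full scale."""
        for honey, syrup, frac in [("Q", "F", 90.0), ("GS", "M", 60.0), ("Q", "G", 75.0)]:
            curve = mixture_spectrum(library, honey, syrup, frac)
            fit = fit_sum_of_sines(curve, grid)
            assert fit.rmse < 0.01

    def test_monotone_capacity_with_warm_start(self, grid, library):
        """8 terms warm-started from the 5-term solution never fit worse."""
        rng = np.random.default_rng(11)
        count = 0
        for _ in range(20):
            h, s = rng.choice(["Q", "GS"]), rng.choice(["F", "G", "M"])
            frac = rng.uniform(60, 100)
            curve = mixture_spectrum(library, h, s, frac) + 0.002 * rng.standard_normal(
                grid.n_bands
            )
            fit5 = fit_sum_of_sines(curve, grid, n_terms=5)
            fit8 = fit_sum_of_sines(curve, grid, n_terms=8, initial=fit5.terms)
            assert fit8.rmse <= fit5.rmse + 1e-12
            count += 1
        assert count == 20

    def test_unconverged_flag_never_raises(self, grid):
        """A hopeless curve still returns a best-so-far fit object."""
        rng = np.random.default_rng(0)
        noise = rng.standard_normal(grid.n_bands)
        fit = fit_sum_of_sines(noise, grid, n_terms=1, restarts=1)
        assert isinstance(fit, SumOfSinesFit)
        assert fit.rmse > 0

    def test_summary_mentions_rmse(self, grid, library):
        fit = fit_sum_of_sines(mixture_spectrum(library, "Q", "F", 90.0), grid)
        text = fit.summary()
        assert "rmse" in text and "terms: 8" in text


class TestReconstruction:
    def test_zero_term_fit_is_zero_curve(self, grid):
        fit = SumOfSinesFit(
            terms=np.empty((0, 3)), grid=grid, rmse=0.0, converged=True
        )
        assert np.array_equal(reconstruct_spectrum(fit), np.zeros(grid.n_bands))

    def test_zero_frequency_quarter_phase_is_constant_one(self, grid):
        fit = SumOfSinesFit(
            terms=np.array([[1.0, 0.0, np.pi / 2]]), grid=grid, rmse=0.0, converged=True
        )
        assert np.allclose(reconstruct_spectrum(fit), 1.0)

    def test_roundtrip_rmse_consistency(self, grid, library):
        curve = mixture_spectrum(library, "GS", "F", 80.0)
        fit = fit_sum_of_sines(curve, grid)
        recon = reconstruct_spectrum(fit, grid)
        recomputed = np.sqrt(np.mean((curve - recon) ** 2))
        assert recomputed == pytest.approx(fit.rmse, abs=1e-12)


def _curve_set(grid, curves, labels):
    n = curves.shape[0]
    prov = pd.DataFrame(
        {"cube_id": ["x"] * n, "tile_row": np.arange(n), "tile_col": np.zeros(n, int)}
    )
    return SpectralCurveSet(
        curves=curves, grid=grid, labels=np.asarray(labels, object), provenance=prov
    )


class TestFeatureMatrix:
    def test_default_width_is_24_and_rows_align(self, grid, library):
        curves = np.array(
            [mixture_spectrum(library, "Q", "F", f) for f in (90.0, 80.0, 70.0, 60.0)]
        )
        fm = build_feature_matrix(_curve_set(grid, curves, ["90", "80", "70", "60"]))
        assert fm.values.shape == (4, 24)
        assert list(fm.labels) == ["90", "80", "70", "60"]
        # 311 bands -> 24 numbers: the advertised ~13x reduction
        assert grid.n_bands / fm.values.shape[1] > 12

    def test_duplicates_and_permutations(self, grid, library):
        base = np.array(
            [
                mixture_spectrum(library, "Q", "F", 90.0),
                mixture_spectrum(library, "Q", "F", 60.0),
            ]
        )
        curves = np.vstack([base, base[0]])
        fm = build_feature_matrix(_curve_set(grid, curves, ["a", "b", "a"]))
        assert np.array_equal(fm.values[0], fm.values[2])

        perm = [1, 2, 0]
        fm_perm = build_feature_matrix(
            _curve_set(grid, curves[perm], np.array(["a", "b", "a"], object)[perm])
        )
        assert np.allclose(fm_perm.values, fm.values[perm])

    def test_feature_stability_under_noise(self, grid, library):
        """Reconstructions from two noisy realizations differ < 3 sigma rms."""
        tau = mixture_spectrum(library, "GS", "G", 80.0)
        sigma = 0.004
        recon = []
        for seed in (21, 22):
            sample, white = simulate_cube_pair(
                tau, grid, dims=(4, 4), noise=NoiseModel(sigma_read=sigma), seed=seed
            )
            t = compute_transmittance(
                average_neighborhoods(sample), average_neighborhoods(white)
            )
            fit = fit_sum_of_sines(t.curves[0], grid)
            recon.append(fit.predict())
        diff_rms = np.sqrt(np.mean((recon[0] - recon[1]) ** 2))
        assert diff_rms < 3 * sigma

    def test_csv_roundtrip(self, grid, library, tmp_path):
        curves = np.array([mixture_spectrum(library, "Q", "M", 70.0)])
        fm = build_feature_matrix(_curve_set(grid, curves, ["70"]))
        path = tmp_path / "features.csv"
        meta = tmp_path / "features.json"
        fm.to_csv(path, metadata_path=meta)
        back = FeatureMatrix.from_csv(path, metadata_path=meta)
        assert np.allclose(back.values, fm.values, rtol=0, atol=1e-12)
        assert back.n_terms == 8
        assert back.metadata["restarts"] == fm.metadata["restarts"]
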