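"""Estimators, fluctuation formulas, fits and the RDF calculator."""

import numpy as np
import pytest

from conftest import make_point_frames, make_water_frames
from triwater.constants import AVOGADRO, BOLTZMANN, GAS_CONSTANT, NM
from triwater.observables import (
    CoexistenceTable,
    CorrectionTable,
    ObservableSeries,
    compute_rdf,
    critical_point_fit,
    density,
    dielectric_scaling,
    enthalpy_vaporization,
    extrapolate_D0,
    heat_capacity_isobaric,
    isothermal_compressibility,
    scaled_dielectric,
    self_diffusion,
    static_dielectric,
    surface_tension,
    temperature_of_max_density,
    thermal_expansion,
    wegner_densities,
)
from triwater.surrogate import gen_dipole_series, gen_fluctuation_series


def series(values, kind, dt=1.0, units=""):
    return ObservableSeries(values=np.asarray(values, float), dt=dt, units=units, kind=kind)


# ---------------------------------------------------------------------------
# RDF


class TestComputeRdf:
    def test_ideal_gas_is_flat(self, rng):
        """Uniform random points give g(r) = 1 away from zero distance."""
        frames = []
        from triwater.io import Frame

        for k in range(40):
            pos = np.random.default_rng(k).uniform(0, 3.0, size=(400, 3))
            frames.append(Frame(names=("O",) * 400, positions=pos, box=np.full(3, 3.0)))
        g = compute_rdf(frames, "OO", cutoff=10.0, n_bins=100)
        window = (g.bin_centers >= 3.0) & (g.bin_centers <= 10.0)
        assert np.all(np.abs(g.g_values[window] - 1.0) < 0.05)

    def test_single_pair_occupies_one_bin(self):
        frames = make_point_frames([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]], box_nm=4.0)
        g = compute_rdf(frames, "OO", cutoff=10.0, n_bins=500)
        nonzero = np.nonzero(g.g_values)[0]
        assert len(nonzero) == 1
        assert abs(g.bin_centers[nonzero[0]] - 5.0) <= 0.01  # the bin containing 5 A

    def test_cubic_lattice_first_peak_at_lattice_constant(self):
        a = 0.4  # nm
        pts = np.array(
            [[i * a, j * a, k * a] for i in range(4) for j in range(4) for k in range(4)]
        )
        frames = make_point_frames(pts, box_nm=4 * a)
        g = compute_rdf(frames, "OO", cutoff=7.9, n_bins=200)
        first_peak = g.bin_centers[np.nonzero(g.g_values)[0][0]]
        assert first_peak == pytest.approx(a * 10.0, abs=g.bin_centers[1] - g.bin_centers[0])

    def test_integral_recovers_pair_count(self, rng):
        """sum g * 4 pi r^2 dr * rho_pair equals the brute-force pair count."""
        n = 40
        pos = rng.uniform(0, 2.0, size=(n, 3))
        box = 2.0
        frames = make_point_frames(pos, box_nm=box)
        cutoff = 9.0
        g = compute_rdf(frames, "OO", cutoff=cutoff, n_bins=300)
        dr = g.bin_centers[1] - g.bin_centers[0]
        rho_pair = (n * (n - 1) / 2.0) / (box**3 * 1000.0)
        integral = np.sum(g.g_values * 4 * np.pi * g.bin_centers**2 * dr) * rho_pair

        diff = pos[:, None, :] - pos[None, :, :]
        diff -= box * np.round(diff / box)
        d = np.linalg.norm(diff, axis=-1) * 10.0
        brute = np.sum(np.triu(d <= cutoff, k=1))
        assert integral == pytest.approx(brute, rel=0.02)

    def test_oh_cross_pair_selection(self):
        frames = make_water_frames(30, box_nm=2.5, n_frames=2)
        g = compute_rdf(frames, "OH", cutoff=10.0, n_bins=200)
        # intramolecular O-H peak at 0.957 A must be present
        assert g.g_values[(g.bin_centers > 0.8) & (g.bin_centers < 1.1)].max() > 1.0

    def test_cutoff_beyond_half_box_errors(self):
        frames = make_point_frames([[0.0] * 3, [0.5] * 3], box_nm=1.5)
        with pytest.raises(ValueError, match="half the shortest box edge"):
            compute_rdf(frames, "OO", cutoff=10.0)

    def test_empty_selection_errors(self):
        frames = make_point_frames([[0.0] * 3, [0.5] * 3], box_nm=4.0)
        with pytest.raises(ValueError, match="empty selection"):
            compute_rdf(frames, "OH", cutoff=10.0)


# ---------------------------------------------------------------------------
# simple thermodynamics


class TestDensity:
    def test_hand_value(self):
        vol = series(np.full(10, 30.6), "volume")
        rho = density(1024, 18.0153, vol)
        expected = 1024 * 18.0153 / (AVOGADRO * 30.6e-21)
        assert rho == pytest.approx(expected, rel=1e-12)
        assert rho == pytest.approx(1.0011, abs=2e-4)

    def test_inverse_proportional_to_volume(self):
        v1 = series(np.full(5, 30.0), "volume")
        v2 = series(np.full(5, 60.0), "volume")
        assert density(1024, 18.0153, v1) == pytest.approx(
            2 * density(1024, 18.0153, v2), rel=1e-12
        )

    def test_fluctuating_volume_equals_its_mean(self, rng):
        v = 30.0 + 0.1 * rng.standard_normal(1000)
        rho_series = density(1024, 18.0153, series(v, "volume"))
        rho_mean = density(1024, 18.0153, series(np.full(3, v.mean()), "volume"))
        assert rho_series == pytest.approx(rho_mean, rel=1e-12)

    def test_nonpositive_volume_errors(self):
        with pytest.raises(ValueError, match="positive"):
            density(10, 18.0, series([1.0, -2.0], "volume"))


class TestStaticDielectric:
    def test_constant_dipole_gives_vacuum(self):
        m = series(np.tile([3.0, -1.0, 2.0], (50, 1)), "dipole_vector")
        assert static_dielectric(m, volume=30.0, T=298.0) == pytest.approx(1.0)

    def test_gaussian_fixture_recovers_target(self):
        m = gen_dipole_series(target_eps=78.0, V=30.0, T=298.0, n=100_000, seed=7)
        eps = static_dielectric(m, volume=30.0, T=298.0)
        assert eps == pytest.approx(78.0, rel=0.03)

    def test_doubling_dipole_quadruples_fluctuation_term(self):
        m = gen_dipole_series(target_eps=10.0, V=30.0, T=298.0, n=20_000, seed=3)
        m2 = series(2.0 * m.values, "dipole_vector")
        e1 = static_dielectric(m, 30.0, 298.0) - 1.0
        e2 = static_dielectric(m2, 30.0, 298.0) - 1.0
        assert e2 == pytest.approx(4.0 * e1, rel=1e-10)

    def test_shift_invariance(self):
        m = gen_dipole_series(target_eps=5.0, V=20.0, T=300.0, n=5000, seed=1)
        shifted = series(m.values + np.array([10.0, -4.0, 2.0]), "dipole_vector")
        assert static_dielectric(shifted, 20.0, 300.0) == pytest.approx(
            static_dielectric(m, 20.0, 300.0), rel=1e-9
        )

    def test_invalid_inputs(self):
        m = gen_dipole_series(5.0, 20.0, 300.0, 10, 0)
        with pytest.raises(ValueError):
            static_dielectric(m, 0.0, 300.0)
        with pytest.raises(ValueError):
            static_dielectric(m, 20.0, 0.0)


class TestDielectricScaling:
    @pytest.mark.parametrize("mu_pes, lam", [(2.9, 1.0), (2.43, 2.9 / 2.43), (1.45, 2.0)])
    def test_lambda_ratio(self, mu_pes, lam):
        assert dielectric_scaling(mu_pes) == pytest.approx(lam, rel=1e-12)

    def test_scaled_dielectric_examples(self):
        assert scaled_dielectric(51.0, 2.0) == pytest.approx(201.0)
        assert scaled_dielectric(64.0, 1.0) == 64.0
        assert scaled_dielectric(1.0, 7.3) == 1.0

    def test_identity_when_model_dipole_matches_dms(self):
        lam = dielectric_scaling(2.9, mu_dms=2.9)
        assert scaled_dielectric(42.0, lam) == pytest.approx(42.0)

    def test_errors(self):
        with pytest.raises(ValueError):
            dielectric_scaling(0.0)
        with pytest.raises(ValueError):
            scaled_dielectric(0.5, 1.0)


# ---------------------------------------------------------------------------
# diffusion


class TestSelfDiffusion:
    def test_exact_linear_msd(self):
        d_true = 2.3  # 1e-5 cm^2/s
        slope = d_true * 1e-5 * 100 * 6  # nm^2/ps
        t = np.arange(1000) * 0.5
        msd = series(slope * t, "msd", dt=0.5)
        assert self_diffusion(msd) == pytest.approx(d_true, rel=1e-10)

    def test_noisy_msd_within_two_percent(self, rng):
        slope = 1.5e-3
        t = np.arange(10_000) * 1.0
        msd = np.clip(slope * t + 0.05 * rng.standard_normal(len(t)), 0, None)
        d = self_diffusion(series(msd, "msd"))
        assert d == pytest.approx(slope / 6 * 1000, rel=0.02)

    def test_constant_msd_is_zero(self):
        msd = series(np.full(100, 4.2), "msd")
        assert self_diffusion(msd) == pytest.approx(0.0, abs=1e-12)

    def test_short_window_errors(self):
        with pytest.raises(ValueError, match="3 points"):
            self_diffusion(series(np.arange(10.0), "msd"), fit_window=(0.1, 0.2))


class TestExtrapolateD0:
    def test_exact_recovery(self):
        d0, k = 2.30, 1.1
        ls = np.array([2.48, 3.12, 3.94, 4.96, 6.25])
        pts = [(l, d0 - k / l) for l in ls]
        assert extrapolate_D0(pts) == pytest.approx(d0, rel=1e-12)

    def test_duplicate_box_size_errors(self):
        with pytest.raises(ValueError, match="distinct"):
            extrapolate_D0([(3.0, 2.0), (3.0, 2.1)])

    def test_noisy_intercept_within_confidence(self, rng):
        d0, k, sigma = 2.30, 1.1, 0.01
        ls = np.array([2.48, 3.12, 3.94, 4.96, 6.25])
        estimates = [
            extrapolate_D0(
                [(l, d0 - k / l + sigma * e) for l, e in zip(ls, rng.standard_normal(5))]
            )
            for _ in range(200)
        ]
        assert abs(np.mean(estimates) - d0) < 3 * np.std(estimates) / np.sqrt(200)
        assert np.std(estimates) < 5 * sigma


# ---------------------------------------------------------------------------
# vaporization enthalpy


class TestEnthalpyVaporization:
    def test_no_depolarization_at_gas_dipole(self):
        corr = CorrectionTable()
        h_match = enthalpy_vaporization(-41.5, 0.018, 298.0, 0.0, corr.mu_gas, corr)
        h_more = enthalpy_vaporization(-41.5, 0.018, 298.0, 0.0, corr.mu_gas + 0.5, corr)
        assert h_more < h_match  # E_pol only ever subtracts

    def test_ideal_terms_only(self):
        corr = CorrectionTable()
        h = enthalpy_vaporization(-41.5, 0.0, 298.0, 0.0, corr.mu_gas, corr)
        assert h == pytest.approx(41.5 + GAS_CONSTANT * 298.0 / 1000.0, rel=1e-9)
        assert h == pytest.approx(43.98, abs=0.01)

    def test_depolarization_quadratic_in_dipole_shift(self):
        corr = CorrectionTable()
        base = enthalpy_vaporization(0.0, 0.0, 298.0, 0.0, corr.mu_gas, corr)
        e1 = base - enthalpy_vaporization(0.0, 0.0, 298.0, 0.0, corr.mu_gas + 0.3, corr)
        e2 = base - enthalpy_vaporization(0.0, 0.0, 298.0, 0.0, corr.mu_gas + 0.6, corr)
        assert e2 == pytest.approx(4.0 * e1, rel=1e-9)

    def test_depolarization_magnitude_is_physical(self):
        """SPC/E-like dipole shift costs ~5 kJ/mol."""
        corr = CorrectionTable(mu_gas=1.85, alpha_gas=1.444)
        base = enthalpy_vaporization(0.0, 0.0, 298.0, 0.0, corr.mu_gas, corr)
        e_pol = base - enthalpy_vaporization(0.0, 0.0, 298.0, 0.0, 2.35, corr)
        assert e_pol == pytest.approx(5.2, abs=0.4)

    def test_temperature_outside_table_errors(self):
        corr = CorrectionTable(temperatures=[280.0, 320.0], dhvap_corr=[0.1, 0.2], cp_corr=[0, 0])
        with pytest.raises(ValueError, match="outside correction table"):
            enthalpy_vaporization(-41.5, 0.018, 350.0, 1.0, 2.3, corr)


# ---------------------------------------------------------------------------
# fluctuation formulas


class TestHeatCapacity:
    def test_constant_enthalpy_gives_correction_only(self):
        h = series(np.full(100, -5000.0), "enthalpy")
        assert heat_capacity_isobaric(h, 298.0, 1024, correction=9.3) == pytest.approx(9.3)

    def test_gaussian_closed_form(self):
        n_mol, t = 1024, 298.0
        var = 2000.0  # (kJ/mol)^2
        h, _ = gen_fluctuation_series(
            "enthalpy_volume", mean=(-5.7e4, 30.6), variance=(var, 1e-4), n=100_000, seed=11
        )
        cp = heat_capacity_isobaric(h, t, n_mol)
        expected = var * 1e6 / (AVOGADRO * n_mol * BOLTZMANN * t**2)
        assert cp == pytest.approx(expected, rel=0.03)

    def test_quarter_at_double_temperature(self):
        h, _ = gen_fluctuation_series(
            "enthalpy_volume", mean=(0.0, 30.0), variance=(100.0, 1.0), n=2000, seed=2
        )
        c1 = heat_capacity_isobaric(h, 300.0, 512)
        c2 = heat_capacity_isobaric(h, 600.0, 512)
        assert c2 == pytest.approx(c1 / 4.0, rel=1e-12)

    def test_shift_invariance(self):
        h, _ = gen_fluctuation_series(
            "enthalpy_volume", mean=(0.0, 30.0), variance=(50.0, 1.0), n=4000, seed=5
        )
        shifted = series(h.values + 1e4, "enthalpy")
        assert heat_capacity_isobaric(shifted, 298.0, 256) == pytest.approx(
            heat_capacity_isobaric(h, 298.0, 256), rel=1e-9
        )


class TestThermalExpansion:
    def test_independent_series_give_zero(self):
        h, v = gen_fluctuation_series(
            "enthalpy_volume",
            mean=(-5.7e4, 30.6),
            variance=(2000.0, 0.01),
            covariance=0.0,
            n=100_000,
            seed=13,
        )
        alpha = thermal_expansion(h, v, 298.0)
        # standard error of the covariance-based estimator
        se = np.sqrt(2000.0 * 0.01 / len(h)) * 1e3 / AVOGADRO * NM**3
        se_alpha = se / (30.6 * NM**3 * BOLTZMANN * 298.0**2)
        assert abs(alpha) < 3 * se_alpha

    def test_proportional_series_closed_form(self):
        c = 1e-4  # nm^3 per kJ/mol
        h, _ = gen_fluctuation_series(
            "enthalpy_volume", mean=(0.0, 1.0), variance=(400.0, 1.0), n=50_000, seed=17
        )
        v = series(30.0 + c * h.values, "volume")
        alpha = thermal_expansion(h, v, 298.0)
        var_h_j = np.var(h.values) * (1e3 / AVOGADRO) ** 2
        expected = (
            c * var_h_j * (NM**3 / (1e3 / AVOGADRO))
            / (np.mean(v.values) * NM**3 * BOLTZMANN * 298.0**2)
        )
        assert alpha == pytest.approx(expected, rel=1e-9)

    def test_constant_volume_is_zero(self):
        h, _ = gen_fluctuation_series(
            "enthalpy_volume", mean=(0.0, 1.0), variance=(10.0, 1.0), n=500, seed=3
        )
        v = series(np.full(500, 30.0), "volume")
        assert thermal_expansion(h, v, 298.0) == pytest.approx(0.0, abs=1e-15)

    def test_length_mismatch_errors(self):
        h = series(np.zeros(10), "enthalpy")
        v = series(np.ones(11), "volume")
        with pytest.raises(ValueError, match="equal length"):
            thermal_expansion(h, v, 298.0)


class TestIsothermalCompressibility:
    def test_constant_volume_is_zero(self):
        v = series(np.full(100, 30.0), "volume")
        assert isothermal_compressibility(v, 298.0) == pytest.approx(0.0, abs=1e-20)

    def test_gaussian_closed_form(self):
        var, mean, t = 0.04, 30.6, 298.0
        _, v = gen_fluctuation_series(
            "enthalpy_volume", mean=(0.0, mean), variance=(1.0, var), n=100_000, seed=19
        )
        kappa = isothermal_compressibility(v, t)
        expected = var * NM**6 / (mean * NM**3 * BOLTZMANN * t) * 1e5
        assert kappa == pytest.approx(expected, rel=0.03)

    def test_linear_in_variance(self):
        _, v1 = gen_fluctuation_series(
            "enthalpy_volume", mean=(0.0, 30.0), variance=(1.0, 0.01), n=20_000, seed=23
        )
        m = v1.values.mean()  # double the fluctuation about the sample mean
        v4 = series(m + 2.0 * (v1.values - m), "volume")
        k1 = isothermal_compressibility(v1, 298.0)
        k4 = isothermal_compressibility(v4, 298.0)
        assert k4 == pytest.approx(4.0 * k1, rel=1e-6)


class TestSurfaceTension:
    def test_isotropic_pressure_gives_zero(self):
        p = series(np.tile([500.0, 500.0, 500.0], (100, 1)), "pressure_diagonal")
        assert surface_tension(p, L_z=12.0) == pytest.approx(0.0, abs=1e-10)

    def test_hundred_bar_anisotropy(self):
        p = series(np.tile([0.0, 0.0, 100.0], (10, 1)), "pressure_diagonal")
        # (10/2) * 100 bar nm = 500 bar nm = 50 mN/m
        assert surface_tension(p, L_z=10.0) == pytest.approx(50.0, rel=1e-12)

    def test_xy_swap_symmetry(self, rng):
        vals = rng.normal(100.0, 10.0, size=(200, 3))
        p = series(vals, "pressure_diagonal")
        p_swapped = series(vals[:, [1, 0, 2]], "pressure_diagonal")
        assert surface_tension(p, 8.0) == pytest.approx(surface_tension(p_swapped, 8.0))

    def test_nonpositive_lz_errors(self):
        p = series(np.zeros((5, 3)), "pressure_diagonal")
        with pytest.raises(ValueError, match="L_z"):
            surface_tension(p, 0.0)


# ---------------------------------------------------------------------------
# critical point & TMD


TRUE_WEGNER = dict(T_c=630.0, rho_c=0.327, B_0=0.9, B_1=0.2, C_2=0.25)


class TestCriticalPointFit:
    def test_noise_free_round_trip(self):
        t = np.arange(350.0, 551.0, 25.0)
        rl, rv = wegner_densities(t, **TRUE_WEGNER)
        fit = critical_point_fit(CoexistenceTable(t, rl, rv))
        for name, value in TRUE_WEGNER.items():
            fitted = getattr(fit, name)
            assert fitted == pytest.approx(value, rel=1e-4), name

    def test_one_percent_noise_tc_scatter(self):
        """With 1% density noise on a grid reaching 10 K below T_c, every
        fitted T_c lands within the +-4 K uncertainty scale."""
        from triwater.surrogate import gen_coexistence_table

        t = np.arange(350.0, 621.0, 10.0)
        tcs = np.array(
            [
                critical_point_fit(
                    gen_coexistence_table(temperatures=t, noise=0.01, seed=s, **TRUE_WEGNER)
                ).T_c
                for s in range(20)
            ]
        )
        assert np.max(np.abs(tcs - TRUE_WEGNER["T_c"])) <= 4.0

    def test_inverted_densities_rejected(self):
        with pytest.raises(ValueError, match="rho_liq"):
            CoexistenceTable(np.array([400.0, 450.0]), np.array([0.1, 0.1]), np.array([0.5, 0.4]))

    def test_too_few_rows_errors(self):
        t = np.array([400.0, 450.0, 500.0])
        rl, rv = wegner_densities(t, **TRUE_WEGNER)
        with pytest.raises(ValueError, match="at least 4"):
            critical_point_fit(CoexistenceTable(t, rl, rv))


class TestTemperatureOfMaxDensity:
    def test_exact_parabola(self):
        t = np.arange(261.0, 293.0, 2.0)
        rho = 1.0 - 1e-5 * (t - 277.0) ** 2
        assert temperature_of_max_density(np.column_stack([t, rho])) == pytest.approx(277.0)

    def test_noisy_parabola_within_one_kelvin(self):
        t = np.arange(261.0, 293.0, 2.0)
        hits = 0
        for s in range(50):
            rho = 1.0 - 1e-5 * (t - 277.0) ** 2 + 1e-4 * np.random.default_rng(s).standard_normal(len(t))
            est = temperature_of_max_density(np.column_stack([t, rho]))
            hits += abs(est - 277.0) <= 1.0
        assert hits >= 40  # +-1 K is the grid's quoted uncertainty, not a hard bound

    def test_monotone_table_errors(self):
        t = np.arange(260.0, 280.0, 2.0)
        rho = 0.9 + 1e-4 * t
        with pytest.raises(ValueError, match="maximum"):
            temperature_of_max_density(np.column_stack([t, rho]))
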