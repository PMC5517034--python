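"""Lyapunov spectra, epochs, power spectra, Poincare sections."""

import math
import warnings

import numpy as np
import pytest

import ecochaos as ec
from ecochaos.chaos import LocalExponentSeries
from _helpers import make_traj


class TestKaplanYorke:
    @pytest.mark.parametrize(
        "spectrum, expected",
        [
            ((0.003, 0.0, -0.3), 2.01),
            ((-0.1, -0.2, -0.3), 0.0),
            ((0.1, 0.0, -0.2), 2.5),
            ((0.0, -1.0, -2.0), 1.0),
        ],
    )
    def test_known_values(self, spectrum, expected):
        assert ec.kaplan_yorke(spectrum) == pytest.approx(expected)

    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            ec.kaplan_yorke((0.0, 0.1, -0.2))

    def test_dimension_bounds_on_random_dissipative_spectra(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            lam = np.sort(rng.uniform(-1, 0.5, 3))[::-1]
            if lam.sum() >= 0:  # keep dissipative
                lam[2] -= lam.sum() + 0.1
            d = ec.kaplan_yorke(lam)
            assert 0.0 <= d < 3.0


class TestBenettin:
    def test_equilibrium_spectrum_equals_jacobian_eigenvalues(
        self, params, interior_equilibrium
    ):
        eig = np.linalg.eigvals(ec.jacobian(interior_equilibrium, params))
        expected = np.sort(eig.real)[::-1]
        res = ec.benettin_spectrum(
            params, ic=interior_equilibrium, t_total=3000.0, t_transient=0.0
        )
        assert np.allclose(res.exponents, expected, atol=5e-4)

    def test_numba_and_scipy_backends_agree(self, params):
        kw = dict(ic=(0.5, 0.5, 0.5), t_total=500.0, t_transient=100.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = ec.benettin_spectrum(params, **kw)
            b = ec.benettin_spectrum(params, backend="scipy", **kw)
        assert np.allclose(a.exponents, b.exponents, atol=1e-6)

    def test_spectrum_shape_on_chaotic_attractor(self, lyap_chaotic):
        lam = lyap_chaotic.exponents
        assert lam[0] > lam[1] > lam[2]
        assert sum(lam) < 0  # dissipative
        assert abs(lam[1]) < 2e-4  # neutral flow direction
        assert lyap_chaotic.converged

    def test_sum_of_exponents_matches_phase_space_contraction(
        self, chaotic_traj, lyap_chaotic
    ):
        """Sum of exponents = ergodic average of the Jacobian trace (2%)."""
        p = chaotic_traj.params
        states = chaotic_traj.states
        x, y, c = states[:, 0], states[:, 1], states[:, 2]
        hx = 1.0 / (1.0 + p.b2 * x)
        hc = 1.0 / (1.0 + p.b1 * c)
        trace = (
            (p.a1 * c * hc - p.a2 * y * hx - p.d1 + x * p.a2 * p.b2 * y * hx * hx)
            + (p.ya * p.a2 * x * hx - p.d2)
            + (
                p.V * (2 * p.k2 * p.d1 - 4 * p.k4 * p.d1 * c * c - p.a1 * p.k1 * x * hc)
                + c * p.V * (-8 * p.k4 * p.d1 * c + p.a1 * p.k1 * x * p.b1 * hc * hc)
            )
        )
        assert sum(lyap_chaotic.exponents) == pytest.approx(trace.mean(), rel=0.02)

    def test_invariant_to_renormalization_interval(self, params):
        a = ec.benettin_spectrum(params, t_total=3.0e4, renorm_interval=1.0)
        b = ec.benettin_spectrum(params, t_total=3.0e4, renorm_interval=0.5)
        assert abs(a.exponents[0] - b.exponents[0]) < max(
            0.2 * abs(a.exponents[0]), 5e-4
        )
        assert a.exponents[2] == pytest.approx(b.exponents[2], rel=0.01)

    def test_rejects_boundary_initial_condition(self, params):
        with pytest.raises(ValueError):
            ec.benettin_spectrum(params, ic=(0.0, 0.5, 0.5), t_total=100.0)


class TestLocalExponents:
    def test_constant_series_at_equilibrium(self, params, interior_equilibrium):
        t = np.arange(0.0, 10.0, 0.1)
        states = np.tile(np.asarray(interior_equilibrium), (len(t), 1))
        series = ec.local_exponents(make_traj(t, states, params))
        expected = np.sort(np.linalg.eigvals(ec.jacobian(interior_equilibrium, params)).real)[::-1]
        assert np.allclose(series.lambdas, expected, atol=1e-12)
        assert np.all(np.diff(series.lambdas, axis=1) <= 0)

    def test_eigenvalues_solve_characteristic_polynomial(self, params, chaotic_traj):
        """Each reported eigenvalue real part comes from a root of det(J - z I)."""
        rng = np.random.default_rng(3)
        idx = rng.choice(len(chaotic_traj), 10, replace=False)
        sub = make_traj(
            np.arange(10) * 0.1, chaotic_traj.states[np.sort(idx)], params
        )
        series = ec.local_exponents(sub)
        for i, s in enumerate(sub.states):
            J = ec.jacobian(ec.EcoState(*s), params)
            # characteristic cubic z^3 + a z^2 + b z + c from trace/minors
            a = -np.trace(J)
            b = 0.5 * (np.trace(J) ** 2 - np.trace(J @ J))
            c = -np.linalg.det(J)
            roots = np.roots([1.0, a, b, c])
            assert np.allclose(
                np.sort(roots.real)[::-1], series.lambdas[i], atol=1e-8
            )

    def test_largest_exponent_has_big_excursions(self, chaotic_traj):
        series = ec.local_exponents(chaotic_traj)
        lam1 = series.lambda1
        med = np.median(lam1)
        assert np.mean(lam1 < 0.2) > 0.9  # mostly below the epoch threshold
        assert lam1.max() > 10 * med  # order-of-magnitude excursions


class TestEpochs:
    def test_square_wave_run_lengths(self, params):
        lam1 = np.array([1, 1, 1, 0, 0, 1], dtype=float)
        t = np.arange(6.0)
        series = LocalExponentSeries(t, np.column_stack([lam1, lam1 - 2, lam1 - 3]))
        dist = ec.detect_epochs(series, threshold=0.5, min_duration=0.0)
        assert sorted(dist.run_lengths.tolist()) == [1.0, 3.0]

    def test_all_below_threshold_gives_empty(self):
        t = np.arange(10.0)
        lam = np.zeros((10, 3)) - 1.0
        dist = ec.detect_epochs(LocalExponentSeries(t, lam), threshold=0.2)
        assert len(dist) == 0

    def test_min_duration_filters_chatter(self):
        lam1 = np.array([0, 1, 0, 1, 1, 1, 1, 0], dtype=float)
        t = np.arange(8.0)
        series = LocalExponentSeries(t, np.column_stack([lam1, lam1, lam1]))
        dist = ec.detect_epochs(series, threshold=0.5, min_duration=2.0)
        assert dist.run_lengths.tolist() == [4.0]

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            ec.detect_epochs(LocalExponentSeries(np.array([]), np.empty((0, 3))))

    def test_halves_of_long_run_agree(self, chaotic_traj):
        """Quasi-ergodicity: epoch medians from disjoint halves within 50%."""
        series = ec.local_exponents(chaotic_traj)
        half = len(series.times) // 2
        d1 = ec.detect_epochs(LocalExponentSeries(series.times[:half], series.lambdas[:half]))
        d2 = ec.detect_epochs(LocalExponentSeries(series.times[half:], series.lambdas[half:]))
        m1, m2 = np.median(d1.run_lengths), np.median(d2.run_lengths)
        assert abs(m1 - m2) <= 0.5 * max(m1, m2)


class TestPowerSpectrum:
    def test_sinusoid_peak_frequency(self, params):
        t = np.arange(0.0, 819.2, 0.1)
        x = 1.5 + 0.5 * np.sin(2 * np.pi * 0.7 * t)
        states = np.column_stack([x, np.ones_like(t), np.ones_like(t)])
        f, p = ec.power_spectrum(make_traj(t, states, params), "x")
        assert f[np.argmax(p)] == pytest.approx(0.7, abs=0.01)

    def test_chaos_is_spectrally_flatter_than_cycle(self, chaotic_traj, limit_cycle_traj):
        f1, p1 = ec.power_spectrum(chaotic_traj, "x")
        f2, p2 = ec.power_spectrum(limit_cycle_traj, "x")
        band = 0.25  # cycles per time unit; the dynamics live below this
        fl_chaos = ec.spectral_flatness(p1[f1 <= band])
        fl_cycle = ec.spectral_flatness(p2[f2 <= band])
        assert fl_chaos > fl_cycle

    def test_rejects_nonuniform_sampling(self, params):
        t = np.array([0.0, 0.1, 0.3, 0.4] + list(np.arange(0.5, 500, 0.1)))
        states = np.ones((len(t), 3))
        with pytest.raises(ValueError):
            ec.power_spectrum(make_traj(t, states, params), "x")


class TestPoincare:
    def test_circle_crosses_at_one_point(self, params):
        t = np.arange(0.0, 100.0, 0.01)
        states = np.column_stack(
            [np.cos(2 * np.pi * t / 5), np.sin(2 * np.pi * t / 5), np.ones_like(t)]
        )
        sec = ec.poincare_section(make_traj(t, states, params), ("x", 0.0, 1))
        assert len(sec) >= 10
        assert np.ptp(sec.points[:, 0]) < 1e-3  # y at crossing: always -1
        assert np.allclose(sec.points[:, 0], -1.0, atol=1e-3)

    def test_crossing_count_scales_with_duration(self, params, chaotic_traj):
        n_full = len(ec.poincare_section(chaotic_traj, ("cbar", 0.35, 0)))
        half = make_traj(
            chaotic_traj.times[: len(chaotic_traj) // 2],
            chaotic_traj.states[: len(chaotic_traj) // 2],
            chaotic_traj.params,
        )
        n_half = len(ec.poincare_section(half, ("cbar", 0.35, 0)))
        assert 0.3 * n_full <= n_half <= 0.7 * n_full

    def test_level_outside_range_rejected(self, chaotic_traj):
        with pytest.raises(ValueError):
            ec.poincare_section(chaotic_traj, ("cbar", 5.0, 0))

    def test_few_crossings_warns(self, params):
        t = np.arange(0.0, 10.0, 0.1)
        x = np.linspace(0.0, 1.0, len(t))
        states = np.column_stack([x, x, x])
        with pytest.warns(UserWarning, match="crossings"):
            ec.poincare_section(make_traj(t, states, params), ("x", 0.5, 1))


class TestErgodicity:
    def test_identical_initial_conditions_zero_spread(self, params):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            spread, est = ec.ergodicity_check(
                params, [(0.5, 0.5, 0.5), (0.5, 0.5, 0.5)], t_total=2000.0
            )
        assert spread == 0.0

    def test_attractor_samples_converge(self, params, chaotic_traj):
        """Exponent estimates from distinct on-attractor starts agree."""
        idx = [len(chaotic_traj) // 4, len(chaotic_traj) // 2, 3 * len(chaotic_traj) // 4]
        ics = [ec.EcoState(*chaotic_traj.states[i]) for i in idx]
        spread, est = ec.ergodicity_check(params, ics, t_total=5.0e4)
        assert len(est) == 3
        assert spread < 0.005
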