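import numpy as np
import pytest

from fractalhrv import (
    acrophase_to_hours,
    hours_to_acrophase,
    parameter_tests,
    population_mean_cosinor,
    single_cosinor,
)
from fractalhrv.cosinor import InsufficientSubjectsError, SingularDesignError, _acrophase_deg


def cosine_series(times_h, M, A, phi_deg, period=24.0):
    return M + A * np.cos(2 * np.pi * times_h / period + np.deg2rad(phi_deg))


class TestSingleCosinor:
    def test_constant_series(self):
        t = np.linspace(0, 24, 50)
        fit = single_cosinor(t, np.full(50, 5.0))
        assert fit.mesor == pytest.approx(5.0)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-10)

    def test_noise_free_recovery(self):
        # maximum 20.5 h after reference -> acrophase -307.5 degrees
        t = np.arange(288) / 288 * 24
        y = 10 + 2 * np.cos(2 * np.pi * (t - 20.5) / 24)
        fit = single_cosinor(t, y)
        assert fit.mesor == pytest.approx(10.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(2.0, abs=1e-9)
        assert fit.acrophase_deg == pytest.approx(-307.5, abs=1e-6)

    def test_matches_grid_search_oracle(self, rng):
        t = np.arange(100) / 100 * 24
        y = cosine_series(t, 3.0, 1.2, -120.0) + rng.normal(0, 1.0, t.size)
        fit = single_cosinor(t, y)
        # brute force over acrophase: for fixed phi the best (M, A) is linear
        best = (np.inf, None, None, None)
        for phi in np.arange(-359.95, 0.05, 0.05):
            c = np.cos(2 * np.pi * t / 24 + np.deg2rad(phi))
            X = np.column_stack([np.ones_like(t), c])
            coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(res[0]) if res.size else float(np.sum((y - X @ coef) ** 2))
            if rss < best[0] and coef[1] >= 0:
                best = (rss, coef[0], coef[1], phi)
        _, M_g, A_g, phi_g = best
        assert fit.mesor == pytest.approx(M_g, abs=1e-3)
        assert fit.amplitude == pytest.approx(A_g, abs=1e-3)
        assert fit.acrophase_deg == pytest.approx(phi_g, abs=0.05)
        # truth within ~2 standard errors
        se = np.sqrt(fit.residual_var * 2 / t.size)
        assert abs(fit.mesor - 3.0) < 3 * se

    def test_residuals_orthogonal_to_design(self, rng):
        t = np.sort(rng.uniform(0, 24, 60))
        y = cosine_series(t, 1.0, 0.5, -200.0) + rng.normal(0, 0.3, 60)
        fit = single_cosinor(t, y)
        w = 2 * np.pi / 24
        resid = y - fit.predict(t)
        for col in (np.ones_like(t), np.cos(w * t), np.sin(w * t)):
            assert abs(resid @ col) < 1e-8 * np.abs(y).sum()

    def test_single_phase_design_raises(self):
        t = np.array([0.0, 24.0, 48.0, 72.0])  # all the same circadian phase
        with pytest.raises((SingularDesignError, ValueError)):
            single_cosinor(t, np.array([1.0, 2.0, 3.0, 4.0]))

    def test_parameter_recovery_bias_small(self, rng):
        # over 200 simulated subjects, mean amplitude bias < 5% of A
        M, A, phi = -1.0, 0.2, -308.0
        t = np.arange(250) / 250 * 24
        amps, mesors = [], []
        for _ in range(200):
            y = cosine_series(t, M, A, phi) + rng.normal(0, 0.15, t.size)
            fit = single_cosinor(t, y)
            amps.append(fit.amplitude)
            mesors.append(fit.mesor)
        assert abs(np.mean(amps) - A) < 0.05 * A
        assert abs(np.mean(mesors) - M) < 0.05 * A


class TestAcrophaseConversion:
    @pytest.mark.parametrize("phi,hours", [(-308.0, 20.533), (-317.0, 21.133), (0.0, 0.0)])
    def test_published_conversions(self, phi, hours):
        assert acrophase_to_hours(phi) == pytest.approx(hours, abs=0.001)

    def test_round_trip(self):
        for h in np.arange(0, 24, 0.5):
            assert acrophase_to_hours(hours_to_acrophase(h)) == pytest.approx(h % 24, abs=1e-9)


class TestPopulationCosinor:
    def _fits(self, betas_cs, mesor=0.0):
        t = np.arange(48) / 2.0
        fits = []
        for i, (bc, bs) in enumerate(betas_cs):
            w = 2 * np.pi / 24
            y = mesor + bc * np.cos(w * t) + bs * np.sin(w * t)
            y = y + 1e-6 * np.sin(7 * t)  # break exact degeneracy of lstsq
            fits.append(single_cosinor(t, y, subject_id=f"S{i}"))
        return fits

    def test_identical_subjects_degenerate_ellipse(self):
        fits = self._fits([(0.3, -0.4)] * 4)
        pop = population_mean_cosinor(fits)
        assert pop.amplitude == pytest.approx(0.5, abs=1e-4)
        assert pop.p_zero_amplitude == 0.0  # zero-area ellipse, nonzero mean

    def test_requires_three_subjects(self):
        fits = self._fits([(0.1, 0.1), (0.2, 0.1)])
        with pytest.raises(InsufficientSubjectsError):
            population_mean_cosinor(fits)

    def test_strong_common_rhythm_detected(self, rng):
        t = np.arange(96) / 4.0
        fits = []
        for i in range(7):
            y = cosine_series(t, 0.0, 1.0, -300.0) + rng.normal(0, 0.2, t.size)
            fits.append(single_cosinor(t, y, subject_id=f"S{i}"))
        pop = population_mean_cosinor(fits)
        assert pop.p_zero_amplitude < 0.001
        assert pop.ellipse_excludes_origin()
        pts = pop.ellipse_points(200)
        assert np.all(np.hypot(pts[:, 0], pts[:, 1]) > 0)
        assert acrophase_to_hours(pop.acrophase_deg) == pytest.approx(20.0, abs=0.5)

    def test_type_one_error_near_nominal(self, rng):
        # A = 0 for every subject: the zero-amplitude test should reject ~5%
        t = np.arange(50) * 0.5
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            fits = [single_cosinor(t, rng.normal(0, 1, t.size)) for _ in range(7)]
            if population_mean_cosinor(fits).p_zero_amplitude < 0.05:
                rejections += 1
        assert 0.02 <= rejections / n_rep <= 0.08

    def test_ellipse_origin_consistency(self, rng):
        # the 95% region excludes the origin exactly when p < 0.05
        t = np.arange(50) * 0.5
        for _ in range(30):
            fits = [
                single_cosinor(t, 0.25 * np.cos(2 * np.pi * t / 24) + rng.normal(0, 1, t.size))
                for _ in range(6)
            ]
            pop = population_mean_cosinor(fits)
            pts = pop.ellipse_points(720)
            # origin inside polygon <-> minimum of the quadratic form at origin < c2
            S = pop.covariance
            mean = np.array([pop.mean_beta_c, pop.mean_beta_s])
            from scipy import stats as ss

            c2 = 2 * (pop.k - 1) / (pop.k * (pop.k - 2)) * ss.f.ppf(0.95, 2, pop.k - 2)
            inside = mean @ np.linalg.solve(S, mean) <= c2
            assert inside == (not pop.ellipse_excludes_origin())


class TestParameterTests:
    def _noisy_fits(self, rng, mesor, amp, phi, k=7, sd=0.05, ids=None):
        t = np.arange(96) / 4.0
        fits = []
        for i in range(k):
            y = cosine_series(t, mesor, amp, phi) + rng.normal(0, sd, t.size)
            fits.append(single_cosinor(t, y, subject_id=(ids[i] if ids else f"S{i}")))
        return fits

    def test_identical_groups_give_p_one(self):
        t = np.arange(96) / 4.0
        mk = lambda: [
            single_cosinor(t, cosine_series(t, 1.0, 0.5, -100.0) + 0.01 * np.sin((i + 2) * t), subject_id=f"S{i}")
            for i in range(5)
        ]
        res = parameter_tests(mk(), mk())
        for key in ("mesor", "amplitude", "joint_amplitude_acrophase"):
            assert res[key]["p"] > 0.999

    def test_mesor_shift_detected_amplitude_unchanged(self, rng):
        # groups differ only in MESOR: that test should reject nearly always,
        # while amplitude/acrophase rejections stay at their nominal rate
        hits_m, fp_a, fp_p = 0, 0, 0
        n_rep = 20
        for _ in range(n_rep):
            a = self._noisy_fits(rng, -1.163, 0.15, -308.0)
            b = self._noisy_fits(rng, -1.163 + 0.214, 0.15, -308.0)
            res = parameter_tests(a, b)
            hits_m += res["mesor"]["p"] < 0.05
            fp_a += res["amplitude"]["p"] < 0.05
            fp_p += res["acrophase"]["p"] < 0.05
        assert hits_m >= 18
        assert fp_a <= 4
        assert fp_p <= 4

    def test_phase_shift_detected_jointly(self, rng):
        a = self._noisy_fits(rng, 0.0, 1.0, -90.0, sd=0.1)
        b = self._noisy_fits(rng, 0.0, 1.0, -180.0, sd=0.1)
        res = parameter_tests(a, b)
        assert res["joint_amplitude_acrophase"]["p"] < 0.05

    def test_paired_requires_matching_subjects(self, rng):
        a = self._noisy_fits(rng, 0, 1, -90, k=4, ids=["A", "B", "C", "D"])
        b = self._noisy_fits(rng, 0, 1, -90, k=4, ids=["A", "B", "C", "E"])
        with pytest.raises(ValueError):
            parameter_tests(a, b, paired=True)


def test_acrophase_quadrants():
    # bc, bs -> phi in (-360, 0]: peak at t = -phi/360*24
    assert _acrophase_deg(1.0, 0.0) == pytest.approx(0.0)
    assert _acrophase_deg(0.0, 1.0) == pytest.approx(-90.0)
    assert _acrophase_deg(-1.0, 0.0) == pytest.approx(-180.0)
    assert _acrophase_deg(0.0, -1.0) == pytest.approx(-270.0)
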