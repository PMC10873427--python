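"""FRET efficiency decomposition, hyperbola fitting and specificity testing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import optimize

from retinaggr import fret
from retinaggr.synth import make_fret_dataset


def _spectrum(wavelengths, intensities):
    return fret.EmissionSpectrum(np.asarray(wavelengths, float), np.asarray(intensities, float))


def _series(f0, fdm, fsds, ad=1.0):
    grid = [470.0, 476.0, 482.0]

    def flat(v):
        return _spectrum(grid, [v, v, v])

    return fret.TreatmentSeries(
        spectrum_untreated=flat(f0), spectrum_dm=flat(fdm), spectrum_sds=flat(fsds),
        acceptor_donor_ratio=ad,
    )


class TestDonorIntensity:
    @pytest.mark.parametrize(
        "wavelength, expected",
        [(476.0, 20.0), (473.0, 15.0), (470.0, 10.0), (482.0, 30.0)],
    )
    def test_interpolation(self, wavelength, expected):
        spec = _spectrum([470, 476, 482], [10, 20, 30])
        assert fret.donor_intensity(spec, wavelength) == pytest.approx(expected)

    def test_out_of_range(self):
        spec = _spectrum([470, 476, 482], [10, 20, 30])
        with pytest.raises(fret.SpectrumRangeError):
            fret.donor_intensity(spec, 500.0)


class TestComputeEfficiencies:
    @pytest.mark.parametrize(
        "f0, fdm, fsds, expected",
        [
            (70, 90, 100, (0.30, 0.20, 0.10)),
            (100, 100, 100, (0.0, 0.0, 0.0)),
            # aggregate-only profile: all FRET survives DM
            (80, 80, 100, (0.20, 0.0, 0.20)),
        ],
    )
    def test_decomposition(self, f0, fdm, fsds, expected):
        p = fret.compute_efficiencies(_series(f0, fdm, fsds))
        assert (p.e_total, p.e_dm_sensitive, p.e_dm_insensitive) == pytest.approx(expected)

    def test_invalid_reference(self):
        with pytest.raises(fret.InvalidReferenceError):
            fret.compute_efficiencies(_series(70, 90, 0))

    @given(
        f0=st.floats(1, 200), fdm=st.floats(1, 200), fsds=st.floats(1, 200)
    )
    @settings(max_examples=100, deadline=None)
    def test_conservation_exact(self, f0, fdm, fsds):
        """e_total - (e_sensitive + e_insensitive) == 0 exactly, any intensities."""
        p = fret.compute_efficiencies(_series(f0, fdm, fsds))
        assert p.e_total - (p.e_dm_sensitive + p.e_dm_insensitive) == 0.0


class TestFitFretCurve:
    def test_noiseless_recovery(self):
        x = np.array([0.25, 0.5, 1, 2, 4, 8])
        y = fret.hyperbola(x, 0.40, 1.5)
        fit = fret.fit_fret_curve(zip(x, y))
        assert fit.e_max == pytest.approx(0.40, rel=1e-6)
        assert fit.ec50 == pytest.approx(1.5, rel=1e-6)
        assert fit.residual_ss == pytest.approx(0.0, abs=1e-15)

    def test_half_saturation_property(self):
        x = np.array([0.25, 0.5, 1, 2, 4, 8])
        y = fret.hyperbola(x, 0.40, 1.5) + 0.005 * np.sin(x)
        fit = fret.fit_fret_curve(zip(x, y))
        assert fit.predict(fit.ec50) == pytest.approx(fit.e_max / 2)

    def test_monotone_increasing_prediction(self):
        fit = fret.FretCurveFit("total", 0.4, 1.5, 0, 0, 0.0, 6)
        grid = np.linspace(0.01, 50, 200)
        assert np.all(np.diff(fit.predict(grid)) > 0)
        assert fit.predict(1e9) == pytest.approx(0.4, rel=1e-6)

    def test_too_few_points(self):
        with pytest.raises(fret.InsufficientDataError):
            fret.fit_fret_curve([(1, 0.1), (2, 0.2)])

    def test_noisy_mean_recovery(self):
        """Monte-Carlo: mean recovered Emax within 5 % of truth at sigma = 0.01."""
        x = np.array([0.25, 0.5, 1, 2, 4, 8])
        emaxes = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = fret.hyperbola(x, 0.40, 1.5) + rng.normal(0, 0.01, x.size)
            emaxes.append(fret.fit_fret_curve(zip(x, y)).e_max)
        assert np.mean(emaxes) == pytest.approx(0.40, rel=0.05)


def _oracle_f_statistic(x, y, ceiling):
    """Independent Nelder-Mead refits + direct residual arithmetic."""

    def ss_free(p):
        e, c = p
        if not (0 <= e <= 1) or c <= 0:
            return 1e9
        return float(np.sum((fret.hyperbola(x, e, c) - y) ** 2))

    def ss_null(p):
        (c,) = p
        if c <= 0:
            return 1e9
        return float(np.sum((fret.hyperbola(x, ceiling, c) - y) ** 2))

    best_free = min(
        (optimize.minimize(ss_free, [e0, c0], method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14}).fun
         for e0 in (0.1, 0.3, 0.8) for c0 in (0.5, 1.5, 4.0)),
    )
    best_null = min(
        (optimize.minimize(ss_null, [c0], method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14}).fun
         for c0 in (0.5, 1.5, 4.0)),
    )
    n = x.size
    return ((best_null - best_free) / 1) / (best_free / (n - 2))


class TestSpecificity:
    def test_matches_brute_force_oracle(self):
        """F equals direct residual arithmetic on small fixed datasets."""
        x = np.array([0.25, 0.5, 1, 2, 4, 8])
        for seed in range(5):
            rng = np.random.default_rng(seed)
            y = fret.hyperbola(x, 0.30, 1.5) + rng.normal(0, 0.02, x.size)
            res = fret.test_specificity(zip(x, y), e_max_nonspecific=0.15)
            # internal consistency: F from the reported sums of squares
            f_direct = ((res.ss_null - res.ss_alt) / 1) / (res.ss_alt / (x.size - 2))
            assert res.f_statistic == pytest.approx(max(f_direct, 0.0), rel=1e-9)
            # independent optimizer oracle
            f_oracle = _oracle_f_statistic(x, y, 0.15)
            assert res.f_statistic == pytest.approx(f_oracle, rel=1e-2, abs=1e-3)

    def test_null_identity(self):
        """Data generated exactly on the null curve: F = 0, p = 1, not specific."""
        x = np.array([0.25, 0.5, 1, 2, 4, 8])
        y = fret.hyperbola(x, 0.15, 1.5)
        res = fret.test_specificity(zip(x, y), e_max_nonspecific=0.15)
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0
        assert not res.is_specific

    def test_df_contract(self):
        x = np.array([0.25, 0.5, 1, 2, 4, 8])
        y = fret.hyperbola(x, 0.30, 1.5)
        res = fret.test_specificity(zip(x, y), e_max_nonspecific=0.15)
        assert res.df_num == 1
        assert res.df_den == 4

    def test_too_few_points(self):
        with pytest.raises(fret.InsufficientDataError):
            fret.test_specificity([(1, 0.1), (2, 0.15), (4, 0.2)], 0.1)


class TestComponentFractions:
    def _fit(self, e_max, component="dm_sensitive"):
        return fret.FretCurveFit(component, e_max, 1.5, 0, 0, 0.0, 6)

    def test_normalization(self):
        fs = fret.component_fractions(self._fit(0.20), self._fit(0.10), True, True)
        assert fs == pytest.approx((2 / 3, 1 / 3))
        assert sum(fs) == pytest.approx(1.0)

    def test_censoring(self):
        fs = fret.component_fractions(self._fit(0.20), self._fit(0.25), False, True)
        assert fs == (0.0, 1.0)

    def test_both_nonspecific_flagged(self):
        assert fret.component_fractions(self._fit(0.2), self._fit(0.1), False, False) is None


class TestGeneratorRoundTrip:
    def test_zero_noise_exact(self):
        """sigma = 0: decomposition returns the hyperbola values exactly."""
        truth = {"e_max_sensitive": 0.20, "ec50_sensitive": 1.5,
                 "e_max_insensitive": 0.10, "ec50_insensitive": 1.5}
        series, _ = make_fret_dataset(truth, noise_sigma=0.0, seed=0)
        for s in series:
            p = fret.compute_efficiencies(s)
            ad = s.acceptor_donor_ratio
            assert p.e_dm_sensitive == pytest.approx(fret.hyperbola(ad, 0.20, 1.5), abs=1e-12)
            assert p.e_dm_insensitive == pytest.approx(fret.hyperbola(ad, 0.10, 1.5), abs=1e-12)
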