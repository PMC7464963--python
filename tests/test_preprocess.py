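"""Pre-processing tests: calibration apex search, region excision, regional
PQN quotients against brute-force enumeration, and binning arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cecalomics.datatypes import Spectrum
from cecalomics.preprocess import (
    RegionalPQN,
    SpectrumBinner,
    bin_spectrum,
    calibrate,
    excise_regions,
    pqn_normalize,
)
from conftest import lorentzian_spectrum


def make_spectrum(ppm, intensity, sid="s"):
    return Spectrum(np.asarray(ppm, float), np.asarray(intensity, float), sid)


class TestCalibrate:
    def test_already_calibrated_spectrum_unchanged(self):
        ppm = np.linspace(-0.2, 3.0, 2001)
        y = lorentzian_spectrum(ppm, [0.0], [100.0]) + 0.01
        out = calibrate(make_spectrum(ppm, y))
        apex = ppm[np.argmax(y)]
        assert apex == 0.0  # grid hits zero exactly here
        assert np.allclose(out.ppm, ppm)
        assert np.array_equal(out.intensity, y)

    def test_offset_apex_produces_pure_translation(self):
        ppm = np.linspace(-0.2, 3.0, 3201)
        y = lorentzian_spectrum(ppm, [0.02], [100.0])
        out = calibrate(make_spectrum(ppm, y))
        shift = ppm[np.argmax(y)]
        assert shift == pytest.approx(0.02, abs=1e-3)
        assert np.allclose(out.ppm, ppm - shift)
        assert np.array_equal(out.intensity, y)

    def test_analyte_apex_lands_at_expected_shift(self):
        # TSP at 0.015, analyte at 1.933 -> analyte apex at 1.918 after
        # calibration; both apexes located independently
        ppm = np.arange(-0.2, 3.0, 1e-4)
        y = lorentzian_spectrum(ppm, [0.015, 1.933], [100.0, 40.0])
        out = calibrate(make_spectrum(ppm, y))
        tsp_apex = ppm[np.argmax(y)]
        analyte_region = (out.ppm > 1.5) & (out.ppm < 2.5)
        analyte_apex = out.ppm[analyte_region][np.argmax(out.intensity[analyte_region])]
        assert tsp_apex == pytest.approx(0.015, abs=2e-4)
        assert analyte_apex == pytest.approx(1.918, abs=2e-4)

    def test_signal_free_window_raises(self):
        rng = np.random.default_rng(0)
        ppm = np.linspace(-0.2, 3.0, 2000)
        y = rng.normal(0, 1.0, ppm.size)
        with pytest.raises(ValueError, match="no reference peak"):
            calibrate(make_spectrum(ppm, y))


class TestExcise:
    def test_empty_removal_is_identity(self):
        ppm = np.linspace(0, 10, 500)
        s = make_spectrum(ppm, np.sin(ppm))
        out = excise_regions(s, [], min_points=10)
        assert np.array_equal(out.ppm, s.ppm)
        assert np.array_equal(out.intensity, s.intensity)

    def test_survivor_count_matches_direct_count(self):
        ppm = np.linspace(0, 10, 1000)
        s = make_spectrum(ppm, np.ones_like(ppm))
        keep_lo, keep_hi = 3.0, 4.0
        out = excise_regions(
            s, [(-1.0, keep_lo - 1e-9), (keep_hi + 1e-9, 11.0)], min_points=10
        )
        expected = int(((ppm >= keep_lo) & (ppm <= keep_hi)).sum())
        assert out.n_points == expected
        assert np.all((out.ppm >= keep_lo) & (out.ppm <= keep_hi))

    def test_removal_of_unpopulated_interval_is_noop(self):
        ppm = np.concatenate([np.linspace(0, 4.6, 300), np.linspace(5.0, 9.0, 300)])
        s = make_spectrum(ppm, np.cos(ppm))
        out = excise_regions(s, [(4.70, 4.90)], min_points=10)
        assert np.array_equal(out.ppm, s.ppm)

    def test_insufficient_remainder_raises(self):
        ppm = np.linspace(0, 10, 300)
        s = make_spectrum(ppm, np.ones_like(ppm))
        with pytest.raises(ValueError, match="insufficient"):
            excise_regions(s, [(0.0, 9.9)], min_points=200)


class TestRegionalPQN:
    def test_identical_cohort_has_unit_factors(self):
        ppm = np.linspace(0.5, 9.0, 100)
        base = np.abs(np.sin(ppm)) + 0.2
        spectra = [make_spectrum(ppm, base.copy(), f"s{i}") for i in range(5)]
        out, factors = pqn_normalize(spectra, 4.8, return_factors=True)
        assert np.array_equal(factors, np.ones_like(factors))
        for a, b in zip(out, spectra):
            assert np.array_equal(a.intensity, b.intensity)

    def test_threefold_dilution_recovered_exactly(self):
        ppm = np.linspace(0.5, 9.0, 200)
        base = np.abs(np.cos(ppm)) + 0.3
        cohort = [make_spectrum(ppm, base.copy(), f"c{i}") for i in range(5)]
        cohort.append(make_spectrum(ppm, base / 3.0, "diluted"))
        out, factors = pqn_normalize(cohort, 4.8, return_factors=True)
        assert np.max(np.abs(factors[-1] - 1.0 / 3.0)) < 1e-12
        assert np.allclose(out[-1].intensity, base, rtol=1e-12)

    def test_six_point_cohort_matches_bruteforce_quotients(self):
        # 3 hand-written 6-point spectra; split after point 3
        ppm = np.array([1.0, 2.0, 3.0, 6.0, 7.0, 8.0])
        X = np.array(
            [
                [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                [2.0, 2.0, 2.0, 8.0, 8.0, 8.0],
                [3.0, 6.0, 9.0, 2.0, 4.0, 8.0],
            ]
        )
        spectra = [make_spectrum(ppm, row, f"s{i}") for i, row in enumerate(X)]
        _, factors = pqn_normalize(spectra, region_split_ppm=4.8, return_factors=True)
        ref = np.median(X, axis=0)
        for i in range(3):
            for r, cols in enumerate((slice(0, 3), slice(3, 6))):
                expected = np.median(X[i, cols] / ref[cols])
                assert factors[i, r] == pytest.approx(expected, abs=1e-15)

    def test_idempotent_on_dilution_cohorts(self):
        # scalar multiples of one shape: second pass must be exactly neutral
        ppm = np.linspace(0.5, 9.0, 150)
        base = np.abs(np.sin(3 * ppm)) + 0.1
        scales = [0.5, 1.0, 1.5, 2.0, 4.0]
        cohort = [make_spectrum(ppm, a * base, f"s{a}") for a in scales]
        once = pqn_normalize(cohort, 4.8)
        _, factors2 = pqn_normalize(once, 4.8, return_factors=True)
        assert np.max(np.abs(factors2 - 1.0)) < 1e-12

    def test_nearly_idempotent_on_heterogeneous_cohorts(self):
        # the median-quotient map is not a projection in general; second-pass
        # factors stay near (but not exactly) 1
        rng = np.random.default_rng(7)
        ppm = np.linspace(0.5, 9.0, 60)
        cohort = [
            make_spectrum(ppm, np.abs(rng.lognormal(0, 1, 60)) + 0.1, f"s{i}")
            for i in range(9)
        ]
        once = pqn_normalize(cohort, 4.8)
        _, factors2 = pqn_normalize(once, 4.8, return_factors=True)
        assert np.max(np.abs(factors2 - 1.0)) < 0.15

    def test_errors(self):
        ppm = np.linspace(0.5, 9.0, 50)
        one = [make_spectrum(ppm, np.ones(50))]
        with pytest.raises(ValueError, match="at least 2"):
            pqn_normalize(one, 4.8)
        zero_high = [
            make_spectrum(ppm, np.where(ppm < 4.8, 1.0, 0.0), f"s{i}") for i in range(3)
        ]
        with pytest.raises(ValueError, match="degenerate reference"):
            pqn_normalize(zero_high, 4.8)

    def test_transformer_agrees_with_function(self):
        rng = np.random.default_rng(1)
        ppm = np.linspace(0.5, 9.0, 80)
        X = np.abs(rng.lognormal(0, 0.5, (6, 80))) + 0.1
        spectra = [make_spectrum(ppm, row, f"s{i}") for i, row in enumerate(X)]
        expected = np.stack([s.intensity for s in pqn_normalize(spectra, 4.8)])
        got = RegionalPQN(ppm=ppm, region_split_ppm=4.8).fit(X).transform(X)
        assert np.allclose(got, expected, rtol=1e-14)


class TestBinning:
    def test_hundred_point_bins_give_410_bins_on_41000_points(self):
        ppm = 0.5 + 1.83e-4 * np.arange(41000)
        s = make_spectrum(ppm, np.ones(41000))
        b = bin_spectrum(s, 100)
        assert b.n_bins == 410
        assert b.bin_width_ppm == pytest.approx(0.0183, rel=1e-9)

    def test_uniform_signal_bins_to_constant(self):
        ppm = np.linspace(0, 3, 300)
        b = bin_spectrum(make_spectrum(ppm, np.ones(300)), 100)
        assert np.allclose(b.bin_values, 100.0)
        assert b.n_bins == 3

    def test_bins_equal_independent_sums_and_remainder_dropped(self):
        rng = np.random.default_rng(4)
        ppm = np.linspace(0, 5, 550)
        y = rng.normal(size=550)
        b = bin_spectrum(make_spectrum(ppm, y), 100)
        assert b.n_bins == 5
        for i in range(5):
            assert b.bin_values[i] == pytest.approx(y[100 * i : 100 * (i + 1)].sum(), rel=1e-12)

    def test_shorter_than_one_bin_raises(self):
        with pytest.raises(ValueError):
            bin_spectrum(make_spectrum(np.linspace(0, 1, 50), np.ones(50)), 100)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        n=st.integers(min_value=100, max_value=1200),
        ppb=st.integers(min_value=1, max_value=100),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_binning_conserves_mass(self, n, ppb, seed):
        if n < ppb:
            return
        rng = np.random.default_rng(seed)
        y = rng.normal(size=n)
        s = make_spectrum(np.linspace(0, 10, n), y)
        b = bin_spectrum(s, ppb)
        used = (n // ppb) * ppb
        assert b.bin_values.sum() == pytest.approx(y[:used].sum(), rel=1e-12, abs=1e-12)

    def test_bin_values_invariant_under_axis_translation(self):
        rng = np.random.default_rng(8)
        ppm = np.linspace(0, 5, 500)
        y = rng.lognormal(size=500)
        b0 = bin_spectrum(make_spectrum(ppm, y), 100)
        b1 = bin_spectrum(make_spectrum(ppm + 0.37, y), 100)
        assert np.array_equal(b0.bin_values, b1.bin_values)
        assert np.allclose(b1.bin_centers_ppm - b0.bin_centers_ppm, 0.37)

    def test_binner_transformer_matches_function(self):
        rng = np.random.default_rng(2)
        ppm = np.linspace(0, 5, 530)
        X = rng.normal(size=(4, 530))
        binner = SpectrumBinner(points_per_bin=100, ppm=ppm).fit(X)
        got = binner.transform(X)
        for i in range(4):
            b = bin_spectrum(make_spectrum(ppm, X[i]), 100)
            assert np.allclose(got[i], b.bin_values)
            assert np.allclose(binner.bin_centers_, b.bin_centers_ppm)
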