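"""Kinetics tests: signal extraction linearity, GLM inversion against the
normal equations, bootstrap band behaviour and band-overlap calls."""

import numpy as np
import pandas as pd
import pytest

from cecalomics.datatypes import BinnedSpectrum, Spectrum
from cecalomics.design import MetaboliteSpec, Peak, TrialDesign
from cecalomics.kinetics import (
    KineticsFit,
    MetaboliteSignalSeries,
    bootstrap_band,
    compare_groups,
    extract_signal,
    fit_group_kinetics,
    fit_kinetics,
)
from cecalomics.preprocess import bin_spectrum
from cecalomics.simulate import generate_signal_series, metabolite_template

DAYS = (15.0, 28.0, 42.0)


def series_from_values(values_by_cell, metabolite="m"):
    rows = [
        (g, d, v)
        for (g, d), vals in values_by_cell.items()
        for v in np.atleast_1d(vals)
    ]
    return MetaboliteSignalSeries(
        metabolite, pd.DataFrame(rows, columns=["group", "time_day", "signal"])
    )


def model_series(group_params, noise_sd, n, rng, days=DAYS):
    cells = {}
    for g, (a, b) in group_params.items():
        for d in days:
            lin = a + b * np.log(d) + rng.normal(0, noise_sd, n)
            cells[(g, d)] = np.clip(lin, 0, None) ** 2
    return series_from_values(cells)


class TestExtractSignal:
    def make_binned(self, values):
        centers = np.linspace(1.0, 5.0, len(values))
        return BinnedSpectrum(centers, np.asarray(values, float), 0.1, "s")

    def test_whole_axis_assignment_gives_total_sum(self):
        b = self.make_binned([1.0, 2.0, 3.0, 4.0])
        assert extract_signal(b, [(0.0, 10.0)]) == 10.0

    def test_zero_spectrum_gives_zero(self):
        b = self.make_binned([0.0, 0.0, 0.0])
        assert extract_signal(b, [(0.0, 10.0)]) == 0.0

    def test_no_bins_in_interval_raises(self):
        b = self.make_binned([1.0, 2.0])
        with pytest.raises(ValueError, match="no bin"):
            extract_signal(b, [(20.0, 30.0)])

    def test_signal_linear_in_generator_concentration(self):
        # ten-step concentration ladder through template -> bin -> extract
        met = MetaboliteSpec("m", (Peak(2.0),), {"A": (1.0, 0.0)}, noise_sd=0.0)
        ppm = np.arange(0.5, 4.0, 1.83e-4)
        template = metabolite_template(met, ppm)
        concentrations = np.linspace(0.5, 5.0, 10)
        signals = []
        for c in concentrations:
            b = bin_spectrum(Spectrum(ppm, c * template, "s"), 100)
            signals.append(extract_signal(b, [met.quant_interval()]))
        r = np.corrcoef(concentrations, signals)[0, 1]
        assert r**2 > 0.999


class TestFitKinetics:
    def test_noiseless_model_inverted_exactly(self):
        cells = {("A", d): np.full(5, (1.0 + 2.0 * np.log(d)) ** 2) for d in DAYS}
        fit = fit_kinetics(series_from_values(cells), "A")
        assert fit.alpha == pytest.approx(1.0, abs=1e-8)
        assert fit.beta == pytest.approx(2.0, abs=1e-8)

    def test_flat_signals_give_zero_slope(self):
        cells = {("A", d): np.full(4, 9.0) for d in DAYS}
        fit = fit_kinetics(series_from_values(cells), "A")
        assert abs(fit.beta) < 1e-10
        assert fit.alpha == pytest.approx(3.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        means = {15.0: 2.1, 28.0: 2.9, 42.0: 3.2}
        cells = {("A", d): np.array([m**2]) for d, m in means.items()}
        fit = fit_kinetics(series_from_values(cells), "A")
        x = np.log(list(means))
        y = np.array(list(means.values()))
        n = len(y)
        beta = (n * (x * y).sum() - x.sum() * y.sum()) / (n * (x**2).sum() - x.sum() ** 2)
        alpha = y.mean() - beta * x.mean()
        assert fit.alpha == pytest.approx(alpha, abs=1e-10)
        assert fit.beta == pytest.approx(beta, abs=1e-10)

    def test_negative_signal_and_single_time_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            series_from_values({("A", 15.0): [-1.0], ("A", 28.0): [1.0]})
        cells = {("A", 15.0): np.ones(3)}
        with pytest.raises(ValueError, match="2 distinct"):
            fit_kinetics(series_from_values(cells), "A")

    def test_sqrt_transform_linearizes_generator_data(self):
        # generator signals are quadratic in the linear predictor; fitting
        # without the sqrt leaves systematically larger residuals
        cells = {("A", d): np.full(3, (0.5 + 0.8 * np.log(d)) ** 2) for d in DAYS}
        series = series_from_values(cells)
        with_sqrt = fit_kinetics(series, "A")
        x = np.log(DAYS)
        y_raw = np.array([(0.5 + 0.8 * np.log(d)) ** 2 for d in DAYS])
        X = np.column_stack([np.ones(3), x])
        resid_raw = y_raw - X @ np.linalg.lstsq(X, y_raw, rcond=None)[0]
        assert np.abs(with_sqrt.residuals).max() < 1e-10
        assert np.abs(resid_raw).max() > 1e-3

    def test_beta_rmse_shrinks_with_larger_cells(self):
        truth = {"A": (2.0, 0.55)}
        errs = {20: [], 40: []}
        for n in errs:
            for rep in range(60):
                rng = np.random.default_rng(1000 + rep)
                fit = fit_kinetics(model_series(truth, 0.35, n, rng), "A")
                errs[n].append(fit.beta - 0.55)
        rmse = {n: np.sqrt(np.mean(np.square(e))) for n, e in errs.items()}
        assert rmse[40] < rmse[20]


class TestBootstrapBand:
    def test_zero_variance_cells_collapse_band(self):
        cells = {("A", d): np.full(6, 4.0) for d in DAYS}
        series = series_from_values(cells)
        grid, lo, hi = bootstrap_band(series, "A", n_boot=300, seed=0)
        assert np.allclose(hi - lo, 0.0)

    def test_same_seed_reproduces_band(self):
        rng = np.random.default_rng(0)
        series = model_series({"A": (2.0, 0.3)}, 0.3, 12, rng)
        b1 = bootstrap_band(series, "A", n_boot=400, seed=7)
        b2 = bootstrap_band(series, "A", n_boot=400, seed=7)
        assert np.array_equal(b1[1], b2[1]) and np.array_equal(b1[2], b2[2])

    def test_band_straddles_fitted_curve(self):
        rng = np.random.default_rng(3)
        series = model_series({"A": (2.0, 0.3)}, 0.3, 25, rng)
        fit = fit_group_kinetics(series, "A", n_boot=500, seed=1)
        assert np.all(fit.band_lower <= fit.curve + 1e-12)
        assert np.all(fit.curve <= fit.band_upper + 1e-12)

    def test_too_few_resamples_rejected(self):
        cells = {("A", d): np.ones(3) for d in DAYS}
        with pytest.raises(ValueError, match="n_boot"):
            bootstrap_band(series_from_values(cells), "A", n_boot=50)

    def test_missing_cell_rejected(self):
        cells = {("A", 15.0): np.ones(3), ("A", 28.0): np.ones(3), ("B", 42.0): np.ones(3)}
        series = series_from_values(cells)
        with pytest.raises(ValueError, match="empty cell"):
            bootstrap_band(series, "A", n_boot=300)


def synthetic_fit(group, grid, lower, upper):
    mid = (lower + upper) / 2
    return KineticsFit(
        metabolite="m", group=group, alpha=0.0, beta=0.0,
        days=np.array(DAYS), sqrt_means=np.zeros(3), sqrt_sds=np.zeros(3),
        day_grid=grid, curve=mid, band_lower=lower, band_upper=upper,
    )


class TestCompareGroups:
    grid = np.linspace(15, 42, 50)

    def test_identical_fits_never_flagged(self):
        lo = np.sin(self.grid / 10) - 0.5
        hi = lo + 1.0
        out = compare_groups(
            [synthetic_fit("A", self.grid, lo, hi), synthetic_fit("B", self.grid, lo, hi)]
        )
        res = out[("A", "B")]
        assert not res["any_disjoint"] and not res["significant"]

    def test_fully_separated_bands_flag_everywhere(self):
        lo = np.zeros_like(self.grid)
        out = compare_groups(
            [
                synthetic_fit("A", self.grid, lo, lo + 1.0),
                synthetic_fit("B", self.grid, lo + 2.0, lo + 3.0),
            ]
        )
        res = out[("A", "B")]
        assert res["disjoint_mask"].all()
        assert res["first_sustained_day"] == pytest.approx(15.0)
        assert res["significant"]

    def test_first_sustained_day_matches_scan_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a_lo = rng.normal(0, 0.2, self.grid.size).cumsum() * 0.05
            a_hi = a_lo + rng.uniform(0.2, 0.5)
            shift = rng.uniform(-1.0, 1.5)
            b_lo = a_lo + shift + rng.normal(0, 0.05, self.grid.size)
            b_hi = b_lo + rng.uniform(0.2, 0.5)
            out = compare_groups(
                [
                    synthetic_fit("A", self.grid, a_lo, a_hi),
                    synthetic_fit("B", self.grid, b_lo, b_hi),
                ],
                min_run_days=0.0,
            )[("A", "B")]
            disjoint = (a_lo > b_hi) | (b_lo > a_hi)
            expected = None
            if disjoint[-1]:
                i = len(disjoint) - 1
                while i >= 0 and disjoint[i]:
                    i -= 1
                expected = float(self.grid[i + 1])
            assert out["first_sustained_day"] == expected

    def test_mismatched_grids_rejected(self):
        g2 = np.linspace(15, 42, 40)
        lo = np.zeros(50)
        fits = [
            synthetic_fit("A", self.grid, lo, lo + 1),
            synthetic_fit("B", g2, np.zeros(40), np.ones(40)),
        ]
        with pytest.raises(ValueError, match="same day grid"):
            compare_groups(fits)


class TestGeneratorRoundTrip:
    def test_planted_group_effect_recovered_from_signal_series(self):
        # group C butyrate-like rise: the fitted slopes should rank C above
        # A and B on generator signals
        design = TrialDesign(n_per_group_per_time=40, dropouts={}, seed=42)
        met = MetaboliteSpec(
            "butyrate-like", (Peak(0.9),),
            {"A": (0.8, 0.35), "B": (0.8, 0.35), "C": (-0.42, 0.80)},
            noise_sd=0.35,
        )
        df = generate_signal_series(design, met)
        series = MetaboliteSignalSeries("butyrate-like", df)
        fits = {g: fit_kinetics(series, g) for g in "ABC"}
        assert fits["C"].beta > fits["A"].beta
        assert fits["C"].beta > fits["B"].beta
        assert fits["C"].beta == pytest.approx(0.80, rel=0.25)
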