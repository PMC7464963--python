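"""Log-time kinetics of metabolite signals with bootstrap confidence bands.

Per group, per-time-point metabolite signals (bin integrals in A.U.) are
square-root transformed to improve normality; the per-time means Y are fit
with a Gaussian-family, identity-link GLM of the form
``Y = alpha + beta * ln(day)`` (natural log). A 95% percentile bootstrap
band around the fitted curve carries the sample-level variability: each
replicate resamples every (group, day) cell with replacement, recomputes
the sqrt-means and refits. Two groups differ significantly (p < 0.05 in the
interval sense) on the days where their bands are disjoint.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import BinnedSpectrum

__all__ = [
    "extract_signal",
    "extract_signals",
    "build_signal_series",
    "MetaboliteSignalSeries",
    "LogTimeKinetics",
    "KineticsFit",
    "fit_kinetics",
    "bootstrap_band",
    "fit_group_kinetics",
    "compare_groups",
]


def extract_signal(
    binned: BinnedSpectrum, intervals: Sequence[tuple[float, float]]
) -> float:
    """Sum of bin values whose centers fall inside any assigned ppm interval."""
    mask = np.zeros(binned.n_bins, dtype=bool)
    for lo, hi in intervals:
        lo, hi = sorted((lo, hi))
        mask |= (binned.bin_centers_ppm >= lo) & (binned.bin_centers_ppm <= hi)
    if not np.any(mask):
        raise ValueError("no bin center falls inside the assigned intervals")
    return float(binned.bin_values[mask].sum())


def extract_signals(
    binned: BinnedSpectrum, assignment: Mapping[str, Sequence[tuple[float, float]]]
) -> dict[str, float]:
    """Per-metabolite signals for one binned spectrum."""
    return {m: extract_signal(binned, iv) for m, iv in assignment.items()}


@dataclass
class MetaboliteSignalSeries:
    """Per-(group, day) sample signals of one metabolite (tidy frame)."""

    metabolite: str
    data: pd.DataFrame  # columns: group, time_day, signal
    transform_applied: bool = False

    def __post_init__(self) -> None:
        need = {"group", "time_day", "signal"}
        if not need <= set(self.data.columns):
            raise ValueError(f"data needs columns {sorted(need)}")
        if not self.transform_applied and (self.data["signal"] < 0).any():
            raise ValueError("signals must be >= 0 before the sqrt transform")
        sizes = self.data.groupby(["group", "time_day"]).size()
        if (sizes == 0).any():
            raise ValueError("every (group, time) cell must be non-empty")

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())

    @property
    def days(self) -> np.ndarray:
        return np.sort(self.data["time_day"].unique().astype(float))

    def cell(self, group: str, day: float) -> np.ndarray:
        sel = (self.data["group"] == group) & (self.data["time_day"] == float(day))
        return self.data.loc[sel, "signal"].to_numpy(float)


def build_signal_series(
    binned: Sequence[BinnedSpectrum],
    metadata: pd.DataFrame,
    intervals: Sequence[tuple[float, float]],
    metabolite: str,
) -> MetaboliteSignalSeries:
    """Assemble a signal series from binned spectra and their metadata."""
    rows = []
    for b in binned:
        meta = metadata.loc[b.sample_id]
        rows.append((meta["group"], float(meta["time_day"]), extract_signal(b, intervals)))
    return MetaboliteSignalSeries(
        metabolite, pd.DataFrame(rows, columns=["group", "time_day", "signal"])
    )


class LogTimeKinetics(RegressorMixin, BaseEstimator):
    """sklearn-style estimator for the sqrt-signal log-time trend.

    ``fit(X, y)`` takes observation-level days (n, 1) and signals (A.U.);
    it averages sqrt(signal) per distinct day and fits the Gaussian GLM with
    identity link on (1, ln day). ``predict`` returns the fitted sqrt-scale
    curve. ``sample_weight``-style per-day weighting by cell size is exposed
    via ``weight_by_cell_size``.
    """

    def __init__(self, weight_by_cell_size: bool = False):
        self.weight_by_cell_size = weight_by_cell_size

    def fit(self, X, y):
        days = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float)
        if np.any(y < 0):
            raise ValueError("signals must be >= 0 (sqrt transform undefined)")
        if np.any(days <= 0):
            raise ValueError("days must be positive (log undefined)")
        uniq = np.unique(days)
        if uniq.size < 2:
            raise ValueError("need at least 2 distinct time points")
        means = np.array([np.sqrt(y[days == d]).mean() for d in uniq])
        sizes = np.array([(days == d).sum() for d in uniq], dtype=float)
        design = sm.add_constant(np.log(uniq))
        weights = sizes if self.weight_by_cell_size else np.ones_like(sizes)
        model = sm.GLM(means, design, family=sm.families.Gaussian(), var_weights=weights)
        with warnings.catch_warnings():
            # a noiseless series is fitted perfectly; the separation warning
            # is expected there, not a defect
            warnings.simplefilter("ignore")
            try:
                res = model.fit()
            except ValueError:
                # degenerate (e.g. constant) response trips the GLM deviance
                # guess; the Gaussian identity-link GLM is exactly WLS
                res = sm.WLS(means, design, weights=weights).fit()
        self.alpha_ = float(res.params[0])
        self.beta_ = float(res.params[1])
        self.days_ = uniq
        self.sqrt_means_ = means
        self.cell_sizes_ = sizes.astype(int)
        self.result_ = res
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        days = np.asarray(X, dtype=float).reshape(-1)
        return self.alpha_ + self.beta_ * np.log(days)


@dataclass
class KineticsFit:
    """Per-group fit of sqrt-signal vs log-day, with optional bootstrap band."""

    metabolite: str
    group: str
    alpha: float
    beta: float
    days: np.ndarray
    sqrt_means: np.ndarray
    sqrt_sds: np.ndarray
    day_grid: np.ndarray
    curve: np.ndarray
    band_lower: np.ndarray | None = None
    band_upper: np.ndarray | None = None
    n_boot: int = 0
    level: float = 0.95
    residuals: np.ndarray = field(default=None)

    def has_band(self) -> bool:
        return self.band_lower is not None


def _day_grid(days: np.ndarray, n: int = 100) -> np.ndarray:
    return np.linspace(float(np.min(days)), float(np.max(days)), n)


def fit_kinetics(
    series: MetaboliteSignalSeries,
    group: str,
    day_grid: np.ndarray | None = None,
    weight_by_cell_size: bool = False,
) -> KineticsFit:
    """GLM fit of one group's per-day sqrt-mean signals vs ln(day)."""
    days = series.days
    if days.size < 2:
        raise ValueError("need at least 2 distinct time points")
    cells = [series.cell(group, d) for d in days]
    obs_days = np.concatenate([np.full(c.size, d) for c, d in zip(cells, days)])
    obs = np.concatenate(cells)
    est = LogTimeKinetics(weight_by_cell_size=weight_by_cell_size).fit(
        obs_days.reshape(-1, 1), obs
    )
    grid = _day_grid(days) if day_grid is None else np.asarray(day_grid, float)
    sds = np.array([np.sqrt(c).std(ddof=1) if c.size > 1 else 0.0 for c in cells])
    return KineticsFit(
        metabolite=series.metabolite,
        group=group,
        alpha=est.alpha_,
        beta=est.beta_,
        days=days,
        sqrt_means=est.sqrt_means_,
        sqrt_sds=sds,
        day_grid=grid,
        curve=est.predict(grid),
        residuals=est.sqrt_means_ - est.predict(days),
    )


def bootstrap_band(
    series: MetaboliteSignalSeries,
    group: str,
    n_boot: int = 2000,
    level: float = 0.95,
    eval_days: np.ndarray | None = None,
    seed: int = 0,
    expand: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Percentile bootstrap band of the fitted curve on a day grid.

    Each replicate resamples every (group, day) cell with replacement,
    recomputes sqrt-means and refits the two-parameter model (the Gaussian
    identity-link GLM on the per-day means coincides with ordinary least
    squares, solved here in closed form for all replicates at once).

    With ``expand=True`` (default) the percentile levels are widened by
    Hesterberg's small-sample expansion — the plain percentile interval of
    a mean at cell sizes around 40 undercovers by 1-2%, worst at the
    leverage-heavy end days of the fit. Returns (eval_days, lower, upper);
    seeded determinism.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    days = series.days
    cells = [series.cell(group, d) for d in days]
    for d, c in zip(days, cells):
        if c.size == 0:
            raise ValueError(f"empty cell at day {d}")
    grid = _day_grid(days) if eval_days is None else np.asarray(eval_days, float)
    rng = np.random.default_rng(seed)
    boot_means = np.empty((n_boot, days.size))
    for j, c in enumerate(cells):
        sq = np.sqrt(c)
        idx = rng.integers(0, c.size, size=(n_boot, c.size))
        boot_means[:, j] = sq[idx].mean(axis=1)
    design = np.column_stack([np.ones(days.size), np.log(days)])
    hat = np.linalg.pinv(design)  # (2, n_days): params = hat @ Y
    params = boot_means @ hat.T  # (n_boot, 2)
    curves = params[:, [0]] + params[:, [1]] * np.log(grid)[None, :]
    a = (1 - level) / 2
    if expand:
        n_min = min(c.size for c in cells)
        if n_min > 1:
            from scipy import stats

            z_exp = stats.t.ppf(1 - a, n_min - 1) * np.sqrt(n_min / (n_min - 1))
            a = float(stats.norm.cdf(-z_exp))
    lower, upper = np.percentile(curves, [100 * a, 100 * (1 - a)], axis=0)
    return grid, lower, upper


def fit_group_kinetics(
    series: MetaboliteSignalSeries,
    group: str,
    n_boot: int = 2000,
    level: float = 0.95,
    eval_days: np.ndarray | None = None,
    seed: int = 0,
    weight_by_cell_size: bool = False,
) -> KineticsFit:
    """Point fit plus bootstrap band in one call."""
    grid = (
        _day_grid(series.days) if eval_days is None else np.asarray(eval_days, float)
    )
    fit = fit_kinetics(series, group, day_grid=grid, weight_by_cell_size=weight_by_cell_size)
    _, lower, upper = bootstrap_band(
        series, group, n_boot=n_boot, level=level, eval_days=grid, seed=seed
    )
    fit.band_lower, fit.band_upper = lower, upper
    fit.n_boot, fit.level = n_boot, level
    return fit


def compare_groups(
    fits: Sequence[KineticsFit],
    min_run_days: float = 4.0,
) -> dict[tuple[str, str], dict]:
    """Pairwise band-overlap calls on a shared day grid.

    For every pair of groups and grid day, the day is flagged disjoint iff
    the two bands do not overlap. A pair is called significant when the
    trailing run of disjoint days (reaching the end of the grid) spans at
    least ``min_run_days``; ``first_sustained_day`` is the start of that
    run. Grids must match across fits; every fit needs a band.
    """
    grid = fits[0].day_grid
    for f in fits[1:]:
        if f.day_grid.size != grid.size or not np.allclose(f.day_grid, grid):
            raise ValueError("fits must share the same day grid")
    for f in fits:
        if not f.has_band():
            raise ValueError(f"fit for group {f.group} has no bootstrap band")
    out: dict[tuple[str, str], dict] = {}
    for fa, fb in itertools.combinations(fits, 2):
        disjoint = (fa.band_lower > fb.band_upper) | (fb.band_lower > fa.band_upper)
        first_day = None
        run_days = 0.0
        if disjoint[-1]:
            i = disjoint.size - 1
            while i >= 0 and disjoint[i]:
                i -= 1
            first_day = float(grid[i + 1])
            run_days = float(grid[-1] - grid[i + 1])
        flag = first_day is not None and run_days >= min_run_days
        pair = tuple(sorted((fa.group, fb.group)))
        out[pair] = {
            "disjoint_days": grid[disjoint],
            "disjoint_mask": disjoint,
            "any_disjoint": bool(disjoint.any()),
            "first_sustained_day": first_day,
            "sustained_span_days": run_days,
            "significant": bool(flag),
        }
    return out
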