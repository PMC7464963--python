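"""Spectral pre-processing: TSP calibration, region excision, regional PQN
normalization and fixed-width binning.

The stage order is fixed: calibrate -> excise -> normalize -> bin
(:func:`preprocess_spectra` enforces it). Probabilistic quotient
normalization (PQN) scales each spectrum by the median ratio to the
point-wise median reference; here it is applied to two axis regions
separately ("regional scaling", split at the excised water gap by default),
so every sample gets one scale factor per region. Binning sums consecutive
runs of ``points_per_bin`` points (an integral-like aggregation), dropping
and logging a trailing remainder so the bin width stays constant.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import BinnedSpectrum, Spectrum

__all__ = [
    "calibrate",
    "excise_regions",
    "pqn_normalize",
    "bin_spectrum",
    "RegionalPQN",
    "SpectrumBinner",
    "preprocess_spectra",
]

logger = logging.getLogger(__name__)

_EPS = np.finfo(float).eps


def calibrate(
    s: Spectrum,
    reference_search_window: tuple[float, float] = (-0.2, 0.2),
    noise_floor_sds: float = 5.0,
) -> Spectrum:
    """Shift the ppm axis so the reference (TSP) apex sits at 0.00 ppm.

    The apex is the tallest point inside ``reference_search_window``.
    Intensities are unchanged. Raises ``ValueError("no reference peak")``
    when the window maximum does not rise ``noise_floor_sds`` robust
    standard deviations above the spectrum median (no usable signal).
    """
    lo, hi = sorted(reference_search_window)
    mask = (s.ppm >= lo) & (s.ppm <= hi)
    if not np.any(mask):
        raise ValueError("no reference peak: search window contains no points")
    med = np.median(s.intensity)
    noise = 1.4826 * np.median(np.abs(s.intensity - med))
    apex_idx = np.flatnonzero(mask)[np.argmax(s.intensity[mask])]
    if s.intensity[apex_idx] - med <= noise_floor_sds * max(noise, _EPS):
        raise ValueError("no reference peak: window maximum below noise floor")
    return Spectrum(s.ppm - s.ppm[apex_idx], s.intensity.copy(), s.sample_id)


def excise_regions(
    s: Spectrum,
    remove: Sequence[tuple[float, float]],
    min_points: int = 200,
) -> Spectrum:
    """Drop points falling inside any of the ppm intervals in ``remove``.

    Remaining points keep their order and values. Raises when fewer than
    ``min_points`` (default two bins' worth) survive.
    """
    keep = np.ones(s.n_points, dtype=bool)
    for lo, hi in remove:
        lo, hi = sorted((lo, hi))
        keep &= ~((s.ppm >= lo) & (s.ppm <= hi))
    if keep.sum() < min_points:
        raise ValueError(
            f"insufficient spectrum: {int(keep.sum())} points remain (< {min_points})"
        )
    return Spectrum(s.ppm[keep], s.intensity[keep], s.sample_id)


def _pqn_factors(X: np.ndarray, region_masks: Sequence[np.ndarray]) -> np.ndarray:
    """Per-sample, per-region median-quotient scale factors."""
    factors = np.empty((X.shape[0], len(region_masks)))
    for r, mask in enumerate(region_masks):
        ref = np.median(X[:, mask], axis=0)
        valid = ref > _EPS
        if not np.any(valid):
            raise ValueError(f"degenerate reference: region {r} has no positive median signal")
        q = X[:, mask][:, valid] / ref[valid]
        factors[:, r] = np.median(q, axis=1)
    return factors


def pqn_normalize(
    spectra: Sequence[Spectrum],
    region_split_ppm: float = 4.8,
    return_factors: bool = False,
):
    """Regional probabilistic quotient normalization across a cohort.

    Spectra must share a common axis. For each of the two regions (axis
    below / at-or-above the split) the reference is the point-wise median
    across samples and each sample's region is divided by its median
    quotient to that reference.
    """
    if len(spectra) < 2:
        raise ValueError("PQN needs at least 2 spectra")
    ppm = spectra[0].ppm
    for s in spectra[1:]:
        if s.n_points != ppm.size or not np.allclose(s.ppm, ppm):
            raise ValueError("spectra must share a common ppm axis")
    X = np.stack([s.intensity for s in spectra])
    masks = [ppm < region_split_ppm, ppm >= region_split_ppm]
    if not (np.any(masks[0]) and np.any(masks[1])):
        raise ValueError("region split must fall inside the axis range")
    factors = _pqn_factors(X, masks)
    out = X.copy()
    for r, mask in enumerate(masks):
        out[:, mask] = out[:, mask] / factors[:, r][:, None]
    normalized = [
        Spectrum(ppm.copy(), out[i], spectra[i].sample_id) for i in range(len(spectra))
    ]
    if return_factors:
        return normalized, factors
    return normalized


def bin_spectrum(s: Spectrum, points_per_bin: int = 100) -> BinnedSpectrum:
    """Sum consecutive runs of ``points_per_bin`` points in axis order.

    Bin value = sum of its points' intensities; bin center = mean ppm of its
    points. A trailing remainder shorter than a full bin is dropped and
    logged. Raises when the spectrum is shorter than one bin.
    """
    if points_per_bin < 1:
        raise ValueError("points_per_bin must be >= 1")
    n_bins, remainder = divmod(s.n_points, points_per_bin)
    if n_bins == 0:
        raise ValueError(
            f"spectrum has {s.n_points} points, fewer than one bin of {points_per_bin}"
        )
    if remainder:
        logger.info(
            "dropping %d trailing points (< 1 bin of %d) from %s",
            remainder,
            points_per_bin,
            s.sample_id or "<unnamed>",
        )
    used = n_bins * points_per_bin
    values = s.intensity[:used].reshape(n_bins, points_per_bin).sum(axis=1)
    centers = s.ppm[:used].reshape(n_bins, points_per_bin).mean(axis=1)
    width = points_per_bin * float(np.median(np.abs(np.diff(s.ppm))))
    return BinnedSpectrum(centers, values, width, s.sample_id)


class RegionalPQN(BaseEstimator, TransformerMixin):
    """sklearn-style regional PQN over a samples x points intensity matrix.

    ``fit`` stores the point-wise median reference of the training cohort;
    ``transform`` rescales each row by its per-region median quotient to that
    reference. ``ppm`` is the common axis of the matrix columns.

    Attributes
    ----------
    reference_ : ndarray
        Point-wise median spectrum of the fitted cohort.
    region_masks_ : list of ndarray
        Boolean column masks of the two regions.
    """

    def __init__(self, ppm: np.ndarray | None = None, region_split_ppm: float = 4.8):
        self.ppm = ppm
        self.region_split_ppm = region_split_ppm

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("X must be a 2-D matrix with >= 2 samples")
        ppm = np.arange(X.shape[1]) if self.ppm is None else np.asarray(self.ppm, float)
        if ppm.size != X.shape[1]:
            raise ValueError("ppm axis length must match the number of columns")
        self.region_masks_ = [ppm < self.region_split_ppm, ppm >= self.region_split_ppm]
        if not (np.any(self.region_masks_[0]) and np.any(self.region_masks_[1])):
            raise ValueError("region split must fall inside the axis range")
        self.reference_ = np.median(X, axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def scale_factors(self, X) -> np.ndarray:
        check_is_fitted(self, "reference_")
        X = np.asarray(X, dtype=float)
        factors = np.empty((X.shape[0], 2))
        for r, mask in enumerate(self.region_masks_):
            ref = self.reference_[mask]
            valid = ref > _EPS
            if not np.any(valid):
                raise ValueError(f"degenerate reference: region {r}")
            factors[:, r] = np.median(X[:, mask][:, valid] / ref[valid], axis=1)
        return factors

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        factors = self.scale_factors(X)
        out = X.copy()
        for r, mask in enumerate(self.region_masks_):
            out[:, mask] = out[:, mask] / factors[:, r][:, None]
        return out


class SpectrumBinner(BaseEstimator, TransformerMixin):
    """sklearn-style binning of a samples x points matrix into fixed bins."""

    def __init__(self, points_per_bin: int = 100, ppm: np.ndarray | None = None):
        self.points_per_bin = points_per_bin
        self.ppm = ppm

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.points_per_bin < 1:
            raise ValueError("points_per_bin must be >= 1")
        n_bins = X.shape[1] // self.points_per_bin
        if n_bins == 0:
            raise ValueError("fewer points than one bin")
        self.n_bins_ = n_bins
        self.n_features_in_ = X.shape[1]
        if self.ppm is not None:
            ppm = np.asarray(self.ppm, float)[: n_bins * self.points_per_bin]
            self.bin_centers_ = ppm.reshape(n_bins, self.points_per_bin).mean(axis=1)
        else:
            self.bin_centers_ = None
        return self

    def transform(self, X):
        check_is_fitted(self, "n_bins_")
        X = np.asarray(X, dtype=float)
        used = self.n_bins_ * self.points_per_bin
        return X[:, :used].reshape(X.shape[0], self.n_bins_, self.points_per_bin).sum(axis=2)


DEFAULT_EXCISIONS: tuple[tuple[float, float], ...] = (
    (-np.inf, 0.5),  # upfield periphery incl. TSP
    (4.70, 4.90),  # residual water
    (9.0, np.inf),  # downfield periphery
)


def preprocess_spectra(
    spectra: Sequence[Spectrum],
    reference_search_window: tuple[float, float] = (-0.2, 0.2),
    excisions: Sequence[tuple[float, float]] = DEFAULT_EXCISIONS,
    region_split_ppm: float = 4.8,
    points_per_bin: int = 100,
) -> list[BinnedSpectrum]:
    """Full pre-processing chain in the fixed order calibrate -> excise ->
    regional PQN -> bin."""
    calibrated = [calibrate(s, reference_search_window) for s in spectra]
    excised = [
        excise_regions(c, excisions, min_points=2 * points_per_bin) for c in calibrated
    ]
    normalized = pqn_normalize(excised, region_split_ppm=region_split_ppm)
    return [bin_spectrum(s, points_per_bin) for s in normalized]
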