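"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "BinnedSpectrum", "AbundanceTable"]


@dataclass
class Spectrum:
    """A calibrated 1D NMR trace: a ppm axis and an intensity vector.

    The axis must be strictly monotone (either direction); intensities must be
    finite and of the same length as the axis.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays")
        if self.ppm.size != self.intensity.size:
            raise ValueError(
                f"axis length {self.ppm.size} != intensity length {self.intensity.size}"
            )
        if self.ppm.size >= 2:
            d = np.diff(self.ppm)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("ppm axis must be strictly monotone")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensities must be finite")
        if not np.all(np.isfinite(self.ppm)):
            raise ValueError("ppm axis must be finite")

    @property
    def n_points(self) -> int:
        return int(self.ppm.size)

    def copy(self) -> "Spectrum":
        return Spectrum(self.ppm.copy(), self.intensity.copy(), self.sample_id)


@dataclass
class BinnedSpectrum:
    """Fixed-width bin integrals forming one sample's feature vector (A.U.)."""

    bin_centers_ppm: np.ndarray
    bin_values: np.ndarray
    bin_width_ppm: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.bin_centers_ppm = np.asarray(self.bin_centers_ppm, dtype=float)
        self.bin_values = np.asarray(self.bin_values, dtype=float)
        if self.bin_centers_ppm.size != self.bin_values.size:
            raise ValueError("bin centers and values must have equal length")
        if not np.all(np.isfinite(self.bin_values)):
            raise ValueError("bin values must be finite")
        if not self.bin_width_ppm > 0:
            raise ValueError("bin width must be positive")
        if self.bin_centers_ppm.size >= 2:
            d = np.diff(self.bin_centers_ppm)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError("bin centers must be strictly monotone")

    @property
    def n_bins(self) -> int:
        return int(self.bin_values.size)


# metadata columns every abundance table must carry
_META_COLS = ("ecosystem", "group", "time_day")


@dataclass
class AbundanceTable:
    """Taxa x samples relative-abundance matrix with joined sample metadata.

    ``abundance`` holds relative abundances in [0, 1] with taxa as rows and
    sample ids as columns; ``metadata`` is indexed by sample id and carries at
    least ``ecosystem``, ``group`` and ``time_day``. Column sums must be 1
    within a small tolerance.
    """

    abundance: pd.DataFrame
    metadata: pd.DataFrame
    taxonomy: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        if not set(self.abundance.columns) <= set(self.metadata.index):
            missing = set(self.abundance.columns) - set(self.metadata.index)
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
        for col in _META_COLS:
            if col not in self.metadata.columns:
                raise ValueError(f"metadata must have a '{col}' column")
        vals = self.abundance.to_numpy()
        if vals.size:
            if np.any(vals < 0):
                raise ValueError("relative abundances must be non-negative")
            sums = vals.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > 1e-6):
                bad = self.abundance.columns[np.abs(sums - 1.0) > 1e-6]
                raise ValueError(f"sample columns must sum to 1: {list(bad)[:5]}")
        # keep metadata aligned and restricted to the table's samples
        self.metadata = self.metadata.loc[list(self.abundance.columns)]

    @property
    def taxa(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def samples(self) -> list[str]:
        return list(self.abundance.columns)

    def subset_samples(self, mask: pd.Series) -> "AbundanceTable":
        keep = self.metadata.index[mask.loc[self.metadata.index]]
        return AbundanceTable(
            self.abundance[list(keep)], self.metadata.loc[list(keep)], self.taxonomy
        )
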