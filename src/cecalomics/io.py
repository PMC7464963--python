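"""Plain-text readers and writers for the pipeline's external formats.

Spectra travel as two-column CSV (ppm, intensity; one file per sample),
metadata and matrices as TSV, assignments and configuration as YAML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import AbundanceTable, BinnedSpectrum, Spectrum

__all__ = [
    "write_spectrum_csv",
    "read_spectrum_csv",
    "write_spectra",
    "read_spectra",
    "write_metadata_tsv",
    "read_metadata_tsv",
    "write_binned_matrix_tsv",
    "read_binned_matrix_tsv",
    "write_abundance_table",
    "read_abundance_table",
    "write_assignment_yaml",
    "read_assignment_yaml",
]


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"ppm": s.ppm, "intensity": s.intensity}).to_csv(path, index=False)


def read_spectrum_csv(path: str | Path, sample_id: str | None = None) -> Spectrum:
    df = pd.read_csv(path)
    sid = sample_id if sample_id is not None else Path(path).stem
    return Spectrum(df["ppm"].to_numpy(float), df["intensity"].to_numpy(float), sid)


def write_spectra(spectra: Sequence[Spectrum], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s in spectra:
        write_spectrum_csv(s, directory / f"{s.sample_id}.csv")


def read_spectra(directory: str | Path) -> list[Spectrum]:
    files = sorted(Path(directory).glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no spectrum CSV files under {directory}")
    return [read_spectrum_csv(f) for f in files]


def write_metadata_tsv(meta: pd.DataFrame, path: str | Path) -> None:
    meta.to_csv(path, sep="\t")


def read_metadata_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_binned_matrix_tsv(
    binned: Sequence[BinnedSpectrum], path: str | Path
) -> None:
    """Samples x bins TSV with ppm-center column headers."""
    centers = binned[0].bin_centers_ppm
    df = pd.DataFrame(
        np.stack([b.bin_values for b in binned]),
        index=[b.sample_id for b in binned],
        columns=[f"{c:.4f}" for c in centers],
    )
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_binned_matrix_tsv(path: str | Path) -> tuple[pd.DataFrame, np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    centers = np.array([float(c) for c in df.columns])
    return df, centers


def write_abundance_table(
    table: AbundanceTable, abundance_path: str | Path, metadata_path: str | Path
) -> None:
    table.abundance.to_csv(abundance_path, sep="\t")
    table.metadata.to_csv(metadata_path, sep="\t")


def read_abundance_table(
    abundance_path: str | Path, metadata_path: str | Path
) -> AbundanceTable:
    abund = pd.read_csv(abundance_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return AbundanceTable(abund, meta)


def write_assignment_yaml(
    assignment: Mapping[str, Sequence[tuple[float, float]]], path: str | Path
) -> None:
    data = {m: [[float(lo), float(hi)] for lo, hi in iv] for m, iv in assignment.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_assignment_yaml(path: str | Path) -> dict[str, list[tuple[float, float]]]:
    data = yaml.safe_load(Path(path).read_text())
    return {m: [(float(lo), float(hi)) for lo, hi in iv] for m, iv in data.items()}
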