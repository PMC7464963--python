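"""End-to-end orchestration: configuration, seed fan-out, stage chaining
and JSON reports.

A single global seed fans out to stage-specific seeds through a fixed
``numpy.random.SeedSequence`` derivation, so every stage is independently
reproducible; the configuration hash travels into every report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import MetaboliteSpec, TaxonSpec, TrialDesign, default_metabolite_panel, default_taxa_panel
from .kinetics import build_signal_series, compare_groups, fit_group_kinetics
from .microbiota import (
    alpha_diversity,
    core_otus,
    diff_abundance,
    filter_taxa,
    group_ecology,
    prevalence_matrix,
)
from .plsda import crossval_svc, fit_plsda, select_peaks, smooth_weight_spectrum
from .preprocess import preprocess_spectra
from .simulate import PpmGrid, generate_abundance_tables, generate_nmr_dataset

__all__ = ["RunConfig", "stage_seed", "run_metabolome", "run_microbiota", "run_all"]

logger = logging.getLogger(__name__)

# fixed stage indices of the seed fan-out
_STAGES = ("nmr", "abundance", "chemometrics", "kinetics")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage integer seed (< 2**31) from the global seed."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence([int(global_seed), 101, idx])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class DesignConfig:
    groups: tuple[str, ...] = ("A", "B", "C")
    times_days: tuple[float, ...] = (15.0, 28.0, 42.0)
    n_per_group_per_time: int = 40
    dropouts: dict = field(default_factory=lambda: {28.0: 1, 42.0: 2})
    n_litter_per_group_per_time: int = 3

    def build(self, seed: int) -> TrialDesign:
        return TrialDesign(
            groups=tuple(self.groups),
            times_days=tuple(float(t) for t in self.times_days),
            n_per_group_per_time=self.n_per_group_per_time,
            dropouts={float(k): int(v) for k, v in self.dropouts.items()},
            n_litter_per_group_per_time=self.n_litter_per_group_per_time,
            seed=int(seed),
        )


@dataclass
class NMRConfig:
    ppm_start: float = -0.5
    ppm_stop: float = 9.5
    ppm_step: float = 1.83e-4
    baseline_noise_sd: float = 0.01
    calibration_shift_sd: float = 0.003
    effects: tuple[str, ...] = ("acetate", "butyrate", "lactate", "pyruvate")


@dataclass
class PreprocessConfig:
    reference_window: tuple[float, float] = (-0.2, 0.2)
    excisions: tuple = tuple((float(a), float(b)) for a, b in ((-1e9, 0.5), (4.70, 4.90), (9.0, 1e9)))
    region_split_ppm: float = 4.8
    points_per_bin: int = 100


@dataclass
class ChemometricsConfig:
    n_components: int = 2
    savgol_window: int = 11
    savgol_polyorder: int = 3
    asls_lam: float = 1e5
    asls_p: float = 0.001
    asls_n_iter: int = 10
    snr_threshold: float = 3.0
    noise_window_ppm: tuple[float, float] = (5.5, 6.5)
    svc_C: float = 0.01
    folds: int = 10


@dataclass
class KineticsConfig:
    n_boot: int = 2000
    level: float = 0.95
    grid_points: int = 100
    min_run_days: float = 4.0
    assignment_half_width: float = 0.02
    weight_by_cell_size: bool = False


@dataclass
class MicrobiotaConfig:
    min_abund: float = 0.005
    min_sample_frac: float = 0.01
    core_abund_thresh: float = 0.001
    core_prev_thresh: float = 0.90
    q_threshold: float = 0.05
    ecology_k: int = 9
    n_background: int = 30


@dataclass
class RunConfig:
    """Fully serializable run configuration; identical configs reproduce
    identical outputs."""

    seed: int = 0
    design: DesignConfig = field(default_factory=DesignConfig)
    nmr: NMRConfig = field(default_factory=NMRConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    chemometrics: ChemometricsConfig = field(default_factory=ChemometricsConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    microbiota: MicrobiotaConfig = field(default_factory=MicrobiotaConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "RunConfig":
        data = dict(data)
        kwargs = {"seed": int(data.get("seed", 0))}
        for name, sub_cls in (
            ("design", DesignConfig),
            ("nmr", NMRConfig),
            ("preprocess", PreprocessConfig),
            ("chemometrics", ChemometricsConfig),
            ("kinetics", KineticsConfig),
            ("microbiota", MicrobiotaConfig),
        ):
            if name in data:
                sub = dict(data[name])
                if name == "preprocess" and "excisions" in sub:
                    sub["excisions"] = tuple(tuple(map(float, iv)) for iv in sub["excisions"])
                kwargs[name] = sub_cls(**sub)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_jsonable(self.to_dict()), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        payload = json.dumps(_jsonable(self.to_dict()), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def default_assignment(
    metabolites: Sequence[MetaboliteSpec], half_width: float = 0.02
) -> dict[str, list[tuple[float, float]]]:
    """ppm assignment intervals around each metabolite's quantification peak."""
    return {m.name: [m.quant_interval(half_width)] for m in metabolites}


def run_metabolome(
    config: RunConfig,
    metabolites: Sequence[MetaboliteSpec] | None = None,
    outdir: str | Path | None = None,
    make_figures: bool = False,
) -> dict:
    """Simulate -> preprocess -> per-time-point PLS-DA/SVC -> kinetics.

    Returns the JSON-serializable report; when ``outdir`` is given, writes
    ``metabolome_report.json`` (and figures when requested) there.
    """
    cfg = config
    if metabolites is None:
        metabolites = default_metabolite_panel(effects=cfg.nmr.effects)
    design = cfg.design.build(seed=stage_seed(cfg.seed, "nmr"))
    grid = PpmGrid(cfg.nmr.ppm_start, cfg.nmr.ppm_stop, cfg.nmr.ppm_step)
    spectra, meta = generate_nmr_dataset(
        design,
        metabolites,
        grid=grid,
        baseline_noise_sd=cfg.nmr.baseline_noise_sd,
        calibration_shift_sd=cfg.nmr.calibration_shift_sd,
    )
    logger.info("generated %d spectra (%d clipped concentrations)", len(spectra),
                meta.attrs.get("n_clipped_concentrations", 0))

    binned = preprocess_spectra(
        spectra,
        reference_search_window=cfg.preprocess.reference_window,
        excisions=cfg.preprocess.excisions,
        region_split_ppm=cfg.preprocess.region_split_ppm,
        points_per_bin=cfg.preprocess.points_per_bin,
    )
    centers = binned[0].bin_centers_ppm
    X = np.stack([b.bin_values for b in binned])
    sample_ids = [b.sample_id for b in binned]
    y_group = meta.loc[sample_ids, "group"].to_numpy()
    days = meta.loc[sample_ids, "time_day"].to_numpy(float)

    chem_seed = stage_seed(cfg.seed, "chemometrics")
    cc = cfg.chemometrics
    noise_bins = np.flatnonzero(
        (centers >= cc.noise_window_ppm[0]) & (centers <= cc.noise_window_ppm[1])
    )
    accuracies: dict[str, float] = {}
    peak_counts: dict[str, int] = {}
    for t in sorted(np.unique(days)):
        sel = days == t
        model = fit_plsda(X[sel], y_group[sel], n_components=cc.n_components)
        acc, _ = crossval_svc(
            model.x_scores_, y_group[sel], C=cc.svc_C, folds=cc.folds, seed=chem_seed
        )
        accuracies[f"{t:g}"] = acc
        smoothed = smooth_weight_spectrum(
            model.x_weights_[:, 0],
            savgol=(cc.savgol_window, cc.savgol_polyorder),
            asls=(cc.asls_lam, cc.asls_p, cc.asls_n_iter),
        )
        selection = select_peaks(
            smoothed,
            (int(noise_bins[0]), int(noise_bins[-1]) + 1),
            snr_threshold=cc.snr_threshold,
            ppm=centers,
            component=1,
        )
        peak_counts[f"{t:g}"] = len(selection)
    best_day = max(accuracies, key=lambda d: accuracies[d])

    kc = cfg.kinetics
    kin_seed = stage_seed(cfg.seed, "kinetics")
    assignment = default_assignment(metabolites, kc.assignment_half_width)
    eval_days = np.linspace(min(design.times_days), max(design.times_days), kc.grid_points)
    kin_report: dict[str, dict] = {}
    figures = {}
    for mi, m in enumerate(metabolites):
        series = build_signal_series(binned, meta, assignment[m.name], m.name)
        fits = [
            fit_group_kinetics(
                series,
                g,
                n_boot=kc.n_boot,
                level=kc.level,
                eval_days=eval_days,
                seed=kin_seed + mi,
                weight_by_cell_size=kc.weight_by_cell_size,
            )
            for g in design.groups
        ]
        comparison = compare_groups(fits, min_run_days=kc.min_run_days)
        kin_report[m.name] = {
            "fits": {f.group: {"alpha": f.alpha, "beta": f.beta} for f in fits},
            "flags": [
                {
                    "pair": list(pair),
                    "first_sustained_day": res["first_sustained_day"],
                    "sustained_span_days": res["sustained_span_days"],
                }
                for pair, res in sorted(comparison.items())
                if res["significant"]
            ],
        }
        if make_figures:
            from .plots import plot_kinetics

            figures[m.name] = plot_kinetics(fits)

    report = {
        "config_hash": cfg.hash(),
        "package_version": __version__,
        "seed": cfg.seed,
        "n_spectra": len(spectra),
        "n_bins": int(X.shape[1]),
        "n_clipped_concentrations": int(meta.attrs.get("n_clipped_concentrations", 0)),
        "svc_accuracy_by_day": accuracies,
        "best_day": best_day,
        "selected_peaks_by_day": peak_counts,
        "kinetics": kin_report,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "metabolome_report.json").write_text(
            json.dumps(_jsonable(report), sort_keys=True, indent=2)
        )
        for name, fig in figures.items():
            fig.savefig(outdir / f"kinetics_{name}.svg")
    return report


def run_microbiota(
    config: RunConfig,
    taxa_specs: Sequence[TaxonSpec] | None = None,
    outdir: str | Path | None = None,
    make_figures: bool = False,
) -> dict:
    """Simulate abundance tables -> filtering, differential abundance,
    diversity, core/prevalence/ecology outputs."""
    cfg = config
    if taxa_specs is None:
        taxa_specs = default_taxa_panel()
    mc = cfg.microbiota
    design = cfg.design.build(seed=stage_seed(cfg.seed, "abundance"))
    tables = generate_abundance_tables(
        design, taxa_specs, n_background=mc.n_background
    )

    per_eco: dict[str, dict] = {}
    core_sets: dict[str, list[str]] = {}
    for eco, table in tables.items():
        kept = filter_taxa(table, mc.min_abund, mc.min_sample_frac)
        diff = diff_abundance(kept, q_threshold=mc.q_threshold) if len(kept.abundance) else pd.DataFrame(
            columns=["ecosystem", "time_day", "taxon", "H", "p", "q", "significant"]
        )
        sig = diff[diff["significant"]]
        alpha = alpha_diversity(table, detection=mc.core_abund_thresh)
        core = core_otus(
            table, abund_thresh=mc.core_abund_thresh, prev_thresh=mc.core_prev_thresh
        )
        core_sets[eco] = core
        per_eco[eco] = {
            "n_taxa_kept": int(len(kept.abundance)),
            "n_samples": int(len(table.samples)),
            "significant": [
                {"time_day": float(r.time_day), "taxon": r.taxon, "q": float(r.q)}
                for r in sig.itertuples()
            ],
            "mean_shannon": float(alpha["shannon"].mean()),
            "mean_richness": float(alpha["richness"].mean()),
            "n_core": len(core),
        }

    all_core = sorted(set().union(*core_sets.values())) if core_sets else []
    prev_result = prevalence_matrix(tables, all_core, detection=mc.core_abund_thresh)
    k = min(mc.ecology_k, max(1, len(all_core)))
    ecology = group_ecology(prev_result, k=k) if all_core else {}

    report = {
        "config_hash": cfg.hash(),
        "package_version": __version__,
        "seed": cfg.seed,
        "ecosystems": per_eco,
        "core_taxa": core_sets,
        "n_core_union": len(all_core),
        "ecology_groups": ecology,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "microbiota_report.json").write_text(
            json.dumps(_jsonable(report), sort_keys=True, indent=2)
        )
        prev_result.prevalence.to_csv(outdir / "prevalence_matrix.tsv", sep="\t")
        if make_figures and all_core:
            from .plots import plot_prevalence_heatmap

            plot_prevalence_heatmap(prev_result).savefig(outdir / "prevalence_heatmap.svg")
    return report


def run_all(config: RunConfig, outdir: str | Path | None = None, make_figures: bool = False) -> dict:
    """Both pipelines under one config."""
    return {
        "metabolome": run_metabolome(config, outdir=outdir, make_figures=make_figures),
        "microbiota": run_microbiota(config, outdir=outdir, make_figures=make_figures),
    }
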