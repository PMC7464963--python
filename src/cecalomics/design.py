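"""Trial design and generator-side truth specifications.

The default design mirrors a three-room broiler feeding trial: groups A
(control), B and C (increasing riboflavin supplementation), sampled at days
15, 28 and 42 of the productive cycle, 40 birds per room per sampling, with
caeca and ileum contents collected per bird and litter sampled per pen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialDesign",
    "MetaboliteSpec",
    "Peak",
    "TaxonSpec",
    "default_metabolite_panel",
    "default_taxa_panel",
]


@dataclass(frozen=True)
class TrialDesign:
    """Sampling layout of the trial the synthetic generators emulate.

    ``dropouts`` maps a sampling day to the number of samples missing from
    that day's full complement (removed at random with the design seed). The
    defaults reproduce 120/119/118 caecal samples at the three days — 357
    spectra in total.
    """

    groups: tuple[str, ...] = ("A", "B", "C")
    times_days: tuple[float, ...] = (15.0, 28.0, 42.0)
    n_per_group_per_time: int = 40
    dropouts: Mapping[float, int] = field(default_factory=lambda: {28.0: 1, 42.0: 2})
    ecosystems: tuple[str, ...] = ("caeca", "ileum", "litter")
    n_litter_per_group_per_time: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group_per_time < 1 or self.n_litter_per_group_per_time < 1:
            raise ValueError("all counts must be >= 1")
        if len(self.groups) < 1 or len(self.times_days) < 1:
            raise ValueError("groups and times must be non-empty")
        t = np.asarray(self.times_days, dtype=float)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing and positive")
        for d, k in dict(self.dropouts).items():
            if float(d) not in [float(x) for x in self.times_days]:
                raise ValueError(f"dropout day {d} is not a sampling day")
            if k < 0 or k >= self.n_per_group_per_time * len(self.groups):
                raise ValueError("dropout count out of range")

    def sample_table(self, ecosystem: str = "caeca") -> pd.DataFrame:
        """Per-sample metadata for one ecosystem, dropouts applied.

        Gut ecosystems (one sample per bird per sampling) share the dropout
        pattern; litter uses ``n_litter_per_group_per_time`` samples per
        (group, day) and no dropouts. Deterministic in the design seed.
        """
        if ecosystem == "litter":
            n = self.n_litter_per_group_per_time
            rows = [
                (f"litter_{g}{i + 1:02d}_d{int(d)}", g, float(d))
                for d in self.times_days
                for g in self.groups
                for i in range(n)
            ]
            return pd.DataFrame(rows, columns=["sample_id", "group", "time_day"]).set_index(
                "sample_id"
            )
        rng = np.random.default_rng(np.random.SeedSequence([int(self.seed), 91]))
        frames = []
        for d in self.times_days:
            rows = [
                (f"{ecosystem}_{g}{i + 1:03d}_d{int(d)}", g, float(d))
                for g in self.groups
                for i in range(self.n_per_group_per_time)
            ]
            df = pd.DataFrame(rows, columns=["sample_id", "group", "time_day"])
            k = int(dict(self.dropouts).get(float(d), 0))
            if k:
                drop = rng.choice(len(df), size=k, replace=False)
                df = df.drop(index=drop)
            frames.append(df)
        return pd.concat(frames, ignore_index=True).set_index("sample_id")


@dataclass(frozen=True)
class Peak:
    """One resonance: center (ppm), multiplet components and Lorentzian width.

    ``components`` are (offset_ppm, relative_weight) pairs around the center;
    weights are normalized over the whole metabolite so a unit concentration
    integrates to unit area.
    """

    center: float
    components: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    width: float = 0.002

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("linewidth must be positive")


@dataclass(frozen=True)
class MetaboliteSpec:
    """Generator-side truth for one metabolite.

    ``kinetics`` maps group label to (alpha, beta) on the sqrt-signal scale:
    a sample at day t has latent sqrt-concentration alpha + beta*ln(t) plus
    Normal(0, noise_sd) noise, squared to give the concentration. The first
    peak is the designated quantification peak (kept isolated in the default
    panel) used to derive ppm assignment intervals.
    """

    name: str
    peaks: tuple[Peak, ...]
    kinetics: Mapping[str, tuple[float, float]]
    noise_sd: float = 0.35

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError("metabolite needs at least one peak")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def sqrt_mean(self, group: str, day: float) -> float:
        a, b = self.kinetics[group]
        return a + b * float(np.log(day))

    def quant_interval(self, half_width: float = 0.02) -> tuple[float, float]:
        """ppm interval around the quantification peak (first in the list)."""
        p = self.peaks[0]
        offs = [o for o, _ in p.components]
        return (p.center + min(offs) - half_width, p.center + max(offs) + half_width)


def _s(center: float, width: float = 0.002) -> Peak:
    return Peak(center, ((0.0, 1.0),), width)


def _d(center: float, j: float = 0.011, width: float = 0.002) -> Peak:
    return Peak(center, ((-j / 2, 0.5), (j / 2, 0.5)), width)


def _t(center: float, j: float = 0.012, width: float = 0.002) -> Peak:
    return Peak(center, ((-j, 0.25), (0.0, 0.5), (j, 0.25)), width)


def _q(center: float, j: float = 0.012, width: float = 0.002) -> Peak:
    return Peak(center, ((-1.5 * j, 0.125), (-0.5 * j, 0.375), (0.5 * j, 0.375), (1.5 * j, 0.125)), width)


# Kinetic truths are stated as {group: (alpha, beta)} on the sqrt-signal
# scale. Group effects are planted so that the affected group's curve crosses
# the shared curve near day 15 and separates progressively, becoming
# band-detectable around the second sampling (day 28) at the default noise.
_LN15 = float(np.log(15.0))


def _effect(alpha: float, beta: float, delta_beta: float, cross_day: float = 15.0):
    """(alpha', beta') for a group whose curve crosses the base at cross_day."""
    lnc = float(np.log(cross_day))
    beta2 = beta + delta_beta
    return (alpha - delta_beta * lnc, beta2)


def default_metabolite_panel(
    effects: Sequence[str] = ("acetate", "butyrate", "lactate", "pyruvate"),
) -> list[MetaboliteSpec]:
    """The ten-metabolite caecal panel with literature chemical shifts.

    ``effects`` selects which planted group effects are active: "acetate"
    (group B dampened), "butyrate" (group C rising faster), "lactate" (group
    C declining faster), "pyruvate" (group C dampened late). Metabolites
    without an active effect share identical kinetics across groups. Chemical
    shifts are configuration, not assertions: the first peak of each spec is
    an isolated quantification peak.
    """
    eff = set(effects)

    def kin(alpha, beta, special=None):
        base = {g: (alpha, beta) for g in ("A", "B", "C")}
        if special:
            base.update(special)
        return base

    panel = [
        MetaboliteSpec(
            "acetate",
            ( _s(1.92), ),
            kin(2.0, 0.55, {"B": _effect(2.0, 0.55, -0.45)} if "acetate" in eff else None),
        ),
        MetaboliteSpec(
            "butyrate",
            (_t(0.90), Peak(1.56, ((-0.012, 0.2), (0.0, 0.6), (0.012, 0.2),)), _t(2.16)),
            kin(0.8, 0.35, {"C": _effect(0.8, 0.35, 0.45)} if "butyrate" in eff else None),
        ),
        MetaboliteSpec(
            "lactate",
            (_d(1.33), _q(4.11)),
            kin(2.5, -0.35, {"C": _effect(2.5, -0.35, -0.45)} if "lactate" in eff else None),
        ),
        MetaboliteSpec("propionate", (_t(1.06), _q(2.18)), kin(1.0, 0.30)),
        MetaboliteSpec("succinate", (_s(2.41),), kin(1.8, -0.25)),
        MetaboliteSpec("formate", (_s(8.45),), kin(0.8, 0.15)),
        MetaboliteSpec(
            "pyruvate",
            (_s(2.37),),
            kin(0.5, 0.35, {"C": _effect(0.5, 0.35, -0.30, cross_day=20.0)} if "pyruvate" in eff else None),
        ),
        MetaboliteSpec(
            "aspartate",
            (_d(2.80), _d(2.68), _d(3.89)),
            kin(1.2, 0.05),
            noise_sd=0.5,
        ),
        MetaboliteSpec(
            "glutamate",
            (_t(3.75), Peak(2.05, ((-0.01, 0.5), (0.01, 0.5))), Peak(2.34, ((0.0, 1.0),))),
            kin(1.5, 0.10),
        ),
        MetaboliteSpec(
            "nicotinate",
            (_s(8.94), _s(8.62), _d(7.53)),
            kin(0.9, 0.05),
            noise_sd=0.45,
        ),
    ]
    return panel


@dataclass(frozen=True)
class TaxonSpec:
    """Generator-side truth for one taxon of the abundance generator.

    ``mean_abundance`` maps ecosystem to the mean relative abundance when the
    taxon is present (0 or missing key = never present there).
    ``prevalence`` is either a scalar probability or a mapping whose keys are
    tried in the order (ecosystem, group, day), (group, day), ecosystem,
    "default". ``group_abundance_multiplier`` scales the present-abundance
    mean per group (differential-abundance effects).
    """

    name: str
    mean_abundance: Mapping[str, float]
    prevalence: float | Mapping = 0.9
    group_abundance_multiplier: Mapping[str, float] | None = None

    def prevalence_at(self, ecosystem: str, group: str, day: float) -> float:
        if isinstance(self.prevalence, Mapping):
            for key in ((ecosystem, group, float(day)), (group, float(day)), ecosystem, "default"):
                if key in self.prevalence:
                    p = float(self.prevalence[key])
                    break
            else:
                raise KeyError(
                    f"no prevalence for {self.name} at ({ecosystem}, {group}, {day})"
                )
        else:
            p = float(self.prevalence)
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"prevalence {p} outside [0, 1] for {self.name}")
        return p

    def mean_at(self, ecosystem: str, group: str) -> float:
        m = float(self.mean_abundance.get(ecosystem, 0.0))
        if m < 0:
            raise ValueError("abundances must be >= 0")
        if self.group_abundance_multiplier:
            m *= float(self.group_abundance_multiplier.get(group, 1.0))
        return m


def default_taxa_panel() -> list[TaxonSpec]:
    """A Fig-5-like panel of core and conditionally-core taxa.

    Encodes the ecological archetypes of a broiler trial: caeca-persistent
    commensals, ileum lactobacilli, litter-resident environmental taxa, and
    group/time-dependent shifts (a Bacteroides bloom in group B, a
    Bifidobacterium gain and litter-taxon loss in group C, a Romboutsia-like
    taxon dropping to 62% prevalence at day 42 under supplementation).
    """
    days = (15.0, 28.0, 42.0)

    def per_day(caeca=None, ileum=None, litter=None, default=0.05):
        prev: dict = {"default": default}
        for eco, vals in (("caeca", caeca), ("ileum", ileum), ("litter", litter)):
            if vals is None:
                continue
            if isinstance(vals, dict):
                for (g, d), p in vals.items():
                    prev[(eco, g, float(d))] = p
            else:
                prev[eco] = vals
        return prev

    groups = ("A", "B", "C")
    taxa = [
        TaxonSpec(
            "Faecalibacterium",
            {"caeca": 0.06, "ileum": 0.004, "litter": 0.004},
            per_day(caeca=0.97, ileum=0.5, litter=0.6),
        ),
        TaxonSpec(
            "Lactobacillus",
            {"caeca": 0.01, "ileum": 0.20, "litter": 0.02},
            per_day(caeca=0.5, ileum=0.98, litter=0.9),
        ),
        TaxonSpec(
            "Romboutsia",
            {"caeca": 0.004, "ileum": 0.01},
            per_day(
                caeca={(g, d): (0.95 if (g == "A" and d == 42.0) else (0.62 if d == 42.0 else 0.2)) for g in groups for d in days},
                ileum={(g, d): (0.95 if (g == "A" and d == 42.0) else (0.62 if d == 42.0 else 0.3)) for g in groups for d in days},
            ),
        ),
        TaxonSpec(
            "Bacteroides_fragilis",
            {"caeca": 0.02},
            per_day(caeca={(g, d): (0.95 if (g == "B" and d >= 28.0) else 0.3) for g in groups for d in days}),
            group_abundance_multiplier={"B": 3.0},
        ),
        TaxonSpec(
            "Alistipes_finegoldii",
            {"caeca": 0.01},
            per_day(caeca={(g, d): (0.95 if (g == "A" and d == 42.0) else (0.05 if g == "B" else 0.3)) for g in groups for d in days}),
        ),
        TaxonSpec(
            "Bifidobacterium",
            {"caeca": 0.008},
            per_day(caeca={(g, d): (0.92 if (g == "C" and d >= 28.0) else 0.2) for g in groups for d in days}),
        ),
        TaxonSpec(
            "Escherichia_Shigella",
            {"caeca": 0.006, "ileum": 0.01, "litter": 0.05},
            per_day(caeca=0.6, ileum=0.6, litter=0.95),
        ),
        TaxonSpec("Subdoligranulum", {"caeca": 0.03}, per_day(caeca=0.93)),
        TaxonSpec("Blautia", {"caeca": 0.025}, per_day(caeca=0.94)),
        TaxonSpec(
            "Enterococcus",
            {"ileum": 0.02, "litter": 0.02},
            per_day(
                ileum={(g, d): (0.92 if d >= 28.0 else 0.4) for g in groups for d in days},
                litter=0.9,
            ),
        ),
        TaxonSpec(
            "Corynebacterium",
            {"ileum": 0.004, "litter": 0.04},
            per_day(ileum={(g, d): (0.6 if d >= 28.0 else 0.1) for g in groups for d in days}, litter=0.95),
        ),
        TaxonSpec(
            "Pseudomonas_litter",
            {"litter": 0.05},
            per_day(litter={(g, d): (0.5 if g == "C" else 0.92) for g in groups for d in days}),
        ),
    ]
    return taxa
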