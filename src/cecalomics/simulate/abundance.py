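"""Synthetic taxa x samples relative-abundance tables.

Presence of a specified taxon in a sample is a Bernoulli draw at its
stratum prevalence; present taxa get a log-normal abundance around their
ecosystem mean, floored safely above the 0.1% detection level, absent taxa
get exactly 0. The leftover mass in each sample is shared among unnamed
background taxa via a Dirichlet draw, so every column sums to exactly 1 and
presence/absence of the specified taxa maps one-to-one onto detection above
0.1%.

Reproducibility contract (tests rely on it): presence indicators for
ecosystem ``eco`` are drawn from
``default_rng(presence_seed_sequence(seed, eco_index))`` where ``eco_index``
is the position of ``eco`` in ``design.ecosystems``; the draw order is taxa
in the given order, then strata in design order (days outer, groups inner),
``rng.random(n_stratum) < p`` per stratum.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ..datatypes import AbundanceTable
from ..design import TaxonSpec, TrialDesign, default_taxa_panel

__all__ = ["generate_abundance_tables", "presence_seed_sequence"]

# floor for a "present" abundance; stays above the 0.1% detection threshold
# even after the safety rescale applied when specified taxa overshoot
_PRESENT_FLOOR = 0.0025
_SPECIFIED_CAP = 0.9
_LOGNORM_SIGMA = 0.4


def presence_seed_sequence(seed: int, eco_index: int) -> np.random.SeedSequence:
    """SeedSequence of the presence-indicator stream for one ecosystem."""
    return np.random.SeedSequence([int(seed), 23, int(eco_index), 0])


def _abundance_seed_sequence(seed: int, eco_index: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(seed), 23, int(eco_index), 1])


def generate_abundance_tables(
    design: TrialDesign,
    taxa_specs: Sequence[TaxonSpec] | None = None,
    n_background: int = 30,
    background_alpha: float = 0.3,
    seed: int | None = None,
) -> Mapping[str, AbundanceTable]:
    """One AbundanceTable per ecosystem in the design.

    ``background_alpha`` is the Dirichlet concentration of the unnamed
    background community; values < 1 give the uneven, sparsely-detected
    background typical of amplicon surveys. Raises on an empty taxa list or
    on a prevalence outside [0, 1].
    """
    if taxa_specs is None:
        taxa_specs = default_taxa_panel()
    if len(taxa_specs) == 0:
        raise ValueError("taxa_specs must not be empty")
    base_seed = int(design.seed if seed is None else seed)

    tables: dict[str, AbundanceTable] = {}
    for e_idx, eco in enumerate(design.ecosystems):
        meta = design.sample_table(eco).copy()
        meta.insert(0, "ecosystem", eco)
        n = len(meta)
        groups = meta["group"].to_numpy()
        days = meta["time_day"].to_numpy(float)

        rng_presence = np.random.default_rng(presence_seed_sequence(base_seed, e_idx))
        rng_abund = np.random.default_rng(_abundance_seed_sequence(base_seed, e_idx))

        present = np.zeros((len(taxa_specs), n), dtype=bool)
        for ti, spec in enumerate(taxa_specs):
            for d in design.times_days:
                for g in design.groups:
                    sel = (groups == g) & (days == float(d))
                    p = spec.prevalence_at(eco, g, float(d))
                    present[ti, sel] = rng_presence.random(int(sel.sum())) < p

        values = np.zeros((len(taxa_specs), n))
        for ti, spec in enumerate(taxa_specs):
            means = np.array([spec.mean_at(eco, g) for g in groups])
            draw = means * rng_abund.lognormal(
                -0.5 * _LOGNORM_SIGMA**2, _LOGNORM_SIGMA, size=n
            )
            values[ti] = np.where(present[ti] & (means > 0), np.maximum(draw, _PRESENT_FLOOR), 0.0)

        colsum = values.sum(axis=0)
        over = colsum > _SPECIFIED_CAP
        if np.any(over):
            values[:, over] *= _SPECIFIED_CAP / colsum[over]
            colsum = values.sum(axis=0)

        background = (
            rng_abund.dirichlet(np.full(n_background, background_alpha), size=n).T
            * (1.0 - colsum)
        )
        names = [s.name for s in taxa_specs] + [f"background_{k + 1:03d}" for k in range(n_background)]
        abund = pd.DataFrame(
            np.vstack([values, background]), index=names, columns=meta.index
        )
        tables[eco] = AbundanceTable(abund, meta)
    return tables
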