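"""Abundance-table statistics: taxon filtering, differential abundance,
alpha diversity, the core-taxon prevalence rule and ecological grouping.

Conventions follow the field's reporting rules exactly as printed: a taxon
is "detected" in a sample when its relative abundance strictly exceeds 0.1%;
it belongs to an ecosystem's core microbiota when it is detected in strictly
more than 90% of that ecosystem's samples at at least one time point.
Filtering for compositional analysis instead keeps taxa reaching at least
0.5% abundance in at least 1% of the ecosystem's samples (inclusive
thresholds). The two rules are independent and both operate on the
unfiltered table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.stats import kruskal
from statsmodels.stats.multitest import multipletests

from .datatypes import AbundanceTable

__all__ = [
    "filter_taxa",
    "core_otus",
    "prevalence_matrix",
    "CorePrevalenceResult",
    "group_ecology",
    "diff_abundance",
    "alpha_diversity",
]

DETECTION_THRESHOLD = 0.001  # "detected" = relative abundance > 0.1%


def filter_taxa(
    table: AbundanceTable,
    min_abund: float = 0.005,
    min_sample_frac: float = 0.01,
) -> AbundanceTable:
    """Keep taxa at >= ``min_abund`` in >= ``min_sample_frac`` of samples.

    Applied per ecosystem (a taxon passing in any ecosystem of the table is
    kept); values are not renormalized. An empty result returns an empty
    table with a warning.
    """
    if not (0 < min_abund < 1 and 0 < min_sample_frac < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    keep = pd.Series(False, index=table.abundance.index)
    for eco, meta in table.metadata.groupby("ecosystem"):
        sub = table.abundance[list(meta.index)]
        n = sub.shape[1]
        counts = (sub.to_numpy() >= min_abund).sum(axis=1)
        keep |= pd.Series(counts >= min_sample_frac * n - 1e-12, index=sub.index)
    if not keep.any():
        warnings.warn("taxon filter removed every taxon", stacklevel=2)
    kept = table.abundance.loc[keep[table.abundance.index]]
    out = AbundanceTable.__new__(AbundanceTable)
    out.abundance = kept
    out.metadata = table.metadata
    out.taxonomy = table.taxonomy
    return out


def core_otus(
    table: AbundanceTable,
    times: Sequence[float] | None = None,
    abund_thresh: float = DETECTION_THRESHOLD,
    prev_thresh: float = 0.90,
) -> list[str]:
    """Core taxa: detected at > ``abund_thresh`` in > ``prev_thresh`` of a
    time point's samples, for at least one time point (strict inequalities).
    """
    known = set(table.metadata["time_day"].unique())
    if times is None:
        times = sorted(known)
    else:
        unknown = set(float(t) for t in times) - set(float(t) for t in known)
        if unknown:
            raise ValueError(f"unknown time labels: {sorted(unknown)}")
    core: set[str] = set()
    for t in times:
        samples = table.metadata.index[table.metadata["time_day"] == float(t)]
        sub = table.abundance[list(samples)].to_numpy()
        frac = (sub > abund_thresh).mean(axis=1)
        core |= set(table.abundance.index[frac > prev_thresh])
    return sorted(core)


@dataclass
class CorePrevalenceResult:
    """Core-taxon set, prevalence matrix across strata, ecology labels."""

    core_taxa: list[str]
    prevalence: pd.DataFrame  # index: taxa; columns: (ecosystem, group, time) in %
    strata: list[tuple[str, str, float]]
    ecology_groups: dict[str, str] = field(default_factory=dict)


def prevalence_matrix(
    tables: Mapping[str, AbundanceTable] | AbundanceTable,
    core_taxa: Sequence[str],
    detection: float = DETECTION_THRESHOLD,
) -> CorePrevalenceResult:
    """Percentage of each stratum's samples carrying each core taxon.

    A stratum is an (ecosystem, group, time) cell; prevalence is
    100 * fraction of its samples with abundance > ``detection``. A taxon
    absent from an ecosystem's table scores 0% in its strata.
    """
    if isinstance(tables, AbundanceTable):
        tables = {
            eco: tables.subset_samples(tables.metadata["ecosystem"] == eco)
            for eco in tables.metadata["ecosystem"].unique()
        }
    cols: dict[tuple[str, str, float], pd.Series] = {}
    for eco, table in tables.items():
        meta = table.metadata
        for (g, t), sub_meta in meta.groupby(["group", "time_day"], sort=True):
            if len(sub_meta) == 0:
                raise ValueError(f"stratum ({eco}, {g}, {t}) has zero samples")
            sub = table.abundance[list(sub_meta.index)]
            detected = (sub > detection).mean(axis=1) * 100.0
            detected = detected.reindex(core_taxa, fill_value=0.0)
            cols[(eco, g, float(t))] = detected
    strata = sorted(cols)
    prev = pd.DataFrame({s: cols[s] for s in strata})
    prev.columns = pd.MultiIndex.from_tuples(strata, names=["ecosystem", "group", "time_day"])
    return CorePrevalenceResult(list(core_taxa), prev, strata)


def group_ecology(
    result: CorePrevalenceResult,
    k: int | None = None,
    rules: str | None = None,
    persistence_threshold: float = 90.0,
) -> dict[str, str]:
    """Label core taxa by ecological behaviour across ecosystems.

    Default mode: average-linkage hierarchical clustering of the taxa's
    prevalence-profile vectors (Euclidean), cut into ``k`` groups labelled
    G1..Gk in dendrogram leaf order (deterministic). ``rules="persistence"``
    instead groups taxa by the pattern of ecosystems in which they exceed
    ``persistence_threshold`` prevalence in at least one stratum.
    """
    prev = result.prevalence
    taxa = list(prev.index)
    if rules == "persistence":
        ecosystems = sorted({e for e, _, _ in prev.columns})
        patterns = {}
        for taxon in taxa:
            row = prev.loc[taxon]
            patterns[taxon] = tuple(
                bool((row[e] > persistence_threshold).any()) for e in ecosystems
            )
        labels = {p: f"G{i + 1}" for i, p in enumerate(sorted(set(patterns.values()), reverse=True))}
        result.ecology_groups = {t: labels[patterns[t]] for t in taxa}
        return result.ecology_groups
    if k is None:
        k = min(9, len(taxa))
    if k > len(taxa):
        raise ValueError(f"k={k} exceeds the number of core taxa ({len(taxa)})")
    if len(taxa) == 1:
        result.ecology_groups = {taxa[0]: "G1"}
        return result.ecology_groups
    X = prev.to_numpy(float)
    Z = linkage(pdist(X, metric="euclidean"), method="average")
    raw = fcluster(Z, t=k, criterion="maxclust")
    order = leaves_list(Z)
    relabel: dict[int, str] = {}
    for leaf in order:
        c = raw[leaf]
        if c not in relabel:
            relabel[c] = f"G{len(relabel) + 1}"
    result.ecology_groups = {taxa[i]: relabel[raw[i]] for i in range(len(taxa))}
    return result.ecology_groups


def diff_abundance(
    table: AbundanceTable,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Kruskal-Wallis across groups per taxon per time point, BH-corrected.

    Mid-rank tie handling is scipy's default. BH families are formed within
    each (ecosystem, time point). All-tied taxa get H = 0, p = 1 with a
    warning. Returns a tidy frame with columns ecosystem, time_day, taxon,
    H, p, q, significant (q < ``q_threshold``).
    """
    rows = []
    n_tied = 0
    for (eco, t), meta in table.metadata.groupby(["ecosystem", "time_day"]):
        groups = sorted(meta["group"].unique())
        if len(groups) < 2:
            raise ValueError(f"need >= 2 groups at ({eco}, {t})")
        sample_sets = [meta.index[meta["group"] == g] for g in groups]
        if any(len(s) < 2 for s in sample_sets):
            raise ValueError(f"every group needs >= 2 samples at ({eco}, {t})")
        sub = table.abundance
        pvals, hstats = [], []
        for taxon in sub.index:
            vals = [sub.loc[taxon, list(s)].to_numpy(float) for s in sample_sets]
            flat = np.concatenate(vals)
            if np.all(flat == flat[0]):
                n_tied += 1
                hstats.append(0.0)
                pvals.append(1.0)
                continue
            h, p = kruskal(*vals)
            hstats.append(float(h))
            pvals.append(float(p))
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for taxon, h, p, q in zip(sub.index, hstats, pvals, qvals):
            rows.append((eco, float(t), taxon, h, p, q, bool(q < q_threshold)))
    if n_tied:
        warnings.warn(
            f"{n_tied} taxon/time combinations were all-tied; p set to 1",
            stacklevel=2,
        )
    return pd.DataFrame(
        rows, columns=["ecosystem", "time_day", "taxon", "H", "p", "q", "significant"]
    )


def alpha_diversity(
    table: AbundanceTable,
    detection: float = 0.0,
    base: float = 2.0,
) -> pd.DataFrame:
    """Per-sample observed richness and Shannon index.

    Richness counts taxa above ``detection``; Shannon is
    ``-sum p_i log_base p_i`` over taxa with p_i > 0 (log base 2 by default,
    matching the customary amplicon-survey scale). Raises on an empty sample.
    """
    out = []
    for sid in table.samples:
        p = table.abundance[sid].to_numpy(float)
        if p.sum() <= 0:
            raise ValueError(f"sample {sid} is empty")
        richness = int((p > detection).sum())
        pos = p[p > 0] / p.sum()
        shannon = float(-(pos * np.log(pos) / np.log(base)).sum())
        out.append((sid, richness, shannon))
    return pd.DataFrame(out, columns=["sample_id", "richness", "shannon"]).set_index(
        "sample_id"
    )
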