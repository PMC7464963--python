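# cecalomics

Analysis pipeline for longitudinal broiler-trial multi-omics: the caecal
¹H-NMR metabolome and the caeca/ileum/litter microbiota of three diet
groups (control A; riboflavin-supplemented B and C) sampled at days 15, 28
and 42 of the productive cycle. It is written for researchers who have
processed 1D NMR spectra and taxa × sample relative-abundance tables and
want the full statistical chain — normalization through significance calls
— reproducible, seeded and testable end to end. A synthetic-data generator
emulating the trial design (including its 357 caecal spectra) drives the
test suite, so nothing needs downloading.

## What it computes

**Metabolome.** Post-Fourier-transform spectra are calibrated to the TSP
reference at 0.00 ppm, stripped of the water band and peripheries,
normalized by *regional* probabilistic quotient normalization (median
quotient to the median reference spectrum, one scale factor per axis
region), and bucketed into 0.0183-ppm bins of 100 points. Group structure
is explored with a NIPALS PLS-DA — a PLS2 regression of the bin matrix X
against the one-hot class matrix Y — whose weight spectra, after
Savitzky–Golay smoothing and asymmetric-least-squares baseline removal,
yield SNR-filtered discriminant peaks; separation is scored by stratified
10-fold cross-validation of a linear SVC (C = 0.01). Metabolite kinetics
are fit per group on square-root-transformed signals,

    Y_i = α + β log X_i + ε_i,

with Y the per-day mean of √signal and X the sampling day, via a
Gaussian-family identity-link GLM; 95% confidence bands come from
resampling each (group, day) cell with replacement and refitting (2000
replicates, expanded-percentile envelope). Non-overlapping bands between
groups are read as significantly different means (p < 0.05).

**Microbiota.** Taxa are filtered (≥ 0.5% abundance in ≥ 1% of an
ecosystem's samples), compared across groups per time point with
Kruskal–Wallis + Benjamini–Hochberg (q < 0.05), summarized by observed
richness and Shannon diversity (log₂), and screened for *core* membership:
detected at > 0.1% relative abundance in > 90% of samples in at least one
time point. Core taxa get a prevalence matrix across (ecosystem, group,
time) strata and an ecological grouping (hierarchical clustering of
prevalence profiles, or a rule-based persistence-pattern mode).

See `docs/methods.md` for the model, all defaults and the design
decisions.

## Worked example

Run the full synthetic trial — 357 caecal spectra with a planted group-B
acetate dampening, group-C butyrate rise and faster group-C lactate
decline — through preprocessing, per-day PLS-DA/SVC and bootstrap
kinetics:

```python
from cecalomics.pipeline import RunConfig, run_metabolome

cfg = RunConfig(seed=0)
cfg.nmr.effects = ("acetate", "butyrate", "lactate")
report = run_metabolome(cfg)

print("spectra:", report["n_spectra"], "| bins:", report["n_bins"])
print("SVC accuracy by day:",
      {d: round(a, 3) for d, a in report["svc_accuracy_by_day"].items()})
for met in ("acetate", "butyrate", "lactate"):
    flags = report["kinetics"][met]["flags"]
    print(met, "->", [(f["pair"], round(f["first_sustained_day"], 1)) for f in flags])
```

prints

```
spectra: 357 | bins: 453
SVC accuracy by day: {'15': 0.408, '28': 0.496, '42': 0.55}
acetate -> [(['A', 'B'], 26.2), (['B', 'C'], 27.3)]
butyrate -> [(['A', 'C'], 24.0), (['B', 'C'], 23.2)]
lactate -> [(['A', 'C'], 21.8), (['B', 'C'], 18.8)]
```

Reading it: the planted effects all cross the shared curves at day 15, so
day-15 accuracy sits near the 3-class chance level (0.33) and rises with
bird age; each planted metabolite/pair combination — and nothing else — is
flagged, with the confidence bands separating in the low-to-mid twenties
of days, i.e. resolvable by the second sampling. The seven metabolites
with identical kinetics across groups report no flags.

A command-line interface mirrors the library
(`cecalomics simulate | preprocess | chemometrics | kinetics | microbiota | run-all`),
reading and writing CSV/TSV/YAML; see `cecalomics --help`.

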