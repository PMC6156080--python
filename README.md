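# mcca — microcircuit calcium analysis

Analysis of in-vivo two-photon population calcium imaging, built for
studies that characterise cortical microcircuit function from
spontaneous activity: which stained cells are active at all, how often
each fires, whether a hyperactive subpopulation exists, how synchronous
cell pairs are relative to chance, and whether functionally similar
cells cluster in space. The package also ships a synthetic-recording
generator with full ground truth so that every stage of the analysis can
be validated quantitatively without animal data.

## Who this is for

Groups doing bulk-loaded (e.g. OGB-1 AM) or genetically encoded
indicator imaging of a few hundred somata in a ~440 µm field of view at
15–30 Hz, who want a scripted, reproducible version of the classic
interactive transient-analysis workflow.

## What it computes

**Transient detection.** Each ROI trace is normalised to
ΔF/F = (F/F₀ − 1)·100 % against a quiet baseline window, smoothed with an
iterated (1,2,1)/4 binomial kernel (default 30 iterations), and
de-trended with a zero-phase running-median high-pass. A peak is a
sample where the first derivative crosses zero with negative curvature
and the amplitude exceeds the local baseline mean by 3 baseline-noise
SDs; the baseline is the median of the nearest activity-free 10-s span
preceding the peak. The transient's foot and tail are the first samples
on either side of the peak within 0.5 SD of baseline, and its area
(AUC) is the trapezoidal integral of ΔF/F − baseline between them, in
(ΔF/F %)·s.

**Functional classification.** Per-cell frequency f = 60·events/duration
(transients/min) assigns silent (no events), low (f < 0.3), medium
(0.3 ≤ f ≤ 3) and hyperactive (f > 3) classes. Cells whose median event
duration exceeds 4 s are flagged astrocyte-like on kinetic grounds and
excluded from network metrics.

**Synchrony.** Event onsets are binned into 328-ms binary rasters;
pairwise synchrony is Pearson's r between bin vectors. Chance levels
come from a two-step surrogate: each raster is reassigned to a randomly
selected ROI, then event times are redistributed uniformly with a 1-s
minimum separation (counts conserved exactly). An OLS fit of r against
pairwise Euclidean distance quantifies spatial structure of co-activity.

**Spatial clustering.** The mean pairwise distance of every class pair
(SS, SL, …, HH) is compared against the distribution obtained by
permuting functional labels with cell positions fixed (add-one,
two-sided permutation p-values).

**Group statistics.** Per-recording summaries (density, active fraction,
mean frequency, mean AUC, subgroup proportions, cumulative frequency
distributions, mean pairwise r) are compared between groups with a
normality screen followed by t or Mann-Whitney tests, chi-square on
subgroup counts, and two-way ANOVA on cumulative distributions.

**Synthetic data.** `GeneratorConfig`/`generate_population` simulate
populations with configurable silent fraction, per-class Poisson event
rates with minimum separation, difference-of-exponentials transient
kernels (fast-rise/1-s-decay neurons, 8-s-decay astrocyte-like cells),
Gaussian noise at a chosen SNR, and spatially localised co-active
ensembles with Gaussian membership footprints — plus optional rendering
of a full image stack against ROI masks.

## Worked example

```python
import numpy as np
from mcca import (GeneratorConfig, generate_population, analyze_recording,
                  bin_raster, pair_table, distance_correlation_fit,
                  population_summary, shuffle_raster, pearson_matrix)
from mcca.io import cells_to_frame

cfg = GeneratorConfig(n_cells=150, silent_fraction=0.3, astrocyte_fraction=0.04,
                      class_weights=(0.35, 0.55, 0.10),
                      n_ensembles=5, ensemble_sigma_um=50.0,
                      ensemble_rate_per_min=1.0, p_participate=0.6, seed=1)
rec, truth = generate_population(cfg)
cells = analyze_recording(rec)

neurons = [c for c in cells if c.kind == "neuron"]
trains = [np.array([e.peak_time_s for e in c.events]) for c in neurons]
xy = rec.roi_xy_um[[i for i, c in enumerate(cells) if c.kind == "neuron"]]
raster = bin_raster(trains, rec.duration_s)
pairs = pair_table(raster, [c.activity_class for c in neurons], xy)
fit = distance_correlation_fit(pairs)
summary = population_summary(cells_to_frame(cells), field_um=rec.field_um,
                             pairs=pairs)

sr = shuffle_raster(trains, rec.duration_s, mode="full",
                    rng=np.random.default_rng(2))
r_s, kept = pearson_matrix(sr)
iu = np.triu_indices(kept.size, 1)

print(f"cells: {summary['n_cells']}  neurons: {summary['n_neurons']}  "
      f"density: {summary['density_cells_per_mm2']:.0f} cells/mm^2")
print(f"active: {summary['fraction_active_pct']:.1f}%  "
      f"mean frequency: {summary['mean_frequency_trans_per_min']:.2f} trans/min  "
      f"mean AUC: {summary['mean_auc_dff_s']:.1f} (dF/F%)*s")
print("subgroups (% of active):",
      {k: round(v, 1) for k, v in summary['subgroup_pct_of_active'].items()})
print(f"mean pairwise r: {summary['mean_pairwise_r']:.4f}  "
      f"shuffled: {float(np.mean(r_s[iu])):.5f}")
print(f"r-vs-distance slope: {fit.slope:.2e} per um  (p = {fit.p_value:.2e})")
```

prints

```
cells: 150  neurons: 147  density: 775 cells/mm^2
active: 63.3%  mean frequency: 1.40 trans/min  mean AUC: 50.2 (dF/F%)*s
subgroups (% of active): {'low': 8.6, 'medium': 79.6, 'hyper': 11.8}
mean pairwise r: 0.0059  shuffled: 0.00001
r-vs-distance slope: -9.50e-05 per um  (p = 6.68e-23)
```

Reading the numbers: of 147 neurons, 63 % showed spontaneous transients;
active cells fired 1.40 transients/min on average with a mean transient
area of ~50 (ΔF/F %)·s. Mean pairwise synchrony (r = 0.0059) collapses to
chance (≈ 0) after the two-step shuffle, and synchrony falls off with
distance (negative slope, p ≪ 0.01) because the simulated co-active
ensembles have 50-µm footprints. The density is low relative to a fully
stained field because only 150 cells were simulated in (0.44 mm)².

## Command line

```sh
mcca simulate --config cfg.yaml --out sim/            # traces.csv, rois.csv, truth.csv
mcca detect --traces sim/traces.csv --rois sim/rois.csv --rate 15.2 \
            --out events.csv --cells cells.csv
mcca network --events events.csv --cells cells.csv --rois sim/rois.csv \
             --duration 360 --out report/          # pairs.csv, summary.json, tests.json
mcca run --config cfg.yaml --out run/                 # all stages + manifest
```

Exit codes: 0 success, 2 configuration error, 1 stage failure. `mcca run`
writes a `manifest.json` with the config hash, per-stage seeds and output
paths; reruns with the same config and seed are byte-identical.

## Layout

| path | contents |
| --- | --- |
| `src/mcca/io.py` | Recording/RoiMaskSet containers, CSV and TIFF readers/writers, ROI trace extraction |
| `src/mcca/synthetic.py` | generator configuration, event trains, kernels, trace/movie rendering, ground truth |
| `src/mcca/detection.py` | ΔF/F, smoothing, drift removal, two-pass peak detection, event refinement, classification |
| `src/mcca/network.py` | rasters, Pearson matrices, surrogates, distance fits, spatial permutation test, group stats |
| `src/mcca/pipeline.py` | config validation, stage orchestration, manifest, determinism |
| `src/mcca/cli.py` | `mcca simulate / detect / network / run` |
| `docs/methods.md` | models, parameter choices, numerical decisions, limitations |
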