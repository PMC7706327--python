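# rhizocore

Virtual soil coring of simulated root systems: a pipeline for evaluating
soil-coring strategies for root length density (RLD) phenotyping in maize
and common bean.

The package

* simulates plots of four plants whose root systems differ only in
  axial/basal emergence angle (shallow / intermediate / deep phenotypes),
  with gravitropism, extension, branching and tip deflection as stochastic
  variables and a fixed elongation budget so total root length is
  phenotype-invariant;
* extracts virtual 44 mm soil cores at six named locations (plus a random
  location per replicate) in 10 cm depth increments to 60 cm, and computes
  the true whole-plot RLD profile;
* estimates the whole-plot profile from core subsets by Voronoi-area
  weighting of the symmetry-expanded coring locations over the periodic
  row-by-plant unit cell, alongside the conventional unadjusted mean;
* evaluates strategies by TOST equivalence testing against truth, rooting
  depth metrics (D50/D80/D90/D95), Manhattan-distance subset rankings,
  resampling ANOVA power curves, and quadratic discriminant classification
  of phenotypes from single-core profiles.

## Quick start

```python
from rhizocore import (
    SimConfig, simulate_plot, extract_core, whole_plot_profile,
    default_layout, voronoi_weights, CoreSpec,
)

config = SimConfig.for_study("maize", "deep")
plot = simulate_plot(config, seed=1)
truth = whole_plot_profile(plot)

layout = default_layout("maize")
core = extract_core(plot, CoreSpec(center=layout.locations[3], location_id=3))
weights = voronoi_weights(layout, (1, 2, 3, 4, 5, 6))
```

## CLI

```bash
rhizocore simulate --species bean --phenotype deep --seed 3 --out segments.csv
rhizocore layout   --species maize --subset 1,3,6
rhizocore core     --species maize --location 3 --seed 2
rhizocore study    --seed 1 --scale test --outdir study_output
rhizocore study    --seed 1 --scale full --outdir study_full   # 100 reps/phenotype
```

`rhizocore study` writes tidy CSVs (core samples, whole-plot profiles, TOST
equivalence matrix, subset rankings, depth metrics, power curves, QDA
misclassification tables), Voronoi weights as JSON, and a run manifest.
`estimate`, `tost`, `power` and `qda` operate on core-sample CSV tables in
the documented schema (`species, phenotype, replicate, location,
depth_top_cm, depth_bottom_cm, root_length_cm, rld_cm_cm3`), so field data
in the same shape can be analyzed with the same estimators.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, property-based invariants, and
`tests/test_acceptance.py`, which checks the calibrated study's headline
behaviors (total-length invariance, QDA separability targets, the
Voronoi-vs-unadjusted equivalence ordering, oracle equivalences for the
geometric and statistical kernels, statistical calibration, determinism).

## Layout

```
src/rhizocore/
  simulate.py   stochastic geometric root-architecture generator
  coring.py     segment-cylinder intersection, core extraction, truth profiles
  layout.py     coring locations, symmetry expansion, Voronoi weights, estimators
  depth.py      depth quantiles (D50...D95), Manhattan distance
  stats.py      TOST, ANOVA + Tukey HSD, QDA, resampling power
  pipeline.py   study orchestration, subset evaluation, CSV/JSON I/O
  cli.py        click command-line interface
```
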