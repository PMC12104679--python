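# needledyn

Image-based early detection of drought stress in conifer seedlings.

`needledyn` implements a complete, testable analysis pipeline around needle-angle
dynamics in time-lapse side-view imagery:

* **`synth`** — seeded synthetic experiments: rendered scene frames (four potted
  seedlings plus a 24-patch color chart per frame), matching float32 thermal
  maps, environment and physiology tables, per-needle apical angle annotations,
  and full ground truth (angles, vitality states, per-plant pixel masks).
  Drought seedlings wilt in the evenings from a configurable onset session, a
  configurable fraction recover the next morning, and wilted seedlings die
  within 1–2 days; a late physiological response (quenching rise, leaf warming)
  switches on at a separate session.
* **`colormask`** — chart-based affine color correction, excess-green/Otsu or
  manual-bounds segmentation, component cleanup and hole filling, and per-plant
  mask splitting by ROI overlap (connected objects outside a rectangle stay
  with their plant).
* **`morpho`** — seedling-level morphometrics from a binary mask: area, longest
  path through the centroid, width/height, convex hull area and vertex count,
  solidity, crack-boundary perimeter, center of mass, and fitted ellipse
  center, all under explicit corner-lattice / pixel-center conventions.
* **`angles`** — needle angle from base/tip coordinates, quadrant averaging,
  the six 30° STx bins, the BD-M / PM-M / PM-M(ST) difference parameters, a
  minimum-sample continuation rule, and apical vitality classification
  (survival / next-morning recovery / death) with per-session tallies.
* **`thermal`** — Tetens-form leaf and air vapor pressures, vapor pressure
  deficit, both crop-water-stress-index variants, leaf temperature difference,
  and leaf-temperature extraction from thermal maps under labeled regions.
* **`stats`** — mixed repeated-measures ANOVA (1–2 within factors, optional
  Greenhouse–Geisser correction), Bonferroni pairwise t-tests with compact
  letter displays, Kruskal–Wallis + Mann–Whitney battery, stepwise multiple
  regression with R²/adjusted R², standardized betas, tolerance/VIF and
  Durbin–Watson, and correlation-matrix PCA.
* **`detect`** — the orchestrated pipeline and the earliest-detection report:
  per parameter, the earliest session at which drought and control diverge
  (omnibus-gated, report-wide Bonferroni).
* **`io_formats`** — PNG/TIFF/CSV/YAML/JSON readers and writers with schema
  validation and a checksummed run manifest.

On the default synthetic scenario the report reproduces the qualitative
ordering that motivates the method: needle-angle difference parameters and
Center of Mass(y) flag at the evening of day 2, while chlorophyll-fluorescence
and needle-temperature parameters respond only on day 6.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria (analytic anchors,
brute-force oracle equivalence for the morphometrics, stepwise parameter
recovery, type-I calibration of the ANOVA and nonparametric batteries, and the
end-to-end detection ordering).

## CLI

```bash
# generate a synthetic experiment (frames, thermal maps, tables, manifest)
needledyn simulate --seed 1 --out-dir runs/sim

# full pipeline: simulate -> color correction -> masks -> morphometrics ->
# angles -> thermal indices -> detection report
needledyn analyze --seed 1 --out-dir runs/analysis --alpha 0.05

# re-render a detection report as markdown
needledyn report --report-csv runs/analysis/detection_report.csv

# segment a single image
needledyn mask photo.png --out mask.png --auto-threshold --min-component 20 --fill-holes
```

`analyze` also accepts `--entry-p/--removal-p` (stepwise regression thresholds)
and `--gg-correction` (sphericity correction in the repeated-measures ANOVA).
A YAML scenario file can be passed with `--config`; see
`needledyn.synth.ExperimentConfig` for every knob.

## Python API sketch

```python
from needledyn.synth import ExperimentConfig, simulate_experiment
from needledyn.detect import analyze_simulation

cfg = ExperimentConfig(rng_seed=1)
pipe = analyze_simulation(simulate_experiment(cfg))
print(pipe.report.table)          # earliest significant session per parameter
print(pipe.vitality_tally)        # per-session survival/recovery/death %
print(pipe.rm_anova.table)        # 3-way repeated-measures ANOVA
```
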