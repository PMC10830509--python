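# coralsettle

Settlement-competency analysis for coral larval assay time series.

Given repeated 24-hour settlement assays (wells of larvae exposed to
candidate settlement cues across larval ages), the package:

- **simulates** assay datasets with known ground truth (`coralsettle.synthetic`),
  including logistic competency onset, cue-specific effects, multimodal
  temporal settlement, and plate-level dependency;
- **binarizes** cohort settlement at a threshold (default 0.3) and fits a
  **hierarchical Bayesian logistic model** of competency against age × cue,
  extracting **TC50** (age at 50% cohort competency probability) with 95%
  credible intervals, threshold sweeps (0.1–0.9), and pairwise cue
  exceedance contrasts (`coralsettle.competency`);
- fits a **binomial spline GAM** of settlement proportion against a cubic
  regression spline of age (≤5 knots) conditional on cue, with a
  plate-by-age varying effect, integrates each fitted curve to a posterior
  **AUC** per draw (trapezoid, resolution 100) and **ranks cues** by
  exceedance probabilities (`coralsettle.gam`);
- computes species-level summaries: short/mid/long precompetency classes
  (boundaries 3 and 5 days), cross-species statistics, the oocyte-diameter
  regression, passive-transport distances, and competency × exponential
  survival dispersal-potential curves (`coralsettle.summaries`).

Sampling uses a built-in No-U-Turn sampler with dual-averaging step-size
and windowed diagonal mass adaptation (`coralsettle.mcmc`), with split-R̂
and effective-sample-size diagnostics. Defaults follow the published
configuration: 3 chains × 6000 iterations, warmup 2000, thinned by 10.

A 21-species summary table (TC50 medians, credible intervals, best cue,
precompetency class, average oocyte diameter) ships as a packaged CSV
fixture (`coralsettle.synthetic.table1_fixture`).

## Command line

```sh
coralsettle simulate --onset 4 --slope 1.5 --seed 1 --out assays.csv
coralsettle fit-tc50 --input assays.csv --out out/ --seed 1
coralsettle sweep --input assays.csv --thresholds 0.1,0.3,0.5 --out sweep.csv
coralsettle fit-gam --input assays.csv --knots 5 --out out/
coralsettle rank-cues --auc out/auc_synthetic.csv --cutoff 0.95
coralsettle classify --tc50 2.12
coralsettle summarize                 # packaged 21-species table
coralsettle regress-egg
coralsettle transport --speed 10 --days 4
coralsettle dispersal --input curve.csv --decay 0.05 --out dispersal.csv
coralsettle run-all --input assays.csv --out out/ --seed 1
```

`run-all` executes every stage (binarize → logistic TC50 → optional
threshold sweep → GAM → AUC ranking → summaries), writes all outputs as
CSV/structured text under `--out`, and records a `manifest.json` with the
config snapshot, seed, and input/output checksums; reruns with the same
seed reproduce output checksums exactly. A YAML run config can be passed
via `--config` (see `coralsettle.io.RunConfig`).

## Layout

```
src/coralsettle/
  datatypes.py    shared record types and sampler configuration
  synthetic.py    assay simulation + packaged species table
  mcmc.py         NUTS sampler, split-Rhat / ESS diagnostics
  competency.py   binarization, logistic TC50 model, sweeps, contrasts
  gam.py          spline basis, binomial GAM, AUC, cue ranking
  summaries.py    classes, cross-species stats, regression, dispersal
  io.py           CSV formats, run config/manifest, pipeline
  cli.py          command-line interface
tests/            unit, property, and acceptance suites
scripts/acceptance.py
```
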