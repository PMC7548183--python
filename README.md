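# rtelab

Analysis toolkit for **reciprocal transplant experiments** (RTE) on tree
seedlings: germination, survival, growth and herbivory of seeds
translocated between habitats and regions, with a single combined test of
microgeographic local adaptation.

## What it does

* **Data model & I/O** (`rtelab.records`) — long-format CSV tables of
  individuals (design factors, shadehouse time, germination timing, yearly
  fates) and measurements (height, diameter, leaf count, herbivory score),
  with full validation, count tabulations (seeds planted / germinated at
  transplant / germinated overall / alive at study end), herbivory
  class-midpoint scoring, relative growth rates, and geometric survival
  coding with right-censoring.
* **Synthetic cohorts** (`rtelab.simulate`) — a generative model matching
  the analysis assumptions (logit germination with shadehouse-time slopes,
  geometric yearly survival per design cell, Gaussian log-scale growth
  with age interactions, 5-class leaf herbivory), fully reproducible from
  one master seed with per-stage substreams.
* **GLMs from scratch** (`rtelab.glm`) — design matrices with sum-to-zero
  or treatment coding and estimability checks; binomial-logit IRLS with
  separation handling; censored geometric time-to-event regression by
  Newton iterations; Gaussian linear models via QR; Wald tests.
* **Adjusted means & the home/away contrast** (`rtelab.adaptation`) —
  least-squares means by prediction averaging over nuisance cells
  (coding-invariant), pairwise comparisons with multiplicity control, and
  the combined sympatric-vs-allopatric contrast
  `C = (m11 + m22) - (m12 + m21)` with delta-method inference and
  significance stars, evaluated age by age.
* **Conditional inference trees & forest** (`rtelab.ctree`) — recursive
  binary splits accepted only when a permutation independence test
  (exact enumeration or Monte Carlo) rejects after Bonferroni adjustment
  across covariates; text/DOT/JSON export; bootstrap forest with
  out-of-bag permutation variable importance.
* **Pipeline & CLI** (`rtelab.pipeline`, `rtelab.cli`) — one command from
  raw (or simulated) tables to a deterministic report bundle.

## CLI

```sh
rte simulate --seed 1 --out data/           # synthetic individuals/measurements
rte validate --individuals data/individuals.csv --measurements data/measurements.csv
rte counts   --individuals data/individuals.csv --by mother_id
rte analyze  --individuals data/individuals.csv --measurements data/measurements.csv --out results/
rte trees    --individuals data/individuals.csv --measurements data/measurements.csv --out results/
rte run      --out results/                 # full pipeline on the bundled synthetic design
rte run      --config analysis.yaml --out results/
```

The `analyze` stage writes `lsmeans.csv` and `contrasts.csv` (the
plot-ready per-trait, per-age home/away results); `trees` writes one
`.txt`/`.dot`/`.json` triple per response. `rte run` produces the whole
bundle plus `manifest.json` (config hash, seed, stage log).

## Layout

```
src/rtelab/
  records.py     data model, validation, CSV I/O, derived traits
  datasets.py    bundled reference count tables (510-seed cohort)
  simulate.py    synthetic RTE generator
  glm.py         design matrices + binomial/geometric/gaussian fitters
  adaptation.py  adjusted means, pairwise comparisons, home/away contrast
  models.py      standard model term lists and response-frame builders
  ctree.py       permutation trees and forest importance
  pipeline.py    end-to-end orchestration
  cli.py         `rte` command-line interface
tests/           pytest suite incl. tests/test_acceptance.py
scripts/acceptance.py
```
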