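# facdeg

Two-level full factorial design and analysis for forced-degradation
optimization, plus the statistics of analytical method validation.

The package covers the complete desk workflow of a stress-testing study:

* **Design** — construct 2^k full factorial designs in standard (Yates)
  order; convert between actual factor settings and coded ±1 levels
  (`facdeg.design`).
* **Effects** — estimate all factorial coefficients by orthogonal
  contrasts, run the Yates pairwise algorithm, screen effect significance
  with F tests against a pooled error term, and reduce the model by
  dropping inert factors (`facdeg.effects`).
* **Optimization** — invert the (reduced) model in closed form to find
  factor settings that achieve a target response, tabulate contour lines,
  and emit decoded actual-unit operating conditions (`facdeg.optimize`).
* **Validation** — calibration least-squares regression, %RSD, balanced
  within/between-day one-way ANOVA with an F test against the critical
  value (`facdeg.validation`).
* **Simulation** — seed-deterministic generators for factorial responses,
  day-nested recovery panels and calibration standards, so every stage is
  testable without external data (`facdeg.simulate`).

Bundled plain-text fixtures (`facdeg/data/`) carry an 8-run alkali
degradation study (NaOH 0.1–1.0 N, irradiation time 15–30 min, microwave
power 420–700 W, % degradation response) and recovery panels at 80/100/120
mg, used throughout the tests and the acceptance report.

## CLI

```sh
facdeg design   --out design.csv                       # 2^k matrix, actual units
facdeg fit      --out-dir fit/ --pool X1X2,X1X3,X1X2X3 # model.json + effects.csv + report
facdeg optimize --model fit/model.json --drop naoh \
                --target 10 --fix naoh=0 --solve power \
                --grid time=-1,-0.75,-0.5,-0.25,0,0.25,0.5,0.75,1 \
                --out-dir opt/                         # contour table + report
facdeg validate --out-dir val/                         # %RSD, ANOVA, F verdicts
facdeg simulate --kind recovery --seed 7 --out sim.csv # synthetic inputs
```

`fit`, `validate` and `design` fall back to the bundled datasets when no
input files are given; all subcommands accept the documented CSV/YAML/JSON
dialects (see `facdeg/io.py`).

## Python API

```python
import facdeg as fd
from facdeg import datasets

design = datasets.load_alkali_design()
model = fd.estimate_coefficients(design)          # saturated 2^3 fit
screen = fd.screen_effects(design)                # Yates screening, pooled error
reduced = fd.reduce_model(model, ["naoh"])        # drop an inert factor
rec = fd.recommend_conditions(reduced, target_y=10.0, fixed={"naoh": 0.0})
```

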