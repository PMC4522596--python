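# granulekit

Quantitative analysis of the material state of RNP granules — P bodies,
stress granules and related protein–RNA condensates — from fluorescence
microscopy. The package is for cell biologists and image analysts who
need to decide, with numbers, whether a granule behaves like a liquid
droplet or like a solid, amyloid-like aggregate.

Four operational criteria separate the two states, and each has a module:

1. **Turnover (`granulekit.frap`)** — FRAP / photoconversion traces are
   background-subtracted and double-normalized against a reference focus,

       I_F,norm(t) = [(I_F − I_B)/I_F,pre] / [(I_R − I_B)/I_R,pre],

   which cancels acquisition bleaching. A QC step fits y = A·e^{p·x} to
   the post-bleach reference, back-extrapolates over the baseline and
   excludes cells whose reference focus was itself photoconverted. The
   recovery is fit with y = A(1 − e^{−p·x}) and summarized as the
   half-recovery time t₁/₂ = ln 2 / p: tens of seconds for liquid-like
   granules, minutes for amyloid-like assemblies. Group output: medians,
   quartiles, unpaired t-test.
2. **Shape (`granulekit.morphometry`)** — thresholding + particle
   analysis with Circularity = 4π·Area/Perimeter² (1 for a perfect
   circle), plus foci-to-cytoplasm partitioning ratios, granule
   count/size time series and fusion-event detection.
3. **Internal mixing (`granulekit.photomanipulation`)** — kymographs and
   the half-bleach asymmetry A(t) = (mean_unbleached − mean_bleached)/(sum),
   which decays as e^{−2kt} for a droplet with internal exchange rate k
   and stays flat for a solid.
4. **Dissolution (`granulekit.photomanipulation`)** — per-structure
   normalized intensity curves under a dispersing treatment such as
   1,6-hexanediol; liquid-like structures dissolve, amyloids persist.

Everything is validated against `granulekit.synthetic`, a seeded
generator producing FRAP traces, granule image fields, half-bleach and
dissolution stacks with analytic ground truth, so every stage is tested
by parameter recovery. See `docs/methods.md` for models, defaults and
limitations.

## Worked example

Simulate the two canonical cohorts — six liquid P-body-like cells with a
true median half-time of 22 s and four amyloid-like cells at 131 s —
and run the full normalize/QC/fit/summarize pipeline:

```python
import json
from granulekit import RunConfig, run_pipeline

config = RunConfig(
    stages=["simulate", "frap"], seed=1, out_dir="demo",
    groups={
        "pbody":   {"t_half_true": 22.0,  "n_cells": 6, "n_postbleach": 300},
        "amyloid": {"t_half_true": 131.0, "n_cells": 4, "n_postbleach": 900},
    },
)
summary = run_pipeline(config)
print(json.dumps(summary["frap"]["groups"], indent=2, sort_keys=True))
```

prints

```json
{
  "amyloid": {
    "median_t_half_s": 130.57032868726736,
    "n_excluded": 0,
    "n_traces": 4,
    "n_usable": 4
  },
  "pbody": {
    "median_t_half_s": 22.051914330923033,
    "n_excluded": 0,
    "n_traces": 6,
    "n_usable": 6
  }
}
```

Both medians recover their generative truths to well within a percent at
realistic noise; no cell was rejected or QC-excluded. The accompanying
`summary["frap"]["comparison"]` carries the two-group t-test
(t = 217.1, p = 2.3e-16 here — the two states are unambiguously
different), and `demo/frap_fits.csv` holds the per-cell fits. The same
analyses are available from the shell:

```sh
granulekit simulate --kind frap --t-half 22 --n-cells 6 --seed 1 --out sim
granulekit frap-fit --traces sim/traces.csv --out results
granulekit morphometry --stack field.tif --pixel-size 0.08 --out tables
granulekit halfbleach --stack hb.tif --mask mask.tif --background 100
granulekit dissolve --stack treat.tif --labels labels.tif --reference-frame 5
```

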