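# cmost

An open microsimulation of colorectal-cancer natural history and screening:
individual-level adenoma initiation, progression and regression over 13 colon
segments in quarterly time steps; preclinical cancer with sojourn times and
stage dwell; colonoscopy / rectosigmoidoscopy / stool-test screening with
polypectomy, complications and guideline surveillance; cost accrual with 3%
discounting; and automated 4-step calibration of the natural-history
parameters against a 105-point epidemiological benchmark set.

Three calibrated parameterizations differing in median adenoma dwell time
ship with the package (8, 13 and 19 years); the 13-year variant is the
default everywhere.

## Library quick start

```python
from cmost import (builtin_params, LifeTable, ScreeningPlan,
                   simulate_population, compare_arms)

params = builtin_params(13)            # calibrated 13-year-dwell variant
lt = LifeTable.us_2008()

plan = ScreeningPlan(modality="colonoscopy", start_age=50, stop_age=75,
                     interval_y=10)
screened = simulate_population(params, lt, plan, n=100_000, seed=1)
baseline = simulate_population(params, lt, None, n=100_000, seed=1)
print(compare_arms(screened, baseline).as_dict())
```

Paired arms run with the same seed share natural-history randomness exactly
(counter-based RNG keyed per individual/lesion/quarter), so arm differences
are pure screening effects.

Scenario runners reproducing the canned experiments live in
`cmost.scenarios`: `run_trial_emulation` (one/two-time rectosigmoidoscopy
trial, ages 55-74, 11.9-year follow-up), `run_decennial_colonoscopy`
(colonoscopy every 10 years, ages 50-75), `run_max_clinical_incidence_reduction`
(perfect lesion removal at age 65) and `run_single_colonoscopy_sweep`
(optimal age of a single lifetime colonoscopy).

## CLI

```bash
cmost params validate src/cmost/data/params_cmost13.yaml
cmost run --n 100000 --seed 1 --out runs/base
cmost scenario decennial --n 100000 --seed 1
cmost calibrate --dwell 13 --n 50000 --out fitted.yaml   # ~15 min
cmost report runs/base
```

## Data fixtures

`src/cmost/data/` contains plain-text fixtures: the 105-point benchmark set
(SEER-2005-09-style incidence/mortality, adenoma prevalence, stage
distributions, a trial incidence-reduction target), a 2008-US-style period
life table, a 13-segment adenoma location distribution, stage-specific
5-year CRC survival, 2012-Medicare-style costs, and the calibrated parameter
files (`params_cmost{8,13,19}.yaml`, produced by `cmost.calibration`).

## Layout

| module | contents |
| --- | --- |
| `cmost.params` | `NaturalHistoryParams`, risk-function evaluation, anchor-point CDFs, YAML persistence |
| `cmost.engine` | life table, domain types, reference per-quarter operations, population simulator (`cmost._kernel`: numba kernels) |
| `cmost.screening` | endoscopy/stool-test models, screening plans, surveillance rules |
| `cmost.econ` | cost tables, discounting, treatment-phase cost accrual, paired-arm comparison |
| `cmost.calibration` | benchmark sets, squared-error objective, greedy + Nelder-Mead step calibration |
| `cmost.scenarios` | canned experiments with paired baselines |
| `cmost.io_report` | run manifests, CSV/JSON round-trip, benchmark plots |
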