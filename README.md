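# wardsim

Monte Carlo simulation of hospital ward nurse staffing. The package
compares baseline staffing establishments — set at mean demand ("standard"),
80% of mean ("low"), or the 90th percentile of demand ("high") — combined
with flexible-staffing policies (within-division redeployment of whole
people, then bank/agency escalation under limited availability), and reports
understaffed/overstaffed patient-shift rates and staffing cost per
patient-day.

## How it works

1. **Synthetic hospital** (`wardsim.synthetic`): wards with day-of-week
   census distributions (discretized truncated normals), Dirichlet acuity
   mixes over five dependency levels, Poisson specialing, a skill mix and a
   diurnal profile over four 6-hour periods. Wards are grouped into
   divisions, the redeployment pools.
2. **Demand** (`wardsim.demand`): per-shift required hours from
   hours-per-patient-day multipliers per acuity level, plus one 6 h
   person-shift per specialed patient; the "actual" requirement applies
   mean-1 lognormal noise per level.
3. **Planning** (`wardsim.planner`): a 20-day observation window is
   simulated per ward; the scenario statistic (mean / 0.8 × mean / P90) is
   spread over the four periods, split by skill mix, and rounded to sums
   achievable with 4 h and 6 h staff blocks.
4. **Engine** (`wardsim.engine`): each shift runs absence (whole
   person-blocks), face-value balance assessment, greedy within-division
   redeployment (3 h / 6 h blocks, no donor harm, no group substitution),
   bank-then-agency requests capped at the ward's face-value shortfall, and
   classification against a ±15% tolerance band around the noisy
   requirement. Redeployed and bank staff count at 90% productivity, agency
   at 75%.
5. **Costing** (`wardsim.costing`): salaried permanent establishment, bank
   at base × (1 + 0.5 × on-cost), capped agency rates, unsocial-hours
   uplift; cost per patient-day (1 patient-day = 4 patient shifts).
6. **Reporting** (`wardsim.reporting`): patient-shift-weighted outcome
   rates, hour shares by source, t-based 95% CIs over replications, and
   scenario × policy grid tables.

Randomness is split into named substreams (census, acuity, specialing,
absence, noise, availability) spawned from the replication seed, so runs
with the same seed share census/absence/noise draws exactly across policies.
Replication `i` uses seed `base_seed + i`; planning uses `base_seed − 1`.
Day 0 is a Monday.

## CLI

```bash
# reference hospitals (4-ward and 20-ward YAMLs, committed under fixtures/)
wardsim fixtures --out-dir fixtures

# establishment plan for one scenario
wardsim plan --hospital fixtures/hospital_4ward.yaml --scenario standard \
    --seed 1 --out-csv plan.csv --out-json plan.json

# replicated simulation of one (scenario, policy) cell
wardsim simulate --hospital fixtures/hospital_4ward.yaml \
    --scenario standard --policy empirical --replications 10 --seed 1 \
    --out runs/standard-empirical

# the full scenario x policy grid with rendered tables
wardsim grid --hospital fixtures/hospital_20ward.yaml --replications 10 \
    --seed 1 --out runs/grid

# re-render tables from an archived grid
wardsim report --grid-json runs/grid/grid_summaries.json

# export a sampled census stream
wardsim sample-census --hospital fixtures/hospital_4ward.yaml --days 7 \
    --seed 1 --out census.csv
```

`simulate` and `grid` accept `--config config.yaml` with keys under
`demand:` (multipliers, noise_cv, specialing_group), `engine:` (absence,
tolerance, availability tables) and `costing:` (rates, on-costs, agency
caps, unsocial uplift); see `wardsim/config.py` for the schema.

## Acceptance

The acceptance contract is property-based (fixed-point limits, hire-cap
invariance, monotone scenario/policy orderings, calibration checks); it
lives in `tests/test_acceptance.py`, one test per criterion. There are no
numeric headline targets to reproduce — the quantitative results of the
motivating study derive from confidential hospital data — so the report
script emits an empty target set after an end-to-end sanity run:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
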