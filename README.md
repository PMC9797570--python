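# gduplan

Planting and harvest scheduling for corn seed populations under
heat-unit (GDU, growing degree unit) uncertainty.

Each seed population must be planted inside its own window of weeks and
is harvested in the first week its accumulated post-planting heat
reaches a population-specific requirement. The package schedules all
populations so that weekly harvest quantities are consistent and respect
storage capacity, under a single weekly GDU scenario or under many
historical scenarios at once:

- **GDU engine** (`gduplan.core`) — daily GDU with 10 °C base / 30 °C
  cap, Sunday-start week numbering (week 1 contains Jan 1), cumulative
  accumulation, the earliest-harvest rule, objective evaluators for all
  four problem variants, and maturity-feasibility diagnostics.
- **Deterministic MILPs** (`gduplan.milp.deterministic`) — case 1:
  minimize total absolute deviation of weekly harvest from a fixed
  capacity (absolute-value linearization with e⁺/e⁻ variables); case 2:
  minimize the peak weekly harvest plus a per-harvest-week penalty
  (minimax linearization with a z variable), yielding the lowest
  capacity required. Solved with HiGHS via `scipy.optimize.milp`.
- **Stochastic MILP** (`gduplan.milp.stochastic`) — one shared planting
  schedule, per-scenario harvest weeks, an exactly linearized cross-
  scenario max envelope, and the deviation-from-capacity objective; the
  small-instance gold standard for the heuristic. A dense audit mode
  reproduces the closed-form variable count `N·K·T + N·T + K·T + T`.
- **Simulated annealing** (`gduplan.sa`) — geometric cooling
  (`T0·α^k`, defaults 30 000 / 0.995 / 700 iterations), Metropolis
  acceptance, and a bespoke neighbor that thins the tallest envelope
  week and fills the shortest one, plus a random-re-plant exploration
  component.
- **Synthetic instances** (`gduplan.synth`) — seeded generators for
  population tables (windows, requirements, right-skewed harvest
  quantities) and seasonal weekly GDU scenarios with site offsets, since
  the original challenge data is not redistributable.
- **Forecast skeleton** (`gduplan.forecast`) — lag-k same-week datasets,
  a climatology baseline behind a pluggable fit/predict contract,
  RMSE/MAE/correlation metrics, and a 70-week rolling forecast.

## Command line

```sh
# generate a synthetic instance (populations.csv + gdu_weekly.csv)
gduplan simulate --n 50 --t 70 --k 10 --seed 1 --out-dir work/

# single-scenario MILPs
gduplan solve-det --case 1 --populations work/populations.csv \
    --gdu work/gdu_weekly.csv --capacity 7000 --out schedule.csv
gduplan solve-det --case 2 --populations work/populations.csv \
    --gdu work/gdu_weekly.csv --out schedule.csv

# multi-scenario: exact MILP (small instances) or simulated annealing
gduplan solve-stoch-milp --populations ... --gdu ... --capacity 6000
gduplan solve-sa --case 1 --populations ... --gdu ... --capacity 6000 \
    --k-max 700 --seed 1 --trace trace.csv

# climatology GDU forecast and the SA-vs-MILP comparison harness
gduplan forecast --gdu history.csv --lag 3 --horizon 70
gduplan evaluate --n 6 --k 2 --t 15 --sa-seeds 5
```

Schedules are written as CSV (`id, plant_week, harvest_week_<scenario>…`,
all weeks 1-based); `--report` adds a per-week harvest profile with a
summary header.

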