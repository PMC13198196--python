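# herdsync

Behavioral-synchrony analysis for scan-sampled ungulate herds: a typed data
model for instantaneous scan sampling, foraging-activity filtering, group and
dyadic synchrony statistics with an independence null, Fleiss-kappa agreement
over complete scans, nearest-neighbor vs. random-conspecific synchrony,
randomized-Elo dominance ranking, the associated regression model contracts,
and a seeded agent-based herd simulator so every stage is testable without
field data.

## Layout

| module | contents |
| --- | --- |
| `herdsync.scan_data` | scan-record data model, CSV I/O, validation, group-size and behavior-budget summaries |
| `herdsync.activity_filter` | strict 80%-foraging threshold filtering at scan and session level |
| `herdsync.synchrony` | group synchrony degree + threshold proportions, Fleiss kappa, dyadic observed/expected synchrony, paired t-test |
| `herdsync.neighbors` | NN1-NN3 / random-conspecific session synchrony, scan-level focal-NN1 table, dyadic proximity likelihood |
| `herdsync.social` | affiliation and winner-loser matrices, randomized-Elo dominance scores and ordinal ranks |
| `herdsync.models` | beta GLM, binomial GLMMs (lme4 backend), Gaussian dyadic LMMs with crossed member intercepts |
| `herdsync.simulate` | seeded generative herd model + observation layer + truth-recovery report |
| `herdsync.pipeline` / `herdsync.cli` | end-to-end orchestration and the `herdsync` command |

## CLI

```bash
# generate a synthetic herd (scans.csv, interactions.csv, truth.json)
herdsync simulate --seed 1 --out runs/sim

# full analysis: filters, synchrony, dominance, model tables, fits
herdsync analyze --scans runs/sim/scans.csv \
    --interactions runs/sim/interactions.csv \
    --foraging-threshold 0.8 --seed-conspecific 1 --seed-elo 2 \
    --out runs/report

# simulate -> analyze -> verify recovery of the simulated truth
herdsync check --seed 8
```

`analyze` writes `summary.json`, `validation.json`, the dyad / session /
scan-level model tables as CSV, `dominance.csv` and `model_fits.json`, with
both the full-data and foraging-filtered variants of the neighbor and dyadic
analyses. Simulation configs are YAML files whose keys mirror
`herdsync.simulate.SimulationConfig`.

## Tests

```bash
python -m pytest -q
```

The suite covers unit oracles (hand-computed kappa/t-test values, a
brute-force pairwise-agreement kappa), property tests (row conservation,
filter monotonicity, Elo score conservation, permutation independence null),
simulation-based calibration (null type-I error rates, sign and ordering
recovery), and the acceptance criteria in `tests/test_acceptance.py`.

One acceptance test is expected to fail offline:
`TestC4PrintedStatistics::test_reproduces_printed_statistics` compares
against the source study's printed statistics, which are properties of its
deposited field dataset (an external OSF download that cannot be
redistributed here). Point `HERDSYNC_OSF_SCANS` at the downloaded scan CSV
to run that comparison.

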