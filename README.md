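# gccea

A Markov cohort cost-effectiveness model for endoscopic gastric-cancer (GC)
prevention strategies in a population at low-to-intermediate risk.

Five strategy arms are compared for a target population aged 50–69:

| strategy | schedule |
|---|---|
| `none` | no OGD intervention (reference) |
| `surveil2y` | baseline OGD, then 2-yearly OGD for high-risk subjects |
| `surveil1y` | baseline OGD, then annual OGD for high-risk subjects |
| `screen2y` | baseline OGD, then 2-yearly OGD for everyone |
| `screen2y_plus_surveil1y` | 2-yearly screening plus annual high-risk surveillance |

High-risk subjects carry premalignant gastric lesions (prevalence 13.5%,
odds ratio 6.0 for GC). Scheduled examinations do not change GC incidence;
they *down-stage* detected cancers by blending a program stage distribution
(85:4:8:3) with the usual-practice distribution (7:17:33:43) according to
the detection weight of each arm's schedule. Stage cohorts are followed to
death under constant-hazard cancer mortality (from stage-specific 5-year
survival) combined with background mortality, accruing stage utilities and
costs; costs and QALYs are discounted at 3% and each arm runs until 99% of
the cohort has died. Outputs include the ICER/dominance frontier, net
health benefit (NHB) threshold analysis, a probabilistic sensitivity
analysis (PSA) with a cost-effectiveness acceptability frontier (CEAF),
and Mantel–Cox log-rank validation of the projection against its input
tables.

Epidemiological inputs (age- and sex-specific background mortality and GC
incidence) are synthetic by default — a Gompertz–Makeham life table and an
exponential-in-age incidence curve with male rates twice female rates —
and can be replaced by any CSV with columns `age,sex,value`.

## Command line

```bash
gccea params show [--config cfg.yaml]
gccea base-case --config cfg.yaml --outdir out/       # league + subgroup tables
gccea dsa       --outdir out/ [--param risk.odds_ratio ...]
gccea psa       --outdir out/ --n 1000 --seed 1
gccea validate  --outdir out/
```

All commands write CSV outputs plus a `manifest.json` (command, config
digest, seed, version, timestamp); exit code is 2 on a configuration
error. The YAML config overrides any subset of parameters, e.g.:

```yaml
risk:
  odds_ratio: 2.4
utilities:
  stage: [0.9, 0.85, 0.75, 0.65]
epidemiology:
  incidence_csv: my_rates.csv   # per 100,000 per year
seed: 7
```

## Package layout

- `gccea.epidemiology` — rate-table generators, CSV I/O, population weights
- `gccea.parameters` — all point estimates/ranges, strategy specs, config I/O
- `gccea.markov` — risk-split incidence, detection weights, the cohort engine
- `gccea.frontier` — ICERs, dominance/extended dominance, NHB/NMB, optimum
- `gccea.sensitivity` — one-way DSA, switch thresholds, method-of-moments
  PSA, CEAF, log-rank validation
- `gccea.cli` — `gccea` entry point and report writers
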