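# breathradar

Toolkit for contactless respiration monitoring from a radar chest-distance
signal, aimed at detecting opioid-induced respiratory depression. It covers
the full computational chain: a synthetic signal simulator with ground
truth, breath-cycle segmentation with body-motion rejection, a low-rate /
cessation alert state machine, radar-vs-belt agreement statistics, and
sensor-placement geometry — everything exercisable end to end without any
recorded data.

## Components

| Module | What it does |
|---|---|
| `breathradar.synth` | Quasi-periodic chest-distance traces (raised-cosine cycles, period jitter, breath-holds, apnea, slump motion transients, noise/drift) plus coupled strain-belt traces and exact ground truth. Presets mirror standard validation protocols. |
| `breathradar.tracker` | Breath segmentation from direction reversals with a 0.75–20 mm excursion gate; excursions beyond 20 mm open motion events and force recalibration; rate = 60 / last completed cycle period. |
| `breathradar.alerting` | Alerts when the rate stays below 8 bpm for 15 s **or** 2 consecutive slow breaths, and when no respiratory motion is seen for 10 s. Body motion pauses (does not reset) the silence clock; alerts latch until reset. |
| `breathradar.validation` | Breath-hold–based two-source synchronisation, peak-to-peak period extraction, and signed per-cycle period error statistics (radar − belt, sample SD). |
| `breathradar.geometry` | Mounting boresight, 65°×53° field-of-view membership, and stall coverage of slumped-posture chest targets. |
| `breathradar.cli_io` | Two-column CSV trace format, JSON configs/reports, figures, and the `breathradar` CLI. |

## CLI

```bash
breathradar simulate --preset overdose_simulation --seed 1 --out-dir out/
breathradar track    --trace out/radar.csv --out-dir out/
breathradar monitor  --trace out/radar.csv --out out/alerts.jsonl
breathradar validate --radar out/radar.csv --belt out/belt.csv --out-dir out/
breathradar coverage --out coverage.json
breathradar report   --preset oird_decline --seed 1 --out-dir out/
```

Presets: `respiration_validation` (comfortable breathing, 3 s sync
breath-hold, continued breathing), `position_tuning` (constant 15 bpm),
`overdose_simulation` (five 30 s breathing blocks with four slump
transients), `oird_decline` (rate ramp to below 8 bpm then apnea),
`cessation` (breathing then prolonged apnea).

Traces are `time_s,value` CSV with a strictly uniform timebase; alert logs
are JSON lines; reports are JSON/CSV.

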