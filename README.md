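# windhover

Toolkit for studying soaring and windhovering bird flight in a wind-tunnel
setting: synthesis of replicated atmospheric turbulence and ramp-induced
(orographic) updrafts, flow characterization and mapping, hover-epoch
detection from motion-capture trajectories, association of hovers with
local flow conditions, and glide-envelope calculations.

Because no recordings ship with the package, a first-class synthetic-data
module generates probe velocity records, updraft flow fields and marker
trajectories **with ground truth**, so every downstream stage is testable
end to end.

## Modules

| Module | Purpose |
| --- | --- |
| `windhover.synthetic` | Turbulent wind records (von Kármán spectrum, exact mean/TI rescaling), parametric ramp-updraft fields, flight plans/trajectories with planted hovers, detection scoring |
| `windhover.flow` | Acceptance-cone filter, per-point flow statistics, Welch power spectra, log-log spectral-slope fits, integral length scale (frozen-turbulence hypothesis) |
| `windhover.mapping` | Regular x–z flow maps: assembly from point measurements, bilinear interpolation, cross-speed comparison |
| `windhover.hover` | Windhover epoch detection (≥ 0.5 s stationary, sub-millimetre per-axis spread) and summaries |
| `windhover.association` | Local flow at hover locations; per-bird/condition cohort statistics |
| `windhover.glide` | Minimum glide angle θ = cot⁻¹(L/D), facility-envelope coverage checks, packaged glide-polar reference table |
| `windhover.io` / `windhover.config` / `windhover.cli` / `windhover.pipeline` | TSV/CSV/JSON formats, YAML configuration, CLI, full-pipeline orchestration |

## CLI

```sh
windhover simulate-wind --intensity 0.126 --length-scale 0.31 --seed 1 --out probe.tsv
windhover characterize --input probe.tsv --band 6:60 --report flow.json
windhover simulate-flight --out-traj traj.tsv --out-truth truth.json
windhover detect-hovers --input traj.tsv --min-duration 0.5 --std-threshold 1.0 --out events.csv
windhover map-flow --points-dir points/ --tunnel-speed 6 --out map.csv
windhover associate --events events.csv --map map.csv --out associated.csv --cohort-out cohorts.csv
windhover glide-envelope
windhover run --out-dir out/            # full pipeline with defaults
windhover run --config my.yaml --out-dir out/
```

Exit codes: 0 success, 2 validation/format error, 3 pipeline-stage failure.
Configuration is a nested YAML document; unknown keys are rejected and all
defaults are the published facility values (see `windhover.config.DEFAULTS`).

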