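# ecmoflow

Reduced-order modelling of peripheral VA-ECMO support levels. A pulsatile
cardiac source at the aortic root and a non-pulsatile ECMO return at the
right femoral access drive a linearized transmission-line (Womersley) model
of the aorta–branch–femoral tree. The package sweeps the blood assist index
(BAI — the ECMO share of total perfusion), solves pressure, flow and wall
shear stress over one cardiac cycle, computes the perfusion/pulsatility/
shear index suite, and tracks the cardiac/ECMO flow interface (watershed)
along the aortic trunk.

Physical defaults: 0.8 s cycle, 5 L/min total perfusion, blood density
1050 kg/m³ and viscosity 0.0035 kg/(m·s), 70 mmHg at every outlet, vessel
diameters 28 / 7 / 7 / 7 / 11.3 / 10.3 mm (aortic inlet, three arch
branches, diaphragm, femoral). Lengths and wall wave speed are
configurable; everything is deterministic.

## Components

| module | what it does |
| --- | --- |
| `ecmoflow.waveforms` | half-sine cardiac ejection + constant ECMO waveforms; composes a pair meeting a target BAI and total mean flow |
| `ecmoflow.network` | vessel tree types, steady Poiseuille nodal solve, per-harmonic Womersley two-port solve, cycle synthesis with station-resolved WSS |
| `ecmoflow.indices` | BAI (instantaneous and mean-flow-ratio), upper/lower flow split ratios, harmonic index, oscillatory shear index, regional mean WSS, Pearson r |
| `ecmoflow.interface` | per-sample watershed localization on the trunk's signed flow and cycle summary |
| `ecmoflow.pipeline` | BAI sweep (default 0/40/60/80 %), report tables, trend statistics, deterministic fixtures, config handling |

## CLI

```sh
# full sweep with report tables (CSV + JSON) in out/
ecmoflow run --bai 0,40,60,80 --out out/
ecmoflow run --config cfg.yaml --out out/

# standalone indices from CSV series (time_s,flow_mL_s / time_s,wss_Pa)
ecmoflow indices --flow flow.csv --ecmo-flow ecmo.csv --wss wss.csv

# deterministic fixture set
ecmoflow fixtures --seed 0 --out fixtures/
```

Config keys (YAML or JSON): `bai_levels`, `period_s`,
`total_mean_flow_L_min`, `systolic_fraction`, `bai_mode`, `n_samples`,
`n_harmonics`, `station_spacing_mm`, `density`, `viscosity`, and a
`network:` block (`lengths_mm`, `diameters_mm`, `wave_speed_m_s`,
`outlet_pressure_mmHg`).

## Python API

```python
from ecmoflow import SweepConfig, run_sweep, render_report

sweep = run_sweep(SweepConfig())
report = sweep.level(0.6).report        # indices at 60 % assist
render_report(sweep, "out/")            # CSV tables + JSON summary
```

## Modelling notes

This is a 1-D frequency-domain model, not CFD: it reproduces trends
(pulsatility loss with rising assist, watershed moving toward the heart,
retrograde descending-aortic mean flow at high assist), not 3-D jet or
vortex features. The upper/lower flow-split trend signs are reported with a
pass/warn status because they are sensitive to three-dimensional effects
that do not survive the model reduction.
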