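# htpbk

High-throughput whole-body PBK (physiologically based kinetic) simulation and
parameterisation-strategy benchmarking.

`htpbk` builds generic human PBK models from pluggable per-property input
sources (lipophilicity, pKa, fraction unbound, solubility, clearance,
intestinal permeability), simulates IV and oral concentration–time profiles,
and scores whole parameterisation *strategies* against observed PK study
datasets using profile-level log2 error metrics, fold-range statistics and
per-compound median aggregation. A synthetic-data generator produces
ground-truth compounds, emulated prediction "tools" with configurable bias and
error, and noisy multi-study datasets, so the whole pipeline is testable
end-to-end without any external data.

## Layout

| module | contents |
|---|---|
| `htpbk.physiology` | reference adult-male anatomy (volumes, flows, tissue composition, GFR, hepatocellularity), allometric demographic scaling |
| `htpbk.compound` | source-tagged property records, strategy definitions, consensus means, LogP/LogD→LogMA conversions, strategy resolution |
| `htpbk.partitioning` | tissue:plasma partition coefficients under five published method families (`pksim`, `schmitt`, `rodgers_rowland`, `poulin_theil`, `berezhkovskiy`) |
| `htpbk.clearance` | IVIVE scaling of hepatocyte CLint (hepatocellularity × liver density × liver volume), plasma-clearance mode, passive renal clearance (GFR × fu) with the plasma-mode off rule |
| `htpbk.engine` | flow-limited whole-body ODE model: IV bolus/infusion (exact matrix-exponential propagation) and oral dosing with dissolution schedule, solubility cap and permeability-limited absorption (stiff ODE integration) |
| `htpbk.nca` | Cmax/Tmax/AUC(0–last) with the linear-up/log-down trapezoid, relative/absolute log2 profile errors, fold-range summaries |
| `htpbk.evaluation` | dataset-level evaluation, per-compound medians, strategy grids, the three-step workflow |
| `htpbk.synthetic` | ground-truth compound sampling, emulated tools, noisy multi-study dataset generation |
| `htpbk.io` | CSV/XLSX study & property table loaders with column maps and unit conversion, result export, run manifests |

## CLI

```bash
# generate a synthetic dataset (studies.csv, properties.csv, truth.csv)
htpbk synth --n-compounds 30 --seed 1 --out scratch/synth

# evaluate one strategy (shipped name or JSON file) against a dataset
htpbk evaluate --studies scratch/synth/studies.csv \
    --properties scratch/synth/properties.csv \
    --strategy best_overall --route po --out scratch/eval

# cartesian strategy grid / three-step workflow
htpbk grid --studies ... --properties ... --base-strategy best_overall \
    --grid-config grid.json --out scratch/grid
htpbk workflow --studies ... --properties ... --base-strategy best_overall \
    --physchem-config p.json --adme-config a.json --absorption-config s.json \
    --out scratch/workflow

# simulate a single study
htpbk simulate --studies ... --properties ... --strategy best_overall \
    --study-id S1 --out profile.csv
```

Grid configs are JSON `{slot: [{"label": ..., "fields": {...}}, ...]}` where
`fields` are `ParameterisationStrategy` attribute overrides.

Three strategy configurations are shipped as package data
(`best_overall`, `best_insilico_proprietary`, `best_insilico_free`).

## Data formats

Study tables are long-format CSV/XLSX, one row per observed timepoint:

```
study_id,compound_id,route,dose_mg,infusion_duration_h,formulation,
dissolution_time80_min,sex,age_y,weight_kg,height_cm,time_h,conc_mg_per_L
```

Property tables: `compound_id,property,subtype,value,source,MW[,unit]` with
`property ∈ {lipophilicity,pKa,fu,solubility,clearance,permeability}`.
Alternative units (nmol/L concentrations, min times, mol/L solubilities, …)
may be declared via a `ColumnMap` / `unit` column and are converted on load.

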