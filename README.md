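# fruitflux

Biophysical simulation of fleshy-fruit growth (water and carbon fluxes into
a single fruit), multi-objective calibration of genotype-specific
parameters against fresh/dry-mass time courses under control (C) and
water-deficit (WD) irrigation, and constrained multi-objective design of
virtual genotypes (ideotypes) — exercised end to end on synthetic
populations that emulate a recombinant-inbred-line phenotyping campaign.

## What is in the box

| module | role |
| --- | --- |
| `fruitflux.model_core` | fruit growth simulator: Lockhart turgor-driven expansion, series pedicel+membrane water pathways (xylem/phloem), three-mechanism sugar uptake, respiration, transpiration. The hot loop is numba-compiled (`fruitflux._kernel`); the turgor equation is solved in closed form (piecewise-linear volumetric balance). |
| `fruitflux.moea` | self-contained elitist NSGA-II: constraint-domination, fast non-dominated sort, crowding distance, SBX crossover, polynomial mutation. |
| `fruitflux.calibration` | per-genotype estimation of the 8 genotypic parameters by minimising the mean fresh/dry-mass NRMSE per treatment (two objectives), repeated runs, merged archives, min–max selection. |
| `fruitflux.ideotype` | 11-parameter constrained search maximising ripe dry-matter content under C while minimising WD fresh-mass loss, per fruit-size class. |
| `fruitflux.synthetic_data` | virtual populations: true parameter vectors, greenhouse climate, treatment inputs, noisy per-fruit observations following the sampling design (3 fruits per early window, 15–20 at ripeness). |
| `fruitflux.analysis` | correlation-matrix PCA with sqrt-eigenvalue loadings, supplementary-variable projection, complete-linkage clustering, dendrogram export. |
| `fruitflux.io_cli` | CSV/JSON/YAML schemas, run configuration, resumable pipeline, `fruitflux` command-line entry point. |

Units: grams, hours, bar, cm, °C. Times at the I/O boundary are days after
anthesis (daa); simulations start at 8 daa.

## Command line

```bash
# generate a synthetic population (obs.csv, inputs.csv, env.csv, truth.json)
fruitflux synth --n 100 --seed 1 --out-dir runs/pop

# simulate one genotype and write its hourly trajectory
fruitflux simulate --inputs runs/pop/inputs.csv --env runs/pop/env.csv \
    --truth runs/pop/truth.json --genotype G001 --out traj.csv

# calibrate the eight genotypic parameters for one genotype
fruitflux calibrate --obs runs/pop/obs.csv --inputs runs/pop/inputs.csv \
    --env runs/pop/env.csv --genotype G001 --repeats 10 --seed 1 --out G001.json

# PCA + complete-linkage clustering of calibrated parameter sets
fruitflux analyze --params runs/pop/calibrated.csv --k 5 --out report/

# ideotype design for a fruit-size class
fruitflux design-ideotypes --size-class small --repeats 20 --seed 1 --out ideo.csv

# full pipeline (synth -> calibrate -> analyze -> design), resumable
fruitflux run-all --config config.yaml --out-dir runs/demo
```

`run-all` accepts a YAML configuration (unknown keys are rejected); every
field has a documented default, see `fruitflux.io_cli.RunConfig`. A
manifest in the output directory records the configuration hash and the
completed stages, so re-running with the same configuration skips finished
work and changing any seed invalidates downstream artifacts.

## Notes on the model

- Fluxes: `Ux` and `Up` are series pedicel+membrane pathways; the xylem sap
  is treated as pure water, the phloem pedicel driving force is purely
  hydrostatic, and both fluxes are linear in turgor `Pf`, which makes the
  Lockhart closure an exact two-branch linear solve (the branch switch is
  the sign of phloem flow, which carries solute only when positive).
- Osmotic pressures are van 't Hoff; saturation vapour pressure is a
  Magnus-type formula; stem water potential follows a daily cosine course
  between the predawn (05:00) and midday (13:00) measurements.
- Non-genotypic constants (`GenericParams`) are configuration defaults, not
  measurements; they are chosen so a mid-bounds genotype ripens inside the
  observed 5–160 g fresh-mass envelope. All of them can be overridden.
- Calibration searches log10 space for parameters whose bounds span two or
  more decades (`phiMax`, `Lp`, `nuM`, `lp1`), linear space otherwise.
- The WD treatment is emulated through its measured consequences on the
  model inputs: stem water potentials shifted by −3 bar, initial water mass
  ×0.8, non-sugar osmotic pressure ×1.3 (all configurable).
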