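# neurocomplexity

Multi-scale entropy, neural-mass brain-network simulation, and
complexity–connectivity association analysis.

The package quantifies the *complexity* of regional neural signals with
multi-scale sample entropy (MSE) and relates it to network *functional
connectivity* (FC), across three settings:

1. **Simulation** — a network of conductance-based neural-mass nodes coupled
   through a structural connectome, swept over the long-range excitatory
   gain `Aee`, showing that stronger coupling raises both signal complexity
   and functional connectivity.
2. **Electrophysiology-style recordings** — scanner-artifact scrubbing of
   LFP traces, band-pass filtering, band-averaged entropy.
3. **fMRI-style cohorts** — confound regression, per-subject nodal MSE and
   connectivity, across-subject MSE–FC correlations per scale, with scale →
   frequency mapping.

Everything runs offline on synthetic data generated by the package itself;
all generators and simulations are deterministic functions of their seed.

## Quick start

```python
import numpy as np
from neurocomplexity import (
    NMMParams, simulate, gen_modular_connectome,
    mse_curve, EntropyParams, fc_matrix, mean_fc,
)

# a 47-node, 5-module structural connectome
con = gen_modular_connectome(n_nodes=47, n_modules=5, seed=1)

# simulate the coupled neural-mass network (200 Hz output)
ts = simulate(con, NMMParams(aee=0.4, seed=7, duration_samples=4000))

# multi-scale entropy of node 0 (tolerance anchored to the scale-1 SD)
curve = mse_curve(ts.node(0), [1, 2, 5, 10, 25, 50], EntropyParams(3, 0.2))
print(np.round(curve.entropy, 3))   # [0.626 0.931 1.083 0.728 0.357 0.062]

# functional connectivity
fc = fc_matrix(ts)
print(round(mean_fc(fc), 3))                              # 0.108
print(round(mean_fc(fc, fc.module_indices("M1")), 3))     # 0.26
```

The sweep experiment (the package's headline analysis) draws `Aee ~ U(0,
0.55)` per run, summarizes each run by its mean MSE and mean FC, and
correlates the summaries across runs:

```python
from neurocomplexity import SweepConfig, run_sweep, associate_sweep
from neurocomplexity.sweep import DESK_SCALES

cfg = SweepConfig(n_runs=16, samples=10_000, scales=DESK_SCALES, seed=1)
table = run_sweep(con, cfg)
assoc = associate_sweep(table)
assoc["mse_full_vs_fc_whole"].r   # 0.89  (complexity tracks connectivity)
assoc["aee_vs_mse_full"].r        # 0.97  (coupling raises complexity)
assoc["aee_vs_fc_whole"].r        # 0.93  (coupling raises connectivity)
```

## Command line

The `complexity` entry point wraps the main procedures:

```bash
complexity synth connectome --nodes 47 --modules 5 --seed 1 --out con.csv
complexity simulate --connectome con.csv --modules con.csv.modules \
    --aee 0.4 --samples 10000 --out sim.csv
complexity mse sim.csv --scales 1-12,14-25:3,29-49:5 --m 3 --bands
complexity fc sim.csv --out fc.csv
complexity sweep --connectome con.csv --modules con.csv.modules \
    --runs 16 --scales sparse --out sweep.csv
complexity associate sweep.csv --out assoc.json
complexity scale-frequency 2 --fs 1.389 --convention nyquist   # 0.347250
complexity imaging cohort-assoc --subjects 12
complexity synth lfp --out lfp.csv && \
    complexity imaging clean-lfp lfp.csv --fs 1000 --triggers lfp.csv.triggers \
        --fs-out 50 --out lfp_clean.csv
```

Every `synth` output carries a JSON sidecar (`<out>.json`) recording the
generator settings and seed. `complexity associate --x msetable.csv --y
fctable.csv --group animal` correlates two per-observation tables directly,
with an optional partial correlation controlling for a grouping column.

```bash
```

## Reproduction

```bash
python -m pytest            # unit, property and acceptance tests (~20 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` runs the desk-scale sweep (16 runs, 10,000 samples,
sparse 1–400 scale grid on a generated 47-node connectome, ~8 min on one
CPU) and writes the three headline correlations: `t1` (mean MSE vs mean FC,
minimum over whole network and modules), `t2` (Aee vs MSE/FC, same
minimum), and `t3` (narrow 2.7–4 Hz delta-band MSE vs FC). See
`docs/methods.md` for definitions, calibration rationale and known
limitations — in particular, the band-resolved correlation profile of the
simulator deviates from the intended ordering (the gamma band, not narrow
delta, attains the maximum), which is reported honestly by the acceptance
suite rather than tuned away.

## Package layout

| module | contents |
|---|---|
| `neurocomplexity.entropy` | SampEn, ApEn, coarse-graining, MSE curves, band averages |
| `neurocomplexity.bnm` | conductance neural-mass network simulator |
| `neurocomplexity.connectome` | structural connectome container and loader |
| `neurocomplexity.stats` | FC matrices, Pearson/partial correlation, linear vs quadratic fits |
| `neurocomplexity.sweep` | the random-`Aee` sweep experiment and its associations |
| `neurocomplexity.imaging` | LFP scrubbing, confound regression, band-pass, cohort MSE–FC analyses, NIfTI helpers |
| `neurocomplexity.synth` | seeded generators: connectomes, 1/f noise, artifact-laden LFP, BOLD-like panels, coupled cohorts |
| `neurocomplexity.frequency` | scale → frequency conventions (`direct`, `nyquist`) |
| `neurocomplexity.cli` | the `complexity` command line |
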