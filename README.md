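# marshnet

Biogeomorphic simulation and channel-network geometry analysis for
vegetated tidal wetlands.

Tidal flats and salt marshes drain through branching channel networks
whose geometry controls flooding, sediment delivery and resilience to
sea-level rise. `marshnet` is for coastal geomorphologists and ecologists
who want to experiment with the mechanism behind that geometry: a
scale-dependent biogeomorphic feedback in which vegetation slows flow and
stabilizes sediment locally while concentrating scour into the bare areas
between plants, recursively incising ever finer side channels.

The package has two halves:

- **Simulator** — an idealized coupled model of depth-averaged
  shallow-water ebb drainage, a sedimentation/erosion/soil-creep bed
  balance, and logistic vegetation dynamics on a regular grid:

  - dh/dt = -∇·(**u**h) + H_in, with thin-film wetting/drying (h ≥ H_c)
  - d**u**/dt = -g∇(h+S) - (**u**·∇)**u** - **τ**/(ρh) + D_U∇²**u**,
    with Manning-Chézy friction, n = n_b + (n_v-n_b)B/k
  - dS/dt = S_in·h_e/(Q_s+h_e) - E_S(1-p_E·B/k)·S·τ_b/ρ + ∇·(D_S∇S),
    D_S = D_0(1-p_D·B/k)
  - dB/dt = rB(1-B/k)·Q_q/(Q_q+h_e) - E_B·B·τ_b/ρ + D_B∇²B

  Bed and vegetation tendencies are accelerated by a morphological factor
  Φ (one M2 tidal period, 44712 s), so decades of morphology run with
  sub-second hydrodynamic steps.

- **Network metrics** — extraction and statistics of channel networks
  from digital terrain models (simulated or measured): median-neighborhood
  channel detection, exact Euclidean unchanneled path lengths, centerline
  skeleton graphs, D8 watershed areas with priority-flood pit filling,
  Hack stream ordering (main channel = order 1; higher order = finer
  scale), bifurcation ratios r_i = n_{i+1}/n_i, Hortonian drainage
  density, exceedance curves and two-sample Kolmogorov-Smirnov similarity.

Grids are `(i shoreward, j alongshore)` row-major; the open outflow
boundary is the last row (`i = n_x - 1`), the other three boundaries are
closed.

## Worked example

Paired reduced-scale runs (64 m × 128 m, 10 accelerated years, same seed
and tussock placement) with vegetation dynamics on versus frozen:

```python
from marshnet.experiment import (vegetation_pair_manifest, run_experiment,
                                 paired_differences)

table = run_experiment(vegetation_pair_manifest(seed=1))
print(table[["max_hack_order", "drainage_density_per_m",
             "mean_vegetation_density_per_m2"]])
print(paired_differences(table))
```

prints (seed 1):

```
             max_hack_order  drainage_density_per_m  mean_vegetation_density_per_m2
run
vegetated                 2                0.036722                      481.301072
unvegetated               1                0.015362                        2.746582

   pair  delta_drainage_density_per_m  delta_max_hack_order  delta_mean_accretion_rate_m_per_yr
0  pair                       0.02136                     1                           -0.000993
```

With vegetation the same terrain develops second-order side branches
(max Hack order 2 vs 1) and more than double the drainage density: the
biogeomorphic feedback, not the initial conditions, produces the extra
network complexity. Lowering the bare-soil diffusivity D_0 (stiffer
abiotic soil) strengthens the same feedback — drainage density falls
monotonically along D_0 ∈ {1e-7, 1e-6, 1e-5} m²/s
(`marshnet.experiment.d0_sweep_manifest`).

The same machinery is scriptable from the shell:

```bash
marshnet simulate --seed 1 --years 10 --out out/run1
marshnet extract --dtm out/run1/dtm.asc --window 10 --threshold 0.02 --out out/net1
marshnet compare --a out/net1 --b out/net2
marshnet fixtures make --kind nested-orders --out out/fix
```

## Layout

- `marshnet.params` — grid/parameter types, validation, parameter
  derivations
- `marshnet.hydrodynamics` — friction closures, momentum/continuity
  tendencies, boundary conditions
- `marshnet.morphodynamics` — bed and vegetation tendencies, conservative
  variable-coefficient diffusion
- `marshnet.simulator` — initialization, the update cycle with
  morphological acceleration, run orchestration, checkpoints (`.npz`)
- `marshnet.network` — channel detection → skeleton graph → flow routing
  → Hack orders → statistics
- `marshnet.fixtures` — synthetic ground-truth terrain and closed-form
  references
- `marshnet.io`, `marshnet.experiment`, `marshnet.cli` — YAML configs
  with unit-suffixed keys, ESRI ASCII / GeoTIFF rasters, experiment
  manifests, command-line interface

`examples/default.yaml` is the default-simulation configuration (all
parameters with unit-suffixed keys); pass it to `marshnet simulate
--config` and override what you need.

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.
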