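# spectpareto

Bias–precision optimization of quantitative ¹⁷⁷Lu SPECT acquisition and
reconstruction settings.

## What this package is for

Dosimetry in molecular radiotherapy (¹⁷⁷Lu-DOTA-TATE, ¹⁷⁷Lu-PSMA) needs
accurate activity-concentration estimates from SPECT images. Two error
sources compete: *bias* from partial-volume effects and slow convergence of
iterative reconstruction, and *random error* from Poisson counting noise.
Both depend on how a fixed total acquisition time is split over projection
angles and on the OS-EM reconstruction settings (number of subsets and
iterations). `spectpareto` is a simulation laboratory for that trade-off:
it builds voxelized phantoms, simulates SPECT acquisitions, produces noise
realizations of shorter scans (by projection-domain bootstrapping or direct
Poisson sampling), reconstructs with OS-EM, calibrates against a uniform
cylinder, and summarizes each setting by

* absolute mean relative error `|C̄_est / C_ref − 1|` (bias axis), and
* coefficient of variation `CV = s / C̄_est` over noise realizations
  (precision axis),

then identifies the Pareto front — settings where bias cannot be reduced
without worsening precision or vice versa.

The core statistical object is the OS-EM reconstruction itself: Poisson
maximum-likelihood fitting of an emission model

`p_j ~ Poisson( [A f]_j + s_j )`

with `A` a rotation-based parallel-beam projector including attenuation and
distance-dependent collimator blur, and `s_j` an additive scatter estimate.
It is exposed statsmodels-style: `OSEMModel(projections, attenuation,
system, scatter_rate).fit(scheme)` returns an `OSEMResults` with
per-iteration snapshots, an optional log-likelihood trace, and `summary()`.

Reconstruction schemes obey the study constraints: the number of subsets is
an even integer divisor of the number of projections (two or more angles per
subset) and iterations × projections ≤ 2400. Over the projection counts
{20, 24, 30, 40, 60, 120} this enumerates 1900 settings.

## Worked example

```python
import numpy as np
from spectpareto import (
    Grid, SystemModel, ReconScheme, OSEMModel, Projector,
    make_sphere_phantom, anchor_sensitivity, forward_project,
    uniform_angles, realize_poisson,
)
from spectpareto.acquisition import scatter_component
from spectpareto.calibration import calibrate_all, factor_lookup
from spectpareto.quantify import estimate_concentration, summarize_realizations

grid = Grid((64, 64, 48), voxel_size=4.42)                  # mm
activity, mu, masks = make_sphere_phantom(grid)             # 5.80 MBq/mL spheres
system = anchor_sensitivity(activity, mu,
                            SystemModel(pixel_size_mm=4.42, num_pixels=64),
                            target_rate_cps=700.0)

angles = uniform_angles(60)
primary = forward_project(activity, mu, system, angles)
scatter = scatter_component(primary, system)
rate = primary + scatter                                    # counts/s per pixel

scheme = ReconScheme(num_projections=60, num_subsets=2, num_iterations=8)
factor = factor_lookup(calibrate_all([scheme], grid, system,
                                     voi_volume_mL=375.0))[(60, 2, 8)]

projector = Projector(grid, system, angles, mu)
estimates = []
for r in range(16):                                         # 10-min acquisitions
    pset = realize_poisson(rate, angles, time_per_projection_s=10.0,
                           rng_seed=1000 + r)
    res = OSEMModel(pset, mu, system, scatter_rate=scatter,
                    projector=projector).fit(scheme)
    estimates.append(estimate_concentration(res.image * factor,
                                            masks["sphere6"]))

rec = summarize_realizations(estimates, c_ref=5.80)
print(f"mean = {rec.c_est_mean:.3f} MBq/mL, "
      f"CV = {100 * rec.cv:.2f} %, "
      f"|rel. error| = {100 * rec.abs_mean_rel_error:.1f} %")
```

Output:

```
mean = 4.028 MBq/mL, CV = 0.24 %, |rel. error| = 30.6 %
```

Reading: at only 16 updates (2 subsets × 8 iterations) the largest sphere
(26.9 mL) is estimated very precisely (CV well below 5 % even at a 10-minute
total acquisition) but with substantial negative bias — the reconstruction
has not yet converged and partial-volume losses are not recovered. More
updates lower the bias and raise the CV; sweeping settings and flagging the
(error, CV) Pareto front is what `run_sphere_arm` / `run_anthro_arm` do:

```sh
spectpareto -v run-sphere-arm --out results/sphere   # smoke-scale sweep
spectpareto -v run-sphere-arm --full --out results/sphere  # full protocol (hours)
```

These write a per-setting CSV (`sphere_records.csv`) with Pareto flags, a
front-composition table, and scatter plots.

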