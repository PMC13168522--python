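# uslr — unbiased and smooth longitudinal registration of brain MRI

`uslr` estimates, for one subject scanned at several timepoints, the set of
latent spatial transforms that connect an (unobserved) subject-specific
template to every scan — and from them a sharper unbiased template, a single
stationary deformation trajectory, tensor-based morphometry (TBM) maps and
time-consistent segmentations. It is aimed at neuroimaging researchers who
process longitudinal T1-weighted series (ageing, Alzheimer's disease,
treatment follow-up) and need measurements that are **unbiased to the choice
of reference timepoint**, **smooth across time**, and **robust to occasional
registration failures**.

## The model

All transforms live in the log domain (Lie algebra): a rigid transform is a
6-vector `(q, d)` in se(3); a non-linear diffeomorphism is the group
exponential of a stationary velocity field (SVF) `T(x)`. There, inversion is
negation and composition is first-order addition (Baker–Campbell–Hausdorff).

The `N` timepoints sit on a graph around a latent template, with latent
transforms `T_1 … T_N` on the spanning-tree edges. The observed data are
`K ≤ N(N−1)/2` pairwise registrations; in the log domain each observation is
a noisy difference of two latents,

    R = W T + ζ,        W[k, ref] = −1,  W[k, tgt] = +1,

with Laplacian noise `R_k ~ Laplace((WT)_k, b_T)` and a zero-drift prior
`Σ_n T_n ~ Laplace(0, b_Z)` that centres the template among the timepoints.
The MAP estimate at each spatial location and coordinate minimises

    (b_T/b_Z) |Σ_n T_n|  +  Σ_k |R_k − (W T)_k|,

a least-absolute-deviations problem solved as a small linear program
(HiGHS), independently per coordinate and — for velocity fields — per
control point on a sparse lattice at 1/8 image resolution. The L1 norm makes
the estimate robust to gross outlier registrations; the drift prior removes
the one-dimensional gauge freedom of a connected graph.

Downstream, a voxelwise linear fit `T_n(x) ≈ c(x) + T̂(x)·t_n` over
acquisition time gives a single per-year trajectory `exp(t·T̂)` — its
Jacobian determinant over one year is the TBM atrophy map — and
intensity-weighted label fusion of all deformed cross-sectional
segmentations yields time-consistent labels for every timepoint.

## Worked example

Everything runs on a built-in synthetic head phantom, so no data download is
needed:

```python
import numpy as np
from uslr import (PhantomConfig, make_phantom_template, simulate_longitudinal_series,
                  build_full_graph, corrupt_registrations, solve_svf_graph,
                  fit_stationary_trajectory, jacobian_period)

cfg = PhantomConfig(seed=1)                  # 5 timepoints over 2 years, AD-like atrophy
tpl = make_phantom_template(cfg)
series = simulate_longitudinal_series(tpl, cfg)

graph = build_full_graph(series.nodes)       # K = 10 pairwise edges
noisy = corrupt_registrations(graph, series.true_svf, b=cfg.reg_noise_b, seed=2)
latents = solve_svf_graph(noisy)             # L1 graph inference

err = np.mean([np.mean(np.abs(l.values - t.values))
               for l, t in zip(latents, series.true_svf)])
print(f"latent-field MAE: {err:.3f} mm (noise scale b = {cfg.reg_noise_b} mm)")

fit = fit_stationary_trajectory(latents, list(series.times))
jac = jacobian_period(fit, 1.0)
hippo = tpl.segmentation == 3                # structure simulated to shrink 3 %/yr
vent = tpl.segmentation == 4                 # structure simulated to expand 6 %/yr
print(f"1-year Jacobian, shrinking structure: {jac[hippo].mean():.3f}")
print(f"1-year Jacobian, expanding structure: {jac[vent].mean():.3f}")
```

which prints

```
latent-field MAE: 0.060 mm (noise scale b = 0.25 mm)
1-year Jacobian, shrinking structure: 0.989
1-year Jacobian, expanding structure: 1.009
```

The latent fields are recovered well below the injected registration-noise
scale, and the fitted trajectory's 1-year Jacobian is below 1 (contraction)
in the structure simulated to atrophy and above 1 (expansion) in the one
simulated to grow — the per-voxel annual rate of volume change that TBM
group studies compare. (The voxelwise rates are attenuated relative to the
simulated −3 %/yr and +6 %/yr because the registration noise is of the same
order as the atrophy displacement; see `docs/methods.md`.)

The same pipeline runs from the shell on a BIDS-like subject directory:

```bash
uslr phantom --out subj/ --seed 1
uslr run --subject subj/ --out out/          # rigid → diff → template → trajectory → seg
uslr stats spc 1 3                           # SPC = 100.0000 %  ASPC = 100.0000 %
```

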