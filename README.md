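# epijam

Quantification of collective cell dynamics across the epithelial
jamming–unjamming transition: PIV-based kinematics, T1 neighbor-exchange
topology, a rigid-pack scaling null model, sigmoidal transition timing, and
fluorescence morphometrics — with synthetic ground-truth generators that
make every stage testable end to end.

## Who this is for

Groups studying collective epithelial migration (crowding MDCK-type
monolayers, unjamming perturbations) who need the standard kinematic and
topological readouts computed reproducibly from time-lapse images,
segmentation label masks, or centroid trajectory tables — and who want the
estimators validated against data with known answers rather than by eye.

## The quantities

- **V_rms = √⟨|v|²⟩** — root-mean-square cell velocity over the field of
  view (µm/h), from PIV fields or trajectories; a drift-corrected variant
  is always co-reported.
- **ξ_v** — velocity correlation length: the 1/e crossing of the
  normalized, mean-subtracted, radially averaged velocity autocorrelation
  C(r); larger ξ_v means more pack-like coordination.
- **T1 events and R_T1** — a T1 is the collapse of a junction between two
  adjacent cells followed by a new junction between two previously
  non-adjacent cells; R_T1 counts events per interior cell per hour.
- **Rigid-pack null model** — if exchanges happen only at interfaces
  between coherent packs of size L_c, then f_int ~ 1/L_c ~ 1/V_rms and
  V_rel ~ V_rms, so R_T1 ~ f_int·V_rel is *independent* of V_rms. A
  measured linear dependence of R_T1 on V_rms rejects this null in favor
  of distributed, fluid-like rearrangement.
- **Shape index q = P/√A** and second-moment aspect ratio per cell.
- **4PL transition fits** — four-parameter logistic on log-time for
  sigmoidal marker courses (junction contrast, cytoplasmic/nuclear
  ratios), reporting EC50 in hours; plus piecewise-linear change-point
  detection for the earlier V_rms decline.
- **Fluorescence metrics** — junction-to-cytoplasm contrast,
  cytoplasmic-to-nuclear ratio, puncta density, control-normalized fold
  change with bootstrap CI.

## Worked example

Generate a fluid-regime monolayer (300 µm box, 144 cells, 36 h at 15-min
frames, exchange gain 0.003 per µm) and test the rate–speed relation:

```python
import pandas as pd
from epijam.synthetic import MonolayerConfig, generate_fluid
from epijam.jamming import paired_rate_speed, rate_speed_test

frames = []
for i, v0 in enumerate((4.0, 8.0, 16.0)):
    cfg = MonolayerConfig(n_cells=144, box_size=300.0, mode="fluid",
                          speed=v0, fluid_t1_gain=0.003, n_frames=145,
                          seed=101 + i)
    run = generate_fluid(cfg)
    frames.append(paired_rate_speed(run.traj, run.events, cfg.n_cells,
                                    bin_width_h=3.0))
pairs = pd.concat(frames)
rel = rate_speed_test(pairs["v_rms"].to_numpy(), pairs["rate"].to_numpy(),
                      n_boot=2000, seed=101)
print(f"slope {rel.slope:.5f} (95% CI {rel.slope_ci[0]:.5f}.."
      f"{rel.slope_ci[1]:.5f}), p = {rel.p_value:.4f}")
```

This prints

```
slope 0.00284 (95% CI 0.00208..0.00359), p = 0.0005
```

— the fitted slope of R_T1 (events/cell/h) on V_rms (µm/h) recovers the
configured gain of 0.003 per cell, the CI excludes zero, and the
permutation p-value rejects the rigid-pack constancy null. Running the same
sweep in `rigid_pack` mode instead gives a slope CI containing zero
(`slope 0.00002, 95% CI -0.00039..0.00043, p = 0.93`): exchanges scripted
at pack interfaces at a fixed per-interface-cell rate do not track cell
speed.

The numbered scripts under `analysis/` run the full narrative — simulate
both regimes (01), kinematics and ξ_v (02), T1 detection/rates/shapes (03),
the null-model contrast (04), sigmoid EC50 ≈ 90 h and onset ≈ 70 h fits
(05), and phantom fluorescence metrics (06) — writing tables under
`results/`.

A `epijam` command-line interface wraps the same stages
(`simulate | piv | kinematics | topology | shapes | nullmodel |
fit-transition | onset | metrics | all`), writing per-run manifests with
config hashes and input checksums; identical seeds give bit-identical
outputs.

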