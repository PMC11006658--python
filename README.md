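# cranioflow

Lumped-parameter modeling of coupled cranial blood and cerebrospinal-fluid
(CSF) dynamics under thoracic pressure change.

Astronauts in microgravity experience a sustained drop in thoracic cavity
pressure together with mildly altered intracranial pressure (ICP) — a
combination implicated in Spaceflight Associated Neuro-ocular Syndrome.
`cranioflow` implements a 13-compartment head–neck–thorax network to ask a
mechanistic question: does a thoracic pressure drop lower CSF pressure
*directly*, by pulling CSF into the compliant spinal dural sac, or
*indirectly*, through its effect on the cardiovascular system (venous
return, cardiac output, central venous pressure)?  It is intended for
computational physiologists studying ICP/CSF regulation and fluid-shift
countermeasures.

## The model in brief

Compartmental mass balance with pressure-dependent compliances:

    C(P) dP/dt = Z P + F(t, P)

* `Z` — fluidity (inverse resistance) matrix, calibrated from steady-state
  mean flows and pressures: `Z_ij = Q̄_ij / (P̄_i − P̄_j)`.
* `C(P)` — compliance matrix.  Cranial interfaces follow
  `C_FV = C0 exp(−r|P_i−P_j|^γ)`; collapsible veins follow
  `C = C0_peak (N + (1−N)/cosh(α(P_trans − 4)))`.
* `F` — constant CSF production (0.30 mL/min), the Starling–Landis
  filtration `K_CB[(P_cap − P_brain) − σ_CB(π_C − π_B)]`, and the cardiac
  output in dynamic mode.
* Monro-Kellie constraint — the rigid cranium fixes total head-level
  volume; enforced by tangent-space (null-space) projection of the extended
  pressure+volume system, exact to machine precision at every step.
* Virtual heart — once per beat, `P_heart` solves
  `F_in(P_heart) = F_out(P_heart)` (venous return with partial collapse at
  `P_thoracic + 2` vs. a Starling-like ejection sigmoid), with baroreflex
  heart-rate relaxation toward
  `σ(MAP) = (α_σ/(1+(P/P0)^ν) − β_σ/(1+(P/P0)^−ν) + γ_σ) HR0`.

Two shipped experiments drop the thoracic pressure from −6 to −10 mmHg over
one minute: a **fixed** study (MAP and CVP clamped over a 13 × 7 grid — 91
combinations — isolating the compliant thoracic–spinal pathway) and a
**dynamic** study (heart and baroreflex active, letting the thoracic change
act through the circulation).

See `docs/methods.md` for the full formulation, calibration and numerical
choices.

## Worked example

```python
from cranioflow import (
    calibrate, load_baseline_config,
    run_fixed_experiment, run_dynamic_experiment,
)

config = calibrate(load_baseline_config())

summary, traj = run_fixed_experiment(92.0, 5.0, config)
print(f"fixed:   max |dICP| = {summary.max_abs_delta_icp:.4f} mmHg, "
      f"final ICP = {summary.icp_final:.4f} mmHg")

summary, traj = run_dynamic_experiment(config)
print(f"dynamic: dICP = {summary.icp_final - summary.icp_initial:+.2f} mmHg, "
      f"dCVP = {summary.delta_cvp:+.2f} mmHg, "
      f"dMAP = {summary.delta_map:+.2f} mmHg, "
      f"output -> {summary.cardiac_output_final:.0f} mL/min")
```

prints

```
fixed:   max |dICP| = 0.0430 mmHg, final ICP = 11.2000 mmHg
dynamic: dICP = -2.12 mmHg, dCVP = -2.88 mmHg, dMAP = +2.01 mmHg, output -> 5598 mL/min
```

Read: with the central pressures clamped, the thoracic drop barely moves
ICP (a sub-0.05 mmHg ring that dies back to the pre-ramp value) — the
direct thoracic-to-spinal compliant pathway cannot produce a sustained CSF
pressure change.  With the circulation responding, the same thoracic drop
lowers central venous pressure by ~3 mmHg, raises cardiac output and MAP,
and ICP follows the venous side down by ~2 mmHg.

The same runs are available from a shell:

```bash
cranioflow run-fixed --map 92 --cvp 5
cranioflow sweep                 # all 91 clamp combinations
cranioflow run-dynamic
cranioflow sensitivity           # ramp-shape invariance of the final state
cranioflow calibration-report    # every derived fluidity / peak compliance
cranioflow plot-sweep            # ICP transient overlay (91 traces)
cranioflow plot-dynamic          # MAP / CVP / ICP time courses
```

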