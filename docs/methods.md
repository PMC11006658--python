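# Methods

## The model

`cranioflow` is a lumped-parameter model of coupled blood and cerebrospinal
fluid (CSF) dynamics in the head, neck and thorax of a supine human.  The
fluid-holding anatomy is abstracted as 13 compliant compartments — Central
Arteries, Intracranial Arteries, Capillaries, Brain, Ventricular CSF,
Cranial CSF, Venous Sinus, Jugular, Secondary Venous, Extrajugular, Spinal
CSF, Central Veins and Thoracic — connected by fixed resistive flow paths
and deformable interfaces.  Units are mmHg, mL and minutes throughout.

Mass conservation at every compartment yields

    C(P) dP/dt = Z P + F(t, P)

with `C(P)` the symmetric compliance matrix (pairwise interfaces contribute
a graph-Laplacian block, self-compliances add to the diagonal), `Z` the
constant fluidity matrix, and `F` the forced flows: a constant CSF
production of 0.30 mL/min from the Capillaries into the Ventricular CSF,
the Starling–Landis transcapillary filtration

    Q_cb = K_CB [(P_cap − P_brain) − σ_CB (π_C − π_B)]

across the blood–brain barrier, and (in dynamic mode) the beat-held cardiac
output entering the Central Arteries and leaving the Central Veins.

Modeling assumptions: fluids are incompressible and isothermal; all flows
except the two above are proportional to the inter-compartment pressure
difference (`Q_ij = Z_ij (P_i − P_j)`); interface volume changes are locally
linear in the pressure-difference change (`dV_ij/dt = C_ij d(P_i − P_j)/dt`);
CSF production is pressure-independent at the pressures of interest; the
body is supine, so no hydrostatic terms exist anywhere in the package; and
in-beat pulsatility is neglected — the heart delivers a constant flow for
each cardiac cycle.

## Calibration

All parameters ship as one declarative YAML document
(`cranioflow/data/baseline.yaml`) mirroring the published baseline tables,
so the packaged state is diffable against its sources.  Calibration turns
the tables into a simulatable model in four steps.

**Exactly conservative mean flows.**  Printed flow tables are rounded, and a
rounded table is generally not volume-conservative (the venous-sinus inflow
and outflow disagree by 0.03 mL/min; the extrajugular return omits the
0.13 mL/min spinal CSF contribution).  Rows whose published source is
"conservation of volume" are therefore *re-derived*: the Starling flow is
evaluated exactly from its law (0.12804 mL/min at baseline, printed as
0.13), the three venous-sinus drainage branches keep their printed ratios
(76.8 / 5.5 / 17.7 % of total drainage) while their total is fixed by the
sinus inflow, and the remaining unknown flows are solved from the interior
mass balances (a small linear system).  Derived values are validated
against the printed ones to 0.2 mL/min.  Without this step the baseline
could not be an exact steady state, which the rest of the pipeline assumes.

**Fluidities.**  Each resistive edge gets `Z_ij = Q̄_ij / (P̄_i − P̄_j)`; the
Ventricular CSF–Brain edge (zero mean flow, zero baseline pressure
difference) instead uses the prescribed `Z = 1000 K_CB = 66` mL/min/mmHg.
Calibrated fluidities span 0.025–1250 mL/min/mmHg — five decades, which is
why the integrator must be stiff-capable.

**Compliances.**  Four cranial interfaces share the exponential law
`C_FV = C0 exp(−r |P_i − P_j|^γ)` (C0 = 6.5333 mL/mmHg, r = 0.633431,
γ = 0.604229) scaled by relative-volume prefactors (5% of the CSF-side
compliance to the brain interfaces, 95% to the venous-sinus interface;
23/140 vs 87/140 splits the ventricular and subarachnoid shares).  The
authoritative baseline value of a cranial edge is the law itself evaluated
at baseline pressures; two printed table entries (0.16 and 0.82 mL/mmHg)
differ from the law (0.1734 and 0.8011) and are treated as rounded report
values.  Collapsible venous compartments follow the hyperbolic-secant law
`C = C0_peak (N + (1−N)/cosh(α (P_trans − 4)))` with N = 0.01 and
α = 0.40026 /mmHg (neck) or 0.29352 /mmHg (central veins); the peak
compliance `C0_peak` is found by inverting the law at the baseline
transmural pressure so each edge reproduces its tabulated baseline value
exactly.  Transmural pressure is the compartment pressure itself for
neck-level compartments and `P_cv − P_thoracic` for the Central Veins.  The
published formulation assigns the venous law per *compartment*; since
compliance lives on edges here, each venous edge uses the transmural
pressure of its owning compartment: the jugular and extrajugular
self-compliances their own pressures, both Secondary Venous interfaces
(0.40 to the jugular, 0.010 to the cranial CSF) the Secondary Venous
pressure, and the large thoracic–central-veins interface the central-venous
transmural pressure.  The choice matters little: those two shared edges are
one to three orders of magnitude smaller than the compartments' dominant
compliances.

**Cardiac tuning.**  The virtual heart (below) contains a subject-specific
output factor `C`.  It is fitted in closed form so that, at the baseline
heart rate (61.6 bpm), thoracic pressure (−6 mmHg) and central-venous
pressure (5 mmHg), the solved heart balance delivers exactly the baseline
cardiac output — the total arterial outflow of 5300 mL/min — and the fit is
verified by re-solving the balance (C ≈ 1.7769).

After calibration the printed baseline pressures are an equilibrium of the
full nonlinear system to < 1e−9 mL/min per compartment, and the
steady-state solver recovers them to < 1e−10 mmHg.

## Constraints and integration

Two constraints supplement mass conservation.  The thoracic pressure is
*prescribed* as a function of time; its dynamic equation is replaced by
`dP/dt = (profile)'(t)` (and likewise for the clamped central compartments
in the fixed study).  The Monro-Kellie condition — the rigid cranium fixes
the total volume of the six head-level compartments — is a linear algebraic
constraint on the extended state.

The state is extended with per-compartment volumes (integrating the net
inflow `Z P + F`) and per-interface volumes (integrating
`C_ij d(P_i − P_j)/dt`), both relative to the initial condition.  Linear
constraints `A X = B` are enforced by tangent-space parameterization: with
`Q` an orthonormal null-space basis of `A` and `X(t) = Q Z(t) + X(0)`, the
projected system `(Qᵀ M Q) dZ/dt = Qᵀ G` is integrated, so the constraint
residual is machine-zero at every accepted step rather than corrected after
the fact.  `A` is constant here, so `Q` is computed once; coordinates
untouched by any constraint keep their identity basis vectors, which keeps
pressure-scale and volume-scale coordinates separate in the error control.
Volume bookkeeping of pressure-prescribed compartments is frozen (their
exchange is with the unmodeled exterior that the clamp replaces).

A structural property of this formulation is worth stating: because the
volume block's mass matrix is the identity and its right-hand side repeats
the net inflow, the projection leaves the *pressure* dynamics identical to
the unconstrained system and distributes the (tiny) trans-cranial volume
flux among the head compartments.  The cranial rigidity itself is encoded
in the compliance topology — the only compliant interface crossing the
cranial boundary is the 0.010 mL/mmHg cranial-CSF–secondary-venous edge —
so the constraint is a bookkeeping guarantee, not an extra force.  The
machinery is nonetheless general: constraint rows that couple into the
pressure block would feed back through the projected mass matrix.

Integration uses implicit Radau (scipy) at rtol 1e−8 / atol 1e−8 with an
explicitly supplied, physically-scaled finite-difference Jacobian.  Two
numerical details: the projected linear solve leaves an O(1e−10) roundoff
floor on the reduced derivative, so letting the solver finite-difference
the right-hand side across machine-scale perturbations (its default
Jacobian and initial-step heuristics) produces noise — hence the supplied
Jacobian and explicit first step; and the `|ΔP|^γ` kink of the cranial law
(γ < 1) is harmless because the baseline pressure differences on those
interfaces are nonzero.  Halving the tolerances moves the reported ICP
trace by < 1e−4 mmHg.

The slowest relaxation is the spinal-CSF storage discharging through
~0.025 mL/min/mmHg fluidities (time constant ≈ 19 min); the steady-state
criterion max |dP/dt| < 1e−6 mmHg/min is therefore reached at ~145–165
minutes of model time, and runs integrate up to a 180-minute horizon with
the criterion checked every minute through the transient and every five
minutes thereafter.

## The heart and baroreflex (dynamic mode)

The heart is a virtual compartment solved once per cardiac cycle, outside
the ODE state.  Each beat, the heart pressure balances venous return
against a Starling-like ejection sigmoid:

    F_in  = max(Z_heart (P_cv − max(P_heart, P_thoracic + 2)), 0)
    F_out = S · HR · SV · C / (1 + α_heart exp(−β (P_heart − P_thoracic)))

`F_in` is nonincreasing and `F_out` strictly increasing in the heart
pressure, so the crossing is unique; it is found by bracketed bisection
(robust at the `max()` kinks).  The balanced flow is imposed for the whole
beat (1/HR minutes) as a forced outflow from the Central Veins and inflow
to the Central Arteries — the heart conserves blood exactly.  Heart rate
relaxes each beat toward a baroreflex set point,

    σ(P) = (α_σ/(1 + (P/P0)^ν) − β_σ/(1 + (P/P0)^−ν) + γ_σ) HR0,

driven by the *beat-averaged* Central Arteries pressure of the completed
cycle, with relaxation factor `exp(−(1/HR)/τ)`.  τ is 4 seconds converted
to 1/15 min so the exponent is dimensionless; the printed coefficients
satisfy σ(P0) = HR0, so the calibrated baseline is an exact fixed point of
the regulated system.  The initial heart-rate history is HR0 (exact, since
runs start from the baseline steady state).  Stroke volume is a constant;
no Frank-Starling dependence of SV on filling is added — filling effects
live entirely in the ejection sigmoid.

The dynamic study advances beat-by-beat through the thoracic ramp and the
fast transient.  Once the per-beat heart-rate and output updates settle at
the beat map's fixed point, the remaining slow relaxation is integrated
with a *quasi-static* regulated closure: the output solved continuously
from the instantaneous pressures with the heart rate at its set point.
The closure coincides with the beat map at the fixed point and lets the
implicit integrator carry the heart feedback stably over long blocks (a
"hold the output for a block, then update" scheme is an unstable discrete
feedback loop and is not used).

## The experiments

Both studies drop the thoracic pressure from −6 to −10 mmHg linearly over
the first minute.  The **fixed** study clamps the Central Arteries and
Central Veins pressures over a 13 × 7 grid ({86…98} × {2…8} mmHg, 91
combinations), pre-equilibrates each point at −6 mmHg, applies the ramp,
and integrates to steady state.  Because the thoracic compartment has no
resistive connection to the network, the post-ramp steady state is
*identical* to the pre-ramp one; all structure is in the transient "ring"
excited through the 0.034 mL/mmHg thoracic–spinal-CSF interface.  The
**dynamic** study leaves the central pressures free and lets the thoracic
drop act on venous return, collapse pressure (`P_thoracic + 2`), ejection
afterload and the baroreflex.

Summary changes are final-steady-state minus pre-ramp values; transient
maxima are taken over the full post-ramp window.  Final states are
profile-shape invariant (only the endpoint pressures matter); sharper ramps
ring harder.  Runs are deterministic — identical configurations produce
bit-identical outputs.

## What the model does and does not capture

The generator of all inputs is the packaged parameter set itself; there is
no synthetic data beyond it and no stochastic element anywhere.  Passing
tests therefore demonstrate internal consistency of the calibrated network
and reproduction of the study's numerical experiments — not validity
against clinical measurements.  Known limitations: no hydrostatic columns
or posture change (supine only — tilt-table behavior is out of scope by
construction), no cerebral autoregulation, no in-beat pulsatility, constant
CSF production, and fixed resistances.  The damaged-myocardium parameter
(S < 1) is exposed but not exercised by any shipped experiment.

One reproduction caveat is documented here deliberately: at the dynamic
study's steady state the model yields a cardiac output of ≈ 5598 mL/min
alongside ΔICP ≈ −2.1 mmHg, ΔCVP ≈ −2.9 mmHg and ΔMAP ≈ +2.2%.  The
network's calibrated carrying capacity ties output to the arteriovenous
difference (≈ 5300/87 mL/min/mmHg), so an output near 5750 mL/min would
require a central-venous drop of ≈ 4.4 mmHg — inconsistent with the ≈ 3
mmHg the same experiment produces.  The package reports what the equations
give.
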