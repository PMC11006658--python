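"""Beat-discretized cardiac output and baroreflex heart-rate regulation.

The heart is a *virtual* compartment outside the network state.  Once per
cardiac cycle a heart pressure ``P_heart`` is found balancing venous return

    F_in(P_heart) = max(Z_heart * (P_cv - max(P_heart, P_collapse)), 0)

against a Starling-like ejection curve

    F_out(P_heart) = S * HR * SV * C / (1 + alpha_heart * exp(-beta * (P_heart - P_ext)))

with ``P_collapse = P_thoracic + 2`` (partial collapse of the central veins)
and ``P_ext = P_thoracic`` (thoracic pressure loads diastolic filling).  The
balanced flow is held constant for the beat (``1/HR`` minutes) as a forced
outflow from the Central Veins and inflow to the Central Arteries.

Heart rate relaxes each beat toward a baroreflex set point built from
sympathetic and parasympathetic sigmoid responses to the beat-averaged
arterial pressure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

log = logging.getLogger(__name__)

__all__ = [
    "CardiacParams",
    "BaroreflexParams",
    "HeartState",
    "flow_in",
    "flow_out",
    "beat_loop",
    "initial_heart_state",
    "solve_heart_pressure",
    "sigma_activation",
    "update_heart_rate",
]


@dataclass(frozen=True)
class CardiacParams:
    """Virtual-heart constants (minutes / mmHg / mL units)."""

    z_heart: float = 1250.0       # central veins -> heart fluidity, mL/min/mmHg
    s: float = 1.0                # pumping efficiency (S < 1: damaged myocardium)
    hr0: float = 61.6             # baseline heart rate, beats/min
    sv: float = 77.2              # stroke volume, mL/beat
    alpha_heart: float = 7.809    # ejection sigmoid amplitude coefficient
    beta: float = 0.381           # ejection sigmoid steepness, 1/mmHg
    c_tuning: float | None = None  # subject-specific output tuning factor
    collapse_offset: float = 2.0  # P_collapse - P_thoracic, mmHg


@dataclass(frozen=True)
class BaroreflexParams:
    """Baroreflex heart-rate regulation constants."""

    tau: float = 4.0 / 60.0       # heart-rate relaxation time, min
    alpha_sigma: float = 1.15     # sympathetic gain
    beta_sigma: float = 0.34      # parasympathetic gain
    gamma_sigma: float = 0.595    # baseline activation
    nu: float = 7.0               # sigmoid slope
    p0: float = 92.0              # baseline arterial pressure, mmHg
    hr0: float = 61.6             # baseline heart rate, beats/min


@dataclass
class HeartState:
    """Per-beat heart bookkeeping carried alongside the network state."""

    heart_rate: float             # beats/min
    beat_index: int = 0
    current_output: float = 0.0   # mL/min, held for the ongoing beat
    heart_pressure: float = 0.0   # mmHg

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise ValueError("heart rate must be positive")

    def advanced(self, heart_rate: float, heart_pressure: float, output: float) -> "HeartState":
        return replace(
            self,
            heart_rate=heart_rate,
            beat_index=self.beat_index + 1,
            heart_pressure=heart_pressure,
            current_output=output,
        )


def initial_heart_state(config, pressures) -> "HeartState":
    """Heart state at the start of a run: baseline rate, balanced output."""
    p_cv = pressures[config.index(config.heart_venous)]
    p_th = pressures[config.index("Thoracic")]
    p_heart, output = solve_heart_pressure(p_cv, p_th, config.cardiac.hr0, config.cardiac)
    return HeartState(
        heart_rate=config.cardiac.hr0, heart_pressure=p_heart, current_output=output
    )


def beat_loop(model, state, config, n_quad: int = 7):
    """Advance the network by one cardiac cycle.

    Steps: (1) integrate the network over the elapsed beat (duration
    ``1/HR`` minutes) with the beat-held cardiac output imposed as a forced
    outflow from the Central Veins and inflow to the Central Arteries;
    (2) compute the beat-averaged Central Arteries pressure; (3) relax the
    heart rate toward the baroreflex set point; (4) solve the heart balance
    for the next beat's output.  Returns the advanced
    :class:`~cranioflow.network.ModelState` (with updated ``heart``).
    """
    heart = state.heart
    if heart is None:
        raise ValueError("beat_loop requires a state with heart bookkeeping")
    i_ca = config.index(config.heart_arterial)
    i_cv = config.index(config.heart_venous)
    i_th = config.index("Thoracic")
    dt = 1.0 / heart.heart_rate
    t0 = state.time
    extra = {
        config.heart_arterial: heart.current_output,
        config.heart_venous: -heart.current_output,
    }
    import numpy as np

    t_eval = np.linspace(t0, t0 + dt, n_quad)
    traj = model.integrate(state, (t0, t0 + dt), t_eval=t_eval, extra_forced=extra)
    map_avg = float(np.trapezoid(traj.pressures[:, i_ca], traj.times) / dt)
    sigma = sigma_activation(map_avg, config.baroreflex)
    hr_next = update_heart_rate(heart.heart_rate, sigma, config.baroreflex)
    new_state = traj.final_state()
    p_heart, output = solve_heart_pressure(
        new_state.pressures[i_cv], new_state.pressures[i_th], hr_next, config.cardiac
    )
    new_state.heart = heart.advanced(hr_next, p_heart, output)
    return new_state


def flow_in(
    p_heart: float, p_cv: float, p_thoracic: float, params: CardiacParams
) -> float:
    """Pressure-driven venous return into the heart (mL/min), clipped at zero.

    Constant for ``p_heart`` below the partial-collapse pressure
    ``p_thoracic + collapse_offset`` and nonincreasing above it.
    """
    p_collapse = p_thoracic + params.collapse_offset
    return max(params.z_heart * (p_cv - max(p_heart, p_collapse)), 0.0)


def flow_out(
    p_heart: float, hr: float, p_external: float, params: CardiacParams
) -> float:
    """Sigmoidal ejection flow from the heart (mL/min).

    Strictly increasing in ``p_heart`` and bounded by ``s * hr * sv * c_tuning``.
    ``p_external`` is the thoracic pressure loading diastolic filling.
    """
    c = 1.0 if params.c_tuning is None else params.c_tuning
    peak = params.s * hr * params.sv * c
    return peak / (1.0 + params.alpha_heart * math.exp(-params.beta * (p_heart - p_external)))


def solve_heart_pressure(
    p_cv: float,
    p_thoracic: float,
    hr: float,
    params: CardiacParams,
    tol: float = 1e-10,
) -> tuple[float, float]:
    """Solve the beat balance ``F_in(P_heart) = F_out(P_heart)``.

    Returns ``(heart_pressure, output)``.  ``F_in`` is nonincreasing and
    ``F_out`` strictly increasing in the heart pressure, so the crossing is
    unique when it exists; it is found by bracketed bisection (robust at the
    ``max()`` kinks of the inflow curve).  If venous return is identically
    zero over the bracket (central-venous pressure at or below every
    attainable filling pressure) the beat delivers zero output and a warning
    is logged instead of raising.
    """
    lo = min(p_thoracic, p_cv) - 50.0
    hi = p_cv + 50.0

    def residual(p: float) -> float:
        return flow_in(p, p_cv, p_thoracic, params) - flow_out(p, hr, p_thoracic, params)

    if flow_in(lo, p_cv, p_thoracic, params) <= 0.0:
        log.warning(
            "venous return is zero across the search bracket (P_cv=%.3f, "
            "P_thoracic=%.3f); heart delivers no output this beat",
            p_cv,
            p_thoracic,
        )
        return lo, 0.0
    if residual(hi) > 0.0:  # pragma: no cover - unreachable for physical params
        raise ValueError("heart balance has no crossing in the search bracket")
    p_heart = brentq(residual, lo, hi, xtol=tol)
    output = flow_out(p_heart, hr, p_thoracic, params)
    return p_heart, output


def sigma_activation(p_arterial_mean: float, params: BaroreflexParams) -> float:
    """Baroreflex heart-rate set point (beats/min) for a beat-averaged MAP.

    Sympathetic drive falls and parasympathetic drive rises with pressure;
    at ``p0`` the set point equals the baseline heart rate exactly
    (``alpha_sigma/2 - beta_sigma/2 + gamma_sigma = 1``).
    """
    if p_arterial_mean <= 0:
        raise ValueError("arterial pressure must be positive")
    ratio_nu = (p_arterial_mean / params.p0) ** params.nu
    sympathetic = params.alpha_sigma / (1.0 + ratio_nu)
    parasympathetic = params.beta_sigma / (1.0 + 1.0 / ratio_nu)
    return (sympathetic - parasympathetic + params.gamma_sigma) * params.hr0


def update_heart_rate(hr_prev: float, sigma: float, params: BaroreflexParams) -> float:
    """Exponential relaxation of heart rate toward the set point over one beat.

    The relaxation factor ``exp(-(1/hr_prev)/tau)`` uses the just-elapsed
    beat duration ``1/hr_prev`` minutes; the update is a contraction, so
    iterating with a constant set point converges geometrically.
    """
    if hr_prev <= 0:
        raise ValueError("heart rate must be positive")
    return sigma + (hr_prev - sigma) * math.exp(-(1.0 / hr_prev) / params.tau)
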