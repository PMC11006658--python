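"""The two thoracic-pressure studies and their summary metrics.

Both experiments drop the thoracic pressure from -6 to -10 mmHg over the
first minute (a piecewise-linear ramp) with the body supine — hydrostatic
terms are absent by construction:

* **Fixed MAP/CVP**: the Central Arteries and Central Veins pressures are
  clamped, isolating the compliant thoracic-to-spinal-CSF pathway.  A 13 x 7
  grid of (MAP, CVP) combinations — 91 runs — probes independence from the
  particular boundary values.  Each run pre-equilibrates at the clamped
  pressures before the ramp.
* **Dynamic MAP/CVP**: the central pressures are driven by the beat-resolved
  virtual heart with baroreflex regulation, letting the thoracic change act
  on venous return and cardiac output.

Each run integrates past the ramp until the steady-state criterion
``max |dP/dt| < 1e-6 mmHg/min`` is met, and reports initial/final/extreme
intracranial (Ventricular CSF) pressures plus the central-pressure and
cardiac-output changes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .cardiac import (
    HeartState,
    beat_loop,
    initial_heart_state,
    sigma_activation,
    solve_heart_pressure,
)
from .errors import ExperimentError, SteadyStateError
from .network import (
    STEADY_STATE_TOL,
    CompartmentalModel,
    ConstantPrescription,
    ModelState,
    Prescription,
    Trajectory,
)
from .parameters import THORACIC, VENTRICULAR_CSF, NetworkConfig

log = logging.getLogger(__name__)

__all__ = [
    "ThoracicProfile",
    "SweepGrid",
    "ExperimentSummary",
    "thoracic_profile",
    "run_fixed_experiment",
    "run_fixed_sweep",
    "run_dynamic_experiment",
    "profile_sensitivity",
    "default_sweep_grid",
]

#: Model-time cap for reaching the steady-state criterion (min).
STEADY_STATE_HORIZON = 180.0


@dataclass(frozen=True)
class ThoracicProfile(Prescription):
    """Prescribed thoracic pressure: constant, linear ramp, or custom.

    The default reproduces the study profile: -6 mmHg before t = 0, a linear
    ramp to -10 mmHg over the first minute, then -10 mmHg.
    """

    kind: str = "linear_ramp"  # constant | linear_ramp | custom
    start: float = -6.0        # mmHg
    end: float = -10.0         # mmHg
    ramp_start: float = 0.0    # min
    ramp_duration: float = 1.0  # min
    custom_value: Callable[[float], float] | None = None
    custom_derivative: Callable[[float], float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "linear_ramp", "custom"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.kind == "custom" and (
            self.custom_value is None or self.custom_derivative is None
        ):
            raise ValueError("custom profiles need value and derivative callables")
        if self.kind == "linear_ramp" and self.ramp_duration <= 0:
            raise ValueError("ramp duration must be positive")

    def value(self, t: float) -> float:
        if self.kind == "constant":
            return self.start
        if self.kind == "custom":
            return self.custom_value(t)
        if t < self.ramp_start:
            return self.start
        if t > self.ramp_start + self.ramp_duration:
            return self.end
        slope = (self.end - self.start) / self.ramp_duration
        return self.start + slope * (t - self.ramp_start)

    def derivative(self, t: float) -> float:
        if self.kind == "constant":
            return 0.0
        if self.kind == "custom":
            return self.custom_derivative(t)
        if self.ramp_start <= t <= self.ramp_start + self.ramp_duration:
            return (self.end - self.start) / self.ramp_duration
        return 0.0

    @property
    def breakpoints(self) -> tuple[float, ...]:
        """Derivative discontinuities the integrator should not step across."""
        if self.kind == "linear_ramp":
            return (self.ramp_start, self.ramp_start + self.ramp_duration)
        return ()


def thoracic_profile(t: float, profile: ThoracicProfile | None = None) -> tuple[float, float]:
    """Thoracic pressure and its time derivative at ``t`` (mmHg, mmHg/min)."""
    if profile is None:
        profile = ThoracicProfile()
    return profile.value(t), profile.derivative(t)


@dataclass(frozen=True)
class SweepGrid:
    """The (MAP, CVP) clamp grid of the fixed study."""

    map_values: tuple[float, ...] = tuple(float(v) for v in range(86, 99))
    cvp_values: tuple[float, ...] = tuple(float(v) for v in range(2, 9))

    def __len__(self) -> int:
        return len(self.map_values) * len(self.cvp_values)

    def points(self):
        for m in self.map_values:
            for c in self.cvp_values:
                yield m, c


def default_sweep_grid() -> SweepGrid:
    return SweepGrid()


@dataclass
class ExperimentSummary:
    """Per-run scalar outcomes (final values after the steady-state criterion)."""

    experiment: str
    map_fixed: float | None
    cvp_fixed: float | None
    icp_initial: float            # mmHg, pre-ramp steady state
    icp_final: float              # mmHg, converged post-ramp
    icp_min: float
    icp_max: float
    max_abs_delta_icp: float      # max_t |ICP(t) - ICP(0)|, mmHg
    delta_map: float              # mmHg
    delta_cvp: float              # mmHg
    delta_cardiac_output: float   # mL/min (0 in fixed mode)
    cardiac_output_final: float | None
    time_to_steady_state: float   # min
    converged: bool = True

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _integrate_to_steady_state(
    model: CompartmentalModel,
    state: ModelState,
    profile: ThoracicProfile,
    rtol: float,
    atol: float,
    ramp_eval_step: float = 0.005,
    tol: float = STEADY_STATE_TOL,
    horizon: float = STEADY_STATE_HORIZON,
) -> tuple[Trajectory, float]:
    """Ramp segment(s) at fine output resolution, then 1-minute blocks until
    the pressure-derivative criterion is met.  Returns (trajectory, t_ss)."""
    t = 0.0
    segments = sorted({*profile.breakpoints, 0.0})
    segments = [s for s in segments if s > 0.0]
    traj: Trajectory | None = None
    for t_next in segments:
        t_eval = np.arange(t, t_next + ramp_eval_step / 2, ramp_eval_step)
        piece = model.integrate(state, (t, t_next), t_eval=t_eval, rtol=rtol, atol=atol)
        traj = piece if traj is None else traj.extend(piece)
        state = traj.final_state()
        t = t_next
    while t < horizon:
        # minute-by-minute checks through the transient; coarser blocks once
        # only the slow spinal-storage mode (tau ~ 19 min) is left relaxing
        block = 1.0 if t < 20.0 else 5.0
        t_next = t + block
        piece = model.integrate(
            state, (t, t_next), t_eval=[t, t + block / 2, t_next], rtol=rtol, atol=atol
        )
        traj = piece if traj is None else traj.extend(piece)
        state = traj.final_state()
        t = t_next
        dpdt = model.pressure_derivative(t, state.pressures)
        if np.max(np.abs(dpdt)) < tol:
            return traj, t
    raise SteadyStateError(
        f"no steady state within {horizon:g} min (|dP/dt| = "
        f"{np.max(np.abs(dpdt)):.3g} mmHg/min)"
    )


def run_fixed_experiment(
    map_fixed: float,
    cvp_fixed: float,
    config: NetworkConfig,
    profile: ThoracicProfile | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> tuple[ExperimentSummary, Trajectory]:
    """One fixed-boundary run: clamp MAP and CVP, ramp the thoracic pressure.

    Phase (a) pre-equilibrates with the thoracic pressure at the profile
    start value; phase (b) applies the ramp and integrates to steady state.
    The summary is computed from phase (b).
    """
    if not (60.0 <= map_fixed <= 120.0):
        log.warning("fixed MAP %.1f mmHg outside the validated range [60, 120]", map_fixed)
    if not (0.0 <= cvp_fixed <= 15.0):
        log.warning("fixed CVP %.1f mmHg outside the validated range [0, 15]", cvp_fixed)
    profile = profile or ThoracicProfile()
    boundary = {
        config.heart_arterial: ConstantPrescription(float(map_fixed)),
        config.heart_venous: ConstantPrescription(float(cvp_fixed)),
    }
    model_pre = CompartmentalModel(
        config,
        prescribed={**boundary, THORACIC: ConstantPrescription(profile.value(-1.0))},
    )
    try:
        pre = model_pre.find_steady_state(method="root")
    except SteadyStateError as exc:
        raise ExperimentError(
            f"pre-equilibration failed at MAP={map_fixed}, CVP={cvp_fixed}: {exc}"
        ) from exc

    model = CompartmentalModel(config, prescribed={**boundary, THORACIC: profile})
    try:
        traj, t_ss = _integrate_to_steady_state(model, pre, profile, rtol, atol)
    except SteadyStateError as exc:
        raise ExperimentError(
            f"ramp phase did not converge at MAP={map_fixed}, CVP={cvp_fixed}: {exc}"
        ) from exc

    icp = traj.pressure(VENTRICULAR_CSF)
    icp0 = pre.pressures[config.index(VENTRICULAR_CSF)]
    summary = ExperimentSummary(
        experiment="fixed",
        map_fixed=float(map_fixed),
        cvp_fixed=float(cvp_fixed),
        icp_initial=float(icp0),
        icp_final=float(icp[-1]),
        icp_min=float(np.min(icp)),
        icp_max=float(np.max(icp)),
        max_abs_delta_icp=float(np.max(np.abs(icp - icp0))),
        delta_map=0.0,
        delta_cvp=0.0,
        delta_cardiac_output=0.0,
        cardiac_output_final=None,
        time_to_steady_state=t_ss,
    )
    return summary, traj


def run_fixed_sweep(
    grid: SweepGrid | None = None,
    config: NetworkConfig | None = None,
    profile: ThoracicProfile | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    keep_trajectories: bool = False,
) -> tuple[list[ExperimentSummary], list[tuple[float, float, str]], list[Trajectory]]:
    """Run the full clamp grid (default 13 x 7 = 91 combinations).

    Failures are recorded per grid point and the sweep continues; the caller
    decides the exit status.  Returns (summaries, failures, trajectories)
    where trajectories is empty unless ``keep_trajectories``.
    """
    if config is None:
        raise ValueError("a calibrated config is required")
    grid = grid or SweepGrid()
    summaries: list[ExperimentSummary] = []
    failures: list[tuple[float, float, str]] = []
    trajectories: list[Trajectory] = []
    for map_fixed, cvp_fixed in grid.points():
        try:
            summary, traj = run_fixed_experiment(
                map_fixed, cvp_fixed, config, profile=profile, rtol=rtol, atol=atol
            )
        except ExperimentError as exc:
            log.error("sweep point (%.0f, %.0f) failed: %s", map_fixed, cvp_fixed, exc)
            failures.append((map_fixed, cvp_fixed, str(exc)))
            continue
        summaries.append(summary)
        if keep_trajectories:
            trajectories.append(traj)
    if summaries:
        worst = max(s.max_abs_delta_icp for s in summaries)
        log.info(
            "sweep complete: %d/%d runs, worst max|dICP| = %.4f mmHg",
            len(summaries), len(grid), worst,
        )
    return summaries, failures, trajectories


def run_dynamic_experiment(
    config: NetworkConfig,
    profile: ThoracicProfile | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    tol: float = STEADY_STATE_TOL,
    horizon: float = STEADY_STATE_HORIZON,
) -> tuple[ExperimentSummary, Trajectory]:
    """The dynamic study: beat-resolved heart and baroreflex, thoracic ramp.

    The calibrated baseline is an exact steady state of the regulated system
    (the tuning factor is fitted so the heart reproduces the baseline output
    at the baseline heart rate), so the pre-ramp phase starts from it.  The
    beat loop advances the network one cardiac cycle at a time through the
    ramp and the fast transient.  Once the per-beat heart-rate and output
    updates have settled at the fixed point of the beat map (heart rate at
    the baroreflex set point, output balancing the ejection and return
    curves at the current pressures), the remaining slow pressure relaxation
    is integrated with the *quasi-static* regulated closure — the cardiac
    output solved continuously from the instantaneous pressures with the
    heart rate at its set point — which coincides with the beat map at the
    fixed point and lets the implicit integrator carry the heart feedback
    stably over long blocks.
    """
    profile = profile or ThoracicProfile()
    model = CompartmentalModel(config, prescribed={THORACIC: profile})
    i_ca = config.index(config.heart_arterial)
    i_cv = config.index(config.heart_venous)
    i_icp = config.index(VENTRICULAR_CSF)

    state = model.baseline_state()
    state.heart = initial_heart_state(config, state.pressures)
    baseline = state.pressures.copy()
    co0 = state.heart.current_output

    times = [0.0]
    pressures = [state.pressures.copy()]
    heart_rows = [(state.heart.heart_rate, state.heart.heart_pressure, co0)]

    def record() -> None:
        times.append(state.time)
        pressures.append(state.pressures.copy())
        heart_rows.append(
            (state.heart.heart_rate, state.heart.heart_pressure, state.heart.current_output)
        )

    # phase 1: beat-resolved ramp and fast transient
    ramp_end = profile.breakpoints[-1] if profile.breakpoints else 0.0
    beat_horizon = min(max(10.0, 5.0 * max(ramp_end, 1.0)), horizon)
    while state.time < beat_horizon:
        prev = state.heart
        state = beat_loop(model, state, config)
        record()
        hr_step = abs(state.heart.heart_rate - prev.heart_rate)
        co_step = abs(state.heart.current_output - prev.current_output)
        if state.time > ramp_end and hr_step < 1e-6 and co_step < 1e-3:
            break

    # phase 2: slow relaxation under the quasi-static regulated heart
    def regulated_heart(t: float, p: np.ndarray) -> dict:
        hr = sigma_activation(p[i_ca], config.baroreflex)
        _, output = solve_heart_pressure(p[i_cv], profile.value(t), hr, config.cardiac)
        return {config.heart_arterial: output, config.heart_venous: -output}

    t_ss = None
    while state.time < horizon:
        t0 = state.time
        block = model.integrate(
            state, (t0, t0 + 5.0), t_eval=np.linspace(t0, t0 + 5.0, 6),
            extra_forced=regulated_heart, rtol=rtol, atol=atol,
        )
        state = block.final_state()
        hr = sigma_activation(state.pressures[i_ca], config.baroreflex)
        p_heart, output = solve_heart_pressure(
            state.pressures[i_cv], profile.value(state.time), hr, config.cardiac
        )
        state.heart = HeartState(
            heart_rate=hr, heart_pressure=p_heart, current_output=output
        )
        record()
        dpdt = model.pressure_derivative(state.time, state.pressures, regulated_heart)
        if np.max(np.abs(dpdt)) < tol:
            t_ss = state.time
            break
    if t_ss is None:
        raise ExperimentError(
            f"dynamic experiment did not reach steady state within {horizon:g} min"
        )

    times_arr = np.array(times)
    p_arr = np.array(pressures)
    hr_arr, hp_arr, co_arr = (np.array(col) for col in zip(*heart_rows))
    n_e = model.n_e
    traj = Trajectory(
        times=times_arr,
        pressures=p_arr,
        compartment_volumes=np.zeros((len(times_arr), model.n)),
        interface_volumes=np.zeros((len(times_arr), n_e)),
        names=model.names,
        interface_labels=model.interface_labels,
        heart_rate=hr_arr,
        heart_pressure=hp_arr,
        cardiac_output=co_arr,
    )
    icp = p_arr[:, i_icp]
    summary = ExperimentSummary(
        experiment="dynamic",
        map_fixed=None,
        cvp_fixed=None,
        icp_initial=float(baseline[i_icp]),
        icp_final=float(icp[-1]),
        icp_min=float(np.min(icp)),
        icp_max=float(np.max(icp)),
        max_abs_delta_icp=float(np.max(np.abs(icp - baseline[i_icp]))),
        delta_map=float(p_arr[-1, i_ca] - baseline[i_ca]),
        delta_cvp=float(p_arr[-1, i_cv] - baseline[i_cv]),
        delta_cardiac_output=float(co_arr[-1] - co0),
        cardiac_output_final=float(co_arr[-1]),
        time_to_steady_state=float(t_ss),
    )
    return summary, traj


def profile_sensitivity(
    profiles: Sequence[ThoracicProfile],
    config: NetworkConfig,
    map_fixed: float = 92.0,
    cvp_fixed: float = 5.0,
    rtol: float = 1e-8,
    atol: float = 1e-8,
):
    """Fixed-boundary runs over alternative thoracic profiles.

    All profiles must share start and end pressures.  The final steady state
    is profile-shape independent (only the endpoint pressures matter); the
    transient peak grows with ramp sharpness.  Returns a list of dicts with
    the per-profile peak and final ICP.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    start, end = profiles[0].start, profiles[0].end
    for p in profiles[1:]:
        if not (math.isclose(p.start, start) and math.isclose(p.end, end)):
            raise ValueError("profiles must share start and end pressures")
    report = []
    for p in profiles:
        summary, _ = run_fixed_experiment(
            map_fixed, cvp_fixed, config, profile=p, rtol=rtol, atol=atol
        )
        report.append(
            {
                "kind": p.kind,
                "ramp_duration": p.ramp_duration if p.kind == "linear_ramp" else np.nan,
                "peak_abs_delta_icp": summary.max_abs_delta_icp,
                "icp_final": summary.icp_final,
                "time_to_steady_state": summary.time_to_steady_state,
            }
        )
    return report
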