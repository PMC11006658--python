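"""Constrained compartmental dynamics: matrices, projection, integration.

The network obeys the mass-balance system

    C(P) dP/dt = Z P + F(t, P)

where ``C`` is the symmetric compliance matrix (graph-Laplacian structure
from pairwise interfaces plus diagonal self-compliances), ``Z`` the constant
fluidity matrix (row sums zero, so resistive flow conserves volume) and
``F`` collects forced flows: constant CSF production, the nonlinear
Starling-Landis filtration, and in dynamic mode the beat-held cardiac output.

The system is extended with volume bookkeeping — per-compartment volumes
integrating the net inflow, and per-interface volumes integrating
``C_ij d(P_i - P_j)/dt`` — and restricted to the manifold of linear
constraints ``A X = B`` (the Monro-Kellie cranial-volume constraint, plus
any user rows) by tangent-space parameterization: with ``Q`` an orthonormal
null-space basis of ``A`` and ``X(t) = Q Z(t) + X(0)``, the reduced system

    (Qᵀ M(X) Q) dZ/dt = Qᵀ G(X)

is integrated with a stiff implicit method, so the constraints hold to
machine precision at every step (no post-hoc projection).  Prescribed
pressures (thoracic always; the central boundary compartments in fixed
experiments) replace the corresponding dynamic equation with
``dP_i/dt = (prescribed profile)'(t)``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.linalg import null_space
from scipy.optimize import root

from .cardiac import HeartState
from .compliance import venous_compliance
from .errors import (
    CalibrationError,
    ConfigurationError,
    ConstraintError,
    IntegrationError,
    SteadyStateError,
)
from .parameters import THORACIC, NetworkConfig, StarlingParams

log = logging.getLogger(__name__)

__all__ = [
    "ModelState",
    "ConstraintSet",
    "Trajectory",
    "CompartmentalModel",
    "Prescription",
    "ConstantPrescription",
    "starling_landis_flow",
    "assemble_fluidity_matrix",
    "assemble_compliance_matrix",
    "build_constraint_basis",
    "reduced_rhs",
    "integrate",
    "find_steady_state",
    "STEADY_STATE_TOL",
]

#: Steady-state criterion on the pressure derivative, mmHg/min.
STEADY_STATE_TOL = 1e-6


# ---------------------------------------------------------------------------
# Prescribed-pressure profiles
# ---------------------------------------------------------------------------

class Prescription:
    """A prescribed pressure as a function of time (value and derivative)."""

    def value(self, t: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def derivative(self, t: float) -> float:  # pragma: no cover - interface
        raise NotImplementedError


@dataclass(frozen=True)
class ConstantPrescription(Prescription):
    pressure: float

    def value(self, t: float) -> float:
        return self.pressure

    def derivative(self, t: float) -> float:
        return 0.0


# ---------------------------------------------------------------------------
# State and trajectory containers
# ---------------------------------------------------------------------------

@dataclass
class ModelState:
    """Snapshot of the network at one time point.

    Volumes are stored relative to the initial condition of the run that
    produced the state (absolute compartment volumes are not part of the
    lumped formulation).
    """

    time: float
    pressures: np.ndarray
    compartment_volumes: np.ndarray
    interface_volumes: np.ndarray
    heart: HeartState | None = None

    def copy(self) -> "ModelState":
        return ModelState(
            time=self.time,
            pressures=self.pressures.copy(),
            compartment_volumes=self.compartment_volumes.copy(),
            interface_volumes=self.interface_volumes.copy(),
            heart=self.heart,
        )


@dataclass(frozen=True)
class ConstraintSet:
    """Linear constraints ``A X = B`` with an orthonormal null-space basis."""

    A: np.ndarray
    B: np.ndarray
    Q: np.ndarray

    def residual(self, x: np.ndarray) -> np.ndarray:
        if self.A.shape[0] == 0:
            return np.zeros(0)
        return self.A @ x - self.B


def build_constraint_basis(a_matrix: np.ndarray, b: np.ndarray | None = None) -> ConstraintSet:
    """Orthonormal null-space basis ``Q`` of a full-row-rank constraint matrix.

    Guarantees ``QᵀQ = I`` and ``A Q = 0`` (to numerical precision) and that
    ``dim range(Q) = n - rank(A)``.  Rank-deficient constraint rows are
    rejected as an ill-posed specification.
    """
    a_matrix = np.atleast_2d(np.asarray(a_matrix, dtype=float))
    m, n = a_matrix.shape
    if b is None:
        b = np.zeros(m)
    if m == 0:
        return ConstraintSet(A=a_matrix.reshape(0, n), B=np.zeros(0), Q=np.eye(n))
    if np.linalg.matrix_rank(a_matrix) < m:
        raise ConstraintError(
            f"constraint matrix has rank < {m}: rows are linearly dependent"
        )
    # Coordinates untouched by any constraint keep their identity basis
    # vector; the null space is computed only over the constrained columns.
    # This is still an orthonormal null-space basis of A, but it does not mix
    # well-scaled coordinates (pressures) with large ones (volumes), which
    # matters for the integrator's componentwise error control.
    touched = np.flatnonzero(np.any(a_matrix != 0.0, axis=0))
    free = np.flatnonzero(np.all(a_matrix == 0.0, axis=0))
    q_sub = null_space(a_matrix[:, touched])
    q = np.zeros((n, len(free) + q_sub.shape[1]))
    for k, col in enumerate(free):
        q[col, k] = 1.0
    q[touched, len(free):] = q_sub
    return ConstraintSet(A=a_matrix, B=np.asarray(b, dtype=float), Q=q)


@dataclass
class Trajectory:
    """Time-indexed record of a run (pressures, volumes, heart variables)."""

    times: np.ndarray
    pressures: np.ndarray             # (nt, n_compartments)
    compartment_volumes: np.ndarray   # (nt, n_compartments), relative
    interface_volumes: np.ndarray     # (nt, n_interfaces), relative
    names: tuple[str, ...]
    interface_labels: tuple[str, ...]
    heart_rate: np.ndarray | None = None
    heart_pressure: np.ndarray | None = None
    cardiac_output: np.ndarray | None = None
    constraint_residual: np.ndarray | None = None
    solver_stats: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def has_heart(self) -> bool:
        return self.heart_rate is not None

    def pressure(self, name: str) -> np.ndarray:
        return self.pressures[:, self.names.index(name)]

    def final_state(self) -> ModelState:
        heart = None
        if self.has_heart:
            heart = HeartState(
                heart_rate=float(self.heart_rate[-1]),
                current_output=float(self.cardiac_output[-1]),
                heart_pressure=float(self.heart_pressure[-1]),
            )
        return ModelState(
            time=float(self.times[-1]),
            pressures=self.pressures[-1].copy(),
            compartment_volumes=self.compartment_volumes[-1].copy(),
            interface_volumes=self.interface_volumes[-1].copy(),
            heart=heart,
        )

    def extend(self, other: "Trajectory") -> "Trajectory":
        """Concatenate a continuation run (dropping its duplicated first point)."""
        if other.names != self.names:
            raise ValueError("trajectories describe different networks")
        skip = 1 if len(other) and np.isclose(other.times[0], self.times[-1]) else 0

        def cat(x, y):
            if x is None or y is None:
                return x if y is None else y
            return np.concatenate([x, y[skip:]])

        return Trajectory(
            times=cat(self.times, other.times),
            pressures=cat(self.pressures, other.pressures),
            compartment_volumes=cat(self.compartment_volumes, other.compartment_volumes),
            interface_volumes=cat(self.interface_volumes, other.interface_volumes),
            names=self.names,
            interface_labels=self.interface_labels,
            heart_rate=cat(self.heart_rate, other.heart_rate),
            heart_pressure=cat(self.heart_pressure, other.heart_pressure),
            cardiac_output=cat(self.cardiac_output, other.cardiac_output),
            constraint_residual=cat(self.constraint_residual, other.constraint_residual),
            solver_stats={
                "nfev": self.solver_stats.get("nfev", 0) + other.solver_stats.get("nfev", 0),
                "segments": self.solver_stats.get("segments", 1)
                + other.solver_stats.get("segments", 1),
            },
        )

    def to_wide_frame(self):
        """Wide-format table: one column per state variable (plus heart)."""
        import pandas as pd

        data = {"time_min": self.times}
        for k, name in enumerate(self.names):
            data[f"P[{name}]"] = self.pressures[:, k]
        for k, name in enumerate(self.names):
            data[f"V[{name}]"] = self.compartment_volumes[:, k]
        for k, label in enumerate(self.interface_labels):
            data[f"Vif[{label}]"] = self.interface_volumes[:, k]
        if self.has_heart:
            data["heart_rate"] = self.heart_rate
            data["heart_pressure"] = self.heart_pressure
            data["cardiac_output"] = self.cardiac_output
        return pd.DataFrame(data)

    def to_long_frame(self):
        """Long-format table (time, variable, value)."""
        wide = self.to_wide_frame()
        return wide.melt(id_vars="time_min", var_name="variable", value_name="value")


# ---------------------------------------------------------------------------
# Elementary flow laws
# ---------------------------------------------------------------------------

def starling_landis_flow(p_cap: float, p_brain: float, params: StarlingParams) -> float:
    """Transcapillary filtration across the blood-brain barrier (mL/min).

    ``K_CB [(P_cap - P_brain) - sigma_CB (pi_C - pi_B)]``; negative values
    indicate osmotic reabsorption into the capillaries.
    """
    return params.k_cb * (
        (p_cap - p_brain) - params.sigma_cb * (params.pi_capillary - params.pi_brain)
    )


# ---------------------------------------------------------------------------
# The assembled model
# ---------------------------------------------------------------------------

class CompartmentalModel:
    """A calibrated network bound to prescribed-pressure profiles.

    Parameters
    ----------
    config
        A fully calibrated :class:`~cranioflow.parameters.NetworkConfig`.
    prescribed
        Mapping from compartment name to a :class:`Prescription` whose value
        replaces that compartment's dynamic equation.
    constrained
        Whether to impose the Monro-Kellie constraint (and any extra rows).
    """

    def __init__(
        self,
        config: NetworkConfig,
        prescribed: Mapping[str, Prescription] | None = None,
        constrained: bool = True,
        extra_constraint_rows: np.ndarray | None = None,
    ):
        if not config.is_calibrated:
            raise CalibrationError(
                "model requires a calibrated config (run parameters.calibrate)"
            )
        self.config = config
        self.names = config.names
        self.n = config.n_compartments
        self._idx = {name: i for i, name in enumerate(self.names)}
        self.prescribed: dict[str, Prescription] = dict(prescribed or {})
        for name in self.prescribed:
            if name not in self._idx:
                raise ConfigurationError(f"prescribed pressure for unknown compartment {name!r}")
        self._prescribed_idx = [self._idx[n] for n in self.prescribed]

        # constant fluidity matrix
        z = np.zeros((self.n, self.n))
        for e in config.flows:
            if e.kind != "resistive":
                continue
            i, j = self._idx[e.source], self._idx[e.dest]
            z[i, j] += e.fluidity
            z[j, i] += e.fluidity
            z[i, i] -= e.fluidity
            z[j, j] -= e.fluidity
        self._z = z

        # compliance edges: (ia, ib, evaluator)
        self._edges = list(config.compliances)
        self._edge_idx = [(self._idx[e.a], self._idx[e.b]) for e in self._edges]
        self.interface_labels = tuple(
            f"{e.a}|{e.b}" if not e.is_self else f"{e.a}|ambient" for e in self._edges
        )
        self._thoracic = self._idx.get(THORACIC)
        self._evaluators = [self._make_evaluator(e) for e in self._edges]

        # forced flows and the Starling edge
        self._forced_edges = [
            (self._idx[e.source], self._idx[e.dest], e.calibrated_mean_flow)
            for e in config.flows
            if e.kind == "forced_constant"
        ]
        star = [e for e in config.flows if e.kind == "starling"]
        if len(star) > 1:
            raise ConfigurationError("at most one Starling-Landis edge is supported")
        self._starling_edge = (
            (self._idx[star[0].source], self._idx[star[0].dest]) if star else None
        )

        # extended state layout: pressures | compartment volumes | interface volumes
        self.n_e = len(self._edges)
        self.n_state = 2 * self.n + self.n_e
        self._off_vc = self.n
        self._off_ve = 2 * self.n

        self.constrained = constrained
        a_rows = []
        if constrained and config.monro_kellie:
            overlap = set(config.monro_kellie) & set(self.prescribed)
            if overlap:
                raise ConfigurationError(
                    f"compartments {sorted(overlap)} are both pressure-prescribed "
                    f"and members of a volume constraint; the specification is "
                    f"ambiguous"
                )
            row = np.zeros(self.n_state)
            for name in config.monro_kellie:
                row[self._off_vc + self._idx[name]] = 1.0
            a_rows.append(row)
        if extra_constraint_rows is not None:
            a_rows.extend(np.atleast_2d(extra_constraint_rows))
        a_matrix = np.array(a_rows).reshape(len(a_rows), self.n_state)
        self.constraints = build_constraint_basis(a_matrix)

    # -- matrix assembly ---------------------------------------------------
    def _make_evaluator(self, e) -> Callable[[np.ndarray], float]:
        cfg = self.config
        if e.model == "constant":
            value = e.baseline_compliance
            return lambda p: value
        if e.model == "cranial":
            ia, ib = self._idx[e.a], self._idx[e.b]
            scale = e.scale_factor
            cp = cfg.cranial
            return lambda p: scale * cp.c0 * math.exp(
                -cp.r * abs(p[ia] - p[ib]) ** cp.gamma
            )
        # venous hyperbolic law
        params = cfg.venous_params_for(e)
        it = self._idx[e.transmural]
        neck = cfg.compartment(e.transmural).level == "neck"
        if neck:
            return lambda p: venous_compliance(p[it], params)
        ith = self._thoracic
        if ith is None:
            raise ConfigurationError(
                "venous compliance referenced to thoracic pressure requires a "
                "thoracic compartment"
            )
        return lambda p: venous_compliance(p[it] - p[ith], params)

    def compliance_values(self, pressures: np.ndarray) -> np.ndarray:
        """Per-edge compliance values at the given pressures (mL/mmHg)."""
        return np.array([f(pressures) for f in self._evaluators])

    def assemble_compliance_matrix(self, pressures: np.ndarray) -> np.ndarray:
        """Symmetric compliance matrix at the given pressures.

        Pairwise interfaces contribute ``+C_ij`` to both diagonals and
        ``-C_ij`` off-diagonal; self-compliances add to the diagonal only.
        """
        c = np.zeros((self.n, self.n))
        for (i, j), value in zip(self._edge_idx, self.compliance_values(pressures)):
            if i == j:
                c[i, i] += value
            else:
                c[i, i] += value
                c[j, j] += value
                c[i, j] -= value
                c[j, i] -= value
        return c

    def assemble_fluidity_matrix(self) -> np.ndarray:
        """The constant fluidity matrix (symmetric, zero row sums)."""
        return self._z.copy()

    def forced_flows(
        self, t: float, pressures: np.ndarray, extra=None
    ) -> np.ndarray:
        """Per-compartment forced inflow vector F(t, P) (mL/min).

        Includes constant forced edges (CSF production), the Starling-Landis
        filtration, and any extra per-compartment flows (the beat-held
        cardiac output in dynamic mode).  ``extra`` may be a mapping
        ``{name: flow}`` or a callable ``(t, P) -> mapping`` for closures
        that respond to the instantaneous state.
        """
        if callable(extra):
            extra = extra(t, pressures)
        f = np.zeros(self.n)
        for i, j, q in self._forced_edges:
            f[i] -= q
            f[j] += q
        if self._starling_edge is not None:
            i, j = self._starling_edge
            q = starling_landis_flow(pressures[i], pressures[j], self.config.starling)
            f[i] -= q
            f[j] += q
        if extra:
            for name, q in extra.items():
                f[self._idx[name]] += q
        return f

    def net_inflow(
        self, t: float, pressures: np.ndarray, extra: Mapping[str, float] | None = None
    ) -> np.ndarray:
        """Net volumetric inflow Z P + F per compartment (mL/min)."""
        return self._z @ pressures + self.forced_flows(t, pressures, extra)

    # -- extended system ---------------------------------------------------
    def extended_system(
        self, t: float, x: np.ndarray, extra: Mapping[str, float] | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """Mass matrix M(X) and right-hand side G(X) of the extended system.

        Layout: pressure block (compliance matrix, with prescribed rows
        replaced by identity rows whose RHS is the profile derivative),
        compartment-volume block (identity mass, net-inflow RHS) and
        interface-volume block (identity mass coupled to ``-C_ij (ė_i-ė_j)``,
        zero RHS).
        """
        p = x[: self.n]
        c_vals = self.compliance_values(p)
        m = np.zeros((self.n_state, self.n_state))
        g = np.empty(self.n_state)

        # pressure block
        for (i, j), value in zip(self._edge_idx, c_vals):
            if i == j:
                m[i, i] += value
            else:
                m[i, i] += value
                m[j, j] += value
                m[i, j] -= value
                m[j, i] -= value
        inflow = self.net_inflow(t, p, extra)
        g[: self.n] = inflow
        for name, prescription in self.prescribed.items():
            i = self._idx[name]
            m[i, : self.n] = 0.0
            m[i, i] = 1.0
            g[i] = prescription.derivative(t)

        # compartment volumes integrate the net inflow; pressure-prescribed
        # compartments exchange volume with the unmodeled exterior (the
        # clamp replaces the circulation), so their bookkeeping is frozen
        vc = slice(self._off_vc, self._off_ve)
        m[vc, vc] = np.eye(self.n)
        g[self._off_vc : self._off_ve] = inflow
        for i in self._prescribed_idx:
            g[self._off_vc + i] = 0.0

        # interface volumes integrate C_ij d(P_i - P_j)/dt
        for k, ((i, j), value) in enumerate(zip(self._edge_idx, c_vals)):
            r = self._off_ve + k
            m[r, r] = 1.0
            m[r, i] -= value
            if i != j:
                m[r, j] += value
        g[self._off_ve :] = 0.0
        return m, g

    def reduced_rhs(
        self,
        t: float,
        z: np.ndarray,
        x0: np.ndarray,
        extra: Mapping[str, float] | None = None,
    ) -> np.ndarray:
        """dZ/dt of the tangent-space-reduced system at X = Q Z + X(0)."""
        q = self.constraints.Q
        x = x0 + q @ z
        m, g = self.extended_system(t, x, extra)
        m_hat = q.T @ m @ q
        g_hat = q.T @ g
        try:
            return np.linalg.solve(m_hat, g_hat)
        except np.linalg.LinAlgError as exc:
            raise IntegrationError(
                f"projected mass matrix singular at t={t:.4f} min"
            ) from exc

    def reduced_jacobian(
        self,
        t: float,
        z: np.ndarray,
        x0: np.ndarray,
        extra: Mapping[str, float] | None = None,
        eps: float = 1e-6,
    ) -> np.ndarray:
        """Finite-difference Jacobian of :meth:`reduced_rhs` in ``z``.

        Supplied to the implicit integrator with a perturbation scaled to the
        state's physical magnitudes (mmHg / mL): the reduced derivative
        carries an O(1e-10) roundoff floor from the projected linear solve,
        so letting the solver difference across machine-epsilon perturbations
        yields noise instead of a Jacobian.
        """
        f0 = self.reduced_rhs(t, z, x0, extra)
        jac = np.empty((len(z), len(z)))
        for k in range(len(z)):
            zp = z.copy()
            h = eps * max(1.0, abs(z[k]))
            zp[k] += h
            jac[:, k] = (self.reduced_rhs(t, zp, x0, extra) - f0) / h
        return jac

    def pressure_derivative(
        self, t: float, pressures: np.ndarray, extra: Mapping[str, float] | None = None
    ) -> np.ndarray:
        """dP/dt at given pressures (prescribed rows use profile derivatives)."""
        x = self.pack_state(
            ModelState(
                time=t,
                pressures=np.asarray(pressures, dtype=float),
                compartment_volumes=np.zeros(self.n),
                interface_volumes=np.zeros(self.n_e),
            )
        )
        dz = self.reduced_rhs(t, np.zeros(self.constraints.Q.shape[1]), x, extra)
        return (self.constraints.Q @ dz)[: self.n]

    # -- state packing -----------------------------------------------------
    def pack_state(self, state: ModelState) -> np.ndarray:
        x = np.empty(self.n_state)
        x[: self.n] = state.pressures
        x[self._off_vc : self._off_ve] = state.compartment_volumes
        x[self._off_ve :] = state.interface_volumes
        return x

    def unpack_state(self, t: float, x: np.ndarray, heart: HeartState | None = None) -> ModelState:
        return ModelState(
            time=t,
            pressures=x[: self.n].copy(),
            compartment_volumes=x[self._off_vc : self._off_ve].copy(),
            interface_volumes=x[self._off_ve :].copy(),
            heart=heart,
        )

    def baseline_state(self) -> ModelState:
        return ModelState(
            time=0.0,
            pressures=self.config.baseline_pressures(),
            compartment_volumes=np.zeros(self.n),
            interface_volumes=np.zeros(self.n_e),
        )

    def state_with_pressures(self, pressures: Mapping[str, float] | None = None) -> ModelState:
        state = self.baseline_state()
        if pressures:
            for name, value in pressures.items():
                state.pressures[self._idx[name]] = value
        return state

    # -- integration -------------------------------------------------------
    def integrate(
        self,
        initial: ModelState,
        t_span: tuple[float, float],
        t_eval: Sequence[float] | None = None,
        extra_forced: Mapping[str, float] | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-8,
        max_step: float = np.inf,
        method: str = "Radau",
        dense_output: bool = False,
        first_step: float | None = None,
    ):
        """Integrate the constrained system over ``t_span`` (minutes).

        Prescribed-pressure values at the initial time are imposed on the
        initial state before integration (they are boundary data, not state).
        Returns a :class:`Trajectory`; when ``dense_output`` is requested the
        scipy dense interpolant of the *reduced* coordinates is attached to
        ``trajectory.solver_stats['dense']`` along with the offset ``x0``.
        """
        t0, t1 = t_span
        x0 = self.pack_state(initial)
        for name, prescription in self.prescribed.items():
            x0[self._idx[name]] = prescription.value(t0)
        q = self.constraints.Q
        z0 = np.zeros(q.shape[1])
        if first_step is None:
            # skip scipy's finite-difference initial-step heuristic: near a
            # stationary point it differences the linear-solve roundoff floor
            # of the reduced derivative and collapses the step size
            first_step = max(min(0.2 * (t1 - t0), 1e-3), 1e-8)

        sol = solve_ivp(
            lambda t, z: self.reduced_rhs(t, z, x0, extra_forced),
            (t0, t1),
            z0,
            method=method,
            t_eval=None if t_eval is None else np.asarray(t_eval, dtype=float),
            rtol=rtol,
            atol=atol,
            max_step=max_step,
            dense_output=dense_output,
            first_step=first_step,
            jac=lambda t, z: self.reduced_jacobian(t, z, x0, extra_forced),
        )
        if not sol.success:
            last = self.unpack_state(sol.t[-1], x0 + q @ sol.y[:, -1], initial.heart)
            raise IntegrationError(
                f"integrator failed at t={sol.t[-1]:.5f} min: {sol.message}",
                last_state=last,
            )
        x_path = x0[:, None] + q @ sol.y
        residuals = (
            np.max(np.abs(self.constraints.A @ x_path - self.constraints.B[:, None]), axis=0)
            if self.constraints.A.shape[0]
            else np.zeros(x_path.shape[1])
        )
        traj = Trajectory(
            times=sol.t.copy(),
            pressures=x_path[: self.n].T.copy(),
            compartment_volumes=x_path[self._off_vc : self._off_ve].T.copy(),
            interface_volumes=x_path[self._off_ve :].T.copy(),
            names=self.names,
            interface_labels=self.interface_labels,
            constraint_residual=residuals,
            solver_stats={"nfev": sol.nfev, "njev": sol.njev, "segments": 1},
        )
        if dense_output:
            traj.solver_stats["dense"] = sol.sol
            traj.solver_stats["x0"] = x0
        return traj

    # -- steady state ------------------------------------------------------
    def find_steady_state(
        self,
        boundary_conditions: Mapping[str, float] | None = None,
        initial_guess: ModelState | None = None,
        extra_forced: Mapping[str, float] | None = None,
        method: str = "root",
        tol: float = STEADY_STATE_TOL,
        horizon: float = 120.0,
    ) -> ModelState:
        """Solve for the steady state under the given fixed boundary pressures.

        ``boundary_conditions`` override / extend the model's prescriptions
        with constant values.  ``method`` is ``"root"`` (damped root-finding
        on the net-inflow residual of the free compartments), ``"integrate"``
        (relax the dynamics until ``max |dP/dt| < tol``) or ``"both"``
        (root-find, then verify against integration within 1e-4 mmHg).
        """
        prescribed = dict(self.prescribed)
        if boundary_conditions:
            for name, value in boundary_conditions.items():
                prescribed[name] = ConstantPrescription(float(value))
            model = CompartmentalModel(self.config, prescribed, constrained=self.constrained)
        else:
            model = self

        guess = initial_guess if initial_guess is not None else model.baseline_state()
        x_guess = guess.pressures.copy()
        for name, prescription in prescribed.items():
            x_guess[model._idx[name]] = prescription.value(0.0)

        if method in ("root", "both"):
            free = [i for i in range(model.n) if i not in model._prescribed_idx]

            def residual(p_free: np.ndarray) -> np.ndarray:
                p = x_guess.copy()
                p[free] = p_free
                return model.net_inflow(0.0, p, extra_forced)[free]

            solution = root(residual, x_guess[free], method="hybr", tol=1e-12)
            p_root = x_guess.copy()
            p_root[free] = solution.x
            # hybr may report lack of *progress* at an already-converged
            # point; the physical criterion on dP/dt is what matters
            dpdt = model.pressure_derivative(0.0, p_root, extra_forced)
            if np.max(np.abs(dpdt)) > tol:
                raise SteadyStateError(
                    f"root-finding did not reach |dP/dt| < {tol:g} "
                    f"(residual {np.max(np.abs(dpdt)):.3g} mmHg/min)"
                )
            if method == "root":
                return ModelState(
                    time=0.0,
                    pressures=p_root,
                    compartment_volumes=np.zeros(model.n),
                    interface_volumes=np.zeros(model.n_e),
                )

        # integration-based relaxation
        state = ModelState(
            time=0.0,
            pressures=x_guess.copy(),
            compartment_volumes=np.zeros(model.n),
            interface_volumes=np.zeros(model.n_e),
        )
        chunk = 5.0
        t = 0.0
        while t < horizon:
            traj = model.integrate(state, (t, t + chunk), t_eval=[t, t + chunk],
                                   extra_forced=extra_forced)
            state = traj.final_state()
            t += chunk
            dpdt = model.pressure_derivative(t, state.pressures, extra_forced)
            if np.max(np.abs(dpdt)) < tol:
                if method == "both":
                    if np.max(np.abs(state.pressures - p_root)) > 1e-4:
                        raise SteadyStateError(
                            "root-finding and integration disagree by more than "
                            "1e-4 mmHg"
                        )
                    state.pressures = p_root
                state.time = 0.0
                state.compartment_volumes = np.zeros(model.n)
                state.interface_volumes = np.zeros(model.n_e)
                return state
        raise SteadyStateError(
            f"no steady state within {horizon:g} min "
            f"(residual {np.max(np.abs(dpdt)):.3g} mmHg/min)"
        )


# ---------------------------------------------------------------------------
# Functional wrappers over CompartmentalModel
# ---------------------------------------------------------------------------

def _model_for(config: NetworkConfig, prescribed=None, constrained=True) -> CompartmentalModel:
    return CompartmentalModel(config, prescribed=prescribed, constrained=constrained)


def assemble_fluidity_matrix(state: ModelState, config: NetworkConfig) -> np.ndarray:
    """Fluidity matrix Z such that ``(Z P)_i`` is the net resistive inflow."""
    return _model_for(config).assemble_fluidity_matrix()


def assemble_compliance_matrix(state: ModelState, config: NetworkConfig) -> np.ndarray:
    """Compliance matrix C evaluated at the state's pressures."""
    return _model_for(config).assemble_compliance_matrix(state.pressures)


def reduced_rhs(z, t, config, constraints=None, x0=None, prescribed=None, extra=None):
    """Reduced-state derivative of the projected system (functional form)."""
    model = _model_for(config, prescribed=prescribed)
    if x0 is None:
        x0 = model.pack_state(model.baseline_state())
    return model.reduced_rhs(t, z, x0, extra)


def integrate(initial: ModelState, t_span, config: NetworkConfig, prescribed=None,
              constrained: bool = True, **kwargs) -> Trajectory:
    """Integrate the constrained network from ``initial`` over ``t_span``."""
    return _model_for(config, prescribed, constrained).integrate(initial, t_span, **kwargs)


def find_steady_state(config: NetworkConfig, boundary_conditions=None, prescribed=None,
                      constrained: bool = True, **kwargs) -> ModelState:
    """Steady state of the network under fixed boundary pressures."""
    return _model_for(config, prescribed, constrained).find_steady_state(
        boundary_conditions=boundary_conditions, **kwargs
    )
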