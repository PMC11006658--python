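"""Network configuration: compartments, flows, compliances and calibration.

The packaged baseline (``data/baseline.yaml``) describes the supine human at
rest: 13 compartments with their steady-state pressures, the mean blood and
CSF flows between them, the compliant interfaces, and the cardiac/baroreflex
constants.  Calibration turns that declarative table into a simulatable
model:

1. :func:`derive_mean_flows` rebuilds an *exactly* volume-conservative set of
   mean flows.  Printed flow tables carry rounded entries (e.g. the
   blood-brain filtration is 0.12804 mL/min before rounding to 0.13), so
   rows marked ``conservation`` are re-derived from mass balance, the
   venous drainage split is kept in its printed ratios with the total fixed
   by conservation, and every printed number is validated against its
   derived value.
2. :func:`calibrate_fluidities` sets each resistive fluidity to
   ``Z = Q̄ / (P̄_src - P̄_dst)`` so the baseline pressures are a steady state;
   the Ventricular CSF - Brain edge instead uses the prescribed multiple of
   the blood-brain filtration coefficient (1000 * K_CB).
3. :func:`calibrate_peak_compliances` inverts the venous hyperbolic law at
   baseline transmural pressure so each venous interface reproduces its
   tabulated baseline compliance, and evaluates the cranial law for the
   brain/CSF interfaces.
4. :func:`calibrate_cardiac_tuning` fits the subject-specific output factor
   ``C`` so the virtual heart delivers the baseline cardiac output (the total
   arterial outflow) at baseline pressures and heart rate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping

import numpy as np
import yaml

from .cardiac import BaroreflexParams, CardiacParams, solve_heart_pressure
from .compliance import (
    CRANIAL_INTERFACE_SCALES,
    CranialComplianceParams,
    VenousComplianceParams,
    scaled_cranial_compliance,
)
from .errors import CalibrationError, ConfigurationError

log = logging.getLogger(__name__)

__all__ = [
    "CompartmentSpec",
    "FlowEdgeSpec",
    "ComplianceEdgeSpec",
    "StarlingParams",
    "VenousLawConstants",
    "NetworkConfig",
    "load_baseline_config",
    "config_from_document",
    "derive_mean_flows",
    "calibrate_fluidities",
    "calibrate_peak_compliances",
    "calibrate_cardiac_tuning",
    "calibrate",
    "calibration_report",
    "starling_mean_flow",
]

COMPARTMENT_LEVELS = ("head", "neck", "body", "thoracic", "boundary")
FLOW_KINDS = ("resistive", "starling", "forced_constant")
FLOW_PROVENANCES = ("literature", "conservation", "drainage_fraction")
COMPLIANCE_MODELS = ("constant", "cranial", "venous")

#: Printed mean flows may disagree with exact conservation by up to this much
#: (mL/min); the worst packaged deviation is ~0.13 on the extrajugular return.
FLOW_VALIDATION_TOL = 0.2

CENTRAL_ARTERIES = "Central Arteries"
CENTRAL_VEINS = "Central Veins"
THORACIC = "Thoracic"
VENTRICULAR_CSF = "Ventricular CSF"
SPINAL_CSF = "Spinal CSF"
CRANIAL_CSF = "Cranial CSF"
BRAIN = "Brain"
CAPILLARIES = "Capillaries"


@dataclass(frozen=True)
class CompartmentSpec:
    """A lumped fluid compartment with its steady-state baseline pressure."""

    name: str
    level: str
    baseline_pressure: float  # mmHg

    def __post_init__(self) -> None:
        if self.level not in COMPARTMENT_LEVELS:
            raise ConfigurationError(
                f"compartment {self.name!r}: unknown level {self.level!r}"
            )


@dataclass(frozen=True)
class StarlingParams:
    """Starling-Landis transcapillary filtration parameters."""

    k_cb: float = 0.066       # filtration coefficient, mL/min/mmHg
    sigma_cb: float = 1.0     # reflection coefficient
    pi_capillary: float = 21.5  # blood colloid osmotic pressure, mmHg
    pi_brain: float = 0.0     # interstitial osmotic pressure, mmHg


@dataclass(frozen=True)
class VenousLawConstants:
    """Shared constants of the venous hyperbolic compliance law."""

    n_ratio: float = 0.01
    alpha_neck: float = 0.40026          # 1/mmHg
    alpha_central_veins: float = 0.29352  # 1/mmHg
    peak_transmural: float = 4.0          # mmHg


@dataclass(frozen=True)
class FlowEdgeSpec:
    """A directed mean-flow path between two compartments.

    ``mean_flow`` is the printed table value; ``derived_mean_flow`` is the
    exactly conservative value set by :func:`derive_mean_flows` and is what
    calibration uses.  ``fluidity`` is populated by
    :func:`calibrate_fluidities` for resistive edges.
    """

    source: str
    dest: str
    mean_flow: float  # mL/min, printed
    kind: str = "resistive"
    provenance: str = "literature"
    fluidity_kcb_multiple: float | None = None
    derived_mean_flow: float | None = None
    fluidity: float | None = None  # mL/min/mmHg

    def __post_init__(self) -> None:
        if self.kind not in FLOW_KINDS:
            raise ConfigurationError(
                f"flow {self.source!r}->{self.dest!r}: unknown kind {self.kind!r}"
            )
        if self.provenance not in FLOW_PROVENANCES:
            raise ConfigurationError(
                f"flow {self.source!r}->{self.dest!r}: unknown provenance "
                f"{self.provenance!r}"
            )
        if self.mean_flow < 0:
            raise ConfigurationError(
                f"flow {self.source!r}->{self.dest!r}: mean flow must be "
                f"nonnegative in the source->dest direction"
            )

    @property
    def calibrated_mean_flow(self) -> float:
        return self.mean_flow if self.derived_mean_flow is None else self.derived_mean_flow


@dataclass(frozen=True)
class ComplianceEdgeSpec:
    """A symmetric compliant interface C_ab = C_ba between two compartments.

    ``a == b`` denotes a self-compliance (compartment to ambient).  For the
    ``venous`` model, ``transmural`` names the compartment whose transmural
    pressure drives the law; ``peak_compliance`` and ``alpha`` are set by
    :func:`calibrate_peak_compliances`.  For the ``cranial`` model,
    ``interface`` names the shared exponential-law interface and
    ``baseline_compliance`` is the law's own value at baseline.
    """

    a: str
    b: str
    model: str = "constant"
    baseline_compliance: float | None = None  # mL/mmHg
    reported_compliance: float | None = None  # printed table value, if distinct
    interface: str | None = None              # cranial edges
    scale_factor: float | None = None         # cranial edges, derived
    transmural: str | None = None             # venous edges
    alpha: float | None = None                # venous edges, derived
    peak_compliance: float | None = None      # venous edges, derived

    def __post_init__(self) -> None:
        if self.model not in COMPLIANCE_MODELS:
            raise ConfigurationError(
                f"compliance {self.a!r}-{self.b!r}: unknown model {self.model!r}"
            )
        if self.model == "cranial" and self.interface not in CRANIAL_INTERFACE_SCALES:
            raise ConfigurationError(
                f"compliance {self.a!r}-{self.b!r}: unknown cranial interface "
                f"{self.interface!r}"
            )
        if self.model == "venous" and self.transmural is None:
            raise ConfigurationError(
                f"compliance {self.a!r}-{self.b!r}: venous model requires a "
                f"'transmural' compartment"
            )
        if self.model != "cranial" and self.baseline_compliance is None:
            raise ConfigurationError(
                f"compliance {self.a!r}-{self.b!r}: baseline_compliance missing"
            )

    @property
    def pair(self) -> frozenset:
        return frozenset((self.a, self.b))

    @property
    def is_self(self) -> bool:
        return self.a == self.b


@dataclass(frozen=True)
class NetworkConfig:
    """Complete declarative model: compartments, edges, laws and constants."""

    compartments: tuple[CompartmentSpec, ...]
    flows: tuple[FlowEdgeSpec, ...]
    compliances: tuple[ComplianceEdgeSpec, ...]
    starling: StarlingParams
    cranial: CranialComplianceParams
    venous_constants: VenousLawConstants
    cardiac: CardiacParams
    baroreflex: BaroreflexParams
    monro_kellie: tuple[str, ...]
    transmantle_pressure: float = 0.2
    heart_arterial: str = CENTRAL_ARTERIES
    heart_venous: str = CENTRAL_VEINS
    raw_document: Mapping | None = field(default=None, compare=False, repr=False)

    # -- lookup helpers ---------------------------------------------------
    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.compartments)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise ConfigurationError(f"unknown compartment {name!r}") from None

    def compartment(self, name: str) -> CompartmentSpec:
        return self.compartments[self.index(name)]

    def baseline_pressures(self) -> np.ndarray:
        return np.array([c.baseline_pressure for c in self.compartments])

    def level_names(self, level: str) -> tuple[str, ...]:
        return tuple(c.name for c in self.compartments if c.level == level)

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    @property
    def is_calibrated(self) -> bool:
        resistive_done = all(
            e.fluidity is not None for e in self.flows if e.kind == "resistive"
        )
        venous_done = all(
            e.peak_compliance is not None
            for e in self.compliances
            if e.model == "venous"
        )
        return resistive_done and venous_done and self.cardiac.c_tuning is not None

    def venous_params_for(self, edge: ComplianceEdgeSpec) -> VenousComplianceParams:
        if edge.model != "venous" or edge.peak_compliance is None or edge.alpha is None:
            raise CalibrationError(
                f"compliance {edge.a!r}-{edge.b!r} has no calibrated venous law"
            )
        vc = self.venous_constants
        return VenousComplianceParams(
            c0_peak=edge.peak_compliance,
            alpha=edge.alpha,
            n_ratio=vc.n_ratio,
            peak_transmural=vc.peak_transmural,
        )


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _require(doc: Mapping, key: str, where: str) -> object:
    if key not in doc:
        raise ConfigurationError(f"missing {key!r} in {where}")
    return doc[key]


def config_from_document(doc: Mapping) -> NetworkConfig:
    """Build a :class:`NetworkConfig` from a parsed configuration document.

    Performs structural validation: unique compartment names, resolvable edge
    endpoints, and complete constant blocks.  Raises
    :class:`~cranioflow.errors.ConfigurationError` naming the offending token.
    """
    constants = _require(doc, "constants", "config")
    st = _require(constants, "starling", "constants")
    starling = StarlingParams(
        k_cb=float(_require(st, "k_cb", "starling")),
        sigma_cb=float(_require(st, "sigma_cb", "starling")),
        pi_capillary=float(_require(st, "pi_capillary", "starling")),
        pi_brain=float(_require(st, "pi_brain", "starling")),
    )
    cc = _require(constants, "cranial_compliance", "constants")
    cranial = CranialComplianceParams(
        c0=float(cc["c0"]), r=float(cc["r"]), gamma=float(cc["gamma"])
    )
    vc = _require(constants, "venous_compliance", "constants")
    venous_constants = VenousLawConstants(
        n_ratio=float(vc["n_ratio"]),
        alpha_neck=float(vc["alpha_neck"]),
        alpha_central_veins=float(vc["alpha_central_veins"]),
        peak_transmural=float(vc.get("peak_transmural", 4.0)),
    )
    ca = _require(constants, "cardiac", "constants")
    cardiac = CardiacParams(
        z_heart=float(ca["z_heart"]),
        s=float(ca["s"]),
        hr0=float(ca["hr0"]),
        sv=float(ca["sv"]),
        alpha_heart=float(ca["alpha_heart"]),
        beta=float(ca["beta"]),
        collapse_offset=float(ca.get("collapse_offset", 2.0)),
    )
    br = _require(constants, "baroreflex", "constants")

    compartments = tuple(
        CompartmentSpec(
            name=str(_require(c, "name", "compartment")),
            level=str(_require(c, "level", "compartment")),
            baseline_pressure=float(_require(c, "baseline_pressure", "compartment")),
        )
        for c in _require(doc, "compartments", "config")
    )
    names = [c.name for c in compartments]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ConfigurationError(f"duplicate compartment names: {dup}")
    name_set = set(names)

    baroreflex = BaroreflexParams(
        tau=float(br["tau_seconds"]) / 60.0,
        alpha_sigma=float(br["alpha_sigma"]),
        beta_sigma=float(br["beta_sigma"]),
        gamma_sigma=float(br["gamma_sigma"]),
        nu=float(br["nu"]),
        p0=compartments[names.index(CENTRAL_ARTERIES)].baseline_pressure
        if CENTRAL_ARTERIES in name_set
        else 92.0,
        hr0=float(ca["hr0"]),
    )

    def check_name(token: str, where: str) -> str:
        if token not in name_set:
            raise ConfigurationError(f"{where} references unknown compartment {token!r}")
        return token

    flows = tuple(
        FlowEdgeSpec(
            source=check_name(str(f["source"]), "flow edge"),
            dest=check_name(str(f["dest"]), "flow edge"),
            mean_flow=float(f["mean_flow"]),
            kind=str(f.get("kind", "resistive")),
            provenance=str(f.get("provenance", "literature")),
            fluidity_kcb_multiple=(
                float(f["fluidity_kcb_multiple"])
                if f.get("fluidity_kcb_multiple") is not None
                else None
            ),
        )
        for f in _require(doc, "flows", "config")
    )

    compliances = []
    seen_pairs: set[frozenset] = set()
    for c in _require(doc, "compliances", "config"):
        edge = ComplianceEdgeSpec(
            a=check_name(str(c["a"]), "compliance edge"),
            b=check_name(str(c["b"]), "compliance edge"),
            model=str(c.get("model", "constant")),
            baseline_compliance=(
                float(c["baseline_compliance"])
                if c.get("baseline_compliance") is not None
                else None
            ),
            reported_compliance=(
                float(c["reported_compliance"])
                if c.get("reported_compliance") is not None
                else None
            ),
            interface=c.get("interface"),
            transmural=(
                check_name(str(c["transmural"]), "compliance transmural")
                if c.get("transmural") is not None
                else None
            ),
        )
        if edge.pair in seen_pairs:
            raise ConfigurationError(
                f"duplicate compliance edge {edge.a!r}-{edge.b!r} "
                f"(C_ab = C_ba; specify each unordered pair once)"
            )
        seen_pairs.add(edge.pair)
        compliances.append(edge)

    monro_kellie = tuple(
        check_name(str(n), "monro_kellie list") for n in doc.get("monro_kellie", ())
    )

    return NetworkConfig(
        compartments=compartments,
        flows=flows,
        compliances=tuple(compliances),
        starling=starling,
        cranial=cranial,
        venous_constants=venous_constants,
        cardiac=cardiac,
        baroreflex=baroreflex,
        monro_kellie=monro_kellie,
        transmantle_pressure=float(constants.get("transmantle_pressure", 0.2)),
        raw_document=doc,
    )


def load_baseline_config(path=None) -> NetworkConfig:
    """Load the packaged baseline network (or a user YAML at ``path``).

    The returned configuration is uncalibrated; pass it through
    :func:`calibrate` before simulation.
    """
    if path is None:
        text = resources.files("cranioflow.data").joinpath("baseline.yaml").read_text()
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise ConfigurationError("configuration document is not a mapping")
    return config_from_document(doc)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def starling_mean_flow(config: NetworkConfig) -> float:
    """Exact Starling-Landis filtration at baseline pressures (mL/min)."""
    st = config.starling
    p_cap = config.compartment(CAPILLARIES).baseline_pressure
    p_brain = config.compartment(BRAIN).baseline_pressure
    return st.k_cb * ((p_cap - p_brain) - st.sigma_cb * (st.pi_capillary - st.pi_brain))


def _interior_names(config: NetworkConfig) -> list[str]:
    """Compartments with a closed mass balance at baseline (no heart/boundary)."""
    exclude = {config.heart_arterial, config.heart_venous}
    exclude.update(config.level_names("thoracic"))
    exclude.update(config.level_names("boundary"))
    return [n for n in config.names if n not in exclude]


def derive_mean_flows(config: NetworkConfig) -> NetworkConfig:
    """Rebuild an exactly volume-conservative mean-flow table.

    Literature rows are primary data (with the Starling edge evaluated
    exactly from its law); ``conservation`` rows and the shared total of each
    ``drainage_fraction`` group are solved from the interior mass balances.
    Every derived value is validated against its printed counterpart within
    ``FLOW_VALIDATION_TOL``.
    """
    interior = _interior_names(config)
    # unknown columns: one per conservation edge, one per drainage-fraction group
    cons_edges = [i for i, e in enumerate(config.flows) if e.provenance == "conservation"]
    frac_groups: dict[str, list[int]] = {}
    for i, e in enumerate(config.flows):
        if e.provenance == "drainage_fraction":
            frac_groups.setdefault(e.source, []).append(i)
    group_keys = sorted(frac_groups)
    n_unknown = len(cons_edges) + len(group_keys)
    col_of_edge = {ei: k for k, ei in enumerate(cons_edges)}
    col_of_group = {g: len(cons_edges) + k for k, g in enumerate(group_keys)}
    frac_of_edge: dict[int, float] = {}
    for g, idxs in frac_groups.items():
        total_printed = sum(config.flows[i].mean_flow for i in idxs)
        if total_printed <= 0:
            raise CalibrationError(
                f"drainage-fraction group from {g!r} has nonpositive printed total"
            )
        for i in idxs:
            frac_of_edge[i] = config.flows[i].mean_flow / total_printed

    known_flow: dict[int, float] = {}
    for i, e in enumerate(config.flows):
        if e.provenance == "literature":
            known_flow[i] = (
                starling_mean_flow(config) if e.kind == "starling" else e.mean_flow
            )

    a_mat = np.zeros((len(interior), n_unknown))
    b_vec = np.zeros(len(interior))
    for r, node in enumerate(interior):
        for i, e in enumerate(config.flows):
            sign = (1.0 if e.dest == node else 0.0) - (1.0 if e.source == node else 0.0)
            if sign == 0.0:
                continue
            if i in known_flow:
                b_vec[r] -= sign * known_flow[i]
            elif i in col_of_edge:
                a_mat[r, col_of_edge[i]] += sign
            else:
                a_mat[r, col_of_group[e.source]] += sign * frac_of_edge[i]

    x, *_ = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    residual = a_mat @ x - b_vec
    if np.max(np.abs(residual)) > 1e-8:
        raise CalibrationError(
            "mean-flow conservation system is inconsistent "
            f"(max residual {np.max(np.abs(residual)):.3g} mL/min)"
        )

    derived: dict[int, float] = dict(known_flow)
    for i in cons_edges:
        derived[i] = float(x[col_of_edge[i]])
    for g, idxs in frac_groups.items():
        for i in idxs:
            derived[i] = float(frac_of_edge[i] * x[col_of_group[g]])

    new_flows = []
    for i, e in enumerate(config.flows):
        q = derived[i]
        if q < -1e-9:
            raise CalibrationError(
                f"conservation yields negative flow {q:.4g} on "
                f"{e.source!r}->{e.dest!r}"
            )
        if abs(q - e.mean_flow) > FLOW_VALIDATION_TOL:
            raise CalibrationError(
                f"derived flow {q:.4f} on {e.source!r}->{e.dest!r} deviates from "
                f"printed value {e.mean_flow} by more than {FLOW_VALIDATION_TOL}"
            )
        if abs(q - e.mean_flow) > 5e-3:
            log.info(
                "flow %s->%s re-derived by conservation: %.5f (printed %.5g)",
                e.source, e.dest, q, e.mean_flow,
            )
        new_flows.append(replace(e, derived_mean_flow=max(q, 0.0)))
    return replace(config, flows=tuple(new_flows))


def calibrate_fluidities(config: NetworkConfig) -> NetworkConfig:
    """Set resistive fluidities ``Z = Q̄ / ΔP̄`` from the derived mean flows."""
    if any(e.derived_mean_flow is None for e in config.flows):
        config = derive_mean_flows(config)
    pressures = {c.name: c.baseline_pressure for c in config.compartments}
    new_flows = []
    for e in config.flows:
        if e.kind != "resistive":
            new_flows.append(e)
            continue
        if e.fluidity_kcb_multiple is not None:
            z = e.fluidity_kcb_multiple * config.starling.k_cb
        else:
            dp = pressures[e.source] - pressures[e.dest]
            if dp == 0.0:
                raise CalibrationError(
                    f"edge {e.source!r}->{e.dest!r}: zero baseline pressure "
                    f"difference with mean flow {e.calibrated_mean_flow:g} and no "
                    f"fluidity override"
                )
            z = e.calibrated_mean_flow / dp
        new_flows.append(replace(e, fluidity=z))
    return replace(config, flows=tuple(new_flows))


def _venous_alpha(config: NetworkConfig, transmural_name: str) -> float:
    level = config.compartment(transmural_name).level
    vc = config.venous_constants
    return vc.alpha_neck if level == "neck" else vc.alpha_central_veins


def _venous_baseline_transmural(config: NetworkConfig, transmural_name: str) -> float:
    """Baseline transmural pressure of a venous compartment.

    Neck-level compartments use the compartment pressure itself; the Central
    Veins (and any other non-neck venous compartment) are referenced to the
    thoracic pressure.
    """
    comp = config.compartment(transmural_name)
    if comp.level == "neck":
        return comp.baseline_pressure
    p_th = config.compartment(THORACIC).baseline_pressure
    return comp.baseline_pressure - p_th


def calibrate_peak_compliances(config: NetworkConfig) -> NetworkConfig:
    """Derive venous peak compliances and cranial baseline compliances.

    Venous edges: invert the hyperbolic law at the baseline transmural
    pressure so the edge reproduces its tabulated baseline compliance
    exactly.  Cranial edges: evaluate the exponential law (with the
    interface's volume prefactor) at baseline pressures; a printed
    ``reported_compliance`` that disagrees is logged, the law value wins.
    """
    vc = config.venous_constants
    pressures = {c.name: c.baseline_pressure for c in config.compartments}
    new_edges = []
    for e in config.compliances:
        if e.model == "venous":
            if e.baseline_compliance is None or e.baseline_compliance <= 0:
                raise CalibrationError(
                    f"compliance {e.a!r}-{e.b!r}: nonpositive baseline compliance"
                )
            alpha = _venous_alpha(config, e.transmural)
            p_trans = _venous_baseline_transmural(config, e.transmural)
            factor = vc.n_ratio + (1.0 - vc.n_ratio) / math.cosh(
                alpha * (p_trans - vc.peak_transmural)
            )
            new_edges.append(
                replace(e, alpha=alpha, peak_compliance=e.baseline_compliance / factor)
            )
        elif e.model == "cranial":
            scale = CRANIAL_INTERFACE_SCALES[e.interface]
            value = scaled_cranial_compliance(
                e.interface, pressures[e.a], pressures[e.b], config.cranial
            )
            if e.reported_compliance is not None and not math.isclose(
                value, e.reported_compliance, abs_tol=0.05
            ):
                log.warning(
                    "cranial compliance %s-%s: law gives %.5f at baseline but the "
                    "table prints %.5g; using the law value",
                    e.a, e.b, value, e.reported_compliance,
                )
            new_edges.append(replace(e, scale_factor=scale, baseline_compliance=value))
        else:
            new_edges.append(e)
    return replace(config, compliances=tuple(new_edges))


def baseline_cardiac_output(config: NetworkConfig) -> float:
    """Total baseline outflow of the arterial root compartment (mL/min)."""
    flows = config.flows
    if any(e.derived_mean_flow is None for e in flows):
        flows = derive_mean_flows(config).flows
    return sum(
        e.calibrated_mean_flow for e in flows if e.source == config.heart_arterial
    )


def calibrate_cardiac_tuning(config: NetworkConfig) -> CardiacParams:
    """Fit the subject-specific tuning factor ``C`` of the ejection curve.

    At baseline (baseline heart rate, thoracic and central-venous pressures)
    the solved heart balance must deliver the baseline cardiac output.  The
    venous-return curve fixes the balancing heart pressure
    ``P_heart = P_cv - CO / Z_heart``; ``C`` then follows in closed form from
    the ejection sigmoid and is verified by re-solving the balance.
    """
    co = baseline_cardiac_output(config)
    params = config.cardiac
    p_cv = config.compartment(config.heart_venous).baseline_pressure
    p_th = config.compartment(THORACIC).baseline_pressure
    p_collapse = p_th + params.collapse_offset
    if params.z_heart * (p_cv - p_collapse) < co:
        raise CalibrationError(
            "venous return cannot supply the baseline cardiac output "
            f"({co:g} mL/min) above the collapse pressure"
        )
    p_heart = p_cv - co / params.z_heart
    denominator = 1.0 + params.alpha_heart * math.exp(-params.beta * (p_heart - p_th))
    c = co * denominator / (params.s * params.hr0 * params.sv)
    if not (0.0 < c <= 100.0):
        raise CalibrationError(f"cardiac tuning factor {c:.4g} outside (0, 100]")
    tuned = replace(params, c_tuning=c)
    _, output = solve_heart_pressure(p_cv, p_th, params.hr0, tuned)
    if abs(output - co) > 1e-6 * co:
        raise CalibrationError(
            f"cardiac calibration failed to reproduce baseline output "
            f"({output:.6f} vs {co:.6f} mL/min)"
        )
    return tuned


def calibrate(config: NetworkConfig) -> NetworkConfig:
    """Full calibration pipeline (flows, fluidities, compliances, heart)."""
    config = derive_mean_flows(config)
    config = calibrate_fluidities(config)
    config = calibrate_peak_compliances(config)
    cardiac = calibrate_cardiac_tuning(config)
    return replace(config, cardiac=cardiac)


def calibration_report(config: NetworkConfig):
    """Tabular report of every derived quantity with its provenance rule.

    Returns a :class:`pandas.DataFrame` with one row per derived fluidity,
    peak compliance and the cardiac tuning factor.
    """
    import pandas as pd

    if not config.is_calibrated:
        config = calibrate(config)
    rows: list[dict] = []
    for e in config.flows:
        if e.kind != "resistive":
            continue
        rule = (
            "Z = multiple * K_CB"
            if e.fluidity_kcb_multiple is not None
            else "Z = mean_flow / (P_src - P_dst)"
        )
        rows.append(
            {
                "quantity": "fluidity",
                "edge": f"{e.source} -> {e.dest}",
                "value": e.fluidity,
                "units": "mL/min/mmHg",
                "rule": rule,
                "mean_flow": e.calibrated_mean_flow,
            }
        )
    for e in config.compliances:
        if e.model == "venous":
            rows.append(
                {
                    "quantity": "peak_compliance",
                    "edge": f"{e.a} - {e.b}",
                    "value": e.peak_compliance,
                    "units": "mL/mmHg",
                    "rule": "C0 = C_base / (N + (1-N)/cosh(alpha (P_trans - 4)))",
                    "mean_flow": np.nan,
                }
            )
        elif e.model == "cranial":
            rows.append(
                {
                    "quantity": "baseline_compliance",
                    "edge": f"{e.a} - {e.b}",
                    "value": e.baseline_compliance,
                    "units": "mL/mmHg",
                    "rule": "scale * C0 exp(-r |dP|^gamma)",
                    "mean_flow": np.nan,
                }
            )
    rows.append(
        {
            "quantity": "cardiac_tuning",
            "edge": "virtual heart",
            "value": config.cardiac.c_tuning,
            "units": "dimensionless",
            "rule": "F_out(P_heart; C) = F_in(P_heart) = baseline output",
            "mean_flow": baseline_cardiac_output(config),
        }
    )
    return pd.DataFrame(rows)
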