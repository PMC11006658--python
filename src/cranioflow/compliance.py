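"""Pressure-dependent compliance laws for craniospinal and venous interfaces.

Two nonlinear laws govern the deformable interfaces of the network:

* a **cranial** exponential law ``C(P_i, P_j) = C0 * exp(-r * |P_i - P_j|**gamma)``
  shared by the four brain/CSF/venous-sinus interfaces, portioned between them
  by fixed relative-volume prefactors, and
* a **venous** hyperbolic-secant law
  ``C(P_trans) = C0_peak * (N + (1 - N) / cosh(alpha * (P_trans - 4)))``
  for the collapsible neck and central veins, peaking at a transmural pressure
  of 4 mmHg and decaying to the asymptotic fraction ``N`` of the peak.

All compliances are strictly positive for finite pressures, which keeps the
assembled compliance matrix well posed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "CranialComplianceParams",
    "VenousComplianceParams",
    "CRANIAL_INTERFACE_SCALES",
    "cranial_compliance",
    "scaled_cranial_compliance",
    "venous_compliance",
]


@dataclass(frozen=True)
class CranialComplianceParams:
    """Parameters of the cranial exponential compliance law."""

    c0: float = 6.5333       # peak compliance, mL/mmHg
    r: float = 0.633431      # decay rate, mmHg^-gamma
    gamma: float = 0.604229  # pressure-difference exponent


@dataclass(frozen=True)
class VenousComplianceParams:
    """Parameters of the hyperbolic-secant venous compliance law."""

    c0_peak: float           # peak compliance, mL/mmHg
    alpha: float             # steepness, 1/mmHg
    n_ratio: float = 0.01    # asymptotic / peak compliance ratio
    peak_transmural: float = 4.0  # transmural pressure of the peak, mmHg


#: Relative-volume prefactors portioning the cranial compliance between the
#: four brain/CSF/venous interfaces.  The bulk (95%) of the CSF-side
#: compliance is assigned to the venous-sinus interface.
CRANIAL_INTERFACE_SCALES: dict[str, float] = {
    "brain_ventricular_csf": 0.05 * (23.0 / 140.0),
    "brain_venous_sinus": 1.0,
    "brain_cranial_csf": 0.05 * (87.0 / 140.0),
    "venous_sinus_cranial_csf": 0.95 * (87.0 / 140.0),
}


def cranial_compliance(
    p_i: float, p_j: float, params: CranialComplianceParams | None = None
) -> float:
    """Unscaled cranial compliance ``C0 * exp(-r |p_i - p_j|**gamma)``.

    Symmetric in its pressure arguments, maximal (``C0``) at zero pressure
    difference and strictly decreasing in ``|p_i - p_j|``.
    """
    if params is None:
        params = CranialComplianceParams()
    return params.c0 * math.exp(-params.r * abs(p_i - p_j) ** params.gamma)


def scaled_cranial_compliance(
    interface: str,
    p_i: float,
    p_j: float,
    params: CranialComplianceParams | None = None,
) -> float:
    """Cranial compliance of a named interface, including its volume prefactor.

    ``interface`` must be one of :data:`CRANIAL_INTERFACE_SCALES`.
    """
    try:
        scale = CRANIAL_INTERFACE_SCALES[interface]
    except KeyError:
        known = ", ".join(sorted(CRANIAL_INTERFACE_SCALES))
        raise ValueError(
            f"unknown cranial interface {interface!r}; expected one of: {known}"
        ) from None
    return scale * cranial_compliance(p_i, p_j, params)


def venous_compliance(p_trans: float, params: VenousComplianceParams) -> float:
    """Venous compliance at transmural pressure ``p_trans`` (mmHg).

    Even about ``peak_transmural`` (4 mmHg), equal to ``c0_peak`` there and
    decaying to ``n_ratio * c0_peak`` as ``|p_trans|`` grows.
    """
    sech = 1.0 / math.cosh(params.alpha * (p_trans - params.peak_transmural))
    return params.c0_peak * (params.n_ratio + (1.0 - params.n_ratio) * sech)
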