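"""Shared fixtures: the calibrated baseline network and small toy networks
built programmatically (no fixture files)."""

from __future__ import annotations

import numpy as np
import pytest

from cranioflow.cardiac import BaroreflexParams, CardiacParams
from cranioflow.compliance import CranialComplianceParams
from cranioflow.parameters import (
    CompartmentSpec,
    ComplianceEdgeSpec,
    FlowEdgeSpec,
    NetworkConfig,
    StarlingParams,
    VenousLawConstants,
    calibrate,
    load_baseline_config,
)


@pytest.fixture(scope="session")
def baseline_config():
    """The packaged 13-compartment network, fully calibrated."""
    return calibrate(load_baseline_config())


@pytest.fixture(scope="session")
def raw_config():
    """The packaged network before calibration."""
    return load_baseline_config()


def _toy_config(compartments, flows, compliances, monro_kellie=()):
    return NetworkConfig(
        compartments=tuple(compartments),
        flows=tuple(flows),
        compliances=tuple(compliances),
        starling=StarlingParams(),
        cranial=CranialComplianceParams(),
        venous_constants=VenousLawConstants(),
        cardiac=CardiacParams(c_tuning=1.0),
        baroreflex=BaroreflexParams(),
        monro_kellie=tuple(monro_kellie),
        heart_arterial="A",
        heart_venous="A",
    )


@pytest.fixture()
def toy2_config():
    """Two compartments, one resistive edge (Z=2), one pair compliance (C=3)
    and a self-compliance on the first compartment (C=1)."""
    compartments = [
        CompartmentSpec("A", "body", 10.0),
        CompartmentSpec("B", "body", 5.0),
    ]
    flows = [
        FlowEdgeSpec("A", "B", mean_flow=10.0, derived_mean_flow=10.0, fluidity=2.0),
    ]
    compliances = [
        ComplianceEdgeSpec("A", "B", model="constant", baseline_compliance=3.0),
        ComplianceEdgeSpec("A", "A", model="constant", baseline_compliance=1.0),
    ]
    return _toy_config(compartments, flows, compliances)


@pytest.fixture()
def toy3_config():
    """Three compartments with self-compliances only: a constant-coefficient
    linear system C dP/dt = Z P with diagonal C, solvable in closed form."""
    compartments = [
        CompartmentSpec("A", "body", 12.0),
        CompartmentSpec("B", "body", 8.0),
        CompartmentSpec("C", "body", 4.0),
    ]
    flows = [
        FlowEdgeSpec("A", "B", mean_flow=8.0, derived_mean_flow=8.0, fluidity=2.0),
        FlowEdgeSpec("B", "C", mean_flow=6.0, derived_mean_flow=6.0, fluidity=1.5),
        FlowEdgeSpec("A", "C", mean_flow=4.0, derived_mean_flow=4.0, fluidity=0.5),
    ]
    compliances = [
        ComplianceEdgeSpec("A", "A", model="constant", baseline_compliance=1.0),
        ComplianceEdgeSpec("B", "B", model="constant", baseline_compliance=2.0),
        ComplianceEdgeSpec("C", "C", model="constant", baseline_compliance=1.5),
    ]
    return _toy_config(compartments, flows, compliances)


@pytest.fixture()
def toy3_constrained_config():
    """The same 3-compartment network with a total-volume constraint row;
    the free dynamics already conserve total volume (no forced flows), so
    the constraint is inactive on the flow."""
    compartments = [
        CompartmentSpec("A", "head", 12.0),
        CompartmentSpec("B", "head", 8.0),
        CompartmentSpec("C", "head", 4.0),
    ]
    flows = [
        FlowEdgeSpec("A", "B", mean_flow=8.0, derived_mean_flow=8.0, fluidity=2.0),
        FlowEdgeSpec("B", "C", mean_flow=6.0, derived_mean_flow=6.0, fluidity=1.5),
        FlowEdgeSpec("A", "C", mean_flow=4.0, derived_mean_flow=4.0, fluidity=0.5),
    ]
    compliances = [
        ComplianceEdgeSpec("A", "A", model="constant", baseline_compliance=1.0),
        ComplianceEdgeSpec("B", "B", model="constant", baseline_compliance=2.0),
        ComplianceEdgeSpec("C", "C", model="constant", baseline_compliance=1.5),
    ]
    return _toy_config(compartments, flows, compliances, monro_kellie=("A", "B", "C"))


@pytest.fixture(scope="session")
def dynamic_result(baseline_config):
    """The dynamic MAP/CVP study, run once per session."""
    from cranioflow.experiments import run_dynamic_experiment

    return run_dynamic_experiment(baseline_config)
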