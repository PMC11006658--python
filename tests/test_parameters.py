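"""Configuration loading and derived-parameter calibration."""

import dataclasses
import math

import numpy as np
import pytest

from cranioflow.cardiac import solve_heart_pressure
from cranioflow.compliance import venous_compliance
from cranioflow.errors import CalibrationError, ConfigurationError
from cranioflow.network import CompartmentalModel, ConstantPrescription
from cranioflow.parameters import (
    calibrate,
    calibrate_cardiac_tuning,
    calibrate_fluidities,
    calibrate_peak_compliances,
    calibration_report,
    config_from_document,
    derive_mean_flows,
    load_baseline_config,
    starling_mean_flow,
)


def _flow(config, source, dest):
    for e in config.flows:
        if e.source == source and e.dest == dest:
            return e
    raise AssertionError(f"no edge {source}->{dest}")


def _compliance(config, a, b):
    for e in config.compliances:
        if {e.a, e.b} == {a, b} or (a == b and e.a == e.b == a):
            return e
    raise AssertionError(f"no compliance {a}-{b}")


class TestLoadBaseline:
    def test_all_thirteen_compartments_present(self, raw_config):
        assert len(raw_config.compartments) == 13
        expected = {
            "Central Arteries", "Intracranial Arteries", "Capillaries", "Brain",
            "Ventricular CSF", "Cranial CSF", "Venous Sinus", "Jugular",
            "Secondary Venous", "Extrajugular", "Spinal CSF", "Central Veins",
            "Thoracic",
        }
        assert set(raw_config.names) == expected

    @pytest.mark.parametrize(
        "name, pressure",
        [
            ("Central Veins", 5.0),
            ("Thoracic", -6.0),
            ("Cranial CSF", 11.1),
            ("Jugular", 5.683),
            ("Capillaries", 34.64),
        ],
    )
    def test_baseline_pressures(self, raw_config, name, pressure):
        assert raw_config.compartment(name).baseline_pressure == pressure

    def test_central_veins_thoracic_compliance(self, raw_config):
        edge = _compliance(raw_config, "Thoracic", "Central Veins")
        assert edge.baseline_compliance == 51.86
        assert edge.model == "venous"

    def test_transmantle_convention(self, raw_config):
        dv = raw_config.compartment("Ventricular CSF").baseline_pressure
        ds = raw_config.compartment("Spinal CSF").baseline_pressure
        assert dv - ds == pytest.approx(raw_config.transmantle_pressure, abs=1e-12)

    def test_missing_block_raises_named_error(self, raw_config):
        doc = {k: v for k, v in raw_config.raw_document.items() if k != "flows"}
        with pytest.raises(ConfigurationError, match="flows"):
            config_from_document(doc)

    def test_unknown_compartment_in_edge_names_token(self, raw_config):
        doc = dict(raw_config.raw_document)
        doc["flows"] = list(doc["flows"]) + [
            {"source": "Juglar", "dest": "Central Veins", "mean_flow": 1.0}
        ]
        with pytest.raises(ConfigurationError, match="Juglar"):
            config_from_document(doc)


class TestFlowDerivation:
    def test_starling_filtration_exact(self, raw_config):
        assert starling_mean_flow(raw_config) == pytest.approx(0.12804, abs=1e-12)

    def test_derived_flows_conserve_volume_everywhere(self, baseline_config):
        inflow = {name: 0.0 for name in baseline_config.names}
        for e in baseline_config.flows:
            inflow[e.source] -= e.derived_mean_flow
            inflow[e.dest] += e.derived_mean_flow
        for name, q in inflow.items():
            if name in ("Central Arteries", "Central Veins", "Thoracic"):
                continue
            assert abs(q) < 1e-9, f"{name}: {q}"
        # the heart closes the loop between the two central compartments
        assert inflow["Central Arteries"] == pytest.approx(-5300.0, abs=1e-9)
        assert inflow["Central Veins"] == pytest.approx(5300.0, abs=1e-9)

    def test_derived_flows_match_printed_table_at_its_precision(self, baseline_config):
        for e in baseline_config.flows:
            assert abs(e.derived_mean_flow - e.mean_flow) <= 0.2

    def test_incompatible_printed_flow_rejected(self, raw_config):
        bad_flows = tuple(
            dataclasses.replace(e, mean_flow=50.0)
            if (e.source, e.dest) == ("Cranial CSF", "Venous Sinus")
            else e
            for e in raw_config.flows
        )
        bad = dataclasses.replace(raw_config, flows=bad_flows)
        with pytest.raises(CalibrationError):
            derive_mean_flows(bad)


class TestFluidities:
    @pytest.mark.parametrize(
        "source, dest, expected, tol",
        [
            # mean flow / baseline pressure difference, by hand from the tables
            ("Ventricular CSF", "Cranial CSF", 3.0, 1e-9),
            ("Central Arteries", "Intracranial Arteries", 79.5, 1e-12),
            ("Central Arteries", "Central Veins", 4505.0 / 87.0, 1e-12),
            ("Jugular", "Central Veins", 893.8, 0.05),
        ],
    )
    def test_calibrated_values(self, baseline_config, source, dest, expected, tol):
        assert _flow(baseline_config, source, dest).fluidity == pytest.approx(
            expected, abs=tol
        )

    def test_ventricular_brain_override_is_thousand_k_cb(self, baseline_config):
        edge = _flow(baseline_config, "Ventricular CSF", "Brain")
        assert edge.fluidity == pytest.approx(1000 * 0.066, abs=1e-12)

    def test_fluidity_reproduces_mean_flow_at_baseline(self, baseline_config):
        p = {c.name: c.baseline_pressure for c in baseline_config.compartments}
        for e in baseline_config.flows:
            if e.kind != "resistive" or e.fluidity_kcb_multiple is not None:
                continue
            flow = e.fluidity * (p[e.source] - p[e.dest])
            assert flow == pytest.approx(e.derived_mean_flow, abs=1e-9)

    def test_zero_pressure_difference_without_override_rejected(self, raw_config):
        bad_flows = tuple(
            dataclasses.replace(e, fluidity_kcb_multiple=None)
            if (e.source, e.dest) == ("Ventricular CSF", "Brain")
            else e
            for e in raw_config.flows
        )
        bad = dataclasses.replace(raw_config, flows=bad_flows)
        with pytest.raises(CalibrationError, match="zero baseline pressure"):
            calibrate_fluidities(bad)


class TestPeakCompliances:
    def test_central_veins_round_trip(self, baseline_config):
        edge = _compliance(baseline_config, "Thoracic", "Central Veins")
        # transmural 5 - (-6) = 11 mmHg at baseline
        expected_peak = 51.86 / (0.01 + 0.99 / math.cosh(0.29352 * 7.0))
        assert edge.peak_compliance == pytest.approx(expected_peak, rel=1e-12)
        params = baseline_config.venous_params_for(edge)
        assert venous_compliance(11.0, params) == pytest.approx(51.86, abs=1e-9)

    def test_jugular_round_trip(self, baseline_config):
        edge = _compliance(baseline_config, "Jugular", "Jugular")
        expected_peak = 1.35 / (0.01 + 0.99 / math.cosh(0.40026 * 1.683))
        assert edge.peak_compliance == pytest.approx(expected_peak, rel=1e-12)
        params = baseline_config.venous_params_for(edge)
        assert venous_compliance(5.683, params) == pytest.approx(1.35, abs=1e-9)

    def test_peak_transmural_baseline_gives_peak_equal_to_baseline(self, raw_config):
        # a venous compartment whose baseline transmural pressure is exactly
        # the law's peak (4 mmHg) needs no amplification: cosh(0) = 1
        doc = {k: v for k, v in raw_config.raw_document.items()}
        import copy

        doc = copy.deepcopy(doc)
        for comp in doc["compartments"]:
            if comp["name"] == "Jugular":
                comp["baseline_pressure"] = 4.0
        cfg = calibrate_peak_compliances(config_from_document(doc))
        edge = _compliance(cfg, "Jugular", "Jugular")
        assert edge.peak_compliance == pytest.approx(1.35, abs=1e-12)

    def test_nonpositive_baseline_compliance_rejected(self, raw_config):
        bad_edges = tuple(
            dataclasses.replace(e, baseline_compliance=-1.0)
            if e.a == e.b == "Jugular"
            else e
            for e in raw_config.compliances
        )
        bad = dataclasses.replace(raw_config, compliances=bad_edges)
        with pytest.raises(CalibrationError, match="nonpositive"):
            calibrate_peak_compliances(bad)

    def test_every_pressure_dependent_law_returns_baseline_value(self, baseline_config):
        """Calibration round trip at baseline pressures, to 1e-9."""
        model = CompartmentalModel(
            baseline_config, prescribed={"Thoracic": ConstantPrescription(-6.0)}
        )
        values = model.compliance_values(baseline_config.baseline_pressures())
        for edge, value in zip(baseline_config.compliances, values):
            assert value == pytest.approx(edge.baseline_compliance, abs=1e-9), (
                edge.a, edge.b,
            )


class TestCardiacTuning:
    def test_baseline_output_reproduced(self, baseline_config):
        cardiac = baseline_config.cardiac
        assert cardiac.c_tuning is not None
        _, output = solve_heart_pressure(5.0, -6.0, 61.6, cardiac)
        assert output == pytest.approx(5300.0, rel=1e-9)

    def test_calibration_is_idempotent(self, baseline_config):
        again = calibrate_cardiac_tuning(baseline_config)
        assert again.c_tuning == pytest.approx(
            baseline_config.cardiac.c_tuning, rel=1e-12
        )
        p1, _ = solve_heart_pressure(5.0, -6.0, 61.6, baseline_config.cardiac)
        p2, _ = solve_heart_pressure(5.0, -6.0, 61.6, again)
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_numerator_scale_before_tuning(self, baseline_config):
        cardiac = baseline_config.cardiac
        assert cardiac.s * cardiac.hr0 * cardiac.sv == pytest.approx(4755.52)


def test_full_calibration_flags_config_as_calibrated(baseline_config):
    assert baseline_config.is_calibrated


def test_calibration_report_lists_every_derived_quantity(baseline_config):
    frame = calibration_report(baseline_config)
    resistive = sum(1 for e in baseline_config.flows if e.kind == "resistive")
    venous = sum(1 for e in baseline_config.compliances if e.model == "venous")
    cranial = sum(1 for e in baseline_config.compliances if e.model == "cranial")
    assert len(frame) == resistive + venous + cranial + 1
    assert (frame[frame.quantity == "cardiac_tuning"].value > 0).all()
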