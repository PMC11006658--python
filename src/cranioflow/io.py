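"""Configuration validation, result serialization and run metadata.

All numeric output is serialized at full precision (shortest round-trip
representation), so re-reading a written trajectory reproduces the computed
values exactly and runs can be regression-tested bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
import math
from importlib import metadata as _im
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigurationError
from .network import Trajectory
from .parameters import (
    NetworkConfig,
    calibrate,
    config_from_document,
    load_baseline_config,
)

log = logging.getLogger(__name__)

__all__ = [
    "RunMetadata",
    "validate_config",
    "config_digest",
    "write_trajectory",
    "read_trajectory",
    "write_summaries",
]


def _model_version() -> str:
    try:
        return _im.version("cranioflow")
    except _im.PackageNotFoundError:  # pragma: no cover - editable edge case
        return "0.0.0"


@dataclasses.dataclass(frozen=True)
class RunMetadata:
    """Sidecar describing a run well enough to reproduce it exactly."""

    config_digest: str
    solver_settings: dict
    experiment_kind: str
    model_version: str = dataclasses.field(default_factory=_model_version)
    timestamp: str = dataclasses.field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat()
    )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def config_digest(config: NetworkConfig) -> str:
    """SHA-256 digest of the configuration document, stable under key order."""
    doc = config.raw_document
    if doc is None:  # digest the parsed structure instead
        doc = {
            "compartments": [dataclasses.asdict(c) for c in config.compartments],
            "flows": [dataclasses.asdict(f) for f in config.flows],
            "compliances": [dataclasses.asdict(c) for c in config.compliances],
        }
    canonical = json.dumps(doc, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()


def validate_config(raw_document: Mapping | str | Path) -> NetworkConfig:
    """Parse, cross-check and calibrate a configuration document.

    Accepts a parsed mapping or a YAML path.  Structural problems (unknown
    compartments, duplicate edges, missing blocks) raise
    :class:`~cranioflow.errors.ConfigurationError`; values that deviate from
    the packaged baseline tables are reported as warnings but accepted.
    Returns the fully calibrated configuration (so calibration completeness
    is itself validated).
    """
    if isinstance(raw_document, (str, Path)):
        with open(raw_document, "r", encoding="utf-8") as fh:
            raw_document = yaml.safe_load(fh)
    if not isinstance(raw_document, Mapping):
        raise ConfigurationError("configuration document is not a mapping")
    config = config_from_document(raw_document)
    _warn_baseline_deviations(config)
    return calibrate(config)


def _warn_baseline_deviations(config: NetworkConfig) -> None:
    reference = load_baseline_config()
    ref_pressure = {c.name: c.baseline_pressure for c in reference.compartments}
    for c in config.compartments:
        ref = ref_pressure.get(c.name)
        if ref is not None and not math.isclose(c.baseline_pressure, ref, abs_tol=1e-9):
            log.warning(
                "compartment %r baseline pressure %g deviates from the packaged "
                "baseline value %g mmHg",
                c.name, c.baseline_pressure, ref,
            )
    ref_comp = {
        e.pair: (e.baseline_compliance, e.reported_compliance)
        for e in reference.compliances
    }
    for e in config.compliances:
        if e.baseline_compliance is None:
            continue
        ref = ref_comp.get(e.pair)
        if ref is None:
            continue
        ref_value = ref[0] if ref[0] is not None else ref[1]
        if ref_value is not None and not math.isclose(
            e.baseline_compliance, ref_value, abs_tol=1e-9
        ):
            log.warning(
                "compliance %r-%r value %g deviates from the packaged baseline "
                "value %g mL/mmHg",
                e.a, e.b, e.baseline_compliance, ref_value,
            )
    ref_flow = {(f.source, f.dest): f.mean_flow for f in reference.flows}
    for f in config.flows:
        ref = ref_flow.get((f.source, f.dest))
        if ref is not None and not math.isclose(f.mean_flow, ref, abs_tol=1e-9):
            log.warning(
                "flow %r->%r value %g deviates from the packaged baseline value "
                "%g mL/min",
                f.source, f.dest, f.mean_flow, ref,
            )


def write_trajectory(
    traj: Trajectory,
    path: str | Path,
    metadata: RunMetadata | None = None,
) -> dict[str, Path]:
    """Write a trajectory as wide CSV, long CSV and JSON metadata sidecar.

    ``path`` is the stem; ``<stem>_wide.csv``, ``<stem>_long.csv`` and
    ``<stem>_meta.json`` are produced.  Values round-trip exactly.
    """
    if len(traj) == 0:
        raise ValueError("refusing to write an empty trajectory")
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    wide_path = stem.with_name(stem.name + "_wide.csv")
    long_path = stem.with_name(stem.name + "_long.csv")
    meta_path = stem.with_name(stem.name + "_meta.json")
    wide = traj.to_wide_frame()
    # repr() of a float is its shortest exact round-trip representation
    wide.to_csv(wide_path, index=False, float_format=lambda v: repr(float(v)))
    traj.to_long_frame().to_csv(
        long_path, index=False, float_format=lambda v: repr(float(v))
    )
    written = {"wide": wide_path, "long": long_path}
    if metadata is not None:
        meta_path.write_text(metadata.to_json())
        written["metadata"] = meta_path
    return written


def read_trajectory(wide_csv: str | Path):
    """Read back a wide-format trajectory CSV as a DataFrame."""
    import pandas as pd

    return pd.read_csv(wide_csv)


def write_summaries(summaries, path: str | Path) -> Path:
    """Write experiment summaries (one row per run) as CSV."""
    import pandas as pd

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame([s.as_dict() for s in summaries])
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return path
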