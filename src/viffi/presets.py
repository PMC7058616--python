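"""Packaged instrument presets and JSON/YAML config loading."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from .instrument import InstrumentDesign, FlowCellGeometry
from .sensitivity import default_presets
from .simulate import SensorNoise, standard_modes

__all__ = ["load_reference_preset", "load_design", "load_config"]


def load_reference_preset() -> dict[str, Any]:
    """The demonstrated-instrument parameter set, wired across all modules.

    A 20x NA 0.75 objective (f_o = 9 mm) with a 180-mm tube lens, 0.2x
    relay onto a 28-facet polygon of 70-mm inner diameter at 45° incidence,
    16.6-mm sCMOS sensor (6.5-µm pixels, 88 lines, 572-MHz pixel rate,
    0.8-ms frame period → 1250 fps, 0.325-µm object-plane pixels), 1 m/s
    flow in a 400x250 µm chip at 1:700 focusing, a 26-µm excitation beam
    scanned at 2.54 m/s relative to the cells, and 0.3/340-µs short/long
    exposures.
    """
    return {
        "design": InstrumentDesign(),
        "flow_cell": FlowCellGeometry(),
        "modes": standard_modes(long_exposure_us=340.0, short_exposure_us=0.3),
        "modality_presets": default_presets(exposure_us=340.0),
        "noise": SensorNoise(),
    }


def _load_raw(path: str | Path) -> dict[str, Any]:
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return data


def load_design(path: str | Path) -> InstrumentDesign:
    """Load an :class:`InstrumentDesign` from a JSON or YAML file.

    Keys are exactly the dataclass field names; unknown keys are rejected.
    """
    data = _load_raw(path)
    known = set(InstrumentDesign.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown design keys: {sorted(unknown)}")
    return InstrumentDesign(**data)


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a free-form JSON/YAML config mapping (normalized to a dict)."""
    return _load_raw(path)
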