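"""File formats and bundled fixture models.

Models, initial states and protocols are stored as YAML (JSON also
parses, being a YAML subset); traces as CSV with columns ``time_s``,
``Em_mV`` and optional ``weight``.  The package ships a set of fixture
models — optimised generic cell models for rabbit sinoatrial-node and
atrial myocytes under several protocols and a drug-block condition —
listed in ``fixtures/manifest.yaml`` together with annotations for the
two ambiguously printed source values that were corrected on
transcription.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import numpy as np
import yaml

from .model import CellState, ModelParameters
from .protocols import StimulusProtocol, Trace

__all__ = [
    "load_model",
    "save_model",
    "load_state",
    "save_state",
    "load_protocol",
    "save_protocol",
    "load_trace",
    "save_trace",
    "fixture",
    "fixture_names",
    "minimal_cell",
    "la_uniform_run",
    "la_random_model",
    "drug_model",
    "tissue_model",
]


def _read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False, default_flow_style=None)


def load_model(path) -> ModelParameters:
    return ModelParameters.from_dict(_read_yaml(path))


def save_model(params: ModelParameters, path) -> None:
    _write_yaml(params.to_dict(), path)


def _state_from_dict(d: dict) -> CellState:
    return CellState(Em=float(d["Em"]), gates=np.asarray(d["gates"], dtype=float))


def load_state(path) -> CellState:
    return _state_from_dict(_read_yaml(path))


def save_state(state: CellState, path) -> None:
    _write_yaml({"Em": float(state.Em), "gates": [float(g) for g in state.gates]}, path)


def load_protocol(path) -> StimulusProtocol:
    return StimulusProtocol.from_dict(_read_yaml(path))


def save_protocol(protocol: StimulusProtocol, path) -> None:
    _write_yaml(protocol.to_dict(), path)


def load_trace(path) -> Trace:
    return Trace.from_csv(path)


def save_trace(trace: Trace, path) -> None:
    trace.to_csv(path)


# ---------------------------------------------------------------------------
# Bundled fixtures


def _fixture_path(name: str) -> Path:
    root = importlib.resources.files("ionfit") / "fixtures"
    p = Path(str(root / name))
    if not p.exists():
        raise FileNotFoundError(f"no fixture named {name!r}")
    return p


def fixture(name: str) -> dict:
    """Raw dictionary of a bundled fixture file (with or without .yaml)."""
    if not name.endswith(".yaml"):
        name += ".yaml"
    return _read_yaml(_fixture_path(name))


def fixture_names() -> list[str]:
    root = importlib.resources.files("ionfit") / "fixtures"
    return sorted(p.name for p in Path(str(root)).glob("*.yaml"))


def minimal_cell(cell: str) -> tuple[ModelParameters, CellState]:
    """Two-current model and initial state for 'cSAN', 'pSAN' or 'RA'."""
    cells = fixture("minimal_2current")["cells"]
    if cell not in cells:
        raise KeyError(f"unknown cell {cell!r}; have {sorted(cells)}")
    entry = cells[cell]
    return (
        ModelParameters.from_dict(entry["model"]),
        _state_from_dict(entry["initial_state"]),
    )


def la_uniform_run(
    run: str = "run1",
) -> tuple[ModelParameters, dict[str, CellState]]:
    """Five-current uniformly paced LA model; states keyed 'PI400'/'PI200'/'PI300'."""
    runs = fixture("la_uniform_5current")["runs"]
    if run not in runs:
        raise KeyError(f"unknown run {run!r}; have {sorted(runs)}")
    entry = runs[run]
    states = {k: _state_from_dict(v) for k, v in entry["initial_states"].items()}
    return ModelParameters.from_dict(entry["model"]), states


def la_random_model() -> tuple[ModelParameters, dict[str, CellState]]:
    """Seven-current LA model; states keyed 'PI400'/'PI200'/'random'."""
    entry = fixture("la_random_7current")
    states = {k: _state_from_dict(v) for k, v in entry["initial_states"].items()}
    return ModelParameters.from_dict(entry["model"]), states


def drug_model(condition: str = "control") -> tuple[ModelParameters, CellState]:
    """Four-current pSAN model under 'control' or 'e4031' (iKr block).

    The two conditions share every parameter except the i3 maximum
    conductance.
    """
    entry = fixture("psan_drug_4current")
    if condition not in entry["g3"]:
        raise KeyError(f"unknown condition {condition!r}; have {sorted(entry['g3'])}")
    params = ModelParameters.from_dict(entry["model"])
    g = [c.gmax for c in params.currents]
    g[2] = float(entry["g3"][condition])
    params = params.with_conductances(g)
    return params, _state_from_dict(entry["initial_states"][condition])


def tissue_model(cell: str = "cSAN") -> tuple[ModelParameters, CellState]:
    """Seven-current model with shared kinetics and cell-specific
    conductances for 'cSAN' or 'RA'."""
    entry = fixture("tissue_7current")
    if cell not in entry["conductances"]:
        raise KeyError(f"unknown cell {cell!r}; have {sorted(entry['conductances'])}")
    params = ModelParameters.from_dict(entry["model"])
    cond = entry["conductances"][cell]
    params = params.with_conductances(cond["g"], gL=float(cond["gL"]))
    return params, _state_from_dict(entry["initial_states"][cell])
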