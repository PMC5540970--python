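"""Parameter configs, packaged calibration fixtures, and fit-report serialization.

Parameter files are JSON or YAML documents keyed by the 14 snake_case
field names of :class:`~etsim.model.ModelParameters`.  Missing keys fall
back to the published defaults (with a logged notice); unknown keys are
rejected so typos cannot silently pass.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .calibrate import DoseRateTable, FitResult
from .errors import ConfigurationError
from .model import ModelParameters

__all__ = [
    "load_parameters",
    "save_parameters",
    "default_parameters_path",
    "activation_rate_table",
    "tnf_synthesis_rate_table",
    "write_fit_report",
]

log = logging.getLogger("etsim")

_DATA = resources.files("etsim") / "data"


def default_parameters_path() -> Path:
    """Path of the packaged default parameter file (the published values)."""
    return Path(str(_DATA / "default_parameters.json"))


def activation_rate_table() -> DoseRateTable:
    """Packaged empirical activation rates (per hour) vs priming LPS dose."""
    with (_DATA / "activation_rates_vs_lps.csv").open() as fh:
        return DoseRateTable.from_csv(fh)


def tnf_synthesis_rate_table() -> DoseRateTable:
    """Packaged estimated TNF synthesis rates (pg/h/monocyte) vs LPS dose."""
    with (_DATA / "tnf_synthesis_rates_vs_lps.csv").open() as fh:
        return DoseRateTable.from_csv(fh)


def load_parameters(path: Union[str, Path, None] = None) -> ModelParameters:
    """Load a parameter set from a JSON/YAML file.

    With no path, returns the packaged defaults.  Unknown keys raise
    :class:`~etsim.errors.ConfigurationError`; missing keys are filled
    from the defaults and logged.
    """
    if path is None:
        path = default_parameters_path()
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"parameter file not found: {path}")
    try:
        doc = yaml.safe_load(path.read_text())  # YAML is a JSON superset
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"could not parse {path}: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path} must contain a mapping of parameter names")
    known = set(ModelParameters.field_names())
    unknown = sorted(set(doc) - known)
    if unknown:
        raise ConfigurationError(f"unknown parameter key(s) in {path}: {', '.join(unknown)}")
    missing = sorted(known - set(doc))
    if missing:
        log.info("parameter file %s missing %d key(s) (%s); using defaults",
                 path, len(missing), ", ".join(missing))
    for k, v in doc.items():
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            raise ConfigurationError(f"parameter {k} in {path} must be a number, got {v!r}")
    return ModelParameters(**{k: float(v) for k, v in doc.items()})


def save_parameters(p: ModelParameters, path: Union[str, Path]) -> None:
    """Write a parameter set as pretty-printed JSON."""
    Path(path).write_text(json.dumps(p.to_dict(), indent=2, sort_keys=True) + "\n")


def write_fit_report(
    result: FitResult,
    path: Union[str, Path],
    *,
    parameters: Optional[ModelParameters] = None,
    seed: Optional[int] = None,
    extra: Optional[dict] = None,
) -> None:
    """Serialize a fit as a self-describing JSON report."""
    from . import __version__

    doc = result.to_dict()
    doc["etsim_version"] = __version__
    if parameters is not None:
        doc["parameters"] = parameters.to_dict()
    if seed is not None:
        doc["seed"] = int(seed)
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
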