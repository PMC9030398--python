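"""Serialization of solutions, instances and load-case configs.

Results are written as tidy tables (one row per muscle) in CSV or JSON with a
deterministic column order; floats are stored at full precision and rounded
only for display.  Load cases and generator configs are plain YAML/JSON
blocks with explicit unit suffixes (``force_N``, ``lever_arm_mm``).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .exceptions import ConfigError
from .solvers import ForceSolution
from .statics import JointInstance, LoadCase

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ("muscle", "force_N", "stress_N_mm2", "method", "objective", "residual")


def results_frame(solutions: Union[ForceSolution, Iterable[ForceSolution]]) -> pd.DataFrame:
    if isinstance(solutions, ForceSolution):
        solutions = [solutions]
    rows = [row for sol in solutions for row in sol.as_records()]
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(
    solutions: Union[ForceSolution, Iterable[ForceSolution]],
    path: Union[str, Path],
    fmt: Optional[str] = None,
) -> Path:
    """Write one or more solutions as a tidy CSV or JSON table."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "csv")
    df = results_frame(solutions)
    if df.empty:
        logger.warning("writing empty result table to %s", path)
    try:
        if fmt == "json":
            path.write_text(json.dumps(df.to_dict(orient="records"), indent=2))
        else:
            df.to_csv(path, index=False)
    except OSError as exc:
        raise ConfigError(f"cannot write results to {path}: {exc}") from exc
    return path


def read_results(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    if path.suffix == ".json":
        df = pd.DataFrame(json.loads(path.read_text()))
        if df.empty:
            df = pd.DataFrame(columns=list(RESULT_COLUMNS))
        return df[list(RESULT_COLUMNS)]
    return pd.read_csv(path)


def load_load_case(path: Union[str, Path]) -> LoadCase:
    """Read a load-case block (YAML or JSON): force_N, lever_arm_mm, direction."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"load-case file not found: {path}")
    data = yaml.safe_load(path.read_text())
    if not isinstance(data, dict):
        raise ConfigError(f"load-case file {path} must contain a mapping")
    try:
        return LoadCase(
            external_force=float(data["force_N"]),
            lever_arm=float(data["lever_arm_mm"]),
            direction=str(data.get("direction", "flexion")),
        )
    except KeyError as exc:
        raise ConfigError(f"load-case file {path} missing key {exc}") from exc


def write_instance(instance: JointInstance, path: Union[str, Path]) -> Path:
    path = Path(path)
    payload = {
        "names": list(instance.names),
        "pcsa_mm2": list(instance.pcsa),
        "arms_mm": list(instance.arms),
        "moment_N_mm": instance.moment,
        "direction": instance.direction,
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def read_instance(path: Union[str, Path]) -> JointInstance:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"instance file not found: {path}")
    data = json.loads(path.read_text())
    try:
        return JointInstance(
            names=tuple(data["names"]),
            pcsa=tuple(float(x) for x in data["pcsa_mm2"]),
            arms=tuple(float(x) for x in data["arms_mm"]),
            moment=float(data["moment_N_mm"]),
            direction=data.get("direction", "flexion"),
        )
    except KeyError as exc:
        raise ConfigError(f"instance file {path} missing key {exc}") from exc
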