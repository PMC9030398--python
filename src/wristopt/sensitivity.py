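"""Parameter sweeps over literature ranges: force and moment envelopes.

Every output quantity here is multilinear and non-decreasing in each of its
inputs — peak force PCSA*sigma, moment contribution PCSA*sigma*d — so the
envelope extremes over a box of ranges are attained at the corners.  The
analytic corner rule is the primary route; a full-factorial grid is kept both
for plotting and as the exhaustive cross-check used by the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .anatomy import MOTIONS, ParameterRanges
from .exceptions import ConfigError, InvalidParameterError

DEFAULT_GRID = 11


@dataclass
class SensitivityEnvelope:
    """Min/max of one output quantity over declared parameter ranges.

    ``grid`` (optional) holds the sampled values together with the parameter
    combination producing each, as a tidy DataFrame.
    """

    quantity: str  # "peak_force" | "muscle_moment" | "total_moment"
    key: str  # muscle name or motion direction
    min: float
    max: float
    units: str
    grid: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        if self.min > self.max:
            raise InvalidParameterError("envelope must satisfy min <= max")


def _axes(ranges_list: Sequence[tuple[float, float]], grid: int) -> list[np.ndarray]:
    return [np.linspace(lo, hi, grid) for lo, hi in ranges_list]


def sweep_peak_force(
    ranges: ParameterRanges, muscle: str, grid: int = DEFAULT_GRID
) -> SensitivityEnvelope:
    """Envelope of peak force PCSA*sigma for one muscle.

    Extremes are the corner products (both factors non-negative); the
    returned grid samples the full factorial PCSA x sigma lattice.
    """
    if muscle not in ranges.muscles:
        raise ConfigError(f"unknown muscle {muscle!r} in ranges")
    (p_lo, p_hi) = ranges.muscles[muscle].pcsa
    (t_lo, t_hi) = ranges.tension

    p_ax, t_ax = _axes([(p_lo, p_hi), (t_lo, t_hi)], grid)
    P, T = np.meshgrid(p_ax, t_ax, indexing="ij")
    df = pd.DataFrame(
        {
            "pcsa_mm2": P.ravel(),
            "tension_N_mm2": T.ravel(),
            "peak_force_N": (P * T).ravel(),
        }
    )
    return SensitivityEnvelope(
        quantity="peak_force",
        key=muscle,
        min=p_lo * t_lo,
        max=p_hi * t_hi,
        units="N",
        grid=df,
    )


def sweep_moment(
    ranges: ParameterRanges, direction: str, grid: int = DEFAULT_GRID
) -> dict[str, SensitivityEnvelope]:
    """Per-muscle and total moment envelopes PCSA*sigma*d for one direction.

    Returns a mapping muscle -> envelope plus a ``"total"`` entry whose
    extremes are the sums of the per-muscle extremes (each term attains its
    own extreme independently on the box).
    """
    if direction not in MOTIONS:
        raise InvalidParameterError(f"unknown motion direction {direction!r}")
    participants = ranges.muscles_for(direction)
    if not participants:
        raise ConfigError(f"no muscle has a moment-arm range for {direction!r}")

    t_lo, t_hi = ranges.tension
    out: dict[str, SensitivityEnvelope] = {}
    for muscle in participants:
        mr = ranges.muscles[muscle]
        p_lo, p_hi = mr.pcsa
        d_lo, d_hi = mr.arms[direction]
        p_ax, t_ax, d_ax = _axes([(p_lo, p_hi), (t_lo, t_hi), (d_lo, d_hi)], grid)
        P, T, D = np.meshgrid(p_ax, t_ax, d_ax, indexing="ij")
        df = pd.DataFrame(
            {
                "pcsa_mm2": P.ravel(),
                "tension_N_mm2": T.ravel(),
                "arm_mm": D.ravel(),
                "moment_N_mm": (P * T * D).ravel(),
            }
        )
        out[muscle] = SensitivityEnvelope(
            quantity="muscle_moment",
            key=muscle,
            min=p_lo * t_lo * d_lo,
            max=p_hi * t_hi * d_hi,
            units="N*mm",
            grid=df,
        )
    out["total"] = SensitivityEnvelope(
        quantity="total_moment",
        key=direction,
        min=sum(env.min for m, env in out.items() if m != "total"),
        max=sum(env.max for m, env in out.items() if m != "total"),
        units="N*mm",
    )
    return out


def _parameter_spec(
    ranges: ParameterRanges, direction: str, parameter: str
) -> tuple[str, Optional[str], tuple[float, float]]:
    """Resolve "MUSCLE.pcsa" / "MUSCLE.arm" / "tension" to (kind, muscle, range)."""
    if parameter == "tension":
        return "tension", None, ranges.tension
    try:
        muscle, kind = parameter.split(".")
    except ValueError:
        raise ConfigError(
            f"parameter {parameter!r} is not 'tension', 'MUSCLE.pcsa' or 'MUSCLE.arm'"
        ) from None
    if muscle not in ranges.muscles:
        raise ConfigError(f"unknown muscle {muscle!r}")
    mr = ranges.muscles[muscle]
    if kind == "pcsa":
        return "pcsa", muscle, mr.pcsa
    if kind == "arm":
        if direction not in mr.arms:
            raise ConfigError(f"{muscle} has no arm range for {direction!r}")
        return "arm", muscle, mr.arms[direction]
    raise ConfigError(f"unknown parameter kind {kind!r}")


def _total_moment(
    ranges: ParameterRanges,
    direction: str,
    values: dict[str, float],
    tension: float,
) -> float:
    total = 0.0
    for muscle in ranges.muscles_for(direction):
        total += values[f"{muscle}.pcsa"] * tension * values[f"{muscle}.arm"]
    return total


def one_at_a_time(
    ranges: ParameterRanges,
    direction: str,
    parameter: str,
    baseline: Union[str, dict] = "midpoint",
    grid: int = DEFAULT_GRID,
) -> SensitivityEnvelope:
    """Vary one parameter over its range with all others fixed at a baseline.

    ``parameter`` is ``"tension"``, ``"MUSCLE.pcsa"`` or ``"MUSCLE.arm"``
    (the arm for ``direction``).  ``baseline`` is ``"midpoint"`` or a mapping
    from parameter identifiers to values inside their ranges.  The output
    quantity is the total moment for ``direction``; the induced output range
    ranks the parameter's influence.
    """
    kind, _, (lo, hi) = _parameter_spec(ranges, direction, parameter)

    base: dict[str, float] = {}
    for muscle in ranges.muscles_for(direction):
        mr = ranges.muscles[muscle]
        base[f"{muscle}.pcsa"] = 0.5 * (mr.pcsa[0] + mr.pcsa[1])
        a_lo, a_hi = mr.arms[direction]
        base[f"{muscle}.arm"] = 0.5 * (a_lo + a_hi)
    base_tension = 0.5 * (ranges.tension[0] + ranges.tension[1])
    if isinstance(baseline, dict):
        for key, value in baseline.items():
            k, _, (b_lo, b_hi) = _parameter_spec(ranges, direction, key)
            if not (b_lo <= value <= b_hi):
                raise InvalidParameterError(
                    f"baseline for {key!r} outside its range [{b_lo}, {b_hi}]"
                )
            if k == "tension":
                base_tension = value
            else:
                base[key] = value
    elif baseline != "midpoint":
        raise ConfigError(f"unknown baseline {baseline!r}")

    samples = np.linspace(lo, hi, grid)
    outputs = []
    for v in samples:
        values = dict(base)
        tension = base_tension
        if kind == "tension":
            tension = v
        else:
            values[parameter] = v
        outputs.append(_total_moment(ranges, direction, values, tension))
    outputs = np.asarray(outputs)
    df = pd.DataFrame({parameter: samples, "total_moment_N_mm": outputs})
    return SensitivityEnvelope(
        quantity="total_moment",
        key=f"{direction}:{parameter}",
        min=float(outputs.min()),
        max=float(outputs.max()),
        units="N*mm",
        grid=df,
    )


def rank_parameters(
    ranges: ParameterRanges,
    direction: str,
    baseline: Union[str, dict] = "midpoint",
    grid: int = DEFAULT_GRID,
) -> pd.DataFrame:
    """One-at-a-time influence ranking for every parameter of a direction.

    Returns a DataFrame (parameter, output_min, output_max, span) sorted by
    descending span — the parameters whose literature uncertainty moves the
    total moment the most come first.  Deterministic for a fixed grid.
    """
    params = ["tension"]
    for muscle in ranges.muscles_for(direction):
        params += [f"{muscle}.pcsa", f"{muscle}.arm"]
    rows = []
    for p in params:
        env = one_at_a_time(ranges, direction, p, baseline=baseline, grid=grid)
        rows.append(
            {
                "parameter": p,
                "output_min": env.min,
                "output_max": env.max,
                "span": env.max - env.min,
            }
        )
    df = pd.DataFrame(rows).sort_values(
        ["span", "parameter"], ascending=[False, True], kind="mergesort"
    )
    return df.reset_index(drop=True)


def envelopes_frame(envelopes: dict[str, SensitivityEnvelope]) -> pd.DataFrame:
    """Tidy (muscle, quantity, min, max, units) table from a sweep result."""
    return pd.DataFrame(
        [
            {
                "muscle": key,
                "quantity": env.quantity,
                "min": env.min,
                "max": env.max,
                "units": env.units,
            }
            for key, env in envelopes.items()
        ]
    )
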