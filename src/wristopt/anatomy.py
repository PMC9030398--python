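"""Muscle anatomical parameters of the wrist and the PCSA / peak-force formulas.

The six primary wrist movers (FCR, PL, FCU, ECU, ECRB, ECRL) are described by
anatomical records compiled from the cadaver and imaging literature: muscle
mass, optimum fiber length, pennation angle, physiological cross-sectional
area (PCSA) and per-motion moment arms.  Two formulas connect them:

* PCSA of a parallel-fibered muscle: ``mass / (density * fiber_length)``;
  for pennate muscles the mass is projected onto the line of action with
  ``cos(pennation)``.
* Peak force: ``PCSA * sigma`` where ``sigma`` is the specific tension,
  reported between 0.2 and 1.0 N/mm^2 under isometric conditions.

Canonical internal units are N, mm, N*mm and degrees.  Literature tables that
print centimeters or N*cm are converted at the I/O boundary (1 cm = 10 mm,
1 N*m = 100 N*cm = 1000 N*mm).

Literature tables frequently print ``0.00`` for quantities that were simply
not reported; those cells are loaded as *missing*, never as literal zeros,
so they cannot corrupt downstream statistics.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import ConfigError, InvalidParameterError, TableSchemaError

logger = logging.getLogger(__name__)

#: Motion directions of the planar single-DOF wrist model.
MOTIONS = ("flexion", "extension", "radial_dev", "ulnar_dev")

#: Canonical six wrist movers.
WRIST_MUSCLES = ("FCR", "PL", "FCU", "ECU", "ECRB", "ECRL")

#: Default muscle density, g/mm^3.
MUSCLE_DENSITY = 0.0010567

#: Reported isometric specific-tension range, N/mm^2.
SPECIFIC_TENSION_RANGE = (0.2, 1.0)

_ARM_COLUMNS = {
    "flexion": "arm_flex_mm",
    "extension": "arm_ext_mm",
    "radial_dev": "arm_rd_mm",
    "ulnar_dev": "arm_ud_mm",
}

_TABLE_COLUMNS = (
    "muscle",
    "source",
    "mass_g",
    "fiber_length_mm",
    "tendon_length_mm",
    "pennation_deg",
    "volume_cm3",
    "pcsa_mm2",
    "arm_flex_mm",
    "arm_ext_mm",
    "arm_rd_mm",
    "arm_ud_mm",
)

#: Packaged fixture tables (see ``data/``).
FIXTURES = {
    "wrist_anatomy": "anatomy_literature.csv",
    "an1981_pcsa": "an1981_pcsa.csv",
    "lemay1996_arms": "lemay1996_arms.csv",
    "worked_extension": "worked_extension.csv",
}


@dataclass(frozen=True)
class PhysicalConstants:
    """Physical constants of the muscle model.

    Parameters
    ----------
    muscle_density
        Muscle tissue density in g/mm^3.
    specific_tension_range
        Admissible (min, max) specific tension in N/mm^2.
    """

    muscle_density: float = MUSCLE_DENSITY
    specific_tension_range: tuple[float, float] = SPECIFIC_TENSION_RANGE

    def __post_init__(self) -> None:
        if self.muscle_density <= 0:
            raise InvalidParameterError("muscle density must be positive")
        lo, hi = self.specific_tension_range
        if not (0 < lo <= hi):
            raise InvalidParameterError(
                "specific tension range must satisfy 0 < min <= max"
            )


@dataclass
class MuscleParameters:
    """One muscle's anatomical record from a single literature source.

    Missing quantities are ``None`` — a literature table printing 0.00 means
    "not reported", and loaders translate those cells accordingly.  PCSA may
    be either reported directly (``pcsa``) or computed from mass and fiber
    length; ``pcsa_provenance`` records which, so the two are never silently
    mixed.

    Attributes
    ----------
    name : str
        Muscle identifier (FCR, PL, FCU, ECU, ECRB, ECRL, or free text).
    mass : float or None
        Muscle mass, g.
    fiber_length : float or None
        Optimum fiber length, mm.
    tendon_length : float or None
        Tendon length, mm.
    pennation_angle : float or None
        Pennation angle, degrees in [0, 90).
    volume : float or None
        Muscle volume, cm^3.
    pcsa : float or None
        Physiological cross-sectional area, mm^2.
    moment_arm : dict
        Non-negative moment arm (mm) per motion direction; absent
        directions are simply not present in the mapping.
    source : str
        Literature tag the record came from.
    """

    name: str
    mass: Optional[float] = None
    fiber_length: Optional[float] = None
    tendon_length: Optional[float] = None
    pennation_angle: Optional[float] = None
    volume: Optional[float] = None
    pcsa: Optional[float] = None
    moment_arm: dict[str, float] = field(default_factory=dict)
    source: str = ""
    pcsa_provenance: str = "reported"  # "reported" | "computed"

    def __post_init__(self) -> None:
        if self.mass is not None and self.mass < 0:
            raise InvalidParameterError(f"{self.name}: mass must be >= 0")
        if self.fiber_length is not None and self.fiber_length <= 0:
            raise InvalidParameterError(f"{self.name}: fiber length must be > 0")
        if self.pennation_angle is not None and not (0 <= self.pennation_angle < 90):
            raise InvalidParameterError(
                f"{self.name}: pennation angle must lie in [0, 90) degrees"
            )
        if self.pcsa is not None and self.pcsa < 0:
            raise InvalidParameterError(f"{self.name}: PCSA must be >= 0")
        for motion, arm in self.moment_arm.items():
            if motion not in MOTIONS:
                raise InvalidParameterError(
                    f"{self.name}: unknown motion direction {motion!r}"
                )
            if arm < 0:
                raise InvalidParameterError(
                    f"{self.name}: moment arm for {motion} must be >= 0"
                )

    def computed_pcsa(self, constants: PhysicalConstants = PhysicalConstants()) -> float:
        """PCSA from mass and fiber length (pennation defaults to 0 if absent)."""
        if self.mass is None or self.fiber_length is None:
            raise InvalidParameterError(
                f"{self.name}: mass and fiber length required to compute PCSA"
            )
        theta = self.pennation_angle if self.pennation_angle is not None else 0.0
        return compute_pcsa_pennate(
            self.mass, theta, self.fiber_length, constants.muscle_density
        )

    def with_computed_pcsa(
        self, constants: PhysicalConstants = PhysicalConstants()
    ) -> "MuscleParameters":
        """Copy of this record with PCSA recomputed from mass/fiber length."""
        return replace(
            self, pcsa=self.computed_pcsa(constants), pcsa_provenance="computed"
        )


def compute_pcsa_parallel(
    mass: float, fiber_length: float, density: float = MUSCLE_DENSITY
) -> float:
    """PCSA (mm^2) of a parallel-fibered muscle.

    Parameters
    ----------
    mass : float
        Muscle mass, g.
    fiber_length : float
        Optimum fiber length, mm.
    density : float
        Muscle density, g/mm^3.
    """
    if mass < 0:
        raise InvalidParameterError("mass must be >= 0")
    if fiber_length <= 0:
        raise InvalidParameterError("fiber length must be > 0")
    if density <= 0:
        raise InvalidParameterError("density must be > 0")
    return mass / (density * fiber_length)


def compute_pcsa_pennate(
    mass: float,
    pennation: float,
    fiber_length: float,
    density: float = MUSCLE_DENSITY,
) -> float:
    """PCSA (mm^2) of a pennate muscle; ``pennation`` in degrees, [0, 90).

    Reduces exactly to :func:`compute_pcsa_parallel` at zero pennation.
    """
    if not (0 <= pennation < 90):
        raise InvalidParameterError("pennation angle must lie in [0, 90) degrees")
    return compute_pcsa_parallel(mass, fiber_length, density) * math.cos(
        math.radians(pennation)
    )


def compute_peak_force(
    pcsa: float,
    sigma: float,
    admissible_range: tuple[float, float] = SPECIFIC_TENSION_RANGE,
) -> float:
    """Peak muscle force (N) as PCSA (mm^2) times specific tension (N/mm^2).

    A specific tension outside ``admissible_range`` is allowed but triggers a
    warning, since reported isometric values fall within 0.2-1.0 N/mm^2.
    """
    if pcsa < 0:
        raise InvalidParameterError("PCSA must be >= 0")
    if sigma < 0:
        raise InvalidParameterError("specific tension must be >= 0")
    lo, hi = admissible_range
    if not (lo <= sigma <= hi):
        warnings.warn(
            f"specific tension {sigma} N/mm^2 outside reported range [{lo}, {hi}]",
            stacklevel=2,
        )
    return pcsa * sigma


def _fixture_path(name: str):
    return resources.files("wristopt.data") / FIXTURES[name]


def _float_or_none(value, *, zero_is_missing: bool) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    x = float(value)
    if zero_is_missing and x == 0.0:
        return None
    return x


def load_muscle_table(
    source: Union[str, Path],
    *,
    zero_is_missing: bool = True,
) -> list[MuscleParameters]:
    """Load anatomical records from a CSV/JSON file or a packaged fixture id.

    ``source`` is either one of the fixture ids in :data:`FIXTURES`
    (``"wrist_anatomy"``, ``"an1981_pcsa"``, ``"lemay1996_arms"``) or a path
    to a table with the documented column header.  Zero-valued anatomical
    cells are loaded as missing by default (literature convention for "not
    reported"); moment arms are kept verbatim, since a zero arm is physically
    meaningful.
    """
    if isinstance(source, str) and source in FIXTURES:
        path = _fixture_path(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"muscle table not found: {path}")

    try:
        if str(path).endswith(".json"):
            df = pd.read_json(str(path))
        else:
            df = pd.read_csv(str(path))
    except (ValueError, OSError) as exc:
        raise TableSchemaError(f"cannot parse muscle table {path}: {exc}") from exc

    if df.empty:
        logger.warning("muscle table %s is empty", path)
        return []

    missing_cols = {"muscle"} - set(df.columns)
    if missing_cols:
        raise TableSchemaError(
            f"muscle table {path} lacks required column(s)",
            column=sorted(missing_cols),
        )
    for col in df.columns:
        if col not in _TABLE_COLUMNS:
            raise TableSchemaError(f"unknown column in muscle table {path}", column=col)

    records: list[MuscleParameters] = []
    for idx, row in df.iterrows():
        def cell(col: str, *, zero_missing: bool = zero_is_missing):
            if col not in df.columns:
                return None
            try:
                return _float_or_none(row[col], zero_is_missing=zero_missing)
            except (TypeError, ValueError) as exc:
                raise TableSchemaError(
                    f"non-numeric cell in muscle table {path}", row=idx, column=col
                ) from exc

        arms = {}
        for motion, col in _ARM_COLUMNS.items():
            arm = cell(col, zero_missing=False)
            if arm is not None:
                arms[motion] = arm
        try:
            records.append(
                MuscleParameters(
                    name=str(row["muscle"]),
                    mass=cell("mass_g"),
                    fiber_length=cell("fiber_length_mm"),
                    tendon_length=cell("tendon_length_mm"),
                    pennation_angle=cell("pennation_deg"),
                    volume=cell("volume_cm3"),
                    pcsa=cell("pcsa_mm2"),
                    moment_arm=arms,
                    source=str(row["source"]) if "source" in df.columns else "",
                )
            )
        except InvalidParameterError as exc:
            raise TableSchemaError(str(exc), row=idx) from exc
    return records


def write_muscle_table(
    records: Iterable[MuscleParameters],
    path: Union[str, Path],
    fmt: Optional[str] = None,
) -> Path:
    """Write anatomical records to CSV or JSON (inferred from suffix).

    Round-trips with :func:`load_muscle_table`: missing values become empty
    cells, and moment arms map onto the per-motion arm columns.
    """
    path = Path(path)
    fmt = fmt or ("json" if path.suffix == ".json" else "csv")
    rows = []
    for rec in records:
        row = {
            "muscle": rec.name,
            "source": rec.source,
            "mass_g": rec.mass,
            "fiber_length_mm": rec.fiber_length,
            "tendon_length_mm": rec.tendon_length,
            "pennation_deg": rec.pennation_angle,
            "volume_cm3": rec.volume,
            "pcsa_mm2": rec.pcsa,
        }
        for motion, col in _ARM_COLUMNS.items():
            row[col] = rec.moment_arm.get(motion)
        rows.append(row)
    df = pd.DataFrame(rows, columns=list(_TABLE_COLUMNS))
    if fmt == "json":
        df.to_json(str(path), orient="records", indent=2)
    else:
        df.to_csv(str(path), index=False)
    return path


@dataclass(frozen=True)
class MuscleRanges:
    """Min/max bounds for one muscle: PCSA and per-motion moment arms."""

    pcsa: tuple[float, float]
    arms: Mapping[str, tuple[float, float]]  # only motions the muscle serves

    def __post_init__(self) -> None:
        if self.pcsa[0] > self.pcsa[1]:
            raise InvalidParameterError("PCSA range must satisfy min <= max")
        for motion, (lo, hi) in self.arms.items():
            if motion not in MOTIONS:
                raise InvalidParameterError(f"unknown motion {motion!r}")
            if lo > hi:
                raise InvalidParameterError(
                    f"moment arm range for {motion} must satisfy min <= max"
                )


@dataclass(frozen=True)
class ParameterRanges:
    """Literature min/max bounds per muscle plus the shared tension range.

    Motions absent for a muscle (unavailable in the source table) are absent
    from its ``arms`` mapping — never silently zero-filled.
    """

    muscles: Mapping[str, MuscleRanges]
    tension: tuple[float, float] = SPECIFIC_TENSION_RANGE

    def __post_init__(self) -> None:
        lo, hi = self.tension
        if lo > hi:
            raise InvalidParameterError("tension range must satisfy min <= max")

    def muscles_for(self, direction: str) -> list[str]:
        """Muscles with a defined moment-arm range for ``direction``."""
        if direction not in MOTIONS:
            raise InvalidParameterError(f"unknown motion direction {direction!r}")
        return [m for m, r in self.muscles.items() if direction in r.arms]


def load_parameter_ranges(source: Union[str, Path, None] = None) -> ParameterRanges:
    """Load sensitivity bounds from CSV; default is the packaged table.

    Empty arm cells mark motions the muscle does not serve.  The specific
    tension range is shared across muscles; inconsistent per-row values are
    rejected.
    """
    if source is None:
        path = resources.files("wristopt.data") / "sensitivity_ranges.csv"
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"ranges table not found: {path}")
    df = pd.read_csv(str(path))
    if "muscle" not in df.columns:
        raise TableSchemaError(f"ranges table {path} lacks 'muscle' column")

    muscles: dict[str, MuscleRanges] = {}
    tensions = set()
    for idx, row in df.iterrows():
        arms = {}
        for motion, base in (
            ("flexion", "arm_flex"),
            ("extension", "arm_ext"),
            ("radial_dev", "arm_rd"),
            ("ulnar_dev", "arm_ud"),
        ):
            lo = _float_or_none(row.get(f"{base}_min"), zero_is_missing=False)
            hi = _float_or_none(row.get(f"{base}_max"), zero_is_missing=False)
            if (lo is None) != (hi is None):
                raise TableSchemaError(
                    "arm range must define both min and max", row=idx, column=base
                )
            if lo is not None:
                arms[motion] = (lo, hi)
        try:
            muscles[str(row["muscle"])] = MuscleRanges(
                pcsa=(float(row["pcsa_min"]), float(row["pcsa_max"])), arms=arms
            )
        except (KeyError, ValueError) as exc:
            raise TableSchemaError(
                f"bad PCSA range in {path}", row=idx, column="pcsa"
            ) from exc
        if "tension_min" in df.columns:
            tensions.add((float(row["tension_min"]), float(row["tension_max"])))

    if len(tensions) > 1:
        raise TableSchemaError(f"inconsistent tension ranges in {path}")
    tension = tensions.pop() if tensions else SPECIFIC_TENSION_RANGE
    return ParameterRanges(muscles=muscles, tension=tension)
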