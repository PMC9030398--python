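"""Random planar joint instances with the statistical structure of the model.

PCSAs and moment arms are drawn uniformly within literature-style bounds (the
default spans are the global extremes of the packaged sensitivity table:
PCSA 30-850 mm^2, arms 0-30 mm, tension 0.2-1.0 N/mm^2).  Only ranges are
reported in the anatomy literature, so uniform draws are the least-informative
choice; the distribution is a config hook, not a claim about anatomy.

All randomness flows through one seeded :class:`numpy.random.Generator`, so a
fixed seed reproduces instances byte-identically across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .exceptions import ConfigError
from .statics import JointInstance

#: Default bounds, mm^2 / mm / N/mm^2 — global spans of the packaged ranges.
DEFAULT_PCSA_BOUNDS = (30.0, 850.0)
DEFAULT_ARM_BOUNDS = (0.0, 30.0)
DEFAULT_TENSION_BOUNDS = (0.2, 1.0)

#: Worked-example moment: 100 N at a 100 mm lever arm.
DEFAULT_MOMENT = 10000.0


@dataclass(frozen=True)
class GeneratorConfig:
    """Bounds, size and seed for random instance generation."""

    muscle_count: int = 3
    pcsa_bounds: tuple[float, float] = DEFAULT_PCSA_BOUNDS
    arm_bounds: tuple[float, float] = DEFAULT_ARM_BOUNDS
    tension_bounds: tuple[float, float] = DEFAULT_TENSION_BOUNDS
    moment: float = DEFAULT_MOMENT  # N*mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.muscle_count < 1:
            raise ConfigError("muscle_count must be >= 1")
        for name, (lo, hi) in (
            ("pcsa_bounds", self.pcsa_bounds),
            ("arm_bounds", self.arm_bounds),
            ("tension_bounds", self.tension_bounds),
        ):
            if lo > hi:
                raise ConfigError(f"{name} must be ordered (min <= max)")
        if self.pcsa_bounds[1] <= 0:
            raise ConfigError("pcsa upper bound must be positive")
        if self.arm_bounds[1] <= 0:
            raise ConfigError(
                "arm upper bound must be positive (an all-zero-arm instance "
                "can never balance a moment)"
            )
        if self.moment < 0:
            raise ConfigError("moment must be >= 0")


def generate_instance(
    config: GeneratorConfig, rng: Optional[np.random.Generator] = None
) -> JointInstance:
    """Draw one joint instance uniformly within the configured bounds.

    Guarantees at least one strictly positive moment arm (redraws the arm
    vector otherwise) so the instance is always solvable.  Passing an
    external ``rng`` lets callers stream many instances from one generator;
    otherwise a fresh generator is seeded from ``config.seed``.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m = config.muscle_count
    # PCSA must be strictly positive: redraw exact-zero draws (measure zero).
    pcsa = rng.uniform(max(config.pcsa_bounds[0], 1e-9), config.pcsa_bounds[1], m)
    arms = rng.uniform(*config.arm_bounds, m)
    while not np.any(arms > 0):
        arms = rng.uniform(*config.arm_bounds, m)
    return JointInstance(
        names=tuple(f"m{i + 1}" for i in range(m)),
        pcsa=tuple(pcsa),
        arms=tuple(arms),
        moment=config.moment,
    )


def generate_instances(config: GeneratorConfig, count: int) -> Iterator[JointInstance]:
    """Stream ``count`` instances from one generator seeded by the config."""
    rng = np.random.default_rng(config.seed)
    for _ in range(count):
        yield generate_instance(config, rng=rng)


def worked_example_instance() -> JointInstance:
    """The canonical three-extensor wrist instance used throughout the docs.

    ECU/ECRB/ECRL with PCSAs 480/450/370 mm^2 (summing to 1300 mm^2), mean
    extension moment arms 6/12/7 mm, balancing the 10 N*m (= 10000 N*mm)
    moment of a 100 N load at a 10 cm lever arm.
    """
    return JointInstance(
        names=("ECU", "ECRB", "ECRL"),
        pcsa=(480.0, 450.0, 370.0),
        arms=(6.0, 12.0, 7.0),
        moment=10000.0,
        direction="extension",
    )
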